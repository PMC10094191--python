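"""Codon-usage indices: codonW composition conventions, ENc, CAI, CBI/Fop,
protein GRAVY/aromaticity, and the assembled per-gene table."""

import math
import random

import pytest

from codonbias import (
    STANDARD,
    CAIReference,
    CodingSequence,
    CodonCountTable,
    CodonUsageError,
    GroupSpec,
    SyntheticSpec,
    cai,
    cbi_fop,
    count_codons,
    enc,
    gc_content,
    generate,
    gravy_aromo,
    index_table,
    pooled_counts,
    rscu,
    third_position_composition,
)
from codonbias.usage_indices import (
    frame_to_records,
    read_index_tsv,
    records_to_frame,
    translate_cds,
    write_index_tsv,
)

# Kyte–Doolittle hydropathy, stated independently of the implementation path.
KD = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}


class TestComposition:
    def test_brute_force_denominators_table3(self, citxet):
        """The could-have denominators enumerate to 254/254/208/191 (U/C/A/G)."""
        counts = citxet["counts"].counts
        for base, expected_den, expected_num in [
            ("U", 254, 111), ("C", 254, 70), ("A", 208, 76), ("G", 191, 43),
        ]:
            den = num = 0
            for codons in STANDARD.synonymous_families.values():
                if any(c[2] == base for c in codons):
                    den += sum(counts[c] for c in codons)
                    num += sum(counts[c] for c in codons if c[2] == base)
            assert (num, den) == (expected_num, expected_den)

    def test_citxet_matches_published_row(self, citxet):
        comp = third_position_composition(citxet["counts"])
        assert comp.u3s == pytest.approx(43.70, abs=0.01)
        assert comp.c3s == pytest.approx(27.56, abs=0.01)
        assert comp.a3s == pytest.approx(36.54, abs=0.01)
        assert comp.g3s == pytest.approx(22.51, abs=0.01)
        assert round(comp.gc3s, 1) == 37.7

    def test_a3s_saturation(self):
        t = CodonCountTable("g", {"AGA": 5, "GCA": 3, "CAA": 2})
        assert third_position_composition(t).a3s == 100.0

    def test_no_synonymous_codons_is_error(self):
        with pytest.raises(CodonUsageError):
            third_position_composition(CodonCountTable("g", {"AUG": 3}))


class TestGcContent:
    @pytest.mark.parametrize("seq,expected", [("GCGC", 100.0), ("AUAU", 0.0)])
    def test_trivial(self, seq, expected):
        assert gc_content(CodingSequence("g", seq)) == expected

    def test_published_mean(self, table1):
        assert table1["gc"].mean() == pytest.approx(50.9, abs=0.05)


class TestEnc:
    def test_single_codon_per_family_is_20(self):
        counts = {fam[0]: 100 for fam in STANDARD.synonymous_families.values()}
        assert enc(CodonCountTable("g", counts)) == pytest.approx(20.0)

    def test_uniform_large_counts_approach_61(self):
        counts = {
            c: 10_000
            for fam in STANDARD.synonymous_families.values()
            for c in fam
        }
        assert enc(CodonCountTable("g", counts)) == pytest.approx(61.0, abs=0.5)

    def test_citxet_value(self, citxet):
        assert enc(citxet["counts"]) == pytest.approx(47.39, abs=0.5)

    def test_published_mean(self, table1):
        assert table1["enc"].mean() == pytest.approx(48.60, abs=0.05)

    def test_within_family_label_permutation_invariance(self, citxet):
        counts = dict(citxet["counts"].counts)
        rng = random.Random(5)
        for codons in STANDARD.synonymous_families.values():
            vals = [counts[c] for c in codons]
            rng.shuffle(vals)
            counts.update(zip(codons, vals))
        assert enc(CodonCountTable("p", counts)) == pytest.approx(
            enc(citxet["counts"])
        )

    def test_missing_ile_class_imputed(self):
        counts = {
            c: 10
            for aa, fam in STANDARD.synonymous_families.items()
            if aa != "I"
            for c in fam
        }
        value = enc(CodonCountTable("g", counts))
        assert 20.0 <= value <= 61.0

    def test_stochastically_decreasing_in_concentration(self):
        def mean_enc(concentration, seed):
            spec = SyntheticSpec(
                n_genes=5, codons_per_gene=200, gc3_bias=0.7,
                concentration=concentration, seed=seed,
            )
            return sum(enc(count_codons(g)) for g in generate(spec)) / 5

        flat = [mean_enc(0.5, s) for s in range(5)]
        sharp = [mean_enc(3.0, s) for s in range(5)]
        assert sum(sharp) / 5 < sum(flat) / 5


class TestCai:
    def _ref(self, weights):
        return CAIReference(weights, provenance="test")

    def test_all_optimal_is_one(self):
        ref = self._ref({"UUU": 1.0, "UUC": 0.5})
        t = CodonCountTable("g", {"UUU": 30})
        assert cai(t, ref) == pytest.approx(1.0)

    def test_geometric_mean_closed_form(self):
        ref = self._ref({"UUU": 0.25, "UUC": 1.0})
        t = CodonCountTable("g", {"UUU": 1, "UUC": 1})
        assert cai(t, ref) == pytest.approx(0.5)

    def test_maximal_codon_gene_scores_one(self):
        """A 300-codon gene built from the reference's own w=1 codons."""
        rng = random.Random(3)
        weights, best = {}, {}
        for aa, fam in STANDARD.synonymous_families.items():
            best[aa] = rng.choice(fam)
            for c in fam:
                weights[c] = 1.0 if c == best[aa] else 0.2
        gene_counts = {}
        for _ in range(300):
            aa = rng.choice(list(best))
            gene_counts[best[aa]] = gene_counts.get(best[aa], 0) + 1
        assert cai(CodonCountTable("g", gene_counts), self._ref(weights)) == 1.0

    def test_length_duplication_invariance(self, citxet):
        ref = CAIReference.from_counts(citxet["counts"])
        single = cai(citxet["counts"], ref)
        doubled = pooled_counts([citxet["counts"], citxet["counts"]])
        assert cai(doubled, ref) == pytest.approx(single, rel=1e-12)

    def test_empty_overlap_is_error(self):
        ref = self._ref({"UUU": 1.0})
        with pytest.raises(CodonUsageError):
            cai(CodonCountTable("g", {"GGG": 5}), ref)

    def test_family_max_must_be_one(self):
        with pytest.raises(CodonUsageError):
            CAIReference({"UUU": 0.5, "UUC": 0.7})


class TestCbiFop:
    def test_all_optimal(self):
        t = CodonCountTable("g", {"UUU": 10, "AAA": 5})
        cbi, fop = cbi_fop(t, {"UUU", "AAA"})
        assert fop == 1.0
        assert cbi == pytest.approx(1.0)

    def test_uniform_usage_gives_zero_cbi(self):
        counts = {
            c: 12
            for fam in STANDARD.synonymous_families.values()
            for c in fam
        }
        optimal = {fam[0] for fam in STANDARD.synonymous_families.values()}
        cbi, _ = cbi_fop(CodonCountTable("g", counts), optimal)
        assert cbi == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_toy(self):
        # Phe 6+4 and Lys 7+3; optimal {UUU, AAA}:
        # N_syn=20, N_opt=13, N_rand=10 -> Fop=0.65, CBI=0.3
        t = CodonCountTable("g", {"UUU": 6, "UUC": 4, "AAA": 7, "AAG": 3})
        cbi, fop = cbi_fop(t, {"UUU", "AAA"})
        assert fop == pytest.approx(0.65)
        assert cbi == pytest.approx(0.3)

    def test_non_synonymous_optimal_rejected(self):
        with pytest.raises(CodonUsageError):
            cbi_fop(CodonCountTable("g", {"UUU": 1}), {"AUG"})


class TestGravyAromo:
    def test_poly_ala_gravy(self):
        seq = CodingSequence("g", "GCU" * 30)
        gravy, _ = gravy_aromo(seq)
        assert gravy == pytest.approx(1.8)

    def test_poly_phe_aromaticity(self):
        seq = CodingSequence("g", "UUU" * 30)
        _, aromo = gravy_aromo(seq)
        assert aromo == 1.0

    def test_residue_wise_oracle(self, synthetic_genes):
        seq = synthetic_genes[0]
        protein = translate_cds(seq)
        expected = sum(KD[a] for a in protein) / len(protein)
        gravy, aromo = gravy_aromo(seq)
        assert gravy == pytest.approx(expected, abs=1e-9)
        assert aromo == pytest.approx(
            sum(protein.count(a) for a in "FYW") / len(protein)
        )

    def test_internal_stop_reported_with_position(self):
        seq = CodingSequence("g", "AUGUAAUUU")
        with pytest.raises(CodonUsageError, match="codon 2"):
            gravy_aromo(seq)


class TestIndexTable:
    def test_synthetic_sweep_invariants(self, synthetic_genes):
        records = index_table(synthetic_genes)
        assert len(records) == 20
        for rec in records:
            assert rec.error is None
            assert 20.0 <= rec.enc <= 61.0
            for name in ("u3s", "c3s", "a3s", "g3s", "gc3s", "gc"):
                assert 0.0 <= getattr(rec, name) <= 100.0
            assert -4.5 <= rec.gravy <= 4.5
            assert 0.0 <= rec.aromo <= 1.0
            assert math.isnan(rec.cai)  # no reference supplied

    def test_order_is_input_order(self, synthetic_genes):
        records = index_table(synthetic_genes)
        assert [r.gene_id for r in records] == [g.gene_id for g in synthetic_genes]

    def test_per_gene_failure_is_not_fatal(self, synthetic_genes):
        bad = CodingSequence("bad", "AUGUAAUUUUAA")  # internal stop
        records = index_table([synthetic_genes[0], bad])
        assert records[0].error is None
        assert records[1].error is not None

    def test_published_table_roundtrip(self, table1, tmp_path):
        records = frame_to_records(table1.drop(columns=["accession"]))
        write_index_tsv(records, tmp_path / "t1.tsv")
        back = read_index_tsv(tmp_path / "t1.tsv")
        assert records_to_frame(back).equals(records_to_frame(records))
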