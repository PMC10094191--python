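"""Per-gene codon-usage indices.

Implements the classic codonW-style panel: synonymous third-position base
composition (U3s/C3s/A3s/G3s, GC3s), whole-CDS GC, Wright's effective number
of codons (ENc), the codon adaptation index (CAI), the codon bias index and
frequency of optimal codons (CBI/Fop), and the protein-level GRAVY and
aromaticity scores.

Composition conventions
-----------------------
``X3s`` follows the codonW "could-have" denominator: the proportion of
synonymous codons ending in base X **among codons whose synonymous family
contains at least one X-ending member**.  A lysine codon (AAA/AAG) can never
end in C, so lysine codons are excluded from the C3s denominator.  ``GC3s``
uses all synonymous codons as denominator.

ENc
---
Within each synonymous family with ``n`` observed codons and usage
proportions ``p_i``, the homozygosity estimate is
``F = (n * sum(p_i^2) - 1) / (n - 1)``.  ``F`` is averaged within the
degeneracy classes {2, 3, 4, 6} and::

    ENc = 2 + 9/F2 + 1/F3 + 5/F4 + 3/F6

Families with ``n <= 1`` or ``F <= 0`` are excluded from their class mean; a
wholly missing 3-fold class (Ile unobserved) is imputed as the mean of F2
and F4; the result is capped at 61.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, fields as dataclass_fields
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import pandas as pd
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .codon_core import (
    STANDARD,
    CodingSequence,
    CodonCountTable,
    CodonUsageError,
    GeneticCode,
    count_codons,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Composition",
    "UsageIndexRecord",
    "CAIReference",
    "third_position_composition",
    "gc_content",
    "enc",
    "cai",
    "cbi_fop",
    "gravy_aromo",
    "translate_cds",
    "index_table",
    "records_to_frame",
    "frame_to_records",
    "write_index_tsv",
    "read_index_tsv",
]


class Composition(NamedTuple):
    u3s: float
    c3s: float
    a3s: float
    g3s: float
    gc3s: float


@dataclass
class UsageIndexRecord:
    """One row of the per-gene index table; NaN marks indices not computed."""

    gene_id: str
    u3s: float = math.nan
    c3s: float = math.nan
    a3s: float = math.nan
    g3s: float = math.nan
    gc3s: float = math.nan
    gc: float = math.nan
    cai: float = math.nan
    cbi: float = math.nan
    fop: float = math.nan
    enc: float = math.nan
    gravy: float = math.nan
    aromo: float = math.nan
    error: str | None = None


#: Table column order for the wide index TSV.
INDEX_COLUMNS = [
    "u3s", "c3s", "a3s", "g3s", "gc3s", "gc",
    "cai", "cbi", "fop", "enc", "gravy", "aromo",
]


@dataclass(frozen=True)
class CAIReference:
    """Relative-adaptiveness weights ``w`` in (0, 1], max 1 within each family.

    There is no hidden default reference set: callers supply one explicitly,
    either as a weight table or derived from a reference gene set via
    :meth:`from_counts`.
    """

    weights: Mapping[str, float]
    provenance: str = ""
    code: GeneticCode = field(default=STANDARD, repr=False)

    def __post_init__(self) -> None:
        w = dict(self.weights)
        unknown = set(w) - self.code.synonymous_codons
        if unknown:
            raise CodonUsageError(f"CAI weights for non-synonymous codons: {sorted(unknown)}")
        for codon, val in w.items():
            if not (0.0 < val <= 1.0):
                raise CodonUsageError(f"CAI weight for {codon} out of (0, 1]: {val}")
        for aa, codons in self.code.synonymous_families.items():
            fam = [w[c] for c in codons if c in w]
            if fam and not math.isclose(max(fam), 1.0, rel_tol=0, abs_tol=1e-9):
                raise CodonUsageError(f"family {aa}: maximum CAI weight must be 1")
        object.__setattr__(self, "weights", w)

    @classmethod
    def from_counts(
        cls,
        reference: CodonCountTable,
        provenance: str = "derived from reference counts",
        zero_weight: float = 0.01,
    ) -> "CAIReference":
        """w = count / max family count; unobserved codons get ``zero_weight``."""
        w: dict[str, float] = {}
        for aa, codons in reference.code.synonymous_families.items():
            top = max(reference.counts[c] for c in codons)
            if top == 0:
                continue  # family absent from the reference: weights undefined
            for c in codons:
                w[c] = reference.counts[c] / top if reference.counts[c] else zero_weight
        return cls(w, provenance, reference.code)

    @classmethod
    def read_tsv(cls, path: str | Path, provenance: str | None = None) -> "CAIReference":
        df = pd.read_csv(path, sep="\t", comment="#")
        return cls(
            dict(zip(df["codon"], df["weight"].astype(float))),
            provenance or f"loaded from {path}",
        )

    def write_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            sorted(self.weights.items()), columns=["codon", "weight"]
        ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Base composition
# ---------------------------------------------------------------------------

def third_position_composition(counts: CodonCountTable) -> Composition:
    """codonW-convention synonymous third-position composition, in percent."""
    code = counts.code
    if counts.synonymous_total == 0:
        raise CodonUsageError(
            f"{counts.gene_id}: no synonymous codons, composition undefined"
        )
    values: dict[str, float] = {}
    for base in "UCAG":
        ending = 0
        capable = 0
        for codons in code.synonymous_families.values():
            if not any(c[2] == base for c in codons):
                continue
            fam_total = sum(counts.counts[c] for c in codons)
            capable += fam_total
            ending += sum(counts.counts[c] for c in codons if c[2] == base)
        values[base] = 100.0 * ending / capable if capable else math.nan
    gc_ending = sum(
        counts.counts[c] for c in code.synonymous_codons if c[2] in "GC"
    )
    gc3s = 100.0 * gc_ending / counts.synonymous_total
    return Composition(values["U"], values["C"], values["A"], values["G"], gc3s)


def gc_content(seq: CodingSequence) -> float:
    """Whole-CDS G+C content in percent."""
    s = seq.sequence
    return 100.0 * (s.count("G") + s.count("C")) / len(s)


# ---------------------------------------------------------------------------
# ENc
# ---------------------------------------------------------------------------

def _family_homozygosity(fam_counts: Sequence[int]) -> float | None:
    n = sum(fam_counts)
    if n <= 1:
        return None
    sum_p2 = sum((c / n) ** 2 for c in fam_counts)
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc(counts: CodonCountTable) -> float:
    """Wright's effective number of codons, in [20, 61]."""
    code = counts.code
    class_f: dict[int, list[float]] = {2: [], 3: [], 4: [], 6: []}
    for aa, codons in code.synonymous_families.items():
        f = _family_homozygosity([counts.counts[c] for c in codons])
        if f is not None:
            class_f[len(codons)].append(f)
    means = {k: (sum(v) / len(v) if v else None) for k, v in class_f.items()}
    if means[3] is None and means[2] is not None and means[4] is not None:
        means[3] = (means[2] + means[4]) / 2.0
    missing = [k for k in (2, 3, 4, 6) if means[k] is None]
    if missing:
        raise CodonUsageError(
            f"{counts.gene_id}: ENc undefined, no computable family in "
            f"degeneracy class(es) {missing}"
        )
    value = 2.0 + 9.0 / means[2] + 1.0 / means[3] + 5.0 / means[4] + 3.0 / means[6]
    return min(value, 61.0)


# ---------------------------------------------------------------------------
# CAI, CBI, Fop
# ---------------------------------------------------------------------------

def cai(counts: CodonCountTable, ref: CAIReference) -> float:
    """Geometric mean of reference weights over the gene's synonymous codons.

    Codons absent from the reference are skipped (the skipped occurrence
    count is logged); Met, Trp and stop codons never contribute.
    """
    log_sum = 0.0
    n = 0
    skipped = 0
    for codon in counts.code.synonymous_codons:
        k = counts.counts[codon]
        if k == 0:
            continue
        w = ref.weights.get(codon)
        if w is None:
            skipped += k
            continue
        log_sum += k * math.log(w)
        n += k
    if skipped:
        logger.info(
            "%s: %d codon occurrences skipped (no CAI reference weight)",
            counts.gene_id, skipped,
        )
    if n == 0:
        raise CodonUsageError(
            f"{counts.gene_id}: no overlap between gene codons and CAI reference"
        )
    return math.exp(log_sum / n)


def cbi_fop(counts: CodonCountTable, optimal: Iterable[str]) -> tuple[float, float]:
    """Codon bias index and frequency of optimal codons.

    ``Fop = N_opt / N_syn``; ``CBI = (N_opt - N_rand) / (N_syn - N_rand)``
    where ``N_rand`` is the optimal count expected under uniform usage
    within each family.
    """
    code = counts.code
    opt = set(optimal)
    if not opt:
        raise CodonUsageError("optimal codon set is empty")
    if not opt <= code.synonymous_codons:
        raise CodonUsageError(
            f"non-synonymous codons in optimal set: {sorted(opt - code.synonymous_codons)}"
        )
    n_syn = counts.synonymous_total
    if n_syn == 0:
        raise CodonUsageError(f"{counts.gene_id}: no synonymous codons")
    n_opt = sum(counts.counts[c] for c in opt)
    n_rand = 0.0
    for codons in code.synonymous_families.values():
        fam_total = sum(counts.counts[c] for c in codons)
        n_in_fam = sum(1 for c in codons if c in opt)
        n_rand += fam_total * n_in_fam / len(codons)
    fop = n_opt / n_syn
    cbi = (n_opt - n_rand) / (n_syn - n_rand) if n_syn != n_rand else math.nan
    return cbi, fop


# ---------------------------------------------------------------------------
# Protein-level indices
# ---------------------------------------------------------------------------

def translate_cds(seq: CodingSequence, code: GeneticCode = STANDARD) -> str:
    """Translate a CDS, dropping one trailing stop; internal stops are errors."""
    rna = seq.sequence
    if len(rna) % 3:
        raise CodonUsageError(f"{seq.gene_id}: length not a multiple of 3")
    protein = code.translate(rna)
    if protein.endswith("*"):
        protein = protein[:-1]
    if "*" in protein:
        raise CodonUsageError(
            f"{seq.gene_id}: internal stop codon at codon {protein.index('*') + 1}"
        )
    return protein


def gravy_aromo(seq: CodingSequence, code: GeneticCode = STANDARD) -> tuple[float, float]:
    """GRAVY (mean Kyte–Doolittle hydropathy) and aromaticity of the protein."""
    protein = translate_cds(seq, code)
    if not protein:
        raise CodonUsageError(f"{seq.gene_id}: empty protein")
    analysis = ProteinAnalysis(protein)
    return analysis.gravy(), analysis.aromaticity()


# ---------------------------------------------------------------------------
# Assembly
# ---------------------------------------------------------------------------

def index_table(
    seqs: Sequence[CodingSequence],
    ref: CAIReference | None = None,
    optimal: Iterable[str] | None = None,
    frame_policy: str = "strict",
) -> list[UsageIndexRecord]:
    """One :class:`UsageIndexRecord` per gene, in input order.

    Per-gene failures are captured in the record's ``error`` field; they do
    not abort the batch.  CAI (and CBI/Fop) stay NaN unless a reference
    (resp. optimal set) is supplied.
    """
    if not seqs:
        raise CodonUsageError("no sequences supplied")
    optimal = set(optimal) if optimal else None
    records = []
    for seq in seqs:
        rec = UsageIndexRecord(seq.gene_id)
        try:
            counts = count_codons(seq, frame_policy)
            comp = third_position_composition(counts)
            rec.u3s, rec.c3s, rec.a3s, rec.g3s, rec.gc3s = comp
            rec.gc = gc_content(seq)
            rec.enc = enc(counts)
            rec.gravy, rec.aromo = gravy_aromo(seq, counts.code)
            if ref is not None:
                rec.cai = cai(counts, ref)
            if optimal:
                rec.cbi, rec.fop = cbi_fop(counts, optimal)
        except CodonUsageError as exc:
            rec.error = str(exc)
            logger.warning("%s: %s", seq.gene_id, exc)
        records.append(rec)
    return records


def records_to_frame(records: Sequence[UsageIndexRecord]) -> pd.DataFrame:
    rows = {r.gene_id: [getattr(r, c) for c in INDEX_COLUMNS] for r in records}
    df = pd.DataFrame.from_dict(rows, orient="index", columns=INDEX_COLUMNS)
    df.index.name = "gene"
    return df


def frame_to_records(df: pd.DataFrame) -> list[UsageIndexRecord]:
    recs = []
    known = {f.name for f in dataclass_fields(UsageIndexRecord)}
    for gene, row in df.iterrows():
        kwargs = {c: float(row[c]) for c in df.columns if c in known}
        recs.append(UsageIndexRecord(str(gene), **kwargs))
    return recs


#: Report rounding per column (published precision: three decimals for
#: CAI/CBI, two elsewhere); in-memory values stay full precision.
_REPORT_DECIMALS = {c: 3 if c in ("cai", "cbi") else 2 for c in INDEX_COLUMNS}


def write_index_tsv(records: Sequence[UsageIndexRecord], path: str | Path) -> None:
    """Wide per-gene index table rounded to report precision."""
    records_to_frame(records).round(_REPORT_DECIMALS).to_csv(path, sep="\t")


def read_index_tsv(path: str | Path) -> list[UsageIndexRecord]:
    return frame_to_records(pd.read_csv(path, sep="\t", comment="#", index_col="gene"))
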