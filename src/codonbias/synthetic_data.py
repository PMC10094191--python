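"""Synthetic CDS generation with controlled codon-usage structure, plus
packaged fixtures of the published codon-count and index tables.

The generator emulates gene sets whose within-family codon choice is steered
by a third-position GC bias: each synonymous family's codon probabilities
put weight ``gc3_bias`` on G/C-ending synonyms and ``1 - gc3_bias`` on
A/U-ending synonyms, sharpened by a concentration exponent.  Amino-acid
composition defaults to the relative synonymous-family totals observed in
the pooled 20-gene table, so synthetic genes exercise the same family-size
structure (and hence the same ENc degeneracy classes) as the study data.
Group structure (e.g. a G/C-biased versus an A/U-biased clade) is expressed
as a list of group specifications with distinct parameters.

Generation is fully deterministic given the spec's integer seed.
"""

from __future__ import annotations

import hashlib
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .codon_core import (
    AA3_TO_AA1,
    STANDARD,
    CodingSequence,
    CodonCountTable,
    CodonUsageError,
    GeneticCode,
)

__all__ = [
    "GroupSpec",
    "SyntheticSpec",
    "Fixture",
    "family_codon_probs",
    "expected_gc3s",
    "generate",
    "load_fixture",
    "FIXTURE_NAMES",
]

#: Synonymous-family totals of the pooled 20-gene count table (4500 codons);
#: used as the default amino-acid composition of synthetic genes.
DEFAULT_AA_WEIGHTS: dict[str, int] = {
    "F": 326, "L": 288, "I": 207, "V": 278, "S": 322, "P": 239, "T": 263,
    "A": 308, "Y": 255, "H": 102, "Q": 217, "N": 198, "K": 245, "D": 336,
    "E": 174, "C": 79, "R": 298, "G": 365,
}


@dataclass(frozen=True)
class GroupSpec:
    """Parameters of one gene group within a synthetic set."""

    label: str
    n_genes: int
    gc3_bias: float = 0.5
    concentration: float = 1.0


@dataclass(frozen=True)
class SyntheticSpec:
    """Specification of a synthetic CDS set.

    ``gc3_bias`` in [0, 1] steers within-family probability mass toward
    G/C-ending synonyms; ``concentration`` sharpens (>1) or flattens (<1)
    the within-family skew, with ``math.inf`` collapsing each family onto a
    single codon (alphabetically first among the maximal weights).  When
    ``groups`` is given it overrides ``n_genes``/``gc3_bias``/
    ``concentration`` per group.
    """

    n_genes: int = 20
    codons_per_gene: int = 225
    gc3_bias: float = 0.5
    concentration: float = 1.0
    aa_weights: Mapping[str, float] | None = None
    groups: tuple[GroupSpec, ...] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.gc3_bias <= 1.0:
            raise CodonUsageError("gc3_bias must be in [0, 1]")
        if self.codons_per_gene < 1 or self.n_genes < 1:
            raise CodonUsageError("n_genes and codons_per_gene must be positive")

    def resolved_groups(self) -> tuple[GroupSpec, ...]:
        if self.groups:
            return self.groups
        return (GroupSpec("synth", self.n_genes, self.gc3_bias, self.concentration),)

    def resolved_aa_weights(self) -> dict[str, float]:
        w = dict(self.aa_weights) if self.aa_weights else dict(DEFAULT_AA_WEIGHTS)
        bad = set(w) - set(STANDARD.synonymous_families)
        if bad:
            raise CodonUsageError(f"aa_weights for non-synonymous families: {sorted(bad)}")
        if any(v < 0 for v in w.values()) or sum(w.values()) <= 0:
            raise CodonUsageError("aa_weights must be non-negative with positive sum")
        return w


def family_codon_probs(
    gc3_bias: float,
    concentration: float = 1.0,
    code: GeneticCode = STANDARD,
) -> dict[str, tuple[tuple[str, ...], np.ndarray]]:
    """Per-family codon sampling probabilities implied by a GC3 bias.

    Weight ``gc3_bias`` per G/C-ending codon, ``1 - gc3_bias`` per
    A/U-ending codon, raised to ``concentration`` and normalized within the
    family.  An infinite concentration puts all mass on the alphabetically
    first maximal-weight codon.
    """
    out = {}
    for aa, codons in code.synonymous_families.items():
        w = np.array(
            [gc3_bias if c[2] in "GC" else 1.0 - gc3_bias for c in codons]
        )
        if math.isinf(concentration):
            p = np.zeros(len(codons))
            p[int(np.argmax(w))] = 1.0  # argmax takes the first (alphabetical) max
        else:
            wk = np.power(w, concentration, where=w > 0, out=np.zeros_like(w))
            if wk.sum() == 0:
                raise CodonUsageError(f"family {aa}: all codon weights vanish")
            p = wk / wk.sum()
        out[aa] = (codons, p)
    return out


def expected_gc3s(spec: SyntheticSpec, group: GroupSpec | None = None) -> float:
    """Closed-form expected GC3s (percent) of genes drawn from the spec."""
    g = group or spec.resolved_groups()[0]
    probs = family_codon_probs(g.gc3_bias, g.concentration)
    weights = spec.resolved_aa_weights()
    total = sum(weights.values())
    gc = sum(
        weights[aa] * sum(p for c, p in zip(codons, pvec) if c[2] in "GC")
        for aa, (codons, pvec) in probs.items()
        if aa in weights
    )
    return 100.0 * gc / total


def generate(spec: SyntheticSpec) -> list[CodingSequence]:
    """Draw a deterministic synthetic CDS set.

    Each gene samples ``codons_per_gene`` amino acids i.i.d. from the spec's
    composition, then one codon per residue from its family's probability
    vector; a start codon is prepended and a stop appended.
    """
    rng = np.random.default_rng(spec.seed)
    weights = spec.resolved_aa_weights()
    aa_list = sorted(weights)
    aa_p = np.array([weights[a] for a in aa_list], dtype=float)
    aa_p /= aa_p.sum()
    genes: list[CodingSequence] = []
    for group in spec.resolved_groups():
        probs = family_codon_probs(group.gc3_bias, group.concentration)
        for i in range(group.n_genes):
            aas = rng.choice(aa_list, size=spec.codons_per_gene, p=aa_p)
            codons = []
            for aa in aas:
                fam_codons, fam_p = probs[aa]
                codons.append(rng.choice(fam_codons, p=fam_p))
            seq = "AUG" + "".join(codons) + "UAA"
            genes.append(
                CodingSequence(
                    f"{group.label}{i + 1:03d}",
                    seq,
                    description=(
                        f"synthetic CDS group={group.label} "
                        f"gc3_bias={group.gc3_bias} "
                        f"concentration={group.concentration}"
                    ),
                )
            )
    return genes


# ---------------------------------------------------------------------------
# Packaged fixtures of the published tables
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Fixture:
    name: str
    payload: object
    sha256: str


_FIXTURE_FILES = {
    "citxet_counts": (
        "citxet_counts.tsv",
        "30950bae9d09606dd90a554b17e692dbb84ab44493240a8c65ea93f09c37bfa4",
    ),
    "xet20_counts": (
        "xet20_counts.tsv",
        "491c7d908803b619c00d9cf7e5c8bf5c5965ac3cc7c479a6cfcce8ff75c1a400",
    ),
    "table1_indices": (
        "table1_indices.tsv",
        "e4269939765416e1214c067c83703bd201e3c9c3fa7222794ae7a975a77f7a3e",
    ),
}

FIXTURE_NAMES = tuple(_FIXTURE_FILES)


def _read_fixture_bytes(filename: str, expected_sha: str) -> bytes:
    data = (resources.files("codonbias") / "fixtures" / filename).read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != expected_sha:
        raise CodonUsageError(
            f"fixture {filename}: checksum mismatch ({digest} != {expected_sha})"
        )
    return data


def load_fixture(name: str) -> Fixture:
    """Load and validate a packaged table fixture.

    * ``citxet_counts`` / ``xet20_counts`` → dict with a
      :class:`~codonbias.codon_core.CodonCountTable` (``counts``), the
      published per-codon RSCU values (``rscu_published``) and the
      preferred-codon flags (``preferred``).
    * ``table1_indices`` → per-gene index DataFrame (20 rows) with the
      accession column plus the twelve published usage indices.
    """
    if name not in _FIXTURE_FILES:
        raise CodonUsageError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURE_FILES)}"
        )
    filename, sha = _FIXTURE_FILES[name]
    data = _read_fixture_bytes(filename, sha)
    import io

    if name == "table1_indices":
        df = pd.read_csv(io.BytesIO(data), sep="\t", comment="#", index_col="gene")
        if df.shape[0] != 20:
            raise CodonUsageError("table1_indices fixture must have 20 rows")
        return Fixture(name, df, sha)

    df = pd.read_csv(io.BytesIO(data), sep="\t", comment="#")
    counts = {
        codon: int(cnt) for codon, cnt in zip(df["codon"], df["count"])
    }
    aa_check = {codon: AA3_TO_AA1[aa] for codon, aa in zip(df["codon"], df["amino_acid"])}
    for codon, aa in aa_check.items():
        if STANDARD.codon_to_aa[codon] != aa:
            raise CodonUsageError(f"fixture {name}: {codon} mislabelled as {aa}")
    table = CodonCountTable(name, counts)
    expected_total = {"citxet_counts": 300, "xet20_counts": 4500}[name]
    if table.synonymous_total != expected_total:
        raise CodonUsageError(
            f"fixture {name}: synonymous total {table.synonymous_total} "
            f"!= {expected_total}"
        )
    payload = {
        "counts": table,
        "rscu_published": dict(zip(df["codon"], df["rscu_published"].astype(float))),
        "preferred": frozenset(df.loc[df["preferred"] == 1, "codon"]),
    }
    return Fixture(name, payload, sha)
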