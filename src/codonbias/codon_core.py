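"""Genetic-code model, codon counting and relative synonymous codon usage (RSCU).

Codons are represented internally in RNA form (``AUG``, never ``ATG``); DNA
input is converted on read.  All downstream statistics distinguish the 59
*synonymous* codons — the 61 sense codons minus AUG (Met) and UGG (Trp),
whose amino acids admit no synonym — from stop codons, which are counted but
excluded from every synonymous statistic.

RSCU for codon *i* of amino acid *j*, whose synonymous family has ``N_i``
members and a total of ``T_j`` observed codons, is::

    RSCU_i = count_i * N_i / T_j

so the mean RSCU within a family is 1 whenever the family was observed at
all.  A family with zero observations yields *undefined* RSCU (NaN), which
is a different fact from RSCU = 0 (codon present in the gene's repertoire
but never used).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "CodonUsageError",
    "AlphabetError",
    "FrameError",
    "GeneticCode",
    "CodingSequence",
    "CodonCountTable",
    "RSCUProfile",
    "CODON_ORDER",
    "STANDARD_CODE",
    "count_codons",
    "rscu",
    "pooled_counts",
    "read_fasta",
    "write_counts_tsv",
    "read_counts_tsv",
    "write_rscu_tsv",
    "read_rscu_tsv",
]


class CodonUsageError(ValueError):
    """Base class for all input/contract violations in this package."""


class AlphabetError(CodonUsageError):
    """Sequence contains a character outside {A, C, G, T, U} or mixes T and U."""


class FrameError(CodonUsageError):
    """Sequence length is not a multiple of three under the strict frame policy."""


RNA_BASES = "ACGU"

#: Fixed alphabetical order of the 64 RNA codons used in every wide table.
CODON_ORDER: tuple[str, ...] = tuple("".join(c) for c in product(RNA_BASES, repeat=3))

# Standard genetic code, RNA codons, one-letter amino acids, '*' for stop.
_CODE_BY_AA = {
    "F": ("UUU", "UUC"),
    "L": ("UUA", "UUG", "CUU", "CUC", "CUA", "CUG"),
    "I": ("AUU", "AUC", "AUA"),
    "M": ("AUG",),
    "V": ("GUU", "GUC", "GUA", "GUG"),
    "S": ("UCU", "UCC", "UCA", "UCG", "AGU", "AGC"),
    "P": ("CCU", "CCC", "CCA", "CCG"),
    "T": ("ACU", "ACC", "ACA", "ACG"),
    "A": ("GCU", "GCC", "GCA", "GCG"),
    "Y": ("UAU", "UAC"),
    "H": ("CAU", "CAC"),
    "Q": ("CAA", "CAG"),
    "N": ("AAU", "AAC"),
    "K": ("AAA", "AAG"),
    "D": ("GAU", "GAC"),
    "E": ("GAA", "GAG"),
    "C": ("UGU", "UGC"),
    "W": ("UGG",),
    "R": ("CGU", "CGC", "CGA", "CGG", "AGA", "AGG"),
    "G": ("GGU", "GGC", "GGA", "GGG"),
    "*": ("UAA", "UAG", "UGA"),
}

STANDARD_CODE: dict[str, str] = {
    codon: aa for aa, codons in _CODE_BY_AA.items() for codon in codons
}

AA3_TO_AA1 = {
    "Phe": "F", "Leu": "L", "Ile": "I", "Met": "M", "Val": "V", "Ser": "S",
    "Pro": "P", "Thr": "T", "Ala": "A", "Tyr": "Y", "His": "H", "Gln": "Q",
    "Asn": "N", "Lys": "K", "Asp": "D", "Glu": "E", "Cys": "C", "Trp": "W",
    "Arg": "R", "Gly": "G",
}
AA1_TO_AA3 = {v: k for k, v in AA3_TO_AA1.items()}


@dataclass(frozen=True)
class GeneticCode:
    """A codon → amino-acid table plus the synonymous-family structure.

    The standard code partitions its 18 multi-codon families into degeneracy
    classes: nine 2-fold families, one 3-fold family (Ile), five 4-fold
    families and three 6-fold families (Leu, Ser, Arg); their 59 codons are
    the synonymous codons on which RSCU and related statistics are defined.
    """

    codon_to_aa: Mapping[str, str]
    families: Mapping[str, tuple[str, ...]] = field(init=False, repr=False)
    synonymous_codons: frozenset[str] = field(init=False, repr=False)
    stop_codons: frozenset[str] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(CODON_ORDER):
            raise CodonUsageError("genetic code must map exactly the 64 RNA codons")
        fams: dict[str, list[str]] = {}
        for codon in CODON_ORDER:  # alphabetical within each family
            fams.setdefault(self.codon_to_aa[codon], []).append(codon)
        object.__setattr__(
            self, "families", {aa: tuple(cs) for aa, cs in fams.items()}
        )
        stops = frozenset(self.families.get("*", ()))
        syn = frozenset(
            c
            for aa, cs in self.families.items()
            if aa != "*" and len(cs) > 1
            for c in cs
        )
        object.__setattr__(self, "stop_codons", stops)
        object.__setattr__(self, "synonymous_codons", syn)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls(STANDARD_CODE)

    def aa_of(self, codon: str) -> str:
        return self.codon_to_aa[codon]

    def family(self, aa: str) -> tuple[str, ...]:
        """Synonymous codons of ``aa`` in alphabetical RNA order."""
        return self.families[aa]

    @property
    def synonymous_families(self) -> dict[str, tuple[str, ...]]:
        """Multi-codon sense families only (Met, Trp and stops excluded)."""
        return {
            aa: cs
            for aa, cs in self.families.items()
            if aa != "*" and len(cs) > 1
        }

    @property
    def degeneracy_classes(self) -> dict[int, tuple[str, ...]]:
        """Family degeneracy → amino acids, e.g. ``{2: (...9 aa...), 3: ('I',), ...}``."""
        out: dict[int, list[str]] = {}
        for aa, cs in self.synonymous_families.items():
            out.setdefault(len(cs), []).append(aa)
        return {k: tuple(sorted(v)) for k, v in sorted(out.items())}

    def translate(self, rna: str) -> str:
        """Translate an in-frame RNA string; stops render as ``*``."""
        return "".join(
            self.codon_to_aa[rna[i : i + 3]] for i in range(0, len(rna), 3)
        )


STANDARD = GeneticCode.standard()

#: The 59 synonymous codons in fixed alphabetical RNA order.
SYNONYMOUS_CODON_ORDER: tuple[str, ...] = tuple(
    c for c in CODON_ORDER if c in STANDARD.synonymous_codons
)


def _normalize_sequence(raw: str) -> str:
    """Uppercase, validate the alphabet and return the RNA form."""
    seq = raw.upper()
    has_t = "T" in seq
    has_u = "U" in seq
    if has_t and has_u:
        raise AlphabetError("sequence mixes DNA (T) and RNA (U) alphabets")
    for pos, ch in enumerate(seq):
        if ch not in "ACGTU":
            raise AlphabetError(f"invalid character {ch!r} at position {pos}")
    return seq.replace("T", "U")


@dataclass(frozen=True)
class CodingSequence:
    """A labelled coding sequence; stored in RNA form regardless of input alphabet."""

    gene_id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise CodonUsageError(f"{self.gene_id}: empty sequence")
        object.__setattr__(self, "sequence", _normalize_sequence(self.sequence))

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class CodonCountTable:
    """Non-negative counts for all 64 codons of one gene (or a pooled set)."""

    gene_id: str
    counts: Mapping[str, int]
    code: GeneticCode = STANDARD

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in CODON_ORDER}
        unknown = set(self.counts) - set(CODON_ORDER)
        if unknown:
            raise CodonUsageError(f"unknown codons in count table: {sorted(unknown)}")
        if any(v < 0 for v in full.values()):
            raise CodonUsageError("negative codon count")
        object.__setattr__(self, "counts", full)

    @property
    def total_codons(self) -> int:
        return sum(self.counts.values())

    @property
    def synonymous_total(self) -> int:
        """Codons in the 59 synonymous positions (Met, Trp, stops excluded)."""
        return sum(self.counts[c] for c in self.code.synonymous_codons)

    def family_counts(self, aa: str) -> dict[str, int]:
        return {c: self.counts[c] for c in self.code.family(aa)}


@dataclass(frozen=True)
class RSCUProfile:
    """Per-codon RSCU over the 59 synonymous codons; NaN marks undefined values."""

    gene_id: str
    rscu: Mapping[str, float]
    family_sizes: Mapping[str, int]

    def defined_codons(self) -> frozenset[str]:
        return frozenset(c for c, v in self.rscu.items() if not math.isnan(v))

    def as_series(self) -> pd.Series:
        return pd.Series(
            [self.rscu[c] for c in SYNONYMOUS_CODON_ORDER],
            index=list(SYNONYMOUS_CODON_ORDER),
            name=self.gene_id,
        )


def count_codons(
    seq: CodingSequence,
    frame_policy: str = "strict",
    code: GeneticCode = STANDARD,
) -> CodonCountTable:
    """Count consecutive non-overlapping codons from position 0.

    ``frame_policy='strict'`` (default) rejects sequences whose length is not
    a multiple of three; ``'trim_tail'`` drops the trailing 1–2 bases.
    """
    if frame_policy not in ("strict", "trim_tail"):
        raise CodonUsageError(f"unknown frame policy {frame_policy!r}")
    rna = seq.sequence
    rem = len(rna) % 3
    if rem:
        if frame_policy == "strict":
            raise FrameError(
                f"{seq.gene_id}: length {len(rna)} is not a multiple of 3 "
                "(use frame_policy='trim_tail' to drop the tail)"
            )
        rna = rna[: len(rna) - rem]
    counts: dict[str, int] = {}
    for i in range(0, len(rna), 3):
        codon = rna[i : i + 3]
        counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(seq.gene_id, counts, code)


def rscu(counts: CodonCountTable) -> RSCUProfile:
    """RSCU per synonymous codon: ``count * family_size / family_total``.

    Families never observed in the gene yield NaN for every member codon.
    """
    code = counts.code
    values: dict[str, float] = {}
    sizes: dict[str, int] = {}
    for aa, codons in code.synonymous_families.items():
        sizes[aa] = len(codons)
        total = sum(counts.counts[c] for c in codons)
        for c in codons:
            values[c] = (
                counts.counts[c] * len(codons) / total if total > 0 else math.nan
            )
    return RSCUProfile(counts.gene_id, values, sizes)


def pooled_counts(
    tables: Sequence[CodonCountTable], gene_id: str = "pooled"
) -> CodonCountTable:
    """Element-wise sum of count tables (e.g. a whole gene set as one table)."""
    if not tables:
        raise CodonUsageError("cannot pool an empty list of count tables")
    summed = {c: sum(t.counts[c] for t in tables) for c in CODON_ORDER}
    return CodonCountTable(gene_id, summed, tables[0].code)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_fasta(path: str | Path) -> list[CodingSequence]:
    """Read a multi-record FASTA of CDS (DNA or RNA, wrapped lines, any case)."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append(
            CodingSequence(rec.id, str(rec.seq), description=rec.description)
        )
    if not records:
        raise CodonUsageError(f"no FASTA records found in {path}")
    return records


def write_counts_tsv(tables: Iterable[CodonCountTable], path: str | Path) -> None:
    """One row per gene, one column per codon in fixed alphabetical RNA order."""
    df = pd.DataFrame(
        [[t.counts[c] for c in CODON_ORDER] for t in tables],
        columns=list(CODON_ORDER),
        index=pd.Index([t.gene_id for t in tables], name="gene"),
    )
    df.to_csv(path, sep="\t")


def read_counts_tsv(path: str | Path) -> list[CodonCountTable]:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return [
        CodonCountTable(str(gene), {c: int(row[c]) for c in CODON_ORDER})
        for gene, row in df.iterrows()
    ]


def write_rscu_tsv(profiles: Iterable[RSCUProfile], path: str | Path) -> None:
    """RSCU matrix, genes × 59 codons, alphabetical RNA codon order; NaN blank."""
    df = pd.DataFrame([p.as_series() for p in profiles])
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_rscu_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="gene")
    return df[list(SYNONYMOUS_CODON_ORDER)]


def iter_codons(rna: str) -> Iterator[str]:
    """Yield consecutive in-frame codons of an RNA string."""
    for i in range(0, len(rna) - len(rna) % 3, 3):
        yield rna[i : i + 3]
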