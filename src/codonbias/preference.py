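"""Preferred- and optimal-codon screening from RSCU profiles.

Frequency classes bin each codon's RSCU at 1.0 and 1.5, with both boundaries
belonging to the middle bin (a codon at exactly 1.50 is *mid*, not *high*).
Preferred codons are screened by ΔRSCU — the difference in mean RSCU between
a high-bias and a low-bias gene group — with membership at ΔRSCU > 0.08 by
default.  A focal gene's *optimal* codons are the intersection of its
high-frequency codons (RSCU > 1.5) with the preferred set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .codon_core import CodonUsageError, RSCUProfile

__all__ = [
    "FrequencyClass",
    "PreferredCodonSet",
    "classify_frequency",
    "preferred_codons",
    "optimal_codons",
    "pattern_similarity",
    "write_preferred_tsv",
]

RSCU_HIGH = 1.5
RSCU_LOW = 1.0
DELTA_RSCU_THRESHOLD = 0.08


class FrequencyClass(Enum):
    HIGH = "high"        # RSCU > 1.5
    MID = "mid"          # 1.0 <= RSCU <= 1.5
    LOW = "low"          # RSCU < 1.0
    UNDEFINED = "undefined"  # family unobserved in this gene


def classify_frequency(
    profile: RSCUProfile,
    high: float = RSCU_HIGH,
    low: float = RSCU_LOW,
) -> dict[str, FrequencyClass]:
    """Total classification of the 59 synonymous codons by RSCU bin."""
    out = {}
    for codon, value in profile.rscu.items():
        if math.isnan(value):
            out[codon] = FrequencyClass.UNDEFINED
        elif value > high:
            out[codon] = FrequencyClass.HIGH
        elif value < low:
            out[codon] = FrequencyClass.LOW
        else:
            out[codon] = FrequencyClass.MID
    return out


def high_frequency_codons(profile: RSCUProfile, high: float = RSCU_HIGH) -> set[str]:
    """Codons with RSCU strictly above the high-frequency cutoff."""
    return {
        c for c, cls in classify_frequency(profile, high=high).items()
        if cls is FrequencyClass.HIGH
    }


@dataclass(frozen=True)
class PreferredCodonSet:
    """ΔRSCU screen result; ``members`` is recomputable from the other fields."""

    delta_rscu: Mapping[str, float]
    threshold: float
    high_group: tuple[str, ...]
    low_group: tuple[str, ...]
    members: frozenset[str] = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(
            self,
            "members",
            frozenset(
                c for c, d in self.delta_rscu.items()
                if not math.isnan(d) and d > self.threshold
            ),
        )


def _mean_rscu(profiles: Sequence[RSCUProfile]) -> dict[str, float]:
    codons = profiles[0].rscu.keys()
    out = {}
    for c in codons:
        vals = [p.rscu[c] for p in profiles if not math.isnan(p.rscu[c])]
        out[c] = sum(vals) / len(vals) if vals else math.nan
    return out


def preferred_codons(
    profiles: Sequence[RSCUProfile],
    grouping: str = "enc_quantile",
    fraction: float = 0.25,
    threshold: float = DELTA_RSCU_THRESHOLD,
    enc_values: Mapping[str, float] | None = None,
    high_group: Iterable[str] | None = None,
    low_group: Iterable[str] | None = None,
) -> PreferredCodonSet:
    """Screen preferred codons as those with ΔRSCU above ``threshold``.

    ΔRSCU(codon) = mean RSCU in the high-bias group − mean RSCU in the
    low-bias group.  Under ``grouping='enc_quantile'`` the high-bias group is
    the ``fraction`` of genes with the lowest ENc (strongest bias) and the
    low-bias group the same fraction with the highest ENc; ``enc_values``
    must then map every gene id to its ENc.  Under ``grouping='explicit'``
    the two disjoint gene-id groups are supplied directly.
    """
    by_id = {p.gene_id: p for p in profiles}
    if grouping == "enc_quantile":
        if enc_values is None:
            raise CodonUsageError("enc_quantile grouping requires enc_values")
        missing = set(by_id) - set(enc_values)
        if missing:
            raise CodonUsageError(f"no ENc value for gene(s): {sorted(missing)}")
        if not 0 < fraction <= 0.5:
            raise CodonUsageError("group fraction must be in (0, 0.5]")
        n_group = max(2, int(round(fraction * len(profiles))))
        ranked = sorted(by_id, key=lambda g: (enc_values[g], g))
        hi_ids, lo_ids = ranked[:n_group], ranked[-n_group:]
    elif grouping == "explicit":
        if high_group is None or low_group is None:
            raise CodonUsageError("explicit grouping requires both gene-id groups")
        hi_ids, lo_ids = list(high_group), list(low_group)
    else:
        raise CodonUsageError(f"unknown grouping {grouping!r}")

    if set(hi_ids) & set(lo_ids):
        raise CodonUsageError("high- and low-bias groups overlap")
    for gid in (*hi_ids, *lo_ids):
        if gid not in by_id:
            raise CodonUsageError(f"unknown gene id in grouping: {gid}")
    if len(hi_ids) < 2 or len(lo_ids) < 2:
        raise CodonUsageError("each contrast group needs at least two genes")

    hi_mean = _mean_rscu([by_id[g] for g in hi_ids])
    lo_mean = _mean_rscu([by_id[g] for g in lo_ids])
    delta = {c: hi_mean[c] - lo_mean[c] for c in hi_mean}
    return PreferredCodonSet(delta, threshold, tuple(hi_ids), tuple(lo_ids))


def optimal_codons(
    profile: RSCUProfile, preferred: PreferredCodonSet | Iterable[str]
) -> set[str]:
    """High-frequency codons (RSCU > 1.5) of the focal gene that are preferred."""
    members = (
        preferred.members
        if isinstance(preferred, PreferredCodonSet)
        else set(preferred)
    )
    return high_frequency_codons(profile) & set(members)


def pattern_similarity(
    p1: RSCUProfile, p2: RSCUProfile
) -> tuple[dict[str, bool], float]:
    """Per-codon usage-pattern agreement and its summary fraction.

    Two genes use a codon *similarly* when both RSCU values fall in the same
    bin of {<1.0, [1.0, 1.5], >1.5}.  The summary is the fraction of similar
    codons over codons defined in both profiles.
    """
    c1 = classify_frequency(p1)
    c2 = classify_frequency(p2)
    if set(c1) != set(c2):
        raise CodonUsageError("profiles are defined on different codon sets")
    verdicts = {}
    for codon in c1:
        if FrequencyClass.UNDEFINED in (c1[codon], c2[codon]):
            continue
        verdicts[codon] = c1[codon] is c2[codon]
    if not verdicts:
        raise CodonUsageError("no codon defined in both profiles")
    return verdicts, sum(verdicts.values()) / len(verdicts)


def write_preferred_tsv(preferred: PreferredCodonSet, path: str | Path) -> None:
    """Annotated ΔRSCU table: codon, delta_rscu, member flag."""
    df = pd.DataFrame(
        sorted(
            (c, d, int(c in preferred.members))
            for c, d in preferred.delta_rscu.items()
        ),
        columns=["codon", "delta_rscu", "member"],
    )
    df.to_csv(path, sep="\t", index=False)
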