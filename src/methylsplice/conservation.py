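"""Fraction-of-conserved-nucleotides statistics over interval sets.

A conservation track holds one score in [0, 1] per base (NaN where no
score exists; unscored bases are excluded from denominators, never counted
as zero).  The summary statistic is the pooled fraction of scored bases
whose score strictly exceeds a cutoff -- pooled over all bases of the
interval set, not averaged per interval, so splitting intervals leaves the
result unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .stats import two_proportion_test

Interval = tuple[str, int, int]


@dataclass
class ConservationTrack:
    """Per-base scores keyed by chromosome; NaN marks unscored bases."""

    scores: Dict[str, np.ndarray]

    def __post_init__(self) -> None:
        for chrom, arr in self.scores.items():
            finite = arr[np.isfinite(arr)]
            if finite.size and (finite.min() < 0 or finite.max() > 1):
                raise ValueError(f"conservation scores outside [0, 1] on {chrom}")

    def gather(self, intervals: Iterable[Interval]) -> np.ndarray:
        """All per-base scores under the intervals (NaN included)."""
        chunks = []
        for chrom, start, end in intervals:
            arr = self.scores.get(chrom)
            if arr is None:
                continue
            chunks.append(arr[max(0, start) : min(len(arr), end)])
        return np.concatenate(chunks) if chunks else np.empty(0)


@dataclass
class ConservedFraction:
    fraction: float
    n_scored: int

    @property
    def defined(self) -> bool:
        return self.n_scored > 0


def fraction_conserved(
    intervals: Iterable[Interval], track: ConservationTrack, cutoff: float
) -> ConservedFraction:
    """Pooled fraction of scored bases with score strictly above ``cutoff``.

    With no scored base the result is flagged undefined (NaN fraction), not
    reported as 0.
    """
    if not 0.0 <= cutoff <= 1.0:
        raise ValueError("cutoff must be in [0, 1]")
    vals = track.gather(intervals)
    scored = vals[np.isfinite(vals)]
    if scored.size == 0:
        return ConservedFraction(math.nan, 0)
    return ConservedFraction(float(np.mean(scored > cutoff)), int(scored.size))


def conservation_profile(
    interval_sets: Mapping[str, Sequence[Interval]],
    track: ConservationTrack,
    cutoffs: Sequence[float],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Conserved fractions per interval set per cutoff, with pairwise
    two-proportion comparisons at each cutoff.

    Empty sets (no scored base) are omitted.  Fractions are monotone
    non-increasing in the cutoff within each set.
    """
    if not interval_sets:
        raise ValueError("need at least one interval set")
    pooled = {}
    for name, ivs in interval_sets.items():
        vals = track.gather(ivs)
        scored = vals[np.isfinite(vals)]
        if scored.size:
            pooled[name] = scored
    rows = []
    for name, scored in pooled.items():
        for c in cutoffs:
            rows.append(
                {
                    "set": name,
                    "cutoff": c,
                    "fraction": float(np.mean(scored > c)),
                    "n_bases": int(scored.size),
                }
            )
    fractions = pd.DataFrame(rows, columns=["set", "cutoff", "fraction", "n_bases"])
    comps = []
    names = list(pooled)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = pooled[names[i]], pooled[names[j]]
            for c in cutoffs:
                res = two_proportion_test(int((a > c).sum()), a.size, int((b > c).sum()), b.size)
                comps.append(
                    {
                        "set_a": names[i],
                        "set_b": names[j],
                        "cutoff": c,
                        "z": res.statistic,
                        "p": res.p_value,
                    }
                )
    return fractions, pd.DataFrame(comps, columns=["set_a", "set_b", "cutoff", "z", "p"])


def track_from_bundle(conservation: Mapping[str, np.ndarray]) -> ConservationTrack:
    return ConservationTrack({c: np.asarray(a, dtype=float) for c, a in conservation.items()})
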