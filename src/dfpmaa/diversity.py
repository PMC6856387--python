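"""Hill-number diversity profiles, rarefaction and saturation curves.

The Hill number of order q over frequencies f_s is

    D_q = (sum_s f_s^q)^(1/(1-q))

with the q=1 case taken as its analytic limit exp(-sum f ln f) (the
exponential of Shannon entropy).  q=0 counts species equivalents without
weighting — the alpha-diversity convention used throughout this package.
"Species equivalents" are whatever the frequencies are over: 16S OTUs or
per-HMM domain scores.

Rarefaction subsamples observed counts without replacement (multivariate
hypergeometric), so expectations under subsampling are exact and testable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AbundanceVector",
    "DiversityProfile",
    "hill_number",
    "diversity_profile",
    "rarefy_counts",
    "rarefaction_curve",
    "percent_change",
]


@dataclass
class AbundanceVector:
    """Nonnegative frequencies over named species equivalents, summing to 1."""

    labels: list[str]
    freqs: np.ndarray
    raw_counts: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        if len(self.labels) != self.freqs.size:
            raise ValueError("labels and freqs differ in length")
        if np.any(self.freqs < 0):
            raise ValueError("frequencies must be nonnegative")
        if self.freqs.size and abs(self.freqs.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {self.freqs.sum()}, expected 1")
        if self.raw_counts is not None:
            self.raw_counts = np.asarray(self.raw_counts)
            if self.raw_counts.size != self.freqs.size:
                raise ValueError("raw_counts and freqs differ in length")

    @classmethod
    def from_counts(cls, labels: Sequence[str], counts: Sequence[int]) -> "AbundanceVector":
        counts = np.asarray(counts)
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        total = counts.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero count vector")
        return cls(list(labels), counts / total, raw_counts=counts)

    @classmethod
    def from_scores(cls, scores: Mapping[str, float]) -> "AbundanceVector":
        """Normalize a per-HMM score table into frequencies."""
        labels = sorted(scores)
        values = np.array([scores[k] for k in labels], dtype=float)
        if np.any(values < 0):
            raise ValueError("scores must be nonnegative")
        total = values.sum()
        if total == 0:
            raise ValueError("cannot normalize an all-zero score table")
        return cls(labels, values / total)


@dataclass
class DiversityProfile:
    """D_q evaluated on a grid of q values; non-increasing in q."""

    q_grid: np.ndarray
    d_values: np.ndarray


def hill_number(av: AbundanceVector, q: float) -> float:
    """Diversity of order q; richness at q=0, exp(Shannon) at q=1."""
    if q < 0:
        raise ValueError("q must be nonnegative")
    f = av.freqs[av.freqs > 0]
    if f.size == 0:
        return 0.0
    if q == 0:
        return float(f.size)
    if q == 1:
        return float(np.exp(-np.sum(f * np.log(f))))
    return float(np.sum(f**q) ** (1.0 / (1.0 - q)))


def diversity_profile(av: AbundanceVector, q_grid: Sequence[float]) -> DiversityProfile:
    """Pointwise Hill numbers along an ascending q grid."""
    q_grid = np.asarray(q_grid, dtype=float)
    if np.any(np.diff(q_grid) < 0):
        raise ValueError("q_grid must be sorted ascending")
    d = np.array([hill_number(av, q) for q in q_grid])
    # the q=1 limit must join continuously with its neighbourhood
    if np.any(q_grid == 1.0) and av.freqs.size:
        d1 = hill_number(av, 1.0)
        for eps in (1e-6, -1e-6):
            if abs(hill_number(av, 1.0 + eps) - d1) >= 1e-3:
                raise AssertionError("Hill profile discontinuous at q=1")
    return DiversityProfile(q_grid=q_grid, d_values=d)


def rarefy_counts(raw_counts: Sequence[int], depth: int, seed: int) -> np.ndarray:
    """Subsample a count vector to a fixed depth without replacement.

    Multivariate hypergeometric draw: the output sums to ``depth`` exactly
    and never exceeds any category's input count.  Deterministic for a
    fixed seed.
    """
    counts = np.asarray(raw_counts, dtype=np.int64)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = int(counts.sum())
    if depth < 0:
        raise ValueError("depth must be nonnegative")
    if depth > total:
        raise ValueError(f"depth {depth} exceeds total count {total}")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(counts, depth)


def rarefaction_curve(
    raw_counts: Sequence[int],
    depths: Sequence[int],
    reps: int = 10,
    seed: int = 0,
) -> np.ndarray:
    """Mean distinct-feature (nonzero-category) counts at each depth.

    Averages ``reps`` independent subsamples per depth; depths at or above
    the total return the exact observed richness.  The curve saturates as
    depth approaches the total.
    """
    counts = np.asarray(raw_counts, dtype=np.int64)
    depths = list(depths)
    if any(b < a for a, b in zip(depths, depths[1:])):
        raise ValueError("depths must be ascending")
    if reps < 1:
        raise ValueError("reps must be >= 1")
    total = int(counts.sum())
    richness = int(np.count_nonzero(counts))
    rng = np.random.default_rng(seed)
    means = []
    for depth in depths:
        if depth >= total:
            means.append(float(richness))
            continue
        vals = [
            np.count_nonzero(rng.multivariate_hypergeometric(counts, depth))
            for _ in range(reps)
        ]
        means.append(float(np.mean(vals)))
    return np.asarray(means)


def percent_change(before: float, after: float) -> float:
    """Percent change from ``before`` to ``after``, to one decimal place."""
    if before <= 0:
        raise ValueError("baseline must be positive")
    return round(100.0 * (after - before) / before, 1)
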