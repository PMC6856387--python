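"""Comparison statistics for score tables and community profiles.

Group contrasts are often only available as published summary statistics
(mean ± SEM, n), so the t tests here work from summaries as well as from
raw vectors.  Also provided: Pearson correlation with its t-based p-value,
a seeded paired bootstrap for before/after score increases, the Hellinger
transform used before ordination, a PCA wrapper with a fixed sign
convention, and the two-model rarefaction-consensus feature-selection rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats as sps
from sklearn.decomposition import PCA

__all__ = [
    "GroupSummary",
    "SelectionRecord",
    "welch_t_from_summary",
    "one_sample_t_from_summary",
    "pearson_r",
    "pearson_p_from_r",
    "paired_bootstrap_increase",
    "hellinger",
    "pca_decompose",
    "consensus_select",
]


@dataclass(frozen=True)
class GroupSummary:
    """Published-style group summary: mean, standard error of the mean, size."""

    mean: float
    sem: float
    n: int

    def __post_init__(self) -> None:
        if self.sem < 0:
            raise ValueError("sem must be nonnegative")
        if self.n < 2:
            raise ValueError("n must be >= 2")

    @classmethod
    def from_raw(cls, values: Sequence[float]) -> "GroupSummary":
        values = np.asarray(values, dtype=float)
        return cls(
            mean=float(values.mean()),
            sem=float(values.std(ddof=1) / np.sqrt(values.size)),
            n=int(values.size),
        )


def _degenerate_p(m1: float, m2: float) -> tuple[float, float, float]:
    # both SEMs zero: no sampling variability, comparison is deterministic
    t = 0.0 if m1 == m2 else np.inf * np.sign(m1 - m2)
    return float(t), float("inf"), 1.0 if m1 == m2 else 0.0


def welch_t_from_summary(
    g1: GroupSummary, g2: GroupSummary, pooled: bool = False
) -> tuple[float, float, float]:
    """Two-sample t test from group summaries; Welch by default.

    Returns ``(t, df, p_two_sided)``.  Sample variances are recovered as
    ``s_i^2 = n_i * sem_i^2``; Welch uses the Satterthwaite df, the pooled
    (classic Student) option uses ``n1 + n2 - 2``.
    """
    if g1.sem == 0 and g2.sem == 0:
        return _degenerate_p(g1.mean, g2.mean)
    v1, v2 = g1.sem**2, g2.sem**2  # variances of the two means
    if pooled:
        s1sq, s2sq = g1.n * v1, g2.n * v2
        sp2 = ((g1.n - 1) * s1sq + (g2.n - 1) * s2sq) / (g1.n + g2.n - 2)
        t = (g1.mean - g2.mean) / np.sqrt(sp2 * (1 / g1.n + 1 / g2.n))
        df = float(g1.n + g2.n - 2)
    else:
        t = (g1.mean - g2.mean) / np.sqrt(v1 + v2)
        df = (v1 + v2) ** 2 / (v1**2 / (g1.n - 1) + v2**2 / (g2.n - 1))
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), float(df), float(p)


def one_sample_t_from_summary(
    g: GroupSummary, mu0: float
) -> tuple[float, float, float]:
    """One-sample t test of a summarized group mean against a fixed value."""
    if g.sem == 0:
        return _degenerate_p(g.mean, mu0)
    t = (g.mean - mu0) / g.sem
    df = float(g.n - 1)
    p = 2.0 * sps.t.sf(abs(t), df)
    return float(t), df, float(p)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Product-moment correlation with its two-sided t-based p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    result = sps.pearsonr(x, y)
    return float(result.statistic), float(result.pvalue)


def pearson_p_from_r(r: float, n: int) -> float:
    """Two-sided p for a given correlation and sample size via t = r sqrt((n-2)/(1-r^2))."""
    if not -1 <= r <= 1:
        raise ValueError("r must lie in [-1, 1]")
    if n < 3:
        raise ValueError("need n >= 3")
    if abs(r) == 1:
        return 0.0
    t = r * np.sqrt((n - 2) / (1 - r**2))
    return float(2.0 * sps.t.sf(abs(t), n - 2))


def paired_bootstrap_increase(
    before: Sequence[float],
    after: Sequence[float],
    B: int = 10_000,
    seed: int = 0,
) -> float:
    """One-sided bootstrap p for "after exceeds before" on paired samples.

    Paired differences are resampled with replacement ``B`` times; the
    p-value is ``(1 + #{resample mean <= 0}) / (B + 1)`` — the add-one
    correction keeps p strictly positive.  Deterministic for a fixed seed.
    """
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.size != after.size:
        raise ValueError("before and after must have equal length")
    n = before.size
    if n == 0:
        raise ValueError("need at least one pair")
    if B < 1:
        raise ValueError("B must be >= 1")
    diffs = after - before
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, n, size=(B, n))
    means = diffs[idx].mean(axis=1)
    return float((1 + np.count_nonzero(means <= 0)) / (B + 1))


def hellinger(counts: Sequence[float]) -> np.ndarray:
    """Square roots of relative abundances; unit Euclidean norm output."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("counts must be nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("cannot transform an all-zero vector")
    return np.sqrt(counts / total)


def pca_decompose(matrix: Sequence[Sequence[float]]) -> tuple[np.ndarray, np.ndarray]:
    """Principal components of a samples x features matrix.

    Columns are centered; returns ``(components, explained_variance_ratios)``
    with ratios non-increasing and summing to at most 1.  Sign convention:
    each component's largest-magnitude loading is positive.
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need a 2-D matrix with at least 2 samples")
    pca = PCA(n_components=min(matrix.shape))
    pca.fit(matrix)
    components = pca.components_.copy()
    for row in components:
        if row[np.argmax(np.abs(row))] < 0:
            row *= -1
    return components, pca.explained_variance_ratio_.copy()


@dataclass(frozen=True)
class SelectionRecord:
    """Features selected by one model on one rarefied data set."""

    rarefaction_id: int
    model_id: str
    selected_features: frozenset[str]

    def __post_init__(self) -> None:
        if self.rarefaction_id < 1:
            raise ValueError("rarefaction_id must be >= 1")
        object.__setattr__(self, "selected_features", frozenset(self.selected_features))


def consensus_select(
    records: Iterable[SelectionRecord],
    n_rarefactions: int,
    min_frac: float = 0.5,
    model_tags: Sequence[str] = ("svc", "lr"),
) -> set[str]:
    """Two-model rarefaction-consensus rule for signature features.

    A feature is kept iff both models selected it in at least
    ``min_frac * n_rarefactions`` of the rarefied data sets (agreement in
    exactly half counts, per "at least half").  The classifiers themselves
    are external; this implements only the agreement rule over their
    selections.
    """
    if len(set(model_tags)) != 2:
        raise ValueError("exactly two distinct model tags are required")
    if n_rarefactions < 1:
        raise ValueError("n_rarefactions must be >= 1")
    by_rarefaction: dict[int, dict[str, set[str]]] = {}
    for rec in records:
        if rec.model_id not in model_tags:
            raise ValueError(f"unknown model tag {rec.model_id!r}")
        sel = by_rarefaction.setdefault(rec.rarefaction_id, {})
        sel.setdefault(rec.model_id, set()).update(rec.selected_features)
    threshold = min_frac * n_rarefactions
    agreement: dict[str, int] = {}
    tag_a, tag_b = model_tags[0], model_tags[1]
    for sel in by_rarefaction.values():
        both = sel.get(tag_a, set()) & sel.get(tag_b, set())
        for feature in both:
            agreement[feature] = agreement.get(feature, 0) + 1
    return {f for f, count in agreement.items() if count >= threshold - 1e-9}
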