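"""dbCAN-style acceptance of per-domain hits.

Three rules, applied in the order the dbCAN parser script applies them:

1. Overlap resolution — among hits on the same sequence whose alignments
   overlap by more than half of the shorter alignment, only the most
   significant (lowest independent E-value) survives.
2. E-value tiers — alignments longer than 80 aa must have i-Evalue below
   1e-5; shorter ones below 1e-3.
3. Coverage — the hit must span at least 30% of the HMM's match states.

All thresholds live in :class:`FilterConfig` and can be changed; the
defaults are the dbCAN parser's published ones.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import groupby
from pathlib import Path
from typing import Iterable, Sequence

from .io import DomainHit

__all__ = [
    "FilterConfig",
    "coverage_fraction",
    "passes_evalue",
    "resolve_overlaps",
    "apply_dbcan_filter",
]


@dataclass(frozen=True)
class FilterConfig:
    """Acceptance thresholds plus the scoring constants they interact with.

    evalue_long / evalue_short
        i-Evalue ceilings for alignments longer than / at most ``long_aa``
        residues (dbCAN defaults 1e-5 and 1e-3 around 80 aa).
    min_cov
        Minimal fraction of HMM match states a hit must span (dbCAN 0.3).
    overlap_frac
        Two same-sequence hits conflict when their alignment overlap exceeds
        this fraction of the shorter alignment (dbCAN 0.5).
    """

    evalue_long: float = 1e-5
    evalue_short: float = 1e-3
    long_aa: int = 80
    min_cov: float = 0.3
    overlap_frac: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.min_cov <= 1):
            raise ValueError("min_cov must be in (0, 1]")
        if not (0 < self.overlap_frac <= 1):
            raise ValueError("overlap_frac must be in (0, 1]")
        if self.evalue_long <= 0 or self.evalue_short <= 0:
            raise ValueError("E-value thresholds must be positive")
        if self.long_aa < 1:
            raise ValueError("long_aa must be >= 1")


def coverage_fraction(hit: DomainHit) -> float:
    """Fraction of the HMM's match states spanned by the hit (the "domain fraction")."""
    if hit.hmm_len <= 0:
        raise ValueError("hmm_len must be positive")
    return (hit.hmm_to - hit.hmm_from + 1) / hit.hmm_len


def passes_evalue(hit: DomainHit, cfg: FilterConfig | None = None) -> bool:
    """Tiered i-Evalue test: stricter ceiling for long alignments."""
    cfg = cfg or FilterConfig()
    if hit.ali_len > cfg.long_aa:
        return hit.i_evalue < cfg.evalue_long
    return hit.i_evalue < cfg.evalue_short


def _conflicts(a: DomainHit, b: DomainHit, overlap_frac: float) -> bool:
    overlap = min(a.ali_to, b.ali_to) - max(a.ali_from, b.ali_from) + 1
    return overlap > overlap_frac * min(a.ali_len, b.ali_len)


def _priority(hit: DomainHit):
    # lower i-Evalue wins; ties to higher bit score, then leftmost alignment
    return (hit.i_evalue, -hit.bit_score, hit.ali_from)


def resolve_overlaps(
    hits: Sequence[DomainHit], cfg: FilterConfig | None = None
) -> list[DomainHit]:
    """Greedy elimination of conflicting same-sequence hits.

    Hits are considered in order of ascending i-Evalue (ties broken by
    descending bit score, then ascending alignment start); each is kept only
    if it does not conflict with an already-kept hit.  The result is
    pairwise non-conflicting and returned sorted by alignment start.
    """
    cfg = cfg or FilterConfig()
    if not hits:
        return []
    seq_ids = {h.seq_id for h in hits}
    if len(seq_ids) > 1:
        raise ValueError(f"hits span multiple sequences: {sorted(seq_ids)}")
    kept: list[DomainHit] = []
    for hit in sorted(hits, key=_priority):
        if all(not _conflicts(hit, other, cfg.overlap_frac) for other in kept):
            kept.append(hit)
    return sorted(kept, key=lambda h: h.ali_from)


def apply_dbcan_filter(
    hits: Iterable[DomainHit],
    cfg: FilterConfig | None = None,
    audit_path: str | Path | None = None,
) -> list[DomainHit]:
    """Full acceptance pass: overlap resolution, then E-value tier, then coverage.

    Returns accepted hits in stable ``(seq_id, ali_from)`` order.  When
    ``audit_path`` is given, a TSV log records every hit with the rule that
    rejected it (or ``kept``).
    """
    cfg = cfg or FilterConfig()
    hits = sorted(hits, key=lambda h: (h.seq_id, h.ali_from, _priority(h)))
    accepted: list[DomainHit] = []
    audit: list[tuple[DomainHit, str]] = []
    for seq_id, group in groupby(hits, key=lambda h: h.seq_id):
        group = list(group)
        survivors = set(map(id, resolve_overlaps(group, cfg)))
        for hit in group:
            if id(hit) not in survivors:
                audit.append((hit, "overlap"))
            elif not passes_evalue(hit, cfg):
                audit.append((hit, "evalue"))
            elif coverage_fraction(hit) < cfg.min_cov:
                audit.append((hit, "coverage"))
            else:
                audit.append((hit, "kept"))
                accepted.append(hit)
    if audit_path is not None:
        with open(audit_path, "w") as fh:
            fh.write("seq_id\thmm_name\tali_from\tali_to\ti_evalue\tcoverage\trule\n")
            for hit, rule in audit:
                fh.write(
                    f"{hit.seq_id}\t{hit.hmm_name}\t{hit.ali_from}\t{hit.ali_to}\t"
                    f"{hit.i_evalue:.3g}\t{coverage_fraction(hit):.4f}\t{rule}\n"
                )
    return accepted
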