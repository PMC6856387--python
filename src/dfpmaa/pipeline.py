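"""End-to-end scoring convenience wrappers.

Two entry paths produce a :class:`~dfpmaa.scoring.ScoreTable`:

- :func:`score_reads` — synthetic path: translate merged reads in six
  frames, scan fragments against a toy registry, filter, score.
- :func:`score_domtblout` — real-data path: take an existing HMMER
  per-domain table (hmmsearch or hmmscan orientation) plus the predicted
  proteins that were scanned (the amino-acid denominator), filter, score.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np

from .filtering import FilterConfig, apply_dbcan_filter
from .io import SequenceRecord, read_domtblout, read_fasta
from .orf import DEFAULT_MIN_AA, six_frame_fragments, total_amino_acids
from .scoring import ScoreTable, dfpmaa_per_hmm
from .synthetic import ToyHMMRegistry, naive_domain_scan

__all__ = ["score_reads", "score_domtblout"]


def score_reads(
    reads: Sequence[SequenceRecord],
    registry: ToyHMMRegistry,
    cfg: FilterConfig | None = None,
    min_aa: int = DEFAULT_MIN_AA,
    min_overlap_aa: int = 10,
    sample_id: str = "sample",
) -> ScoreTable:
    """Translate, scan, filter, and score a set of merged reads."""
    cfg = cfg or FilterConfig()
    fragments = [f for r in reads for f in six_frame_fragments(r, min_aa)]
    total_aa = total_amino_acids(fragments)
    mean_len = float(np.mean([len(r) for r in reads])) if reads else float("nan")
    if total_aa == 0:
        return ScoreTable(sample_id, {}, 0, mean_len, len(reads))
    hits = naive_domain_scan(fragments, registry, min_overlap_aa=min_overlap_aa)
    accepted = apply_dbcan_filter(hits, cfg)
    scores = dfpmaa_per_hmm(accepted, total_aa)
    return ScoreTable(sample_id, scores, total_aa, mean_len, len(reads))


def score_domtblout(
    domtblout_path: str | Path,
    proteins_path: str | Path,
    orientation: str = "search",
    cfg: FilterConfig | None = None,
    sample_id: str = "sample",
) -> ScoreTable:
    """Score an existing per-domain table against its scanned proteins.

    ``proteins_path`` is the FASTA of predicted protein fragments actually
    submitted to scanning; its total residue count is the normalization
    denominator.
    """
    cfg = cfg or FilterConfig()
    total_aa = sum(len(rec.seq) for rec in read_fasta(proteins_path))
    if total_aa == 0:
        raise ValueError(f"no amino acids in {proteins_path}")
    hits = read_domtblout(domtblout_path, orientation=orientation)
    accepted = apply_dbcan_filter(hits, cfg)
    scores = dfpmaa_per_hmm(accepted, total_aa)
    return ScoreTable(sample_id, scores, total_aa, float("nan"), 0)
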