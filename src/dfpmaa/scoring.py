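"""DFPMAA_250 scoring: normalized, integrated counts of carbohydrate-active domains.

For each HMM the score is the sum of the accepted hits' HMM-coverage
fractions ("domain fractions"), normalized per million amino acids of
predicted protein submitted to scanning:

    DFPMAA_250(h) = 1e6 * sum_i coverage_fraction(hit_i on h) / total_aa

The "250" marks the reference read length (nt) at which the score is
calibrated: the ratio itself is read-length-neutral, but the 0.3-coverage
acceptance rule makes scores decay once mean read lengths drop below about
190 nt, so scores are comparable across datasets only above that gate
(:func:`length_gate`).  An explicit ``rescale_to_reference`` option is
provided for users who prefer a hard 250/mean-length rescale instead of the
gate.

The sum of DFPMAA_250 over all HMMs estimates a sample's overall
carbohydrate-processing capability; per-class aggregation (GH, GT, PL, CE,
CBM, AA) profiles how that capability is distributed.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .filtering import coverage_fraction
from .io import DomainHit, SequenceRecord

__all__ = [
    "CazyClass",
    "ScoreTable",
    "dfpmaa_per_hmm",
    "sum_dfpmaa",
    "cazy_class_of",
    "class_proportions",
    "trim_reads",
    "length_gate",
    "SCALE",
    "REFERENCE_READ_LEN_NT",
    "MIN_MEAN_READ_LEN_NT",
]

#: per-million normalization constant
SCALE = 1e6
#: reference read length (nt) at which the score is calibrated
REFERENCE_READ_LEN_NT = 250.0
#: mean paired-read length (nt) below which scores are not cross-comparable
MIN_MEAN_READ_LEN_NT = 187.6


class CazyClass(enum.Enum):
    """Carbohydrate-active enzyme domain categories."""

    AA = "AA"  # auxiliary activities
    CBM = "CBM"  # carbohydrate-binding modules
    CE = "CE"  # carbohydrate esterases
    GH = "GH"  # glycoside hydrolases
    GT = "GT"  # glycosyltransferases
    PL = "PL"  # polysaccharide lyases
    OTHER = "OTHER"  # dockerins, cohesins, SLH, ...


def cazy_class_of(hmm_name: str) -> CazyClass:
    """Class of an HMM from its maximal leading alphabetic prefix.

    ``GH13_2`` -> GH, ``CBM50`` -> CBM; names whose alphabetic prefix is not
    a CAZy class code (dockerin, cohesin, SLH, ...) map to OTHER.
    """
    if not hmm_name:
        raise ValueError("HMM name must be nonempty")
    prefix = ""
    for ch in hmm_name:
        if ch.isalpha():
            prefix += ch
        else:
            break
    try:
        return CazyClass(prefix)
    except ValueError:
        return CazyClass.OTHER


@dataclass
class ScoreTable:
    """Per-sample map HMM name -> DFPMAA_250, with its normalization metadata."""

    sample_id: str
    scores: dict[str, float]
    total_aa: int
    mean_read_len_nt: float = float("nan")
    n_reads: int = 0

    def __post_init__(self) -> None:
        for hmm, value in self.scores.items():
            if value < 0:
                raise ValueError(f"score for {hmm!r} is negative: {value}")
        if any(v > 0 for v in self.scores.values()) and self.total_aa <= 0:
            raise ValueError("total_aa must be positive when any score is positive")

    def sum(self) -> float:
        return sum_dfpmaa(self)

    def class_proportions(self) -> dict[CazyClass, float]:
        return class_proportions(self)

    def to_tsv(self, path: str | Path) -> None:
        from .io import write_score_table

        write_score_table(self, path)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ScoreTable":
        from .io import read_score_table, read_score_table_metadata

        meta = read_score_table_metadata(path)
        return cls(
            sample_id=meta.get("sample_id", "sample"),
            scores=read_score_table(path),
            total_aa=int(meta.get("total_aa", 0)),
            mean_read_len_nt=float(meta.get("mean_read_len_nt", "nan")),
            n_reads=int(meta.get("n_reads", 0)),
        )


def dfpmaa_per_hmm(
    accepted_hits: Iterable[DomainHit],
    total_aa: int,
    rescale_to_reference: bool = False,
    mean_read_len_nt: float | None = None,
) -> dict[str, float]:
    """Summed domain fractions per HMM, normalized per million amino acids.

    ``accepted_hits`` must already have passed the dbCAN-style filter.
    HMMs without hits are absent from the map (zero downstream).  With
    ``rescale_to_reference``, scores are additionally multiplied by
    ``250 / mean_read_len_nt`` (the opt-in hard rescale).
    """
    if total_aa <= 0:
        raise ValueError("total_aa must be positive")
    scores: dict[str, float] = {}
    for hit in accepted_hits:
        scores[hit.hmm_name] = scores.get(hit.hmm_name, 0.0) + coverage_fraction(hit)
    factor = SCALE / total_aa
    if rescale_to_reference:
        if not mean_read_len_nt or mean_read_len_nt <= 0:
            raise ValueError("rescale_to_reference requires a positive mean_read_len_nt")
        factor *= REFERENCE_READ_LEN_NT / mean_read_len_nt
    return {hmm: fractions * factor for hmm, fractions in scores.items()}


def sum_dfpmaa(table: "ScoreTable | Mapping[str, float]") -> float:
    """Integrated score over all HMMs — the sample-level readout."""
    scores = table.scores if isinstance(table, ScoreTable) else table
    return float(sum(scores.values()))


def class_proportions(
    table: "ScoreTable | Mapping[str, float]",
) -> dict[CazyClass, float]:
    """Share of the integrated score carried by each CAZy domain class."""
    scores = table.scores if isinstance(table, ScoreTable) else table
    total = sum_dfpmaa(scores)
    if total <= 0:
        raise ValueError("class proportions undefined for an all-zero table")
    props: dict[CazyClass, float] = {}
    for hmm, value in scores.items():
        cls = cazy_class_of(hmm)
        props[cls] = props.get(cls, 0.0) + value / total
    return props


def trim_reads(
    reads: Sequence[SequenceRecord],
    target_mean_len_nt: float,
    seed: int,
) -> list[SequenceRecord]:
    """Randomly trim 5' and 3' ends to bring the mean read length to a target.

    Each read longer than the target loses ``len - round(target)``
    nucleotides, with the total trim split uniformly at random between the
    two ends; shorter reads pass through unchanged.  Deterministic for a
    fixed seed.  Used to emulate shorter sequencing platforms when probing
    read-length sensitivity.
    """
    if not reads:
        return []
    mean_len = float(np.mean([len(r) for r in reads]))
    if target_mean_len_nt > mean_len:
        raise ValueError(
            f"target mean length {target_mean_len_nt} exceeds current mean {mean_len:.1f}"
        )
    rng = np.random.default_rng(seed)
    target = int(round(target_mean_len_nt))
    trimmed: list[SequenceRecord] = []
    for read in reads:
        excess = len(read) - target
        if excess <= 0:
            trimmed.append(read)
            continue
        five = int(rng.integers(0, excess + 1))
        three = excess - five
        end = len(read) - three
        trimmed.append(
            SequenceRecord(
                id=read.id,
                seq=read.seq[five:end],
                qualities=None if read.qualities is None else read.qualities[five:end],
            )
        )
    return trimmed


def length_gate(mean_read_len_nt: float) -> bool:
    """Whether a dataset's mean read length supports cross-dataset score comparison.

    Scores remain computable below the gate, but the 0.3-coverage rule makes
    them systematically underestimated.
    """
    if mean_read_len_nt <= 0:
        raise ValueError("mean read length must be positive")
    return mean_read_len_nt >= MIN_MEAN_READ_LEN_NT
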