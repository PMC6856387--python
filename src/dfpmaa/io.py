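"""Readers and writers for the formats the scoring pipeline touches.

Sequence data (FASTA/FASTQ) goes through Biopython; the HMMER3 per-domain
tabular output (``--domtblout``) and the TSV score tables are parsed here.
All coordinates follow the HMMER convention: 1-based, inclusive on both
ends, so every length is ``to - from + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "DomainHit",
    "DomtbloutParseError",
    "read_domtblout",
    "read_fasta",
    "read_fastq",
    "write_fasta",
    "write_score_table",
    "read_score_table",
]


@dataclass
class SequenceRecord:
    """One nucleotide or amino-acid sequence, optionally with per-base qualities."""

    id: str
    seq: str
    qualities: list[int] | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be nonempty")
        if not self.seq:
            raise ValueError(f"sequence {self.id!r} is empty")
        if self.qualities is not None and len(self.qualities) != len(self.seq):
            raise ValueError(
                f"sequence {self.id!r}: {len(self.qualities)} quality scores "
                f"for {len(self.seq)} bases"
            )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class DomainHit:
    """One per-domain alignment record from a profile-HMM scan.

    ``hmm_from``/``hmm_to`` are match-state coordinates on the HMM,
    ``ali_from``/``ali_to`` are residue coordinates on the scanned sequence;
    both pairs are 1-based inclusive.  ``i_evalue`` is HMMER's independent
    per-domain E-value, the statistic used for per-hit filtering.
    """

    seq_id: str
    seq_len: int
    hmm_name: str
    hmm_len: int
    full_evalue: float
    i_evalue: float
    bit_score: float
    hmm_from: int
    hmm_to: int
    ali_from: int
    ali_to: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.hmm_len <= 0:
            raise ValueError(f"hit on {self.hmm_name!r}: hmm_len must be positive")
        if not (1 <= self.hmm_from <= self.hmm_to <= self.hmm_len):
            raise ValueError(
                f"hit on {self.hmm_name!r}: bad HMM coordinates "
                f"{self.hmm_from}-{self.hmm_to} (hmm_len {self.hmm_len})"
            )
        if not (1 <= self.ali_from <= self.ali_to <= self.seq_len):
            raise ValueError(
                f"hit on {self.seq_id!r}: bad alignment coordinates "
                f"{self.ali_from}-{self.ali_to} (seq_len {self.seq_len})"
            )
        if self.i_evalue < 0:
            raise ValueError("i_evalue must be nonnegative")

    @property
    def ali_len(self) -> int:
        """Alignment length on the sequence, in residues."""
        return self.ali_to - self.ali_from + 1

    @property
    def hmm_span(self) -> int:
        """Number of HMM match states covered by this hit."""
        return self.hmm_to - self.hmm_from + 1


class DomtbloutParseError(ValueError):
    """Raised when a domtblout data line cannot be parsed; names the line."""


# Fixed 22-column prefix of HMMER3 --domtblout; column 23 onward is the
# free-text description of the target.
_N_DOMTBL_COLS = 22


def read_domtblout(path: str | Path, orientation: str = "search") -> list[DomainHit]:
    """Parse HMMER3 per-domain tabular output into :class:`DomainHit` records.

    Parameters
    ----------
    path
        The ``--domtblout`` file written by hmmsearch or hmmscan.
    orientation
        ``"search"`` when the HMMs were the queries (hmmsearch against a
        sequence database: HMM length is the ``qlen`` column); ``"scan"``
        when the sequences were the queries (hmmscan: roles swapped).

    Lines beginning with ``#`` are comments.  Every data line yields exactly
    one hit or a :class:`DomtbloutParseError` naming the offending line.
    """
    if orientation not in ("search", "scan"):
        raise ValueError(f"orientation must be 'search' or 'scan', got {orientation!r}")
    hits: list[DomainHit] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if line.startswith("#") or not line.strip():
                continue
            fields = line.split(None, _N_DOMTBL_COLS)
            if len(fields) < _N_DOMTBL_COLS:
                raise DomtbloutParseError(
                    f"{path}:{lineno}: expected at least {_N_DOMTBL_COLS} "
                    f"whitespace-delimited fields, found {len(fields)}"
                )
            description = fields[22].rstrip("\n") if len(fields) > _N_DOMTBL_COLS else ""
            try:
                target_name, target_len = fields[0], int(fields[2])
                query_name, query_len = fields[3], int(fields[5])
                if orientation == "search":
                    hmm_name, hmm_len = query_name, query_len
                    seq_id, seq_len = target_name, target_len
                else:
                    hmm_name, hmm_len = target_name, target_len
                    seq_id, seq_len = query_name, query_len
                hit = DomainHit(
                    seq_id=seq_id,
                    seq_len=seq_len,
                    hmm_name=hmm_name,
                    hmm_len=hmm_len,
                    full_evalue=float(fields[6]),
                    i_evalue=float(fields[12]),
                    bit_score=float(fields[13]),
                    hmm_from=int(fields[15]),
                    hmm_to=int(fields[16]),
                    ali_from=int(fields[17]),
                    ali_to=int(fields[18]),
                    description=description,
                )
            except ValueError as exc:
                if isinstance(exc, DomtbloutParseError):
                    raise
                raise DomtbloutParseError(f"{path}:{lineno}: {exc}") from exc
            hits.append(hit)
    return hits


def read_fasta(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream FASTA records; the header token before the first whitespace is the id."""
    for rec in SeqIO.parse(str(path), "fasta"):
        yield SequenceRecord(id=rec.id, seq=str(rec.seq))


def read_fastq(path: str | Path) -> Iterator[SequenceRecord]:
    """Stream 4-line FASTQ records with Phred qualities.

    Malformed records ('+' separator or quality-length mismatch) raise
    ``ValueError`` from the underlying parser.
    """
    for rec in SeqIO.parse(str(path), "fastq"):
        yield SequenceRecord(
            id=rec.id,
            seq=str(rec.seq),
            qualities=list(rec.letter_annotations["phred_quality"]),
        )


def write_fasta(records, path: str | Path, width: int = 70) -> None:
    """Write records as wrapped FASTA."""
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), width):
                fh.write(rec.seq[i : i + width] + "\n")


def write_score_table(table, path: str | Path) -> None:
    """Serialize per-HMM scores as TSV (header row ``hmm\\tdfpmaa_250``).

    ``table`` is either a plain mapping HMM name -> score or a
    :class:`dfpmaa.scoring.ScoreTable`, whose sample metadata is then kept
    in ``#``-prefixed header comments.  Scores are written with enough
    significant digits to round-trip within 1e-9.
    """
    from .scoring import ScoreTable  # deferred: scoring imports this module

    with open(path, "w") as fh:
        if isinstance(table, ScoreTable):
            fh.write(f"# sample_id={table.sample_id}\n")
            fh.write(f"# total_aa={table.total_aa}\n")
            fh.write(f"# mean_read_len_nt={table.mean_read_len_nt!r}\n")
            fh.write(f"# n_reads={table.n_reads}\n")
            scores: Mapping[str, float] = table.scores
        else:
            scores = table
        fh.write("hmm\tdfpmaa_250\n")
        for hmm in sorted(scores):
            value = float(scores[hmm])
            if value < 0:
                raise ValueError(f"score for {hmm!r} is negative: {value}")
            fh.write(f"{hmm}\t{value!r}\n")


def read_score_table(path: str | Path) -> dict[str, float]:
    """Read a score-table TSV back into a mapping HMM name -> score.

    Metadata comments are ignored here; use
    :meth:`dfpmaa.scoring.ScoreTable.from_tsv` to recover the full object.
    """
    scores: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            name, _, value = line.rstrip("\n").partition("\t")
            if name == "hmm":
                continue
            scores[name] = float(value)
    return scores


def read_score_table_metadata(path: str | Path) -> dict[str, str]:
    """Return the ``# key=value`` header comments of a score-table TSV."""
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, value = line[1:].strip().partition("=")
            if value:
                meta[key.strip()] = value.strip()
    return meta
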