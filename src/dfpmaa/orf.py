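"""Naive six-frame gene-fragment prediction.

Shotgun reads are random genome fragments, so coding stretches rarely start
with a methionine and can sit on either strand in any frame.  Dedicated
fragment gene predictors (FragGeneScan and kin) model this with
indel-tolerant HMMs; this module is a deliberately simple translator used
for synthetic pipelines: translate all six frames with the bacterial
genetic code (translation table 11), split at stop codons, and keep every
maximal stop-free fragment of at least ``min_aa`` residues.

The amino acids counted for score normalization are exactly the residues of
the fragments submitted to domain scanning (:func:`total_amino_acids`), not
read length divided by three.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

from Bio.Data import CodonTable

from .io import SequenceRecord

__all__ = ["ProteinFragment", "six_frame_fragments", "total_amino_acids"]

#: Minimum fragment length retained by default, in residues.  Well below the
#: smallest scorable domain overlap, and prokaryote-appropriate.
DEFAULT_MIN_AA = 20

_TABLE_11 = CodonTable.unambiguous_dna_by_id[11]
#: codon -> amino acid for the bacterial code; stops map to '*', anything
#: containing N or a non-ACGT letter falls through to 'X' at lookup time.
CODON_TO_AA: dict[str, str] = dict(_TABLE_11.forward_table)
CODON_TO_AA.update({codon: "*" for codon in _TABLE_11.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class ProteinFragment:
    """A maximal stop-free translated stretch of one read.

    ``frame`` is +1/+2/+3 on the forward strand, -1/-2/-3 on the reverse;
    ``nt_start``/``nt_end`` are 0-based half-open coordinates on the read's
    forward strand, so ``nt_end - nt_start == 3 * len(aa_seq)`` always.
    """

    read_id: str
    frame: int
    aa_seq: str
    nt_start: int
    nt_end: int

    def __post_init__(self) -> None:
        if self.frame not in (1, 2, 3, -1, -2, -3):
            raise ValueError(f"invalid frame {self.frame}")
        if "*" in self.aa_seq:
            raise ValueError("fragment contains a stop codon")
        if self.nt_end - self.nt_start != 3 * len(self.aa_seq):
            raise ValueError(
                f"fragment span {self.nt_start}-{self.nt_end} inconsistent "
                f"with {len(self.aa_seq)} residues"
            )

    @property
    def fragment_id(self) -> str:
        """Stable id of the form ``readid_frame_start``."""
        return f"{self.read_id}_{self.frame:+d}_{self.nt_start}"

    def __len__(self) -> int:
        return len(self.aa_seq)


def _translate(seq: str) -> str:
    get = CODON_TO_AA.get
    return "".join(
        get(seq[i : i + 3], "X") for i in range(0, len(seq) - len(seq) % 3, 3)
    )


def six_frame_fragments(
    record: SequenceRecord, min_aa: int = DEFAULT_MIN_AA
) -> list[ProteinFragment]:
    """Extract stop-free protein fragments of >= ``min_aa`` residues from all six frames."""
    if min_aa < 1:
        raise ValueError("min_aa must be >= 1")
    seq = record.seq.upper()
    rc = reverse_complement(seq)
    n = len(seq)
    fragments: list[ProteinFragment] = []
    for strand_seq, sign in ((seq, 1), (rc, -1)):
        for offset in range(3):
            aa = _translate(strand_seq[offset:])
            start = 0
            for piece in aa.split("*"):
                if len(piece) >= min_aa:
                    # nt coordinates on the translated strand
                    s = offset + 3 * start
                    e = s + 3 * len(piece)
                    if sign == 1:
                        nt_start, nt_end = s, e
                    else:
                        nt_start, nt_end = n - e, n - s
                    fragments.append(
                        ProteinFragment(
                            read_id=record.id,
                            frame=sign * (offset + 1),
                            aa_seq=piece,
                            nt_start=nt_start,
                            nt_end=nt_end,
                        )
                    )
                start += len(piece) + 1  # skip the stop codon
    return fragments


def total_amino_acids(fragments: Iterable[ProteinFragment]) -> int:
    """Total residues across fragments — the denominator of score normalization."""
    return sum(len(f.aa_seq) for f in fragments)
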