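"""Synthetic data for exercising the whole pipeline without downloads.

The generator builds a toy HMM catalog (CAZy-style names, lengths, one
amino-acid "signature" per model), plants reverse-translated signatures
into stop-rich genomes on random strands, simulates error-free merged
shotgun reads, and scans translated fragments for near-exact signature
overlaps — a desk-scale stand-in for a profile-HMM search that emits real
:class:`~dfpmaa.io.DomainHit` records and valid domtblout files.

Because reverse translation uses one fixed codon per amino acid and reads
are error-free by default, six-frame translation recovers planted
signatures exactly, making end-to-end expectations (coverage fractions,
density ratios, depth behaviour) analytically predictable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import DomainHit, SequenceRecord
from .orf import CODON_TO_AA, ProteinFragment, reverse_complement
from .scoring import CazyClass, cazy_class_of

__all__ = [
    "ToyHMM",
    "ToyHMMRegistry",
    "ToyGenomeAnnotation",
    "PlantedSegment",
    "make_registry",
    "make_toy_genome",
    "simulate_reads",
    "naive_domain_scan",
    "emit_domtblout",
]

#: the 20 standard amino acids
AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

#: one fixed codon per amino acid (lexicographically smallest in table 11)
CODON_OF: dict[str, str] = {}
for _codon in sorted(CODON_TO_AA):
    _aa = CODON_TO_AA[_codon]
    if _aa != "*" and _aa not in CODON_OF:
        CODON_OF[_aa] = _codon

_STOP_CODONS = ("TAA", "TAG", "TGA")

#: default class mix, proportioned roughly like the dbCAN catalog
DEFAULT_CLASS_MIX: dict[str, float] = {
    "GH": 0.55,
    "GT": 0.17,
    "CBM": 0.12,
    "CE": 0.05,
    "PL": 0.05,
    "AA": 0.04,
    "OTHER": 0.02,
}

_OTHER_NAMES = ("dockerin", "cohesin", "SLH")


@dataclass(frozen=True)
class ToyHMM:
    """A toy profile: its consensus signature plays the role of the match states."""

    name: str
    length: int
    cazy_class: CazyClass
    signature: str

    def __post_init__(self) -> None:
        if self.length != len(self.signature):
            raise ValueError("length must equal signature length")
        if cazy_class_of(self.name) is not self.cazy_class:
            raise ValueError(
                f"name {self.name!r} implies class {cazy_class_of(self.name)}, "
                f"not {self.cazy_class}"
            )


@dataclass
class ToyHMMRegistry:
    """Catalog of toy HMMs, addressable by name."""

    hmms: list[ToyHMM]

    def __post_init__(self) -> None:
        names = [h.name for h in self.hmms]
        if len(set(names)) != len(names):
            raise ValueError("HMM names must be unique")
        self._by_name = {h.name: h for h in self.hmms}

    def __len__(self) -> int:
        return len(self.hmms)

    def __iter__(self):
        return iter(self.hmms)

    def __getitem__(self, name: str) -> ToyHMM:
        return self._by_name[name]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("name\tlength\tcazy_class\tsignature\n")
            for h in self.hmms:
                fh.write(f"{h.name}\t{h.length}\t{h.cazy_class.value}\t{h.signature}\n")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "ToyHMMRegistry":
        hmms = []
        with open(path) as fh:
            header = fh.readline()
            for line in fh:
                name, length, cazy_class, signature = line.rstrip("\n").split("\t")
                hmms.append(
                    ToyHMM(name, int(length), CazyClass(cazy_class), signature)
                )
        return cls(hmms)


@dataclass(frozen=True)
class PlantedSegment:
    """One planted domain-coding segment (0-based half-open nt coordinates)."""

    start: int
    end: int
    strand: str  # '+' or '-'
    hmm_name: str


@dataclass
class ToyGenomeAnnotation:
    """Ground truth for a toy genome: where every signature was planted."""

    genome_id: str
    segments: list[PlantedSegment]
    genome_len: int

    def __post_init__(self) -> None:
        for seg in self.segments:
            if not (0 <= seg.start < seg.end <= self.genome_len):
                raise ValueError(f"segment {seg} outside genome of length {self.genome_len}")

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("genome_id\tstart\tend\tstrand\thmm_name\n")
            for seg in self.segments:
                fh.write(
                    f"{self.genome_id}\t{seg.start}\t{seg.end}\t{seg.strand}\t{seg.hmm_name}\n"
                )


def _allocate_counts(n: int, mix: Mapping[str, float]) -> dict[str, int]:
    """Largest-remainder apportionment of n HMMs across classes."""
    keys = sorted(mix)
    quotas = {k: n * mix[k] for k in keys}
    counts = {k: int(quotas[k]) for k in keys}
    short = n - sum(counts.values())
    for k in sorted(keys, key=lambda k: quotas[k] - counts[k], reverse=True)[:short]:
        counts[k] += 1
    return counts


def make_registry(
    n_hmms: int,
    class_mix: Mapping[str, float] | None = None,
    seed: int = 0,
    length_range: tuple[int, int] = (30, 300),
) -> ToyHMMRegistry:
    """Build a toy HMM catalog with random signatures.

    ``class_mix`` maps class codes (GH, GT, PL, CE, CBM, AA, OTHER) to
    proportions summing to 1; the default roughly mirrors the dbCAN
    catalog's class balance.  Deterministic for a fixed seed.
    """
    if n_hmms < 1:
        raise ValueError("n_hmms must be >= 1")
    mix = dict(class_mix) if class_mix is not None else dict(DEFAULT_CLASS_MIX)
    if abs(sum(mix.values()) - 1.0) > 1e-9 or any(v < 0 for v in mix.values()):
        raise ValueError("class_mix proportions must be nonnegative and sum to 1")
    unknown = set(mix) - {c.value for c in CazyClass}
    if unknown:
        raise ValueError(f"unknown classes in mix: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    lo, hi = length_range
    hmms: list[ToyHMM] = []
    for cls_code, count in _allocate_counts(n_hmms, mix).items():
        for i in range(1, count + 1):
            if cls_code == "OTHER":
                name = f"{_OTHER_NAMES[(i - 1) % len(_OTHER_NAMES)]}{(i - 1) // len(_OTHER_NAMES) + 1}"
            else:
                name = f"{cls_code}{i}"
            length = int(rng.integers(lo, hi + 1))
            signature = "".join(
                AA_ALPHABET[j] for j in rng.integers(0, len(AA_ALPHABET), length)
            )
            hmms.append(ToyHMM(name, length, CazyClass(cls_code), signature))
    return ToyHMMRegistry(hmms)


def reverse_translate(aa_seq: str) -> str:
    """Deterministic coding sequence for a signature (one fixed codon per residue)."""
    return "".join(CODON_OF[aa] for aa in aa_seq)


def _stop_rich_spacer(rng: np.random.Generator, length_nt: int) -> str:
    n_codons = max(1, round(length_nt / 3))
    return "".join(_STOP_CODONS[i] for i in rng.integers(0, 3, n_codons))


def make_toy_genome(
    registry: ToyHMMRegistry,
    n_segments_per_hmm: int = 1,
    spacer_len: int = 150,
    seed: int = 0,
    genome_id: str = "toy_genome",
) -> tuple[SequenceRecord, ToyGenomeAnnotation]:
    """Interleave reverse-translated signatures with stop-rich spacers.

    Each HMM is planted ``n_segments_per_hmm`` times on a random strand, in
    shuffled order, separated by spacers of random stop codons (so
    translated fragments break cleanly at domain boundaries).  The
    annotation records every planted segment; deterministic for a fixed
    seed.
    """
    if n_segments_per_hmm < 1 or spacer_len < 3:
        raise ValueError("n_segments_per_hmm must be >= 1 and spacer_len >= 3")
    rng = np.random.default_rng(seed)
    plan = [h for h in registry for _ in range(n_segments_per_hmm)]
    rng.shuffle(plan)  # type: ignore[arg-type]
    parts: list[str] = []
    segments: list[PlantedSegment] = []
    pos = 0
    for hmm in plan:
        spacer = _stop_rich_spacer(rng, spacer_len)
        parts.append(spacer)
        pos += len(spacer)
        coding = reverse_translate(hmm.signature)
        strand = "+" if rng.integers(0, 2) == 0 else "-"
        if strand == "-":
            coding = reverse_complement(coding)
        parts.append(coding)
        segments.append(PlantedSegment(pos, pos + len(coding), strand, hmm.name))
        pos += len(coding)
    parts.append(_stop_rich_spacer(rng, spacer_len))
    pos += len(parts[-1])
    genome = SequenceRecord(id=genome_id, seq="".join(parts))
    return genome, ToyGenomeAnnotation(genome_id, segments, len(genome.seq))


def simulate_reads(
    genome: SequenceRecord,
    n_reads: int,
    read_len: int,
    seed: int = 0,
    error_rate: float = 0.0,
) -> list[SequenceRecord]:
    """Uniform error-free (by default) single reads from both strands.

    Start positions are uniform over the genome, strands are random; an
    optional uniform substitution rate is available but defaults to 0
    because the downstream scanner is identity-based.
    """
    if read_len > len(genome.seq):
        raise ValueError("read_len exceeds genome length")
    if n_reads < 0:
        raise ValueError("n_reads must be nonnegative")
    rng = np.random.default_rng(seed)
    L = len(genome.seq)
    starts = rng.integers(0, L - read_len + 1, size=n_reads)
    strands = rng.integers(0, 2, size=n_reads)
    reads: list[SequenceRecord] = []
    for i, (start, minus) in enumerate(zip(starts, strands)):
        seq = genome.seq[start : start + read_len]
        if minus:
            seq = reverse_complement(seq)
        if error_rate > 0:
            bases = list(seq)
            for j in np.flatnonzero(rng.random(read_len) < error_rate):
                bases[j] = "ACGT"[rng.integers(0, 4)]
            seq = "".join(bases)
        reads.append(SequenceRecord(id=f"read{i}", seq=seq))
    return reads


def _window_hit(
    frag: str, sig: str, diag: int, min_overlap_aa: int, min_identity: float
) -> tuple[int, int, int] | None:
    """Best near-exact window on one fragment/signature diagonal.

    Returns (frag_start, frag_end, n_matches) over the maximal
    end-trimmed window with identity >= min_identity, or None.
    """
    lo = max(0, -diag)
    hi = min(len(frag), len(sig) - diag)
    if hi - lo < min_overlap_aa:
        return None
    matches = [frag[x] == sig[x + diag] for x in range(lo, hi)]
    try:
        a = matches.index(True)
        b = len(matches) - matches[::-1].index(True)
    except ValueError:
        return None
    # trim mismatching interior ends until identity clears the bar
    while b - a >= min_overlap_aa:
        n_match = sum(matches[a:b])
        if n_match >= min_identity * (b - a):
            return lo + a, lo + b, n_match
        # drop the end with the longer mismatch run
        a2 = a + 1
        while a2 < b and not matches[a2]:
            a2 += 1
        b2 = b - 1
        while b2 > a and not matches[b2 - 1]:
            b2 -= 1
        if a2 >= b2:
            return None
        if a2 - a >= b - b2:
            a = a2
        else:
            b = b2
    return None


def naive_domain_scan(
    fragments: Iterable[ProteinFragment],
    registry: ToyHMMRegistry,
    min_overlap_aa: int = 10,
    min_identity: float = 0.9,
    k: int = 8,
) -> list[DomainHit]:
    """Find near-exact ungapped overlaps between fragments and signatures.

    Seeds exact ``k``-mers against an index of all signatures, then extends
    each fragment/signature diagonal to its maximal window with identity at
    least ``min_identity`` and length at least ``min_overlap_aa``.  Each
    hit's pseudo-statistics are monotone in the number of matched residues:
    ``i_evalue = 10 ** (-matched/2)`` and ``bit_score = matched``.
    """
    index: dict[str, list[tuple[int, int]]] = {}
    sigs = [h.signature for h in registry.hmms]
    for hmm_idx, sig in enumerate(sigs):
        for pos in range(len(sig) - k + 1):
            index.setdefault(sig[pos : pos + k], []).append((hmm_idx, pos))
    hits: list[DomainHit] = []
    for frag in fragments:
        aa = frag.aa_seq
        seen: set[tuple[int, int]] = set()
        for i in range(len(aa) - k + 1):
            for hmm_idx, pos in index.get(aa[i : i + k], ()):
                key = (hmm_idx, pos - i)
                if key in seen:
                    continue
                seen.add(key)
                window = _window_hit(
                    aa, sigs[hmm_idx], pos - i, min_overlap_aa, min_identity
                )
                if window is None:
                    continue
                a, b, matched = window
                diag = pos - i
                hmm = registry.hmms[hmm_idx]
                hits.append(
                    DomainHit(
                        seq_id=frag.fragment_id,
                        seq_len=len(aa),
                        hmm_name=hmm.name,
                        hmm_len=hmm.length,
                        full_evalue=10.0 ** (-matched / 2),
                        i_evalue=10.0 ** (-matched / 2),
                        bit_score=float(matched),
                        hmm_from=a + diag + 1,
                        hmm_to=b + diag,
                        ali_from=a + 1,
                        ali_to=b,
                    )
                )
    return hits


def emit_domtblout(
    hits: Sequence[DomainHit], path: str | Path, orientation: str = "search"
) -> None:
    """Write hits as HMMER3-style per-domain tabular output.

    ``orientation="search"`` puts the HMM in the query columns (as
    hmmsearch does); ``"scan"`` swaps the roles.  Floats are written with
    full round-trip precision so re-parsing is field-exact.
    """
    if orientation not in ("search", "scan"):
        raise ValueError(f"orientation must be 'search' or 'scan', got {orientation!r}")
    with open(path, "w") as fh:
        fh.write("# synthetic per-domain hits; format: HMMER3 --domtblout\n")
        fh.write(
            "# target name, accession, tlen, query name, accession, qlen, "
            "E-value, score, bias, #, of, c-Evalue, i-Evalue, score, bias, "
            "hmm from, hmm to, ali from, ali to, env from, env to, acc, description\n"
        )
        for hit in hits:
            if orientation == "search":
                target, tlen = hit.seq_id, hit.seq_len
                query, qlen = hit.hmm_name, hit.hmm_len
            else:
                target, tlen = hit.hmm_name, hit.hmm_len
                query, qlen = hit.seq_id, hit.seq_len
            desc = hit.description or "-"
            fh.write(
                f"{target} - {tlen} {query} - {qlen} "
                f"{hit.full_evalue!r} {hit.bit_score!r} 0.0 1 1 "
                f"{hit.i_evalue!r} {hit.i_evalue!r} {hit.bit_score!r} 0.0 "
                f"{hit.hmm_from} {hit.hmm_to} {hit.ali_from} {hit.ali_to} "
                f"{hit.ali_from} {hit.ali_to} 0.99 {desc}\n"
            )
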