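"""Small-RNA read preprocessing: adapter-required trimming, length and
quality filtering, and unique-sequence collapsing.

Reads without a detectable 3' adapter are discarded (the insert must be
shorter than the read, so a missing adapter means the read is not a clean
small-RNA insert).  Surviving inserts are kept only if 16–28 nt long, then
collapsed to unique sequences with multiplicities.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Iterable, Sequence

import pysam

__all__ = [
    "CollapsedRead",
    "trim_adapter",
    "length_filter",
    "collapse_reads",
    "process_fastq",
    "write_collapsed_fasta",
    "write_collapsed_tsv",
]

MIN_INSERT_LEN = 16
MAX_INSERT_LEN = 28

_RNA_TO_DNA = str.maketrans("uU", "tT")


def _normalize(seq: str) -> str:
    """Uppercase and map U→T: the internal canonical alphabet is DNA."""
    return seq.translate(_RNA_TO_DNA).upper()


@dataclass(frozen=True)
class CollapsedRead:
    """A unique insert sequence with the number of raw reads that collapsed
    into it and the mean Phred quality over all supporting bases."""

    sequence: str
    count: int
    mean_quality: float = 40.0

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("collapsed count must be >= 1")


def trim_adapter(
    sequence: str,
    quality: Sequence[int] | None,
    adapter: str,
    max_mismatch_rate: float = 0.1,
    min_overlap: int = 6,
) -> tuple[str, Sequence[int] | None] | None:
    """Locate the 3' adapter and return the insert preceding it.

    The adapter may occur in full or as a 3'-partial prefix running off the
    end of the read; up to ``max_mismatch_rate`` mismatches over the
    compared length are tolerated.  Returns ``None`` (read discarded) when
    no occurrence of at least ``min_overlap`` nt is found.  Qualities, when
    supplied, are sliced in register with the insert.
    """
    if len(adapter) < 6:
        raise ValueError("adapter must be at least 6 nt")
    seq = _normalize(sequence)
    ad = _normalize(adapter)

    # fast path: exact full-adapter occurrence
    pos = seq.find(ad)
    if pos < 0:
        pos = _scan_adapter(seq, ad, max_mismatch_rate, min_overlap)
    if pos < 0:
        return None
    qual = quality[:pos] if quality is not None else None
    return seq[:pos], qual


def _scan_adapter(seq: str, ad: str, rate: float, min_overlap: int) -> int:
    last_start = len(seq) - min_overlap
    for i in range(0, last_start + 1):
        length = min(len(ad), len(seq) - i)
        allowed = int(rate * length)
        mismatches = 0
        for a, b in zip(seq[i : i + length], ad[:length]):
            if a != b:
                mismatches += 1
                if mismatches > allowed:
                    break
        else:
            return i
    return -1


def length_filter(insert: str, min_len: int = MIN_INSERT_LEN, max_len: int = MAX_INSERT_LEN) -> bool:
    """Keep an insert iff its length is within [min_len, max_len] inclusive."""
    return min_len <= len(insert) <= max_len


def collapse_reads(inserts: Iterable[str | tuple[str, Sequence[int]]]) -> list[CollapsedRead]:
    """Collapse inserts to unique sequences, in lexicographic order.

    Accepts bare sequences or ``(sequence, qualities)`` pairs; in the
    latter case the collapsed record carries the mean Phred over all
    supporting bases.  Sum of counts equals the number of inputs.
    """
    counts: dict[str, int] = {}
    qual_sum: dict[str, float] = {}
    base_n: dict[str, int] = {}
    for item in inserts:
        if isinstance(item, tuple):
            seq, qual = item
        else:
            seq, qual = item, None
        seq = _normalize(seq)
        counts[seq] = counts.get(seq, 0) + 1
        if qual is not None and len(qual) > 0:
            qual_sum[seq] = qual_sum.get(seq, 0.0) + float(sum(qual))
            base_n[seq] = base_n.get(seq, 0) + len(qual)
    out = []
    for seq in sorted(counts):
        mq = qual_sum[seq] / base_n[seq] if seq in base_n else 40.0
        out.append(CollapsedRead(seq, counts[seq], mq))
    return out


def process_fastq(
    path: str | os.PathLike,
    adapter: str,
    max_mismatch_rate: float = 0.1,
    min_overlap: int = 6,
    min_mean_quality: float = 20.0,
    min_len: int = MIN_INSERT_LEN,
    max_len: int = MAX_INSERT_LEN,
) -> list[CollapsedRead]:
    """Run the full preprocessing chain on one FASTQ file.

    adapter-required trim → mean-quality filter → 16–28 nt length filter →
    unique-sequence collapse.
    """
    kept: list[tuple[str, Sequence[int]]] = []
    with pysam.FastxFile(str(path)) as fh:
        for entry in fh:
            qual = entry.get_quality_array() if entry.quality else None
            trimmed = trim_adapter(entry.sequence, qual, adapter, max_mismatch_rate, min_overlap)
            if trimmed is None:
                continue
            insert, q = trimmed
            if not length_filter(insert, min_len, max_len):
                continue
            if q is not None and len(q) > 0 and (sum(q) / len(q)) < min_mean_quality:
                continue
            kept.append((insert, q if q is not None else []))
    return collapse_reads(kept)


def write_collapsed_fasta(reads: Sequence[CollapsedRead], path: str | os.PathLike) -> None:
    """Write collapsed reads in the ``>seq<i>_x<count>`` dialect."""
    with open(path, "w") as fh:
        for i, r in enumerate(reads, start=1):
            fh.write(f">seq{i}_x{r.count}\n{r.sequence}\n")


def write_collapsed_tsv(reads: Sequence[CollapsedRead], path: str | os.PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("sequence\tcount\tmean_quality\n")
        for r in reads:
            fh.write(f"{r.sequence}\t{r.count}\t{r.mean_quality:.4g}\n")
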