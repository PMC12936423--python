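"""Alignment of collapsed small-RNA reads to mature miRNA references.

The mapping model mirrors how editing detectors treat isomiRs: each read is
placed on a mature reference at a small 5' offset (±2 nt), its last two 3'
nucleotides are ignored for scoring (non-templated additions), and at most
one substitution mismatch is accepted.  A read is only used downstream if
exactly one reference attains its best score ("unique best hit").
Coordinates of mismatches are reported 1-based on the mature reference,
which is how edited positions are conventionally named (e.g. miR-200b-3p
position 5).
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO

from .preprocess import CollapsedRead, _normalize

__all__ = [
    "MatureMiRNA",
    "AlignmentHit",
    "LibraryStats",
    "load_reference",
    "align_read",
    "align_to_references",
    "assign_best_hit",
    "quantify",
]


@dataclass(frozen=True)
class MatureMiRNA:
    """A mature miRNA reference sequence (stored as DNA, 5'→3')."""

    id: str
    sequence: str
    blacklisted: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", _normalize(self.sequence))


@dataclass
class AlignmentHit:
    """One placement of a read on one mature reference.

    ``offset`` is the signed 5' shift: +k means the read starts at mature
    position 1+k (5'-trimmed isomiR); −k means the read carries k extra 5'
    bases that fall outside the reference.  ``mismatches`` holds
    ``(mature_position_1based, ref_base, read_base)`` tuples.
    ``tied_placement`` marks reads with two equally good placements inside
    the same reference; such reads are treated as ambiguous.
    """

    read: CollapsedRead
    mirna_id: str
    offset: int
    mismatches: list[tuple[int, str, str]] = field(default_factory=list)
    unique: bool = True
    tied_placement: bool = False

    @property
    def n_mismatches(self) -> int:
        return len(self.mismatches)

    def covered_interval(self, ref_len: int, trim3: int = 2) -> tuple[int, int]:
        """1-based inclusive mature interval scored by this alignment."""
        scored_len = max(0, len(self.read.sequence) - trim3)
        start = 1 + max(0, self.offset)
        end = min(ref_len, scored_len + self.offset)
        return start, end


def load_reference(
    fasta: str | os.PathLike, blacklist: Iterable[str] = ()
) -> list[MatureMiRNA]:
    """Read mature miRNA sequences from FASTA (RNA or DNA alphabet) and
    flag any identifier present in the repeat-element blacklist."""
    bl = set(blacklist)
    refs = []
    seen = set()
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate reference id: {rec.id}")
        seen.add(rec.id)
        refs.append(MatureMiRNA(rec.id, str(rec.seq), rec.id in bl))
    if not refs:
        raise ValueError(f"no sequences in reference FASTA {fasta}")
    return refs


def load_blacklist(path: str | os.PathLike) -> set[str]:
    with open(path) as fh:
        return {line.strip() for line in fh if line.strip()}


def align_read(
    read: CollapsedRead | str,
    ref: MatureMiRNA,
    max_mismatches: int = 1,
    max_offset: int = 2,
    trim3: int = 2,
    max_3p_overhang: int = 2,
    min_overlap: int = 12,
) -> AlignmentHit | None:
    """Score all placements of ``read`` on ``ref`` and return the best one,
    or ``None`` when no placement has ≤ ``max_mismatches`` mismatches.

    The last ``trim3`` read bases are excluded from scoring; scored read
    bases overhanging the reference 3' end are tolerated up to
    ``max_3p_overhang`` nt (they are not scored), 5' overhangs only through
    negative offsets.
    """
    if isinstance(read, str):
        read = CollapsedRead(_normalize(read), 1)
    seq = read.sequence
    scored = seq[: len(seq) - trim3] if trim3 else seq
    best: tuple[int, int, list[tuple[int, str, str]]] | None = None
    n_at_best = 0
    for offset in range(-max_offset, max_offset + 1):
        # read index j pairs with reference index j + offset (0-based)
        j_lo = max(0, -offset)
        j_hi = min(len(scored), len(ref.sequence) - offset)
        if j_hi - j_lo < min_overlap:
            continue
        if len(scored) - j_hi > max_3p_overhang:
            continue
        mm: list[tuple[int, str, str]] = []
        for j in range(j_lo, j_hi):
            if scored[j] != ref.sequence[j + offset]:
                mm.append((j + offset + 1, ref.sequence[j + offset], scored[j]))
                if len(mm) > max_mismatches:
                    break
        else:
            if best is None or len(mm) < best[0]:
                best = (len(mm), offset, mm)
                n_at_best = 1
            elif len(mm) == best[0]:
                n_at_best += 1
    if best is None:
        return None
    return AlignmentHit(
        read=read,
        mirna_id=ref.id,
        offset=best[1],
        mismatches=best[2],
        tied_placement=n_at_best > 1,
    )


def align_to_references(
    read: CollapsedRead | str, refs: Sequence[MatureMiRNA], **kwargs
) -> list[AlignmentHit]:
    """All per-reference best hits for one read."""
    hits = []
    for ref in refs:
        hit = align_read(read, ref, **kwargs)
        if hit is not None:
            hits.append(hit)
    return hits


def assign_best_hit(hits: Sequence[AlignmentHit]) -> AlignmentHit | None:
    """Pick the unique best hit among per-reference hits for one read.

    Returns ``None`` when there are no hits.  When two or more references
    tie at the minimum mismatch count (or the winning placement is tied
    within its own reference) the returned hit has ``unique=False`` and
    must be excluded from per-position tallies.
    """
    if not hits:
        return None
    best_mm = min(h.n_mismatches for h in hits)
    winners = sorted(
        (h for h in hits if h.n_mismatches == best_mm), key=lambda h: h.mirna_id
    )
    hit = winners[0]
    hit.unique = len(winners) == 1 and not hit.tied_placement
    return hit


@dataclass
class LibraryStats:
    """Per-sample mapped counts with RPM/CPM normalisation."""

    sample_id: str
    counts: dict[str, float]

    def __post_init__(self) -> None:
        self.total_mapped = float(sum(self.counts.values()))
        if self.total_mapped <= 0:
            raise ValueError(f"sample {self.sample_id}: zero mapped reads")

    def rpm(self, mirna_id: str) -> float:
        return self.counts.get(mirna_id, 0.0) * 1e6 / self.total_mapped

    @property
    def rpm_table(self) -> dict[str, float]:
        return {m: c * 1e6 / self.total_mapped for m, c in self.counts.items()}

    # counts-per-million over mapped reads coincides with RPM here
    cpm = rpm


def quantify(
    assignments: Sequence[tuple[CollapsedRead, AlignmentHit]], sample_id: str
) -> LibraryStats:
    """Aggregate unique hits into per-miRNA counts, weighting each collapsed
    read by its multiplicity.  Raises on an empty hit set."""
    counts: dict[str, float] = {}
    for read, hit in assignments:
        if not hit.unique:
            continue
        counts[hit.mirna_id] = counts.get(hit.mirna_id, 0.0) + read.count
    if not counts:
        raise ValueError(f"sample {sample_id}: no uniquely mapped reads")
    return LibraryStats(sample_id, counts)


def map_sample(
    reads: Sequence[CollapsedRead], refs: Sequence[MatureMiRNA], **kwargs
) -> list[tuple[CollapsedRead, AlignmentHit]]:
    """Align every collapsed read and keep the assigned best hit per read
    (unique or flagged ambiguous)."""
    out = []
    for read in reads:
        hit = assign_best_hit(align_to_references(read, refs, **kwargs))
        if hit is not None:
            out.append((read, hit))
    return out


def weighted_multimap_fraction(
    assignments: Sequence[tuple[CollapsedRead, AlignmentHit]]
) -> float:
    total = sum(r.count for r, _ in assignments)
    multi = sum(r.count for r, h in assignments if not h.unique)
    return multi / total if total else float("nan")
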