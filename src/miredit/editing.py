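"""A-to-I editing site detection from aligned small-RNA reads.

Inosine pairs like guanosine during sequencing, so editing shows up as
A→G mismatches against the mature reference.  For every adenosine outside
the 3'-terminal exclusion zone the detector tallies the weighted number of
covering reads (n) and of reads reporting G (x), tests x against the
sequencing-error null with an exact one-sided binomial test, adjusts
across sites with Benjamini–Hochberg, and then applies three specificity
filters: repeat-element miRNAs, canonical expression < 1 RPM, and edited
sequences that multimap to another reference.

The null per-read probability p0 of observing G at an A site by error is
e/3 where e is the per-base error rate; by default it is derived from the
Phred qualities of the covering reads, with a fixed fallback.

The editing level is f = x/n, reported as a percentage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .align import AlignmentHit, LibraryStats, MatureMiRNA, align_to_references
from .preprocess import CollapsedRead
from .stats import bh_adjust

__all__ = [
    "EditSiteStat",
    "tally_site",
    "tally_all_sites",
    "binomial_edit_test",
    "bh_adjust",
    "apply_exclusion_filters",
    "detect_sample",
    "build_editing_table",
]

TERMINAL_EXCLUSION_3P = 5  # mature 3'-terminal bases never screened
FALLBACK_P0 = 0.001


@dataclass
class EditSiteStat:
    """Per-(miRNA, position) editing evidence within one sample."""

    mirna_id: str
    position: int  # 1-based on the mature reference
    x: float  # weighted reads reporting G
    n: float  # weighted reads covering the position
    p0: float
    p_value: float = float("nan")
    fdr: float = float("nan")
    status: str = "tallied"  # "called" or "filtered(<reason>)"

    @property
    def editing_level(self) -> float:
        """Editing level f = x/n as a percentage."""
        return 100.0 * self.x / self.n if self.n else float("nan")


Assignments = Sequence[tuple[CollapsedRead, AlignmentHit]]


def _screenable_positions(ref: MatureMiRNA, exclusion_3p: int) -> list[int]:
    limit = len(ref.sequence) - exclusion_3p
    return [i + 1 for i in range(limit) if ref.sequence[i] == "A"]


def tally_site(
    assignments: Assignments, ref: MatureMiRNA, position: int, trim3: int = 2
) -> tuple[float, float]:
    """Weighted (x, n) for one site: n counts reads whose scored alignment
    covers the position, x those reporting G there.  Reads carrying a
    non-A→G mismatch at the position contribute to n only."""
    if not (1 <= position <= len(ref.sequence)):
        raise ValueError(f"{ref.id}: position {position} out of range")
    if ref.sequence[position - 1] != "A":
        raise ValueError(
            f"{ref.id} position {position}: reference base is "
            f"{ref.sequence[position - 1]}, not A"
        )
    x = n = 0.0
    for read, hit in assignments:
        if not hit.unique or hit.mirna_id != ref.id:
            continue
        lo, hi = hit.covered_interval(len(ref.sequence), trim3)
        if not (lo <= position <= hi):
            continue
        n += read.count
        for pos, ref_base, read_base in hit.mismatches:
            if pos == position and ref_base == "A" and read_base == "G":
                x += read.count
    return x, n


def binomial_edit_test(x: float, n: float, p0: float) -> float:
    """Exact one-sided upper-tail binomial probability P[X >= x | n, p0].

    One-sided because editing can only raise the A→G rate above the
    sequencing-error floor.
    """
    if not (0 < p0 < 1):
        raise ValueError(f"p0 must lie in (0, 1), got {p0}")
    x, n = int(round(x)), int(round(n))
    if not (0 <= x <= n):
        raise ValueError("need 0 <= x <= n")
    if x == 0:
        return 1.0
    return float(sps.binom.sf(x - 1, n, p0))


def _site_p0(
    assignments: Assignments, ref: MatureMiRNA, position: int, trim3: int = 2
) -> float:
    """p0 from covering-read qualities: mean(10^(-Q/10))/3 weighted by read
    multiplicity; the division by 3 converts the per-base error rate into
    the probability of the specific A→G substitution."""
    err_sum = weight = 0.0
    for read, hit in assignments:
        if not hit.unique or hit.mirna_id != ref.id:
            continue
        lo, hi = hit.covered_interval(len(ref.sequence), trim3)
        if lo <= position <= hi:
            err_sum += read.count * 10 ** (-read.mean_quality / 10)
            weight += read.count
    if weight == 0:
        return FALLBACK_P0
    return err_sum / weight / 3.0


def _edited_sequence_multimaps(
    ref: MatureMiRNA, position: int, refs: Sequence[MatureMiRNA]
) -> bool:
    """True when the in-silico edited mature sequence attains an
    equal-or-better hit on another reference."""
    edited = ref.sequence[: position - 1] + "G" + ref.sequence[position:]
    hits = align_to_references(edited, refs)
    own = [h for h in hits if h.mirna_id == ref.id]
    own_mm = min(h.n_mismatches for h in own) if own else 1
    return any(h.mirna_id != ref.id and h.n_mismatches <= own_mm for h in hits)


def apply_exclusion_filters(
    site: EditSiteStat,
    library: LibraryStats,
    refs_by_id: Mapping[str, MatureMiRNA],
    refs: Sequence[MatureMiRNA],
    alpha: float = 0.05,
    min_rpm: float = 1.0,
) -> str:
    """Assign the final status of a tallied+tested site.

    Exclusions, in order: repeat-element host miRNA; canonical miRNA
    expression below ``min_rpm`` RPM; edited sequence multimapping to
    another reference.  Surviving sites are ``called`` when their BH FDR
    is at or below ``alpha``.
    """
    ref = refs_by_id[site.mirna_id]
    if ref.blacklisted:
        site.status = "filtered(repeat_element)"
    elif library.rpm(site.mirna_id) < min_rpm:
        site.status = "filtered(low_expression)"
    elif site.x > 0 and _edited_sequence_multimaps(ref, site.position, refs):
        site.status = "filtered(multimapping)"
    elif np.isfinite(site.fdr) and site.fdr <= alpha:
        site.status = "called"
    else:
        site.status = "filtered(not_significant)"
    return site.status


def tally_all_sites(
    assignments: Assignments,
    refs: Sequence[MatureMiRNA],
    exclusion_3p: int = TERMINAL_EXCLUSION_3P,
    trim3: int = 2,
) -> list[EditSiteStat]:
    """Tally every screenable A site of every reference with coverage."""
    by_mirna: dict[str, list[tuple[CollapsedRead, AlignmentHit]]] = {}
    for read, hit in assignments:
        if hit.unique:
            by_mirna.setdefault(hit.mirna_id, []).append((read, hit))
    sites = []
    for ref in refs:
        sub = by_mirna.get(ref.id)
        if not sub:
            continue
        for pos in _screenable_positions(ref, exclusion_3p):
            x, n = tally_site(sub, ref, pos, trim3)
            if n == 0:
                continue
            sites.append(EditSiteStat(ref.id, pos, x, n, p0=float("nan")))
    return sites


def detect_sample(
    assignments: Assignments,
    library: LibraryStats,
    refs: Sequence[MatureMiRNA],
    alpha: float = 0.05,
    p0_policy: str = "quality",
    p0_fixed: float = FALLBACK_P0,
    exclusion_3p: int = TERMINAL_EXCLUSION_3P,
    min_rpm: float = 1.0,
    trim3: int = 2,
) -> list[EditSiteStat]:
    """Full per-sample detection: tally → binomial test → BH → filters."""
    if p0_policy not in ("quality", "fixed"):
        raise ValueError(f"unknown p0 policy: {p0_policy}")
    refs_by_id = {r.id: r for r in refs}
    sites = tally_all_sites(assignments, refs, exclusion_3p, trim3)
    for s in sites:
        ref = refs_by_id[s.mirna_id]
        if p0_policy == "quality":
            s.p0 = _site_p0(assignments, ref, s.position, trim3)
        else:
            s.p0 = p0_fixed
        s.p_value = binomial_edit_test(s.x, s.n, s.p0)
    if sites:
        fdrs = bh_adjust([s.p_value for s in sites])
        for s, q in zip(sites, fdrs):
            s.fdr = float(q)
    for s in sites:
        apply_exclusion_filters(s, library, refs_by_id, refs, alpha, min_rpm)
    return sites


def build_editing_table(
    per_sample: Mapping[str, Sequence[EditSiteStat]],
    groups: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Cohort editing matrix: one row per site called in ≥ 1 sample.

    Columns: per-sample editing level (%), site frequency (% of samples
    with a call) and, when group labels are given, the mean level per
    group.  Levels are reported for every sample covering the site, calls
    or not, so group means reflect the underlying fractions.
    """
    called: set[tuple[str, int]] = set()
    levels: dict[tuple[str, int], dict[str, float]] = {}
    for sample, sites in per_sample.items():
        for s in sites:
            key = (s.mirna_id, s.position)
            levels.setdefault(key, {})[sample] = round(s.editing_level, 2)
            if s.status == "called":
                called.add(key)
    samples = list(per_sample)
    rows = []
    for key in sorted(called):
        mirna, pos = key
        row: dict[str, object] = {"mirna": mirna, "position": pos}
        n_called = sum(
            1
            for sample in samples
            if any(
                s.mirna_id == mirna and s.position == pos and s.status == "called"
                for s in per_sample[sample]
            )
        )
        for sample in samples:
            row[sample] = levels[key].get(sample, float("nan"))
        row["frequency_pct"] = round(100.0 * n_called / len(samples), 2)
        if groups:
            for g in sorted(set(groups.values())):
                vals = [
                    levels[key][s]
                    for s in samples
                    if groups.get(s) == g and s in levels[key]
                ]
                row[f"mean_pct_{g}"] = (
                    round(float(np.mean(vals)), 2) if vals else float("nan")
                )
        rows.append(row)
    return pd.DataFrame(rows)
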