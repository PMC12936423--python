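"""Seed retargeting analysis for edited miRNAs.

An A-to-I edit inside the seed (miRNA positions 2–8 from the 5' end)
changes which mRNAs the silencing complex can pair with.  This module
derives the wild-type and edited seeds, scans 3'UTR sequences for the
canonical site types on the mRNA sense strand, and applies the candidate
cascade used to nominate gained targets:

(a) significantly downregulated under the edited mimic
    (FDR <= 0.05 and log2FC <= -1) — and, when a wild-type contrast is
    supplied, not significantly downregulated under the wild-type mimic;
(b) present in the supplied prediction list (e.g. a miRDB export);
(c) at least one edited-seed binding site but no wild-type site in the
    3'UTR.

Site types, with the 7-nt "m8 core" = reverse complement of seed
positions 2–8 of the miRNA:
  7mer-m8 : the core itself;
  7mer-A1 : reverse complement of positions 2–7 followed by an A;
  8mer    : the core followed by an A.
The binary "binding site" count collapses overlapping matches so that
sites sharing an m8 core count once.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

__all__ = [
    "SeedContext",
    "TargetCandidate",
    "extract_seed",
    "apply_edit",
    "seed_site_scan",
    "count_binding_sites",
    "candidate_filter",
    "targetome_shift",
    "load_utrs",
    "load_predictions",
]

SITE_TYPES = ("7mer-m8", "7mer-A1", "8mer")

_RNA_TO_DNA = str.maketrans("uU", "tT")


def _dna(seq: str) -> str:
    return seq.translate(_RNA_TO_DNA).upper()


def extract_seed(mature: str) -> str:
    """Seed = nucleotides 2–8 (1-based, inclusive) from the miRNA 5' end."""
    if len(mature) < 8:
        raise ValueError(f"mature sequence too short for a seed: {mature!r}")
    return mature[1:8].upper()


def apply_edit(mature: str, position: int) -> str:
    """Apply one A-to-I edit in silico: the adenosine at ``position``
    (1-based) is replaced by G, since inosine is read as guanosine."""
    if not (1 <= position <= len(mature)):
        raise ValueError(f"position {position} outside 1..{len(mature)}")
    base = mature[position - 1].upper()
    if base != "A":
        raise ValueError(
            f"cannot edit position {position}: base is {base}, not A"
        )
    g = "G" if mature.isupper() else "g"
    return mature[: position - 1] + g + mature[position:]


@dataclass(frozen=True)
class SeedContext:
    """A miRNA's seed and the mRNA-sense match patterns derived from it."""

    mirna_id: str
    mature: str
    edit_position: int | None = None
    seed: str = field(init=False)
    patterns: Mapping[str, str] = field(init=False)

    def __post_init__(self) -> None:
        mature = apply_edit(self.mature, self.edit_position) if self.edit_position else self.mature
        seed = extract_seed(mature)
        core = str(Seq(_dna(seed)).reverse_complement())  # 7mer-m8 core
        object.__setattr__(self, "seed", seed)
        object.__setattr__(
            self,
            "patterns",
            {"7mer-m8": core, "7mer-A1": core[1:] + "A", "8mer": core + "A"},
        )

    @property
    def core(self) -> str:
        return self.patterns["7mer-m8"]


def _check_utr(utr: str) -> str:
    utr = utr.upper()
    bad = set(utr) - set("ACGT")
    if bad:
        raise ValueError(f"UTR contains non-ACGT symbols: {sorted(bad)}")
    return utr


def seed_site_scan(
    utr: str, ctx: SeedContext, site_types: Iterable[str] = SITE_TYPES
) -> list[tuple[int, int, str]]:
    """Every occurrence of the requested site types in the UTR.

    Returns ``(start, end, site_type)`` with 0-based half-open coordinates
    on the UTR sense strand; overlapping occurrences are all reported.
    """
    utr = _check_utr(utr)
    unknown = set(site_types) - set(SITE_TYPES)
    if unknown:
        raise ValueError(f"unknown site type(s): {sorted(unknown)}")
    sites = []
    for st in site_types:
        pat = ctx.patterns[st]
        start = utr.find(pat)
        while start >= 0:
            sites.append((start, start + len(pat), st))
            start = utr.find(pat, start + 1)
    return sorted(sites)


def count_binding_sites(
    utr: str, ctx: SeedContext, site_types: Iterable[str] = ("7mer-m8", "8mer")
) -> int:
    """Binary-site count: distinct m8-core occurrences (an 8mer contains
    the core and counts once), plus — only if requested — 7mer-A1 matches
    whose position does not extend an m8 core."""
    utr = _check_utr(utr)
    core_starts = set()
    start = utr.find(ctx.core)
    while start >= 0:
        core_starts.add(start)
        start = utr.find(ctx.core, start + 1)
    n = len(core_starts) if ({"7mer-m8", "8mer"} & set(site_types)) else 0
    if "7mer-A1" in site_types:
        pat = ctx.patterns["7mer-A1"]
        start = utr.find(pat)
        while start >= 0:
            if (start - 1) not in core_starts:
                n += 1
            start = utr.find(pat, start + 1)
    return n


@dataclass
class TargetCandidate:
    """One gene's evidence against the candidate cascade."""

    gene: str
    wt_sites: int
    ed_sites: int
    log2fc: float
    fdr: float
    predicted: bool
    score: float = float("nan")
    passes: bool = False
    reasons: list[str] = field(default_factory=list)


def candidate_filter(
    de: pd.DataFrame,
    site_counts: Mapping[str, tuple[int, int]],
    predictions: Mapping[str, float],
    fdr_max: float = 0.05,
    lfc_max: float = -1.0,
    wt_de: pd.DataFrame | None = None,
) -> list[TargetCandidate]:
    """Apply criteria (a)–(c) to every gene in the edited-mimic DE table.

    ``site_counts`` maps gene → (wt_sites, ed_sites); ``predictions`` maps
    gene → prediction score.  ``wt_de``, when given, is the wild-type
    mimic contrast used to enforce the "only downregulated under the
    edited mimic" reading of criterion (a).
    """
    wt_down: set[str] = set()
    if wt_de is not None:
        wt_down = set(
            wt_de.loc[(wt_de.fdr <= fdr_max) & (wt_de.log2fc <= lfc_max), "feature"]
        )
    out = []
    for row in de.itertuples():
        gene = row.feature
        wt_n, ed_n = site_counts.get(gene, (0, 0))
        cand = TargetCandidate(
            gene=gene,
            wt_sites=wt_n,
            ed_sites=ed_n,
            log2fc=float(row.log2fc),
            fdr=float(row.fdr),
            predicted=gene in predictions,
            score=float(predictions.get(gene, float("nan"))),
        )
        if not (cand.fdr <= fdr_max and cand.log2fc <= lfc_max):
            cand.reasons.append("not_downregulated")
        if gene in wt_down:
            cand.reasons.append("downregulated_in_wt")
        if not cand.predicted:
            cand.reasons.append("not_predicted")
        if cand.ed_sites < 1:
            cand.reasons.append("no_ed_site")
        if cand.wt_sites > 0:
            cand.reasons.append("wt_site_present")
        cand.passes = not cand.reasons
        out.append(cand)
    return out


@dataclass(frozen=True)
class TargetomeShift:
    gained: frozenset
    lost: frozenset
    shared: frozenset

    @property
    def counts(self) -> dict[str, int]:
        return {
            "gained": len(self.gained),
            "lost": len(self.lost),
            "shared": len(self.shared),
        }


def targetome_shift(wt_targets: Iterable[str], ed_targets: Iterable[str]) -> TargetomeShift:
    """Set decomposition of the wild-type vs edited targetomes."""
    wt, ed = frozenset(wt_targets), frozenset(ed_targets)
    return TargetomeShift(gained=ed - wt, lost=wt - ed, shared=wt & ed)


def load_utrs(fasta: str | os.PathLike) -> dict[str, str]:
    """3'UTR sequences keyed by gene symbol."""
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(fasta), "fasta")}


def load_predictions(tsv: str | os.PathLike) -> dict[str, float]:
    """Predicted-target list: TSV with columns gene, score (0–100)."""
    df = pd.read_csv(tsv, sep="\t")
    if not {"gene", "score"} <= set(df.columns):
        raise ValueError("prediction list needs 'gene' and 'score' columns")
    return dict(zip(df.gene, df.score.astype(float)))
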