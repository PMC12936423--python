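"""Efficiency-corrected relative qPCR quantification.

Amplification efficiency is derived from the standard-curve slope,
E = 10^(−1/slope) (E = 2 means perfect doubling per cycle); assays with
E < 1.6 are discarded.  Relative expression of a target between a test
and a control group follows the efficiency-corrected ratio on group-mean
Ct values,

    ratio = E_target^(ΔCt_target) / E_ref^(ΔCt_ref),
    ΔCt = mean Ct(control) − mean Ct(test),

with multiple reference assays combined by the geometric mean of their
per-assay factors.  With E = 2 exactly this reduces to the textbook
2^(−ΔΔCt).  The edited/wild-type miRNA ratio readout is the quotient of
the two relative ratios against a shared reference.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "QpcrAssay",
    "efficiency_from_slope",
    "filter_efficiency",
    "relative_ratio",
    "ed_wt_ratio",
    "read_qpcr",
]

MIN_EFFICIENCY = 1.6


def efficiency_from_slope(slope: float) -> float:
    """E = 10^(−1/slope); a slope of −3.3219 gives E ≈ 2."""
    if slope >= 0:
        raise ValueError(f"standard-curve slope must be negative, got {slope}")
    return 10.0 ** (-1.0 / slope)


@dataclass
class QpcrAssay:
    """One assay's Ct values with per-sample group labels."""

    assay_id: str
    role: str  # "target" or "reference"
    slope: float
    ct: pd.Series  # index: sample id
    groups: pd.Series  # index: sample id

    def __post_init__(self) -> None:
        self.efficiency = efficiency_from_slope(self.slope)

    def mean_ct(self, group: str) -> float:
        vals = self.ct[self.groups == group]
        if vals.empty:
            raise ValueError(f"assay {self.assay_id}: no Ct values for group {group!r}")
        return float(vals.mean())


def filter_efficiency(
    assays: list[QpcrAssay], min_e: float = MIN_EFFICIENCY
) -> list[QpcrAssay]:
    """Keep assays with E >= min_e (the boundary is retained)."""
    return [a for a in assays if a.efficiency >= min_e]


def _factor(assay: QpcrAssay, test_group: str, control_group: str) -> float:
    dct = assay.mean_ct(control_group) - assay.mean_ct(test_group)
    return assay.efficiency**dct


def relative_ratio(
    target: QpcrAssay,
    references: QpcrAssay | list[QpcrAssay],
    test_group: str,
    control_group: str,
) -> float:
    """Efficiency-corrected relative expression of ``target`` in the test
    group versus the control group, normalised to the reference assay(s)."""
    refs = references if isinstance(references, list) else [references]
    if not refs:
        raise ValueError("at least one reference assay is required")
    num = _factor(target, test_group, control_group)
    den = math.exp(
        float(np.mean([math.log(_factor(r, test_group, control_group)) for r in refs]))
    )
    return num / den


def ed_wt_ratio(
    ed_assay: QpcrAssay,
    wt_assay: QpcrAssay,
    references: QpcrAssay | list[QpcrAssay],
    test_group: str,
    control_group: str,
) -> float:
    """Edited/wild-type miRNA relative level between two groups (the
    ADAR1-knockdown readout)."""
    return relative_ratio(ed_assay, references, test_group, control_group) / relative_ratio(
        wt_assay, references, test_group, control_group
    )


def read_qpcr(path) -> list[QpcrAssay]:
    """Parse a qPCR CSV with columns assay, role, slope, sample, group, ct."""
    df = pd.read_csv(path)
    needed = {"assay", "role", "slope", "sample", "group", "ct"}
    if not needed <= set(df.columns):
        raise ValueError(f"qPCR table needs columns {sorted(needed)}")
    assays = []
    for assay_id, sub in df.groupby("assay", sort=True):
        slopes = sub.slope.unique()
        if len(slopes) != 1:
            raise ValueError(f"assay {assay_id}: inconsistent slopes {slopes}")
        sub = sub.set_index("sample")
        assays.append(
            QpcrAssay(
                assay_id=str(assay_id),
                role=str(sub.role.iloc[0]),
                slope=float(slopes[0]),
                ct=sub.ct.astype(float),
                groups=sub.group,
            )
        )
    return assays
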