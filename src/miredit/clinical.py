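"""Clinical association of editing levels: group comparison, correlation
with outcome/stage, and Kaplan–Meier survival with a median split.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats as sps

__all__ = [
    "ClinicalRecord",
    "KMCurve",
    "mann_whitney_u",
    "pearson_r",
    "median_dichotomize",
    "km_estimate",
    "logrank_test",
    "read_clinical",
    "associate",
]

CLINICAL_COLUMNS = ["sample", "group", "os_months", "event", "figo", "tnm_m"]


@dataclass(frozen=True)
class ClinicalRecord:
    sample: str
    group: str
    os_months: float | None = None
    event: int | None = None
    figo: int | None = None
    tnm_m: int | None = None

    def __post_init__(self) -> None:
        if self.os_months is not None and self.os_months < 0:
            raise ValueError("overall survival must be >= 0")
        if self.figo is not None and not (1 <= self.figo <= 4):
            raise ValueError("FIGO ordinal must lie in 1..4")


def read_clinical(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"clinical table missing columns: {missing}")
    return df


def mann_whitney_u(a, b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U with midrank ties.

    Exact p when min(n) <= 8 and there are no ties; otherwise the normal
    approximation with tie correction.  Returns (U of the first sample, p).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    no_ties = len(np.unique(np.concatenate([a, b]))) == a.size + b.size
    method = "exact" if (min(a.size, b.size) <= 8 and no_ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def pearson_r(x, y) -> tuple[float, float]:
    """Product-moment correlation with a two-sided t-based p (n−2 df)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need two equal-length vectors with n >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("correlation undefined for a constant vector")
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def median_dichotomize(values) -> list[str]:
    """Split at the sample median: strictly above → 'high', otherwise
    (including ties at the median) → 'low'."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError("need at least 2 values to dichotomize")
    med = float(np.median(v))
    if np.all(v == v[0]):
        warnings.warn("all values identical; every sample labelled 'low'")
    return ["high" if x > med else "low" for x in v]


@dataclass
class KMCurve:
    """Product-limit survival curve: times (starting at 0), S(t), and the
    number at risk just before each time."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return float(self.survival[max(idx, 0)])


def km_estimate(times, events) -> KMCurve:
    """Kaplan–Meier product-limit estimate under right censoring."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if (times < 0).any():
        raise ValueError("survival times must be >= 0")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    tab = kmf.event_table
    grid = np.asarray(tab.index, dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy()
    at_risk = tab["at_risk"].to_numpy(dtype=float)
    if grid.size == 0 or grid[0] != 0.0:
        grid = np.concatenate([[0.0], grid])
        surv = np.concatenate([[1.0], surv])
        at_risk = np.concatenate([[float(times.size)], at_risk])
    return KMCurve(grid, surv, at_risk)


def logrank_test(
    times_a, events_a, times_b, events_b
) -> tuple[float, float]:
    """Standard 1-df log-rank comparison of two survival curves."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups need at least one subject")
    res = _ll_logrank(ta, tb, np.asarray(events_a), np.asarray(events_b))
    return float(res.test_statistic), float(res.p_value)


def associate(clinical: pd.DataFrame, editing: pd.Series) -> dict:
    """Standard association battery for one editing site.

    ``editing`` maps sample id → editing level (%).  Compares tumour vs
    control levels (Mann–Whitney), correlates tumour levels with OS, FIGO
    and the TNM M flag (Pearson on ordinal scores), and runs a
    median-split Kaplan–Meier / log-rank on the tumour group.
    """
    df = clinical.set_index("sample")
    ed = editing.reindex(df.index)
    tum = df[df.group == "tumour"]
    ctl = df[df.group == "control"]
    out: dict = {}
    if len(tum) and len(ctl):
        u, p = mann_whitney_u(ed[tum.index].dropna(), ed[ctl.index].dropna())
        out["mw_u"], out["mw_p"] = u, p
    ed_t = ed[tum.index].astype(float)
    for col in ("os_months", "figo", "tnm_m"):
        sub = pd.concat([ed_t, tum[col]], axis=1).dropna()
        if len(sub) >= 3 and sub.iloc[:, 0].std() > 0 and sub.iloc[:, 1].std() > 0:
            r, p = pearson_r(sub.iloc[:, 0], sub.iloc[:, 1])
            out[f"r_{col}"], out[f"r_{col}_p"] = r, p
    surv = pd.concat([ed_t, tum[["os_months", "event"]]], axis=1).dropna()
    if len(surv) >= 4:
        labels = np.array(median_dichotomize(surv.iloc[:, 0]))
        hi = surv[labels == "high"]
        lo = surv[labels == "low"]
        if len(hi) and len(lo):
            chi2, p = logrank_test(
                hi.os_months, hi.event, lo.os_months, lo.event
            )
            out["logrank_chi2"], out["logrank_p"] = chi2, p
            out["km_high"] = km_estimate(hi.os_months, hi.event)
            out["km_low"] = km_estimate(lo.os_months, lo.event)
    return out
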