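"""Count-matrix statistics: low-count filtering, TMM normalisation,
log-CPM transform, empirical-Bayes moderated differential expression, and
the closed-form RNA-seq power / sample-size calculation.

TMM (trimmed mean of M-values) computes one scaling factor per library as
the exponentiated, inverse-variance-weighted mean of log expression ratios
(M-values) against a reference library, after trimming the most extreme
30% of M-values and 5% of A-values; factors are rescaled to geometric
mean 1 so they only encode composition differences, not depth.

The moderated test shrinks per-feature residual variances toward a pooled
prior fitted by method-of-moments on the log-variance distribution
(scaled-F model), then forms t-statistics with augmented degrees of
freedom — the standard empirical-Bayes construction for small-n designs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special
from scipy import stats as sps

from .stats import bh_adjust

__all__ = [
    "CountMatrix",
    "DEResult",
    "PowerParams",
    "filter_low_counts",
    "tmm_factors",
    "log_cpm",
    "moderated_de",
    "rnaseq_power_n",
]


@dataclass
class CountMatrix:
    """Features × samples raw counts with library sizes, optional group
    labels and TMM factors."""

    counts: pd.DataFrame
    groups: pd.Series | None = None
    tmm: pd.Series | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        if self.groups is not None:
            self.groups = pd.Series(self.groups).reindex(self.counts.columns)

    @property
    def lib_sizes(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def cpm(self) -> pd.DataFrame:
        return self.counts * 1e6 / self.lib_sizes


def filter_low_counts(
    m: CountMatrix, mode: str = "gene", min_count: float = 10.0, require: str = "all"
) -> CountMatrix:
    """Drop lowly expressed features on the CPM-equivalent scale.

    ``gene`` mode removes features whose expression, assessed as CPM
    against the threshold equivalent to ``min_count`` raw counts in the
    smallest library, falls below that threshold; ``mirna`` mode is the
    same rule with a default threshold of 1 raw-count-equivalent.
    ``require='all'`` keeps a feature only if every sample clears the
    threshold; ``'any'`` if at least one does.
    """
    if mode not in ("gene", "mirna"):
        raise ValueError(f"unknown filter mode: {mode}")
    if require not in ("all", "any"):
        raise ValueError(f"require must be 'all' or 'any'")
    if mode == "mirna" and min_count == 10.0:
        min_count = 1.0
    cpm_threshold = min_count * 1e6 / float(m.lib_sizes.min())
    cpm = m.cpm()
    ok = cpm >= cpm_threshold
    keep = ok.all(axis=1) if require == "all" else ok.any(axis=1)
    return CountMatrix(m.counts.loc[keep], m.groups)


def _tmm_pair(
    obs: np.ndarray, ref: np.ndarray, lib_obs: float, lib_ref: float,
    trim_m: float, trim_a: float,
) -> float:
    """log2 TMM factor of one library against the reference."""
    mask = (obs > 0) & (ref > 0)
    o, r = obs[mask], ref[mask]
    fo, fr = o / lib_obs, r / lib_ref
    m_vals = np.log2(fo / fr)
    a_vals = 0.5 * np.log2(fo * fr)
    # inverse asymptotic (delta-method) variance weights
    w = 1.0 / ((lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r))
    if np.allclose(m_vals, m_vals[0] if m_vals.size else 0.0, atol=1e-10):
        return float(m_vals[0]) if m_vals.size else 0.0
    n = m_vals.size
    lo_m, hi_m = math.floor(n * trim_m) + 1, n - math.floor(n * trim_m)
    lo_a, hi_a = math.floor(n * trim_a) + 1, n - math.floor(n * trim_a)
    rank_m = sps.rankdata(m_vals)
    rank_a = sps.rankdata(a_vals)
    keep = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not keep.any():
        return 0.0
    return float(np.sum(w[keep] * m_vals[keep]) / np.sum(w[keep]))


def tmm_factors(
    m: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05,
    ref_sample: str | None = None,
) -> pd.Series:
    """Per-sample TMM normalisation factors, geometric mean 1.

    The reference library is the one whose upper-quartile CPM is closest
    to the mean upper quartile, unless ``ref_sample`` names one.
    """
    counts = m.counts
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = m.lib_sizes.astype(float)
    if (lib <= 0).any():
        bad = lib.index[lib <= 0].tolist()
        raise ValueError(f"all-zero sample(s): {bad}")
    if ref_sample is None:
        uq = counts.div(lib, axis=1).quantile(0.75)
        ref_sample = (uq - uq.mean()).abs().idxmin()
    ref = counts[ref_sample].to_numpy(dtype=float)
    logf = {}
    for s in counts.columns:
        if s == ref_sample:
            logf[s] = 0.0
        else:
            logf[s] = _tmm_pair(
                counts[s].to_numpy(dtype=float), ref, lib[s], lib[ref_sample],
                trim_m, trim_a,
            )
    f = pd.Series({s: 2.0 ** v for s, v in logf.items()})[counts.columns]
    f /= np.exp(np.mean(np.log(f)))  # geometric mean 1
    m.tmm = f
    return f


def log_cpm(m: CountMatrix) -> pd.DataFrame:
    """log2 counts-per-million with a 0.5 prior count on TMM-effective
    library sizes: log2((c + 0.5) / (lib·tmm + 1) × 1e6)."""
    if m.tmm is None:
        tmm_factors(m)
    eff = m.lib_sizes * m.tmm
    return np.log2((m.counts + 0.5).div(eff + 1.0, axis=1) * 1e6)


@dataclass
class DEResult:
    feature: str
    log2fc: float
    t: float
    p_value: float
    fdr: float = float("nan")

    @property
    def direction(self) -> str:
        return "up" if self.log2fc > 0 else ("down" if self.log2fc < 0 else "flat")


def _trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x for y > 0 (Newton on 1/trigamma)."""
    if x <= 0:
        return float("inf")
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = special.polygamma(1, y)
        dif = tri * (1.0 - tri / x) / special.polygamma(2, y)
        y += dif
        if abs(dif) < 1e-10 * y:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of sample variances toward a fitted prior.

    Fits a scaled-F model to the variance distribution by matching moments
    of log(s2), returning (posterior variances, prior df d0, prior s0^2).
    """
    s2 = np.asarray(s2, dtype=float)
    pos = s2 > 0
    e = np.log(s2[pos]) - special.digamma(df / 2) + math.log(df / 2)
    if e.size < 2:  # degenerate: no variance distribution to fit
        s02 = float(np.exp(e[0])) if e.size else 0.0
        return np.full_like(s2, s02), float("inf"), s02
    emean = float(np.mean(e))
    evar = float(np.var(e, ddof=1)) - float(special.polygamma(1, df / 2))
    if evar > 0:
        d0 = 2.0 * _trigamma_inverse(evar)
        s02 = math.exp(
            emean + float(special.digamma(d0 / 2)) - math.log(d0 / 2)
        )
    else:
        d0, s02 = float("inf"), math.exp(emean)
    if math.isinf(d0):
        post = np.full_like(s2, s02)
    else:
        post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


def moderated_de(
    logmat: pd.DataFrame,
    groups: pd.Series,
    contrast: tuple[str, str] | None = None,
    prior_df: float | None = None,
) -> pd.DataFrame:
    """Two-group moderated t-test on a log-expression matrix.

    log2FC is mean(test) − mean(control) per feature, with
    ``contrast=(test, control)``; by default the two group labels in
    sorted order are (test, control) = (labels[1], labels[0]).
    ``prior_df`` overrides the fitted prior degrees of freedom (0 gives
    ordinary two-sample t-statistics).  Returns a DataFrame with columns
    feature, log2fc, t, p_value, fdr, direction sorted by p.
    """
    groups = pd.Series(groups).reindex(logmat.columns)
    labels = sorted(groups.dropna().unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly two groups, got {labels}")
    if contrast is None:
        contrast = (labels[1], labels[0])
    test, control = contrast
    a = logmat.loc[:, groups == test].to_numpy(dtype=float)
    b = logmat.loc[:, groups == control].to_numpy(dtype=float)
    n1, n2 = a.shape[1], b.shape[1]
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = a.mean(axis=1) - b.mean(axis=1)
    df_resid = n1 + n2 - 2
    s2 = (a.var(axis=1, ddof=1) * (n1 - 1) + b.var(axis=1, ddof=1) * (n2 - 1)) / df_resid
    if prior_df is None:
        s2_post, d0, _ = squeeze_var(s2, df_resid)
    elif prior_df == 0:
        s2_post, d0 = s2, 0.0
    elif math.isinf(prior_df):
        s2_post, d0 = np.full_like(s2, float(np.mean(s2))), prior_df
    else:
        _, _, s02 = squeeze_var(s2, df_resid)
        d0 = prior_df
        s2_post = (d0 * s02 + df_resid * s2) / (d0 + df_resid)
    se = np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, diff / se, 0.0)
    df_total = df_resid + (0.0 if math.isinf(d0) else d0)
    if math.isinf(df_total) or df_total > 1e6:
        p = 2.0 * sps.norm.sf(np.abs(t))
    else:
        p = 2.0 * sps.t.sf(np.abs(t), df_total)
    p = np.clip(p, 0.0, 1.0)
    out = pd.DataFrame(
        {
            "feature": logmat.index,
            "log2fc": diff,
            "t": t,
            "p_value": p,
            "fdr": bh_adjust(p),
        }
    )
    out["direction"] = np.where(
        out.log2fc > 0, "up", np.where(out.log2fc < 0, "down", "flat")
    )
    return out.sort_values("p_value", kind="mergesort").reset_index(drop=True)


@dataclass(frozen=True)
class PowerParams:
    """Inputs to the closed-form RNA-seq sample-size calculation: mean
    sequencing depth per feature, per-group coefficient of variation,
    detectable fold change, two-sided size and target power."""

    depth: float
    cv: float
    effect: float
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.depth <= 0 or self.cv < 0:
            raise ValueError("need depth > 0 and cv >= 0")
        if self.effect <= 1:
            raise ValueError("fold change must exceed 1")
        if not (0 < self.alpha < 1 and 0 < self.power < 1):
            raise ValueError("alpha and power must lie in (0, 1)")


def rnaseq_power_n(p: PowerParams) -> int:
    """Samples per group to detect a fold change ``effect`` at the given
    size and power, for negative-binomial counts of mean depth μ and
    coefficient of variation cv:

        n = ceil( 2 (z_{1−α/2} + z_{power})² (1/μ + cv²) / ln(Δ)² )
    """
    z_a = sps.norm.ppf(1 - p.alpha / 2)
    z_b = sps.norm.ppf(p.power)
    n = 2 * (z_a + z_b) ** 2 * (1.0 / p.depth + p.cv**2) / math.log(p.effect) ** 2
    return max(1, math.ceil(n))
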