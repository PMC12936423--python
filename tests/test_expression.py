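"""Count filtering, TMM normalisation, log-CPM, moderated DE and the
sample-size closed form."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from miredit.expression import (
    CountMatrix,
    PowerParams,
    filter_low_counts,
    log_cpm,
    moderated_de,
    rnaseq_power_n,
    tmm_factors,
)


def _cm(mat, groups=None, columns=None):
    df = pd.DataFrame(mat)
    if columns is not None:
        df.columns = columns
    g = pd.Series(groups, index=df.columns) if groups is not None else None
    return CountMatrix(df, g)


class TestFilterLowCounts:
    def test_all_zero_feature_dropped(self):
        cm = _cm({"a": [0, 100, 50], "b": [0, 90, 60]})
        out = filter_low_counts(cm)
        assert 0 not in out.counts.index

    def test_nine_counts_in_smallest_library_dropped(self):
        counts = pd.DataFrame(
            {"small": [9, 991], "big": [200, 9800]},
            index=["g1", "g2"],
        )
        out = filter_low_counts(CountMatrix(counts), mode="gene")
        assert "g1" not in out.counts.index

    def test_feature_above_threshold_everywhere_kept(self):
        counts = pd.DataFrame({"small": [50, 950], "big": [600, 9400]}, index=["g1", "g2"])
        out = filter_low_counts(CountMatrix(counts), mode="gene")
        assert "g1" in out.counts.index

    def test_bad_mode_rejected(self):
        with pytest.raises(ValueError):
            filter_low_counts(_cm({"a": [1]}), mode="protein")


class TestTMM:
    def test_identical_libraries_unit_factors(self, rng):
        col = rng.poisson(100, 500)
        cm = _cm({"a": col, "b": col, "c": col})
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_depth_scaling_absorbed_by_library_size(self, rng):
        col = rng.poisson(rng.lognormal(5, 1, 400))
        cm = _cm({"a": col, "b": col * 3})
        assert np.allclose(tmm_factors(cm), 1.0)

    def test_geometric_mean_one(self, rng):
        cm = _cm({c: rng.poisson(rng.lognormal(4, 1, 300)) for c in "abcde"})
        f = tmm_factors(cm)
        assert np.exp(np.mean(np.log(f))) == pytest.approx(1.0)
        assert (f > 0).all()

    def test_all_zero_sample_is_error(self):
        cm = _cm({"a": [10, 20], "b": [0, 0]})
        with pytest.raises(ValueError):
            tmm_factors(cm)

    def test_matches_literal_trimmed_mean_definition(self, rng):
        """Factor for one library against an explicit reference equals a
        from-scratch doubly-trimmed weighted mean of M-values."""
        obs = rng.poisson(rng.lognormal(5, 1, 300)).astype(float)
        ref = rng.poisson(rng.lognormal(5, 1, 300)).astype(float)
        cm = _cm({"obs": obs.astype(int), "ref": ref.astype(int)})
        f = tmm_factors(cm, ref_sample="ref")

        lib_o, lib_r = obs.sum(), ref.sum()
        mask = (obs > 0) & (ref > 0)
        o, r = obs[mask], ref[mask]
        m = np.log2((o / lib_o) / (r / lib_r))
        a = 0.5 * np.log2((o / lib_o) * (r / lib_r))
        w = 1.0 / ((lib_o - o) / (lib_o * o) + (lib_r - r) / (lib_r * r))
        n = m.size
        keep = np.ones(n, dtype=bool)
        for vals, trim in ((m, 0.30), (a, 0.05)):
            ranks = sps.rankdata(vals)
            k = np.floor(n * trim)
            keep &= (ranks >= k + 1) & (ranks <= n - k)
        log_f = np.sum(w[keep] * m[keep]) / np.sum(w[keep])
        # rescale both to geometric mean 1, as the implementation does
        raw = np.array([2.0**log_f, 1.0])
        raw = raw / np.exp(np.mean(np.log(raw)))
        assert f["obs"] == pytest.approx(raw[0], rel=1e-6)
        assert f["ref"] == pytest.approx(raw[1], rel=1e-6)


class TestLogCpm:
    def test_stated_formula(self):
        counts = pd.DataFrame({"a": [0, 999_999], "b": [0, 999_999]}, index=["g0", "g1"])
        cm = CountMatrix(counts)
        cm.tmm = pd.Series({"a": 1.0, "b": 1.0})
        out = log_cpm(cm)
        expected = math.log2(0.5 / (999_999 + 1) * 1e6)
        assert out.loc["g0", "a"] == pytest.approx(expected)

    def test_scale_invariance_and_monotonicity(self, rng):
        base = rng.poisson(200, size=(100, 3))
        cm1 = _cm(pd.DataFrame(base, columns=list("abc")))
        cm2 = _cm(pd.DataFrame(base * 2, columns=list("abc")))
        l1, l2 = log_cpm(cm1), log_cpm(cm2)
        assert np.abs(l1.values - l2.values).max() < 0.01
        col = l1["a"].to_numpy()
        counts = base[:, 0]
        order = np.argsort(counts, kind="mergesort")
        assert (np.diff(col[order]) >= -1e-12).all()


class TestModeratedDE:
    def test_identical_groups_null_statistics(self):
        mat = pd.DataFrame(
            np.tile(np.arange(10.0), (4, 1)).T, columns=list("abcd")
        )
        mat.index = [f"g{i}" for i in range(10)]
        groups = pd.Series(["x", "x", "y", "y"], index=mat.columns)
        # add feature-specific but group-identical values
        de = moderated_de(mat + 0.0, groups)
        assert np.allclose(de.log2fc, 0.0)
        assert np.allclose(de.t, 0.0)

    def test_prior_df_zero_is_ordinary_t(self, rng):
        mat = pd.DataFrame(
            rng.normal(5, 1, (60, 10)), columns=[f"s{i}" for i in range(10)]
        )
        mat.index = [f"g{i}" for i in range(60)]
        groups = pd.Series(["c"] * 5 + ["t"] * 5, index=mat.columns)
        de = moderated_de(mat, groups, prior_df=0).set_index("feature")
        t_ref, p_ref = sps.ttest_ind(mat.iloc[:, 5:], mat.iloc[:, :5], axis=1)
        ref = pd.DataFrame({"t": t_ref, "p": p_ref}, index=mat.index)
        assert np.allclose(de.t, ref.reindex(de.index).t)
        assert np.allclose(de.p_value, ref.reindex(de.index).p)

    def test_huge_prior_df_ranks_by_standardized_fold_change(self, rng):
        mat = pd.DataFrame(
            rng.normal(0, 1, (80, 12)), columns=[f"s{i}" for i in range(12)]
        )
        mat.index = [f"g{i}" for i in range(80)]
        groups = pd.Series(["c"] * 6 + ["t"] * 6, index=mat.columns)
        de = moderated_de(mat, groups, prior_df=float("inf")).set_index("feature")
        # in the full-shrinkage limit every feature shares one variance, so
        # the ranking must equal the |fold change| ranking
        by_t = de.t.abs().sort_values(ascending=False).index
        lfc = de.log2fc.abs().sort_values(ascending=False).index
        assert list(by_t) == list(lfc)

    def test_small_group_rejected(self):
        mat = pd.DataFrame(np.ones((5, 3)), columns=list("abc"))
        groups = pd.Series(["x", "x", "y"], index=mat.columns)
        with pytest.raises(ValueError):
            moderated_de(mat, groups)

    def test_recovers_planted_de_with_fdr_control(self):
        """10% true DE at |log2FC|=2, n=10/group: ≥80% recovered at
        FDR<=0.05 with realized FDP <= 0.10 (averaged over seeds)."""
        recalls, fdps = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            n_genes, n = 400, 10
            truth = np.zeros(n_genes, dtype=bool)
            truth[:40] = True
            mat = rng.normal(8, 0.7, (n_genes, 2 * n))
            mat[:40, n:] += np.where(rng.random(40) < 0.5, 2.0, -2.0)[:, None]
            df = pd.DataFrame(
                mat, index=[f"g{i}" for i in range(n_genes)],
                columns=[f"s{i}" for i in range(2 * n)],
            )
            groups = pd.Series(["c"] * n + ["t"] * n, index=df.columns)
            de = moderated_de(df, groups).set_index("feature")
            called = set(de.index[(de.fdr <= 0.05)])
            true_set = {f"g{i}" for i in range(40)}
            recalls.append(len(called & true_set) / 40)
            fdps.append(len(called - true_set) / max(len(called), 1))
        assert np.mean(recalls) >= 0.8
        assert np.mean(fdps) <= 0.10


class TestPower:
    def test_monotone_in_power(self):
        lo = rnaseq_power_n(PowerParams(100, 0.4, 2, power=0.8))
        hi = rnaseq_power_n(PowerParams(100, 0.4, 2, power=0.9))
        assert hi >= lo

    def test_large_effect_needs_one_sample(self):
        assert rnaseq_power_n(PowerParams(1000, 0.01, 1e6)) == 1

    def test_direct_arithmetic(self):
        p = PowerParams(depth=100, cv=0.4, effect=2, alpha=0.05, power=0.8)
        z = sps.norm.ppf(1 - 0.05 / 2) + sps.norm.ppf(0.8)
        expected = math.ceil(2 * z**2 * (1 / 100 + 0.16) / math.log(2) ** 2)
        assert rnaseq_power_n(p) == expected

    def test_effect_at_most_one_rejected(self):
        with pytest.raises(ValueError):
            PowerParams(100, 0.4, 1.0)
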