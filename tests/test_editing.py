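"""Editing-site tallying, the binomial error-model test, BH adjustment
and the exclusion filters."""

from math import comb

import numpy as np
import pytest

from miredit.align import AlignmentHit, MatureMiRNA
from miredit.editing import (
    EditSiteStat,
    apply_exclusion_filters,
    bh_adjust,
    binomial_edit_test,
    build_editing_table,
    detect_sample,
    tally_all_sites,
    tally_site,
)
from miredit.align import LibraryStats
from miredit.preprocess import CollapsedRead


def _assignment(seq, count, ref, mismatches=(), offset=0):
    read = CollapsedRead(seq, count, 30.0)
    return read, AlignmentHit(read, ref.id, offset, list(mismatches))


REF = MatureMiRNA("mir-x", "TAATACTGCCTGGTAATGATGA")  # A at position 5


class TestTally:
    def test_counts_g_reads_over_covering_reads(self):
        edited = REF.sequence[:4] + "G" + REF.sequence[5:]
        assignments = [
            _assignment(REF.sequence, 8, REF),
            _assignment(edited, 2, REF, [(5, "A", "G")]),
        ]
        assert tally_site(assignments, REF, 5) == (2, 10)

    def test_non_a_to_g_mismatch_counts_to_n_only(self):
        other = REF.sequence[:4] + "C" + REF.sequence[5:]
        assignments = [
            _assignment(REF.sequence, 5, REF),
            _assignment(other, 5, REF, [(5, "A", "C")]),
        ]
        assert tally_site(assignments, REF, 5) == (0, 10)

    def test_non_a_reference_position_is_error(self):
        with pytest.raises(ValueError, match="not A"):
            tally_site([], REF, 1)  # reference base T
        with pytest.raises(ValueError, match="not A"):
            tally_site([], REF, 9)  # reference base C

    def test_terminal_3p_positions_not_screened(self):
        """A sites within the 3'-terminal 5 nt are excluded from screening."""
        assignments = [_assignment(REF.sequence, 10, REF)]
        sites = tally_all_sites(assignments, [REF])
        positions = {s.position for s in sites}
        ref_len = len(REF.sequence)
        assert all(p <= ref_len - 5 for p in positions)
        # every A before the exclusion zone with coverage is tallied
        expected = {
            i + 1
            for i in range(ref_len - 5)
            if REF.sequence[i] == "A"
        }
        assert positions == expected

    def test_reads_not_covering_position_excluded_from_n(self):
        # 5'-trimmed isomiR starting at mature position 7 does not cover 5
        assignments = [
            _assignment(REF.sequence, 6, REF),
            _assignment(REF.sequence[6:], 4, REF, offset=6),
        ]
        assert tally_site(assignments, REF, 5) == (0, 6)


class TestBinomialTest:
    def test_zero_edited_reads_p_one(self):
        assert binomial_edit_test(0, 50, 0.001) == 1.0

    def test_all_edited_reads_closed_form(self):
        assert binomial_edit_test(10, 10, 0.01) == pytest.approx(0.01**10, rel=1e-12)

    def test_matches_enumeration_oracle_small_n(self):
        p0 = 0.001
        for n in range(1, 51):
            for x in range(0, n + 1, max(1, n // 7)):
                tail = sum(
                    comb(n, k) * p0**k * (1 - p0) ** (n - k) for k in range(x, n + 1)
                )
                assert binomial_edit_test(x, n, p0) == pytest.approx(
                    tail, abs=1e-12
                )

    @pytest.mark.parametrize("p0", [0.0, 1.0, -0.1, 1.5])
    def test_invalid_p0_rejected(self, p0):
        with pytest.raises(ValueError):
            binomial_edit_test(1, 10, p0)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.037])[0] == pytest.approx(0.037)

    def test_hand_computed_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_permutation_invariance(self, rng):
        p = rng.uniform(size=25)
        base = bh_adjust(p)
        perm = rng.permutation(25)
        assert np.allclose(bh_adjust(p[perm]), base[perm])

    def test_matches_naive_step_up(self, rng):
        """BH equals the from-scratch step-up computation."""
        p = rng.uniform(size=40)
        order = np.argsort(p)
        m = len(p)
        adj = np.empty(m)
        running = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            running = min(running, p[i] * m / (rank_idx + 1))
            adj[i] = running
        assert np.allclose(bh_adjust(p), adj)


class TestExclusionFilters:
    refs = [
        MatureMiRNA("mir-a", "TAATACTGCCTGGTAATGATGA"),
        MatureMiRNA("mir-black", "TTTTACTGCCTGGTAATGCCGA", blacklisted=True),
    ]
    refs_by_id = {r.id: r for r in refs}

    def _site(self, mirna="mir-a", fdr=0.001):
        return EditSiteStat(mirna, 5, 10, 100, 0.001, 1e-9, fdr)

    def test_low_expression_filtered(self):
        lib = LibraryStats("s", {"mir-a": 1, "other": 2_000_000})
        status = apply_exclusion_filters(
            self._site(), lib, self.refs_by_id, self.refs
        )
        assert status == "filtered(low_expression)"

    def test_blacklisted_mirna_filtered(self):
        lib = LibraryStats("s", {"mir-black": 100, "mir-a": 100})
        site = EditSiteStat("mir-black", 5, 10, 100, 0.001, 1e-9, 1e-8)
        status = apply_exclusion_filters(site, lib, self.refs_by_id, self.refs)
        assert status == "filtered(repeat_element)"

    def test_multimapping_edited_sequence_filtered(self):
        # two references whose sequences differ only at the edited A:
        # the edited sequence matches the decoy perfectly
        decoy = MatureMiRNA("mir-decoy", "TAATGCTGCCTGGTAATGATGA")
        refs = [self.refs[0], decoy]
        lib = LibraryStats("s", {"mir-a": 100, "mir-decoy": 100})
        status = apply_exclusion_filters(
            self._site(), lib, {r.id: r for r in refs}, refs
        )
        assert status == "filtered(multimapping)"

    def test_significant_site_called(self):
        lib = LibraryStats("s", {"mir-a": 100})
        status = apply_exclusion_filters(
            self._site(), lib, self.refs_by_id, self.refs
        )
        assert status == "called"

    def test_insignificant_site_not_called(self):
        lib = LibraryStats("s", {"mir-a": 100})
        status = apply_exclusion_filters(
            self._site(fdr=0.2), lib, self.refs_by_id, self.refs
        )
        assert status == "filtered(not_significant)"


class TestDetectAndTable:
    def test_detect_sample_calls_planted_site(self):
        ref = REF
        edited = ref.sequence[:4] + "G" + ref.sequence[5:]
        assignments = [
            _assignment(ref.sequence, 900, ref),
            _assignment(edited, 100, ref, [(5, "A", "G")]),
        ]
        lib = LibraryStats("s", {ref.id: 1000})
        sites = detect_sample(assignments, lib, [ref], p0_policy="fixed")
        by_pos = {s.position: s for s in sites}
        assert by_pos[5].status == "called"
        assert by_pos[5].editing_level == pytest.approx(10.0)
        assert all(s.status != "called" for s in sites if s.position != 5)

    def test_table_shape_and_group_means(self):
        s_t = [EditSiteStat("m", 5, 10, 100, 1e-3, 1e-9, 1e-8, "called")]
        s_n = [EditSiteStat("m", 5, 1, 100, 1e-3, 0.5, 0.5, "filtered(not_significant)")]
        table = build_editing_table(
            {"T1": s_t, "N1": s_n}, {"T1": "tumour", "N1": "control"}
        )
        assert len(table) == 1
        row = table.iloc[0]
        assert row["T1"] == pytest.approx(10.0)
        assert row["N1"] == pytest.approx(1.0)
        assert row["frequency_pct"] == pytest.approx(50.0)
        assert row["mean_pct_tumour"] == pytest.approx(10.0)

    def test_site_called_nowhere_absent(self):
        s = [EditSiteStat("m", 5, 0, 100, 1e-3, 1.0, 1.0, "filtered(not_significant)")]
        assert build_editing_table({"T1": s}).empty
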