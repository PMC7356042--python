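"""Fold changes, replicate t-tests and the dual-concentration protection call."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from lipscout.lipquant import (
    AreaMatrix,
    PeptideStat,
    compute_stats,
    fold_change,
    select_protected,
    stats_to_frame,
)
from lipscout.lipquant import test_difference as diff_pvalue

from .oracles import exact_permutation_pvalue, student_t_pvalue

areas = st.lists(st.floats(min_value=1.0, max_value=1e7), min_size=2, max_size=6)


class TestFoldChange:
    def test_identical_vectors_give_one(self):
        assert fold_change([100, 110, 90], [100, 110, 90]) == pytest.approx(1.0)

    def test_exact_doubling(self):
        assert fold_change([200, 220, 180], [100, 110, 90]) == pytest.approx(2.0)

    def test_ratio_of_means_not_mean_of_ratios(self):
        # means 200 and 100 even though per-replicate ratios vary
        assert fold_change([150, 250], [100, 100]) == pytest.approx(2.0)

    def test_positive_areas_required(self):
        with pytest.raises(ValueError):
            fold_change([0, 1], [1, 1])
        with pytest.raises(ValueError):
            fold_change([], [1, 1])

    @given(a=areas, b=areas)
    @settings(max_examples=200, derandomize=True)
    def test_symmetry(self, a, b):
        assert fold_change(a, b) * fold_change(b, a) == pytest.approx(1.0)

    @given(a=areas, b=areas, scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=200, derandomize=True)
    def test_scale_invariance(self, a, b, scale):
        base = fold_change(a, b)
        scaled = fold_change([x * scale for x in a], [x * scale for x in b])
        assert scaled == pytest.approx(base, rel=1e-9)


class TestTestDifference:
    def test_identical_groups_convention(self):
        assert diff_pvalue([100, 100, 100], [100, 100, 100]) == 1.0

    def test_zero_variance_unequal_means_convention(self):
        assert diff_pvalue([200, 200, 200], [100, 100, 100]) == 0.0

    def test_matches_textbook_t_formula(self):
        control = [100.0, 110.0, 90.0]
        treated = [200.0, 220.0, 180.0]
        ours = diff_pvalue(treated, control)
        oracle = student_t_pvalue(treated, control)
        assert ours == pytest.approx(oracle, abs=1e-6)

    @given(a=areas, b=areas)
    @settings(max_examples=100, derandomize=True)
    def test_matches_textbook_t_formula_everywhere(self, a, b):
        if np.std(a) == 0 and np.std(b) == 0:
            return
        assert diff_pvalue(a, b) == pytest.approx(student_t_pvalue(a, b),
                                                      abs=1e-9)

    def test_consistent_with_exact_permutation_null(self):
        """With n = 3 the exact permutation null has only C(6,3) = 20 atoms,
        so agreement is necessarily coarse: the parametric p must land in
        the same acceptance region as the exact nonparametric p."""
        rng = np.random.default_rng(5)
        agree = 0
        trials = 40
        for _ in range(trials):
            control = rng.lognormal(11, 0.15, 3)
            treated = rng.lognormal(11.05, 0.15, 3)
            p_t = diff_pvalue(treated, control)
            p_perm = exact_permutation_pvalue(treated, control)
            agree += (p_t < 0.1) == (p_perm <= 0.1)
        assert agree >= trials - 6

    def test_welch_and_log_variants(self):
        control = [100.0, 101.0, 99.0]
        treated = [200.0, 260.0, 140.0]  # very unequal variances
        student = diff_pvalue(treated, control, method="student")
        welch = diff_pvalue(treated, control, method="welch")
        assert welch > student  # Welch pays for the df correction here
        logged = diff_pvalue(treated, control, log_areas=True)
        assert 0 < logged < 1

    def test_replicate_minimum(self):
        with pytest.raises(ValueError):
            diff_pvalue([100.0], [100.0, 110.0])

    @given(a=areas, b=areas, scale=st.floats(min_value=1e-3, max_value=1e3))
    @settings(max_examples=100, derandomize=True)
    def test_scale_invariance(self, a, b, scale):
        if np.std(a) == 0 and np.std(b) == 0:
            return
        base = diff_pvalue(a, b)
        scaled = diff_pvalue([x * scale for x in a], [x * scale for x in b])
        assert scaled == pytest.approx(base, rel=1e-6)


def _stat(pid, entries, protected=False):
    return PeptideStat(pid, tuple(entries), protected)


class TestSelectProtected:
    def test_published_style_row_is_selected(self):
        # fold changes and p-values of a strongly protected peptide at both
        # ligand concentrations
        stat = _stat("G-[275-286]-K/2",
                     [(1.0, 1.73, 0.0001), (10.0, 1.74, 0.0003)])
        kept = select_protected([stat], alpha=0.05, concentrations=[1.0, 10.0])
        assert [s.precursor_id for s in kept] == ["G-[275-286]-K/2"]
        assert kept[0].protected

    def test_single_concentration_effect_rejected(self):
        stat = _stat("X", [(1.0, 1.8, 0.001), (10.0, 0.95, 0.001)])
        assert select_protected([stat], concentrations=[1.0, 10.0]) == []
        stat = _stat("Y", [(1.0, 1.8, 0.001), (10.0, 1.7, 0.2)])
        assert select_protected([stat], concentrations=[1.0, 10.0]) == []

    def test_missing_concentration_is_error(self):
        stat = _stat("X", [(1.0, 1.8, 0.001)])
        with pytest.raises(ValueError):
            select_protected([stat], concentrations=[1.0, 10.0])

    def test_alpha_validated(self):
        with pytest.raises(ValueError):
            select_protected([], alpha=1.5)


class TestAreaMatrix:
    def _frame(self):
        rows = []
        for pid, mult in (("A", 2.0), ("B", 1.0)):
            for cond, factor in (("control", 1.0), ("treated@1", mult),
                                 ("treated@10", mult)):
                for rep, jitter in enumerate((0.97, 1.0, 1.03), start=1):
                    rows.append({"precursor_id": pid, "condition": cond,
                                 "replicate": rep,
                                 "area": 1e5 * factor * jitter})
        return pd.DataFrame(rows)

    def test_compute_stats_and_frame_layout(self):
        matrix = AreaMatrix(self._frame())
        stats = compute_stats(matrix, [1.0, 10.0])
        by_id = {s.precursor_id: s for s in stats}
        assert by_id["A"].fold_at(1.0) == pytest.approx(2.0)
        assert by_id["A"].protected
        assert by_id["B"].fold_at(10.0) == pytest.approx(1.0)
        assert not by_id["B"].protected
        frame = stats_to_frame(stats, [1.0, 10.0])
        assert list(frame.columns) == [
            "precursor_id", "fc_1uM", "p_1uM", "fc_10uM", "p_10uM", "protected"]

    def test_bh_correction_only_weakens_calls(self):
        matrix = AreaMatrix(self._frame())
        raw = compute_stats(matrix, [1.0, 10.0])
        corrected = compute_stats(matrix, [1.0, 10.0], bh_correct=True)
        for before, after in zip(raw, corrected):
            for c in (1.0, 10.0):
                assert after.p_at(c) >= before.p_at(c) - 1e-12

    def test_validation(self):
        frame = self._frame()
        frame.loc[0, "area"] = -5.0
        with pytest.raises(ValueError):
            AreaMatrix(frame)
        short = self._frame().groupby(
            ["precursor_id", "condition"]).head(1)
        with pytest.raises(ValueError):
            AreaMatrix(short)

    def test_tsv_roundtrip(self, tmp_path):
        matrix = AreaMatrix(self._frame())
        path = tmp_path / "areas.tsv"
        matrix.write_tsv(path)
        back = AreaMatrix.read_tsv(path)
        pd.testing.assert_frame_equal(matrix.frame, back.frame)
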