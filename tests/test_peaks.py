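import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromqc.core import BatchPanel, Peak, PeakTable, Trace, ValidationError
from chromqc.peaks import (
    MatchConfig,
    PeakNotFoundError,
    detect_peaks,
    filter_min_area,
    locate_by_relative_retention,
    locate_by_rt_difference,
    match_common_peaks,
    shear_solvent_region,
)
from chromqc.synth import default_panel_design, gaussian_peak, make_batch_panel


def table_from(rts_areas, sample_id="s", wl=237.0):
    return PeakTable(sample_id, wl, [Peak(rt, a, wavelength_nm=wl) for rt, a in rts_areas])


class TestDetectPeaks:
    def test_flat_trace_yields_no_peaks(self):
        tr = Trace(np.arange(0.0, 10.0, 0.01), np.zeros(1000), 237.0)
        assert len(detect_peaks(tr)) == 0

    def test_too_short_trace_rejected(self):
        with pytest.raises(ValidationError):
            detect_peaks(Trace(np.array([0.0, 1.0]), np.zeros(2), 237.0))

    def test_single_gaussian_recovered_with_analytic_area(self):
        t = np.arange(0.0, 2.0, 0.001)
        tr = Trace(t, gaussian_peak(t, 1.0, 10.0, 0.05), 237.0)
        out = detect_peaks(tr, min_height=0.1, min_prominence=0.1)
        assert len(out) == 1
        peak = out.peaks[0]
        assert peak.rt_min == pytest.approx(1.0, abs=0.001)
        assert peak.area == pytest.approx(10.0 * 0.05 * np.sqrt(2 * np.pi), rel=0.02)
        assert peak.height == pytest.approx(10.0, rel=0.01)

    def test_two_separated_gaussians_both_found(self):
        t = np.arange(0.0, 4.0, 0.001)
        y = gaussian_peak(t, 1.0, 5.0, 0.05) + gaussian_peak(t, 2.0, 8.0, 0.05)
        out = detect_peaks(Trace(t, y, 237.0), min_height=0.1, min_prominence=0.1)
        assert len(out) == 2
        assert out.rts == pytest.approx([1.0, 2.0], abs=0.001)


class TestShearAndFilter:
    def test_shear_removes_solvent_front(self):
        out = shear_solvent_region(table_from([(3.0, 1.0), (6.0, 1.0)]), 5.0)
        assert out.rts.tolist() == [6.0]

    def test_shear_zero_cut_is_identity(self):
        t = table_from([(3.0, 1.0), (6.0, 1.0)])
        assert shear_solvent_region(t, 0.0).rts.tolist() == t.rts.tolist()

    def test_peak_exactly_at_cut_is_retained(self):
        out = shear_solvent_region(table_from([(5.0, 1.0)]), 5.0)
        assert len(out) == 1

    def test_area_screen_is_strict(self):
        out = filter_min_area(table_from([(6.0, 0.3), (7.0, 0.4), (8.0, 0.5)]), 0.4)
        assert out.areas.tolist() == [0.5]

    def test_zero_threshold_keeps_positive_areas(self):
        t = table_from([(6.0, 0.1), (7.0, 2.0)])
        assert len(filter_min_area(t, 0.0)) == 2

    def test_matrix_screen_requires_every_batch_above_threshold(self):
        panel = BatchPanel(
            [
                table_from([(6.0, 0.5), (9.0, 2.0)], "a"),
                table_from([(6.0, 0.35), (9.0, 2.0)], "b"),
            ]
        )
        m = match_common_peaks(panel, MatchConfig(min_area=0.0))
        out = filter_min_area(m, 0.4)
        assert out.n_peaks == 1
        assert out.consensus_rt_min.tolist() == [9.0]

    @given(
        rts=st.lists(
            st.floats(0.1, 100.0, allow_nan=False), min_size=0, max_size=15, unique=True
        ),
        cut=st.floats(0.0, 50.0),
        threshold=st.floats(0.0, 5.0),
        data=st.data(),
    )
    @settings(max_examples=50, deadline=None)
    def test_shear_and_filter_commute(self, rts, cut, threshold, data):
        areas = [data.draw(st.floats(0.01, 10.0)) for _ in rts]
        t = table_from(list(zip(rts, areas)))
        a = filter_min_area(shear_solvent_region(t, cut), threshold)
        b = shear_solvent_region(filter_min_area(t, threshold), cut)
        assert a.rts.tolist() == b.rts.tolist()
        assert a.areas.tolist() == b.areas.tolist()


class TestMatchCommonPeaks:
    def test_identical_batches_make_every_peak_common(self):
        rows = [(6.0, 1.0), (9.0, 2.0), (14.0, 0.8)]
        panel = BatchPanel([table_from(rows, f"b{i}") for i in range(3)])
        m = match_common_peaks(panel, MatchConfig(min_area=0.0))
        assert m.n_peaks == 3
        assert np.allclose(m.areas, [[1.0, 2.0, 0.8]] * 3)

    def test_peak_missing_from_one_batch_is_not_common(self):
        full = [(6.0, 1.0), (9.0, 2.0)]
        partial = [(6.0, 1.0)]
        panel = BatchPanel(
            [table_from(full, "a"), table_from(full, "b"), table_from(partial, "c")]
        )
        m = match_common_peaks(panel, MatchConfig(min_area=0.0))
        assert m.n_peaks == 1
        assert m.consensus_rt_min.tolist() == [6.0]

    def test_empty_batch_is_an_error_naming_the_batch(self):
        panel = BatchPanel([table_from([(6.0, 1.0)], "a"), table_from([], "b")])
        with pytest.raises(ValidationError, match="b"):
            match_common_peaks(panel)

    def test_batch_order_permutation_only_relabels_rows(self):
        sim = make_batch_panel(default_panel_design(seed=5))
        tables = [shear_solvent_region(t, 5.0) for t in sim.truth[237.0].batches]
        m1 = match_common_peaks(BatchPanel(tables), MatchConfig())
        perm = list(reversed(range(len(tables))))
        m2 = match_common_peaks(BatchPanel([tables[i] for i in perm]), MatchConfig())
        assert m1.n_peaks == m2.n_peaks
        assert np.allclose(m1.consensus_rt_min, m2.consensus_rt_min, atol=1e-9)
        lookup = {bid: row for bid, row in zip(m2.batch_ids, m2.areas)}
        for bid, row in zip(m1.batch_ids, m1.areas):
            assert np.allclose(row, lookup[bid])

    @pytest.mark.parametrize("seed", range(10))
    def test_ground_truth_recovered_on_default_panel(self, seed):
        """With jitter well inside the tolerance the planted 29 common peaks
        are recovered exactly, with planted areas in the matrix."""
        design = default_panel_design(seed=seed)
        sim = make_batch_panel(design)
        tables = [shear_solvent_region(t, 5.0) for t in sim.truth[237.0].batches]
        m = match_common_peaks(BatchPanel(tables), MatchConfig())
        assert m.n_peaks == len(design.common_peaks)
        planted_rts = sorted(s.rt_mean_min for s in design.common_peaks)
        assert np.allclose(m.consensus_rt_min, planted_rts, atol=0.3)


class TestLocalization:
    def test_exact_relative_retention_match(self):
        t = table_from([(10.0, 1.0), (20.0, 2.0)])
        peak = locate_by_relative_retention(t, is_rt=10.0, expected_rrv=2.0, tol=0.01)
        assert peak.rt_min == 20.0

    def test_nearest_relative_retention_wins(self):
        # candidates at rrv 1.10 and 1.30, expecting 1.12 within 5%
        t = table_from([(11.0, 1.0), (13.0, 5.0)])
        peak = locate_by_relative_retention(t, is_rt=10.0, expected_rrv=1.12, tol=0.05)
        assert peak.rt_min == 11.0

    def test_empty_table_raises_not_found(self):
        with pytest.raises(PeakNotFoundError):
            locate_by_relative_retention(table_from([]), 10.0, 1.2)

    def test_outside_tolerance_reports_nearest_candidate(self):
        t = table_from([(15.0, 1.0)])
        with pytest.raises(PeakNotFoundError, match="15.000"):
            locate_by_relative_retention(t, is_rt=10.0, expected_rrv=1.2, tol=0.01)

    def test_rt_difference_exact_match(self):
        t = table_from([(12.5, 1.0)])
        peak = locate_by_rt_difference(t, is_rt=10.0, expected_delta=2.5, tol=0.1)
        assert peak.rt_min == 12.5

    def test_equidistant_tie_breaks_to_larger_area(self):
        t = table_from([(11.0, 1.0), (13.0, 5.0)])
        peak = locate_by_rt_difference(t, is_rt=10.0, expected_delta=2.0, tol=1.5)
        assert peak.area == 5.0

    def test_rt_difference_outside_tolerance_raises(self):
        t = table_from([(11.0, 1.0)])
        with pytest.raises(PeakNotFoundError):
            locate_by_rt_difference(t, is_rt=10.0, expected_delta=5.0, tol=0.5)
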