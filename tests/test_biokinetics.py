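"""Biodistribution loading, decay handling, tail fitting, TIAC integration."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from augerdose.biokinetics import (
    BiodistributionSample,
    BiodistributionSeries,
    TimeActivityCurve,
    apply_physical_decay,
    fit_tail_exponential,
    load_biodistribution,
    time_integrated_activity,
)


def _series(times, values, tissue="toy", decay_corrected=False, flags=None):
    flags = flags or ["ok"] * len(times)
    return BiodistributionSeries(
        tissue=tissue,
        samples=[
            BiodistributionSample(time_h=t, pct_id_per_g=v, flag=f)
            for t, v, f in zip(times, values, flags)
        ],
        decay_corrected=decay_corrected,
    )


class TestLoad:
    CSV = (
        "tissue,time_h,pct_id_per_g,sd,n,flag\n"
        "kidney,1,,,5,saturated\n"
        "kidney,24,,,5,saturated\n"
        "kidney,48,30.0,4.0,5,ok\n"
        "kidney,336,12.8,2.0,5,ok\n"
        "kidney,2016,0.2,0.05,5,ok\n"
        "pip_tumor,48,60.0,8.0,5,ok\n"
        "pip_tumor,336,32.0,5.0,5,ok\n"
        "blood,48,2.0,0.5,5,ok\n"
        "blood,336,0.2,0.05,5,ok\n"
    )

    def test_one_series_per_tissue_with_correct_lengths(self, tmp_path):
        path = tmp_path / "biodist.csv"
        path.write_text(self.CSV)
        series = load_biodistribution(path)
        assert len(series) == 3
        by_name = {s.tissue: s for s in series}
        assert len(by_name["kidney"].samples) == 5
        assert len(by_name["pip_tumor"].samples) == 2

    def test_saturated_rows_become_gaps_not_zeros(self, tmp_path):
        path = tmp_path / "biodist.csv"
        path.write_text(self.CSV)
        kidney = {s.tissue: s for s in load_biodistribution(path)}["kidney"]
        assert [g.time_h for g in kidney.gaps] == [1.0, 24.0]
        assert list(kidney.times()) == [48.0, 336.0, 2016.0]
        assert 0.0 not in kidney.concentrations()

    def test_duplicate_time_rows_rejected(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text(
            "tissue,time_h,pct_id_per_g,sd,n\nk,1,1.0,0,3\nk,1,2.0,0,3\n"
        )
        with pytest.raises(ValueError, match="duplicate"):
            load_biodistribution(path)

    def test_missing_columns_rejected(self, tmp_path):
        path = tmp_path / "cols.csv"
        path.write_text("tissue,time_h\nk,1\n")
        with pytest.raises(ValueError, match="missing required columns"):
            load_biodistribution(path)

    def test_negative_concentration_rejected(self, tmp_path):
        path = tmp_path / "neg.csv"
        path.write_text("tissue,time_h,pct_id_per_g,sd,n\nk,1,-0.5,0,3\n")
        with pytest.raises(ValueError):
            load_biodistribution(path)


class TestDecay:
    def test_sample_at_injection_time_unchanged(self, spectrum):
        s = _series([0.0, 100.0], [10.0, 5.0], decay_corrected=True)
        phys = apply_physical_decay(s, spectrum, "to_physical")
        assert phys.samples[0].pct_id_per_g == pytest.approx(10.0)

    def test_one_half_life_halves_concentration(self, spectrum):
        t_half = 59.0 * 24.0
        s = _series([0.0, t_half], [10.0, 8.0], decay_corrected=True)
        phys = apply_physical_decay(s, spectrum, "to_physical")
        assert phys.samples[1].pct_id_per_g == pytest.approx(4.0)

    def test_round_trip_identity(self, spectrum):
        s = _series([1.0, 48.0, 336.0], [3.0, 2.0, 1.0], decay_corrected=True)
        back = apply_physical_decay(
            apply_physical_decay(s, spectrum, "to_physical"),
            spectrum,
            "to_corrected",
        )
        for a, b in zip(s.samples, back.samples):
            assert b.pct_id_per_g == pytest.approx(a.pct_id_per_g, rel=1e-12)

    def test_passthrough_when_already_in_convention(self, spectrum):
        s = _series([1.0, 48.0], [3.0, 2.0], decay_corrected=False)
        assert apply_physical_decay(s, spectrum, "to_physical") is s

    def test_unknown_mode_rejected(self, spectrum):
        s = _series([1.0], [3.0])
        with pytest.raises(ValueError):
            apply_physical_decay(s, spectrum, "sideways")


class TestTailFit:
    def test_pure_monoexponential_breaks_at_first_point(self):
        t = np.array([1.0, 24.0, 48.0, 96.0, 200.0])
        c = 10.0 * np.exp(-0.01 * t)
        curve = fit_tail_exponential(_series(t, c))
        assert curve.tail_start_h == 1.0
        assert curve.fit_r2 == pytest.approx(1.0, abs=1e-12)
        assert curve.lambda_eff_per_h == pytest.approx(0.01, rel=1e-9)
        assert curve.head == ()

    def test_rise_then_fall_breaks_at_peak(self):
        # peak at the 2nd of 6 points, exponential decay after
        t = np.array([1.0, 24.0, 48.0, 72.0, 168.0, 336.0])
        c = np.concatenate(
            ([1.0], 10.0 * np.exp(-0.01 * (t[1:] - 24.0)))
        )
        series = _series(t, c)
        curve = fit_tail_exponential(series)

        # exhaustive breakpoint-scan oracle: earliest index whose suffix
        # log-linear fit reaches the threshold with >= 3 points
        def suffix_r2(i):
            y = np.log(c[i:])
            slope, intercept = np.polyfit(t[i:], y, 1)
            resid = y - (slope * t[i:] + intercept)
            return 1.0 - resid @ resid / ((y - y.mean()) @ (y - y.mean()))

        oracle = next(
            i for i in range(len(t) - 2) if suffix_r2(i) >= 0.9
        )
        assert oracle == 1  # the peak
        assert curve.tail_start_h == t[oracle]
        assert len(curve.head) == 1

    def test_kidney_two_point_tail_effective_half_life(self):
        # 12.8 %ID/g at 2 weeks to 0.2 %ID/g at 12 weeks
        series = _series([336.0, 2016.0], [12.8, 0.2])
        curve = fit_tail_exponential(series, min_tail_points=2)
        expected_half_life_wk = 10.0 * math.log(2.0) / math.log(64.0)
        assert curve.effective_half_life_h / 168.0 == pytest.approx(
            expected_half_life_wk, rel=1e-9
        )

    def test_decay_corrected_series_rejected(self):
        s = _series([1.0, 2.0, 3.0], [3.0, 2.0, 1.0], decay_corrected=True)
        with pytest.raises(ValueError, match="decay-corrected"):
            fit_tail_exponential(s)

    def test_no_admissible_breakpoint_mentions_threshold(self):
        # non-monotone noise-like data cannot reach R^2 = 0.999
        s = _series([1.0, 2.0, 3.0, 4.0], [1.0, 3.0, 0.5, 2.0])
        with pytest.raises(ValueError, match="relax the threshold"):
            fit_tail_exponential(s, r2_threshold=0.999)


class TestTiac:
    def test_constant_retention_integrates_to_c0_over_lambda(self, spectrum):
        # constant biological retention: physical decay only
        lam = spectrum.decay_constant_per_hour
        t = np.linspace(1.0, 5000.0, 12)
        c = 10.0 * np.exp(-lam * t)
        tiac = time_integrated_activity(fit_tail_exponential(_series(t, c)))
        # breakpoint at the first point: analytic tail c(t0)/lambda from t0
        # plus the flat-back head c(t0)*t0
        c0 = 10.0 * math.exp(-lam * 1.0)
        expected = (c0 / lam + c0 * 1.0) / 100.0
        assert tiac.value == pytest.approx(expected, rel=1e-6)

    def test_single_exponential_closed_form(self):
        t = np.linspace(0.5, 600.0, 8)
        c = 40.0 * np.exp(-0.02 * t)
        tiac = time_integrated_activity(fit_tail_exponential(_series(t, c)))
        expected = (c[0] / 0.02 + c[0] * 0.5) / 100.0
        assert tiac.value == pytest.approx(expected, rel=1e-6)

    def test_head_plus_tail_matches_fine_quadrature(self):
        curve = TimeActivityCurve(
            tissue="toy",
            head=((2.0, 5.0), (10.0, 8.0), (30.0, 6.0)),
            tail_amplitude=7.0,
            lambda_eff_per_h=0.01,
            tail_start_h=50.0,
            fit_r2=1.0,
            last_datum_h=400.0,
        )
        tiac = time_integrated_activity(curve)
        # 1e6-step quadrature oracle over the same piecewise curve
        t_nodes = [0.0, 2.0, 10.0, 30.0, 50.0]
        c_nodes = [5.0, 5.0, 8.0, 6.0, 7.0 * math.exp(-0.01 * 50.0)]
        grid = np.linspace(0.0, 50.0, 500_001)
        head = np.trapezoid(np.interp(grid, t_nodes, c_nodes), grid)
        tail_grid = np.linspace(50.0, 5000.0, 500_001)
        tail = np.trapezoid(7.0 * np.exp(-0.01 * tail_grid), tail_grid)
        tail += 7.0 * math.exp(-0.01 * 5000.0) / 0.01
        assert tiac.value == pytest.approx((head + tail) / 100.0, rel=1e-3)
        assert 0.0 <= tiac.extrapolated_fraction <= 1.0

    def test_non_integrable_tail_rejected(self):
        with pytest.raises(ValueError):
            TimeActivityCurve(
                tissue="bad",
                head=(),
                tail_amplitude=1.0,
                lambda_eff_per_h=-0.01,
                tail_start_h=0.0,
                fit_r2=1.0,
                last_datum_h=10.0,
            )

    @given(st.floats(min_value=0.001, max_value=0.05))
    def test_tiac_monotone_in_tail_half_life(self, lam):
        # slower clearance (longer effective half-life) => larger TIAC
        def tiac_for(l):
            curve = TimeActivityCurve(
                tissue="toy",
                head=(),
                tail_amplitude=10.0,
                lambda_eff_per_h=l,
                tail_start_h=1.0,
                fit_r2=1.0,
                last_datum_h=100.0,
            )
            return time_integrated_activity(curve).value

        assert tiac_for(lam) > tiac_for(lam * 1.5)

    def test_round_trip_decay_gives_same_tiac(self, spectrum):
        t = np.array([1.0, 48.0, 168.0, 336.0, 504.0, 1000.0])
        c = 30.0 * np.exp(-0.004 * t)
        phys = _series(t, c, decay_corrected=False)
        corrected = apply_physical_decay(phys, spectrum, "to_corrected")
        restored = apply_physical_decay(corrected, spectrum, "to_physical")
        v1 = time_integrated_activity(fit_tail_exponential(phys)).value
        v2 = time_integrated_activity(fit_tail_exponential(restored)).value
        assert v2 == pytest.approx(v1, rel=1e-10)
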