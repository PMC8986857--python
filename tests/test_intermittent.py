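import warnings

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from peaq import (ConstantCa, DoseModel, NoiseModel, OscillatingCa,
                  ProtocolSpec, background_correct, build_schedule,
                  fit_scale_trend, intermittent_quantify, light_dose_saving,
                  normalize_fit, repair_first_post_cycle_frame, run_ipeaq,
                  scale_factor, simulate_trace)
from peaq.calibration import FLAG_ABOVE, FLAG_OK, HillFit
from peaq.intermittent import IpeaqError, remaining_dose_fraction
from peaq.workflows import calibrate_titration, simulate_titration


@pytest.fixture(scope="module")
def norm_curve():
    fit = HillFit(f_diff=-100.0, f_max=100.0, kd=266.0, h=2.1,
                  kind="fluorescence")
    return normalize_fit(fit)


class TestScaleFactor:
    def test_simple_division(self, norm_curve):
        ca_half = norm_curve.fit.kd  # F_T = 0.5 at the midpoint
        assert scale_factor(50.0, ca_half, norm_curve) == pytest.approx(100.0)

    def test_midpoint_is_exactly_half(self, norm_curve):
        assert scale_factor(43.0, 266.0, norm_curve) == pytest.approx(86.0)

    def test_zero_ft_rejected(self, norm_curve):
        with pytest.raises(IpeaqError, match="not positive"):
            scale_factor(10.0, 0.0, norm_curve)

    def test_unnormalized_curve_rejected(self, curves):
        with pytest.raises(IpeaqError, match="normalized"):
            scale_factor(10.0, 100.0, curves["fluorescence"])


class TestScaleTrend:
    def test_constant_points_flat_line(self):
        m = fit_scale_trend([0.0, 10.0, 20.0], [5.0, 5.0, 5.0],
                            [3.0, 3.0, 3.0])
        assert m.slope == pytest.approx(0.0, abs=1e-12)
        assert m.intercept == pytest.approx(5.0)

    def test_two_points_exact_interpolation(self):
        m = fit_scale_trend([0.0, 10.0], [2.0, 4.0], [100.0, 1.0])
        assert m(0.0) == pytest.approx(2.0, abs=1e-9)
        assert m(10.0) == pytest.approx(4.0, abs=1e-9)
        assert m(20.0) == pytest.approx(6.0, abs=1e-9)  # line extrapolation

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000))
    def test_matches_weighted_normal_equations(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        t = np.sort(rng.uniform(0, 100, n))
        t[0], t[-1] = 0.0, 100.0  # guarantee spread
        a = rng.uniform(1, 10, n)
        f0 = rng.uniform(0.5, 50, n)
        m = fit_scale_trend(t, a, f0)
        w = f0 ** 2
        x = np.column_stack([np.ones_like(t), t])
        expected = np.linalg.solve(x.T @ (w[:, None] * x), x.T @ (w * a))
        assert m.intercept == pytest.approx(expected[0], abs=1e-10, rel=1e-10)
        assert m.slope == pytest.approx(expected[1], abs=1e-10, rel=1e-10)

    def test_single_point_rejected(self):
        with pytest.raises(IpeaqError, match="2 calibration points"):
            fit_scale_trend([0.0], [1.0], [1.0])

    def test_coincident_times_rank_deficient(self):
        with pytest.raises(IpeaqError, match="rank deficient"):
            fit_scale_trend([5.0, 5.0], [1.0, 2.0], [1.0, 1.0])


class TestIntermittentQuantify:
    def test_noiseless_round_trip_exact(self, norm_curve):
        m = fit_scale_trend([0.0, 10.0], [80.0, 80.0], [10.0, 10.0])
        ca_star = 150.0
        f0 = 80.0 * norm_curve.eval(ca_star)
        ca, flag = intermittent_quantify(f0, 5.0, m, norm_curve)
        assert flag == FLAG_OK
        assert ca == pytest.approx(ca_star, rel=1e-9)

    def test_above_unity_ratio_clipped_and_flagged(self, norm_curve):
        m = fit_scale_trend([0.0, 10.0], [80.0, 80.0], [10.0, 10.0])
        ca, flag = intermittent_quantify(100.0, 5.0, m, norm_curve)
        assert flag == FLAG_ABOVE
        assert ca == pytest.approx(norm_curve.working_range()[1])

    def test_collapsed_trend_rejected(self, norm_curve):
        m = fit_scale_trend([0.0, 10.0], [10.0, -10.0], [1.0, 1.0])
        with pytest.raises(IpeaqError, match="collapsed"):
            intermittent_quantify(5.0, 10.0, m, norm_curve)


class TestDipRepair:
    def test_midpoint_interpolation(self):
        out, orig = repair_first_post_cycle_frame([10.0, 6.0, 9.0], [1])
        assert list(out) == [10.0, 9.5, 9.0]
        assert orig == {1: 6.0}

    def test_no_flags_is_identity(self):
        out, orig = repair_first_post_cycle_frame([1.0, 2.0, 3.0], [])
        assert list(out) == [1.0, 2.0, 3.0]
        assert orig == {}

    def test_boundary_flag_left_with_warning(self):
        with pytest.warns(UserWarning, match="boundary"):
            out, orig = repair_first_post_cycle_frame([5.0, 6.0], [0])
        assert list(out) == [5.0, 6.0]

    def test_only_flagged_indices_change(self):
        rng = np.random.default_rng(3)
        y = rng.uniform(0, 10, 50)
        flags = [7, 20, 33]
        out, _ = repair_first_post_cycle_frame(y, flags)
        untouched = np.setdiff1d(np.arange(50), flags)
        assert np.array_equal(out[untouched], y[untouched])

    def test_repaired_matches_dip_free_simulation(self, params):
        """Repairing the post-cycle dip recovers the dip-free trace."""
        spec = ProtocolSpec(n_cycles=3, n_intermittent=4)
        sch = build_schedule(spec)
        common = dict(ca=ConstantCa(150.0), noise=NoiseModel.none(),
                      background_level=0.0)
        dipped = simulate_trace(params, sch, **common)
        clean = simulate_trace(params.replace(post_cycle_dip_factor=1.0),
                               sch, **common)
        post = sch.post_cycle_frame_indices()
        f_d = dipped.cell("cell_000")["fluorescence"].to_numpy()
        f_c = clean.cell("cell_000")["fluorescence"].to_numpy()
        assert not np.allclose(f_d[post], f_c[post])
        # repair within the F0 series: cycle F0 frames + intermittent frames
        cyc_ids = sch.frame_cycle_ids()
        series_idx, seen = [], set()
        for i, c in enumerate(cyc_ids):
            if c is None:
                series_idx.append(i)
            elif c not in seen:
                seen.add(c)
                series_idx.append(i)
        series = f_d[series_idx]
        flags = [series_idx.index(i) for i in post]
        repaired, _ = repair_first_post_cycle_frame(series, flags)
        assert np.allclose(repaired[flags], f_c[post], rtol=5e-3)


class TestLightDose:
    def _dose(self, n):
        return DoseModel.from_protocol(ProtocolSpec(n_intermittent=n))

    def test_eight_intermittent_saves_80_percent(self):
        assert light_dose_saving(self._dose(8)) == pytest.approx(0.80)

    def test_no_intermittent_saves_nothing(self):
        assert light_dose_saving(self._dose(0)) == 0.0

    def test_two_intermittent_less_than_half_remaining(self):
        rem = remaining_dose_fraction(self._dose(2))
        assert rem == pytest.approx(0.40)
        assert rem < 0.5

    def test_limit_is_frame_to_cycle_ratio(self):
        saved = light_dose_saving(self._dose(10_000_000))
        assert saved == pytest.approx(1.0 - 1.0 / 10.0, abs=1e-5)

    def test_saving_increases_and_is_bounded(self):
        vals = [light_dose_saving(self._dose(n)) for n in range(0, 40)]
        assert all(b > a for a, b in zip(vals, vals[1:]))
        assert all(v < 1.0 - 1.0 / 10.0 for v in vals)


class TestEndToEnd:
    def test_constant_ca_agreement_and_flat_trend(self, params):
        """Constant probe and Ca: the A(t) slope vanishes within its
        standard error and intermittent estimates agree with the
        photochromism-based ones within 3%."""
        p = params.replace(fatigue_retention=1.0)
        spec = ProtocolSpec(n_cycles=4, n_intermittent=8)
        sch = build_schedule(spec)
        tit = simulate_titration(p, spec, seed=0)
        curves = calibrate_titration(tit, fingerprint=spec.fingerprint())
        tr = simulate_trace(p, sch, ConstantCa(150.0),
                            noise=NoiseModel.none(), background_level=4.0)
        tr.fingerprint = spec.fingerprint()
        tr = background_correct(tr)
        res, models = run_ipeaq(tr, sch, curves["contrast"],
                                curves["fluorescence_normalized"],
                                brightness_gate=10.0)
        m = models["cell_000"]
        assert abs(m.slope) < m.slope_stderr
        peaq_ca = [r.ca_nM for r in res if r.method == "peaq"]
        inter_ca = [r.ca_nM for r in res if r.method == "intermittent"]
        assert inter_ca
        for ca in inter_ca:
            assert ca == pytest.approx(np.mean(peaq_ca), rel=0.03)

    def test_bleaching_tracked_by_trend(self, params):
        """Strong fatigue: the A(t) line tracks the simulated brightness
        decay and constant-Ca intermittent estimates stay within 5%."""
        p = params.replace(fatigue_retention=0.98)
        spec = ProtocolSpec(n_cycles=6, n_intermittent=8)
        sch = build_schedule(spec)
        tit = simulate_titration(p, spec, seed=0)
        curves = calibrate_titration(tit, fingerprint=spec.fingerprint())
        tr = simulate_trace(p, sch, ConstantCa(150.0),
                            noise=NoiseModel.none(), background_level=4.0)
        tr.fingerprint = spec.fingerprint()
        tr = background_correct(tr)
        res, models = run_ipeaq(tr, sch, curves["contrast"],
                                curves["fluorescence_normalized"],
                                brightness_gate=10.0)
        m = models["cell_000"]
        assert m.slope < 0  # brightness decays
        a = m.points["A"].to_numpy()
        decay_fit = m(m.points["time_s"].iloc[-1]) / m(
            m.points["time_s"].iloc[0])
        decay_true = a[-1] / a[0]
        assert decay_fit == pytest.approx(decay_true, rel=0.05)
        for r in res:
            if r.method == "intermittent":
                assert r.ca_nM == pytest.approx(150.0, rel=0.05)

    def test_oscillation_peaks_recovered(self, params):
        """One photochromism cycle per 8 intermittent frames, noiseless:
        intermittent estimates at the spike plateaus match ground truth
        within 5% (spikes inside the joint working range of both
        calibrations)."""
        spec = ProtocolSpec(n_cycles=6, n_intermittent=8)
        sch = build_schedule(spec)
        tit = simulate_titration(params, spec, seed=0)
        curves = calibrate_titration(tit, fingerprint=spec.fingerprint())
        traj = OscillatingCa(baseline_nM=60.0, peak_nM=180.0, period_s=36.0,
                             spike_width_s=8.0, amplitude_decay=0.85,
                             t_first_s=16.0)
        tr = simulate_trace(params, sch, traj, noise=NoiseModel.none(),
                            background_level=4.0)
        tr.fingerprint = spec.fingerprint()
        tr = background_correct(tr)
        res, _ = run_ipeaq(tr, sch, curves["contrast"],
                           curves["fluorescence_normalized"])
        at_peaks = [r for r in res if r.method == "intermittent"
                    and traj(r.time_s) > 100.0]
        assert len(at_peaks) >= 5
        times = [r.time_s for r in res]
        assert times == sorted(times)
        for r in at_peaks:
            assert r.ca_nM == pytest.approx(traj(r.time_s), rel=0.05)
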