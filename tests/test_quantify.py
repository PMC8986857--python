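import numpy as np
import pytest

from peaq import (ConstantCa, IlluminationEvent, IlluminationSchedule,
                  NoiseModel, ProtocolSpec, acquisition_cycle_duration,
                  background_correct, build_schedule, contrast_from_plateau,
                  default_gcamp6s_q, fit_off_decay, quantify, segment_cycles,
                  signal_to_background, simulate_trace)
from peaq.calibration import FLAG_ABOVE, FLAG_OK
from peaq.quantify import QuantError

from conftest import make_traceset


class TestBackgroundCorrect:
    def test_subtracts_background_trace(self):
        tr = make_traceset([34.0, 34.0], background=[4.0, 4.0])
        out = background_correct(tr)
        assert np.allclose(out.cell("cell_000")["fluorescence"], 30.0)

    def test_zero_background_is_identity(self):
        tr = make_traceset([10.0, 20.0])
        out = background_correct(tr)
        assert np.allclose(out.cell("cell_000")["fluorescence"], [10.0, 20.0])

    def test_double_correction_refused(self):
        tr = make_traceset([10.0, 20.0])
        with pytest.raises(QuantError, match="already"):
            background_correct(background_correct(tr))

    def test_length_mismatch_rejected(self):
        tr = make_traceset([10.0, 20.0], background=[4.0])
        with pytest.raises(Exception, match="length"):
            background_correct(tr)


class TestSignalToBackground:
    def test_worked_ratio_example(self):
        # a 30-count cell over a 4-count empty region
        assert signal_to_background(30.0, 4.0) == 6.5

    def test_twice_background_gives_one(self):
        assert signal_to_background(8.0, 4.0) == 1.0

    def test_equal_gives_zero(self):
        assert signal_to_background(4.0, 4.0) == 0.0

    def test_nonpositive_background_rejected(self):
        with pytest.raises(QuantError):
            signal_to_background(10.0, 0.0)


class TestSegmentCycles:
    def test_discard_first_cycle_counting(self, noiseless_trace, schedule):
        feats = segment_cycles(noiseless_trace, schedule, n_discard=1)
        assert len(feats) == 2
        assert [f.cycle_id for f in feats] == [2, 3]

    def test_contrast_from_first_and_last_frame(self):
        values = [100.0, 60.0, 40.0, 25.0, 14.0]
        cycles = [1] * 5
        sch = IlluminationSchedule(
            [IlluminationEvent("cyan", 46.7, 0.1, True, 1)] * 5)
        tr = make_traceset(values, times=np.arange(5) * 0.1,
                           cycle_ids=cycles, corrected=True)
        feats = segment_cycles(tr, sch, n_discard=0)
        assert feats[0].f0 == 100.0
        assert feats[0].f_end == 14.0
        assert feats[0].contrast == pytest.approx(0.86)

    def test_negative_contrast_for_on_switching_cycle(self):
        # apo-like cycle whose fluorescence rises under cyan light
        values = [100.0, 110.0, 120.0, 128.0, 132.0]
        sch = IlluminationSchedule(
            [IlluminationEvent("cyan", 46.7, 0.1, True, 1)] * 5)
        tr = make_traceset(values, times=np.arange(5) * 0.1,
                           cycle_ids=[1] * 5, corrected=True)
        feats = segment_cycles(tr, sch, n_discard=0)
        assert feats[0].contrast == pytest.approx(-0.32)

    def test_nonpositive_f0_cycle_dropped_with_warning(self):
        sch = IlluminationSchedule(
            [IlluminationEvent("cyan", 46.7, 0.1, True, 1)] * 3)
        tr = make_traceset([-1.0, 5.0, 3.0], times=np.arange(3) * 0.1,
                           cycle_ids=[1, 1, 1], corrected=True)
        with pytest.warns(UserWarning, match="F0"):
            feats = segment_cycles(tr, sch, n_discard=0)
        assert feats == []

    def test_too_few_cycles_for_discard(self, noiseless_trace, schedule):
        with pytest.raises(QuantError, match="at least"):
            segment_cycles(noiseless_trace, schedule, n_discard=3)


class TestOffDecayFit:
    def test_saturated_time_constant(self, params, schedule):
        tr = simulate_trace(params, schedule, ConstantCa(39000.0),
                            noise=NoiseModel.none(), background_level=0.0)
        sub = tr.cell("cell_000")
        c2 = sub[sub["cycle_id"] == 2]
        amp, plat, tau = fit_off_decay(c2["time_s"].to_numpy(),
                                       c2["fluorescence"].to_numpy())
        assert tau == pytest.approx(0.18, abs=1e-3)

    def test_calcium_free_time_constant(self, params, schedule):
        tr = simulate_trace(params, schedule, ConstantCa(0.0),
                            noise=NoiseModel.none(), background_level=0.0)
        sub = tr.cell("cell_000")
        c2 = sub[sub["cycle_id"] == 2]
        amp, plat, tau = fit_off_decay(c2["time_s"].to_numpy(),
                                       c2["fluorescence"].to_numpy())
        assert tau == pytest.approx(0.50, abs=1e-3)

    def test_half_intensity_doubles_tau_same_plateau_ratio(self, params):
        out = {}
        for frac, n in ((1.0, 10), (0.5, 20)):
            spec = ProtocolSpec(n_off_frames=n, cyan_mW=46.7 * frac,
                                period_s=4.0, n_cycles=2)
            sch = build_schedule(spec)
            tr = simulate_trace(params, sch, ConstantCa(39000.0),
                                noise=NoiseModel.none(), background_level=0.0)
            sub = tr.cell("cell_000")
            c2 = sub[sub["cycle_id"] == 2]
            amp, plat, tau = fit_off_decay(c2["time_s"].to_numpy(),
                                           c2["fluorescence"].to_numpy(),
                                           window=n)
            f0 = c2["fluorescence"].iloc[0]
            out[frac] = (tau, plat / f0)
        assert out[0.5][0] / out[1.0][0] == pytest.approx(2.0, rel=1e-3)
        assert out[0.5][1] == pytest.approx(out[1.0][1], rel=1e-3)

    def test_constant_trace_rejected(self):
        with pytest.raises(QuantError, match="no decay"):
            fit_off_decay(np.arange(10.0), np.ones(10))

    def test_small_window_rejected(self):
        with pytest.raises(QuantError, match="window"):
            fit_off_decay(np.arange(10.0), np.exp(-np.arange(10.0)),
                          window=3)


class TestPlateauContrast:
    def test_plateau_equal_f0_gives_zero(self):
        assert contrast_from_plateau(100.0, 100.0) == 0.0

    def test_worked_ratio(self):
        assert contrast_from_plateau(100.0, 14.0) == pytest.approx(0.86)

    def test_nonpositive_f0_rejected(self):
        with pytest.raises(QuantError):
            contrast_from_plateau(0.0, 1.0)

    def test_intensity_independent_while_last_frame_is_not(self, params):
        """At half cyan power the 10-frame window no longer reaches the
        plateau: the last-frame contrast is visibly low while the
        extrapolated-plateau contrast stays put."""
        results = {}
        for frac in (1.0, 0.5):
            spec = ProtocolSpec(cyan_mW=46.7 * frac, n_cycles=2)
            sch = build_schedule(spec)
            tr = simulate_trace(params, sch, ConstantCa(39000.0),
                                noise=NoiseModel.none(), background_level=0.0)
            last = segment_cycles(tr, sch, n_discard=1)[0]
            plat = segment_cycles(tr, sch, n_discard=1,
                                  f_end_source="exponential_plateau")[0]
            results[frac] = (last.contrast, plat.contrast)
        full, half = results[1.0], results[0.5]
        assert half[1] == pytest.approx(full[1], rel=0.01)   # plateau-based
        assert abs(half[0] - full[0]) / full[0] > 0.01       # last-frame


class TestQuantify:
    def test_midpoint_contrast_maps_to_kd(self, curves):
        from peaq.quantify import CycleFeatures
        curve = curves["contrast"]
        midpoint = curve.fit.f_max + curve.fit.f_diff / 2
        ft = CycleFeatures(cell_id="c", cycle_id=2, t_cycle_s=0.0, f0=100.0,
                           f_end=100.0 * (1 - midpoint), contrast=midpoint)
        res = quantify([ft], curve, brightness_gate=0.0)
        assert res[0].ca_nM == pytest.approx(curve.fit.kd, rel=1e-9)
        assert res[0].flag == FLAG_OK

    def test_saturating_contrast_flagged_and_clipped(self, curves):
        from peaq.quantify import CycleFeatures
        curve = curves["contrast"]
        ft = CycleFeatures(cell_id="c", cycle_id=2, t_cycle_s=0.0, f0=100.0,
                           f_end=15.0, contrast=0.85)
        res = quantify([ft], curve, brightness_gate=0.0)
        assert res[0].flag == FLAG_ABOVE
        assert res[0].ca_nM == pytest.approx(curve.working_range()[1])
        assert res[0].ca_raw_nM > res[0].ca_nM

    def test_wrong_kind_rejected(self, curves):
        with pytest.raises(QuantError, match="contrast"):
            quantify([], curves["fluorescence"])

    def test_brightness_gate_excludes_dim_cells(self, curves):
        from peaq.quantify import CycleFeatures
        curve = curves["contrast"]
        mid = curve.fit.f_max + curve.fit.f_diff / 2
        dim = CycleFeatures(cell_id="dim", cycle_id=2, t_cycle_s=0.0,
                            f0=5.0, f_end=5.0 * (1 - mid), contrast=mid)
        bright = CycleFeatures(cell_id="bright", cycle_id=2, t_cycle_s=0.0,
                               f0=80.0, f_end=80.0 * (1 - mid), contrast=mid)
        res = quantify([dim, bright], curve, brightness_gate=30.0)
        assert [r.cell_id for r in res] == ["bright"]

    def test_end_to_end_constant_200nM(self, params, schedule, curves):
        tr = simulate_trace(params, schedule, ConstantCa(200.0),
                            noise=NoiseModel.none(), background_level=4.0)
        tr.fingerprint = curves["contrast"].fingerprint
        tr = background_correct(tr)
        feats = segment_cycles(tr, schedule, n_discard=1)
        res = quantify(feats, curves["contrast"],
                       trace_fingerprint=tr.fingerprint)
        assert len(res) == 2
        for r in res:
            assert r.flag == FLAG_OK
            assert r.ca_nM == pytest.approx(200.0, rel=0.02)

    def test_robust_to_fatigue_halving_f0(self, params, curves):
        """With fatigue halving F0 over the run, quantified Ca of a
        constant-Ca trace stays within 5% of truth."""
        p = params.replace(fatigue_retention=0.5 ** (1 / 20))
        spec = ProtocolSpec(n_cycles=21)
        sch = build_schedule(spec)
        tr = simulate_trace(p, sch, ConstantCa(150.0),
                            noise=NoiseModel.none(), background_level=0.0)
        feats = segment_cycles(tr, sch, n_discard=1)
        assert feats[-1].f0 / feats[0].f0 < 0.55
        res = quantify(feats, curves["contrast"], brightness_gate=0.0)
        for r in res:
            assert r.ca_nM == pytest.approx(150.0, rel=0.05)

    def test_contrast_invariant_under_trace_rescale(self, params, schedule,
                                                    curves):
        tr = simulate_trace(params, schedule, ConstantCa(150.0),
                            cells=(1.0, 13.7), noise=NoiseModel.none(),
                            background_level=0.0)
        feats = segment_cycles(tr, schedule, n_discard=1)
        by_cell = {}
        for ft in feats:
            by_cell.setdefault(ft.cell_id, []).append(ft.contrast)
        c0 = by_cell["cell_000"]
        c1 = by_cell["cell_001"]
        assert np.allclose(c0, c1, atol=1e-3)


class TestCycleDuration:
    def test_default_protocol_1p1_s(self, schedule):
        assert acquisition_cycle_duration(schedule) == pytest.approx(1.1)

    @pytest.mark.parametrize("n,e,p", [(2, 0.1, 0.1), (5, 0.05, 0.2),
                                       (12, 0.033, 0.07)])
    def test_sum_of_frames_and_pulse(self, n, e, p):
        spec = ProtocolSpec(n_off_frames=n, exposure_s=e, violet_pulse_s=p,
                            period_s=n * e + p + 0.1, n_cycles=1)
        sch = build_schedule(spec)
        assert acquisition_cycle_duration(sch) == pytest.approx(n * e + p)
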