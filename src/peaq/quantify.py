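"""From raw traces to per-cycle photochromism features and absolute Ca2+.

The analysis chain is: subtract the background trace measured in an empty
sample region; segment the trace into photochromism cycles and compute,
per retained cycle, ``F0`` (first cyan frame), ``F_end`` (last cyan frame
or the plateau of an exponential fit) and the photochromism contrast
``(F0 - F_end)/F0``; then invert each contrast through a contrast
calibration curve to an absolute concentration, flagging values in the
unreliable extreme bands of the calibration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .calibration import FLAG_ABOVE, FLAG_BELOW, FLAG_OK, CalibrationCurve
from .schedule import IlluminationSchedule
from .simulate import TraceSet


class QuantError(ValueError):
    pass


DEFAULT_BRIGHTNESS_GATE = 30.0  # counts; dimmer cells are excluded


@dataclass(frozen=True)
class CycleFeatures:
    """Photochromism features of one off-switching cycle of one cell."""

    cell_id: str
    cycle_id: int
    t_cycle_s: float          # time of the F0 frame
    f0: float
    f_end: float
    contrast: float           # (f0 - f_end) / f0
    f_end_source: str = "last_frame"   # or "exponential_plateau"
    decay_amplitude: float | None = None
    decay_plateau: float | None = None
    decay_tau_s: float | None = None


@dataclass(frozen=True)
class QuantResult:
    """Absolute concentration estimate at one timepoint."""

    cell_id: str
    time_s: float
    ca_nM: float              # clipped to the working-range edge when flagged
    ca_raw_nM: float          # unclipped inversion (inf if not invertible)
    flag: str                 # ok / below_range / above_range
    method: str               # "peaq" or "intermittent"


def background_correct(trace: TraceSet) -> TraceSet:
    """Subtract the background trace frame-by-frame from every cell.

    Correcting an already-corrected trace set is refused.
    """
    if trace.background_corrected:
        raise QuantError("trace set is already background-corrected")
    trace.validate()
    frames = trace.frames.copy()
    bg = np.asarray(trace.background, dtype=float)
    frames["fluorescence"] = frames["fluorescence"].to_numpy() \
        - bg[frames["frame"].to_numpy()]
    return TraceSet(
        frames=frames, background=bg,
        expression_scales=trace.expression_scales, seed=trace.seed,
        fingerprint=trace.fingerprint, background_corrected=True,
        metadata={**trace.metadata, "background_corrected": True})


def signal_to_background(f_total: float, b: float) -> float:
    """Signal-to-background ratio (f_total - b) / b of an uncorrected cell
    signal ``f_total`` over background ``b``."""
    if b <= 0:
        raise QuantError("background must be > 0")
    return (f_total - b) / b


def fit_off_decay(times_s, f, window: int = 10):
    """Fit ``f(t) = amplitude * exp(-t / tau) + plateau`` to the first
    ``window`` off-switching frames.

    Initialization is deterministic: plateau from the last point of the
    window, amplitude from first minus last, tau from the time at which
    the trace first crosses 1/e of the amplitude (linear interpolation).
    Rising traces are handled by the sign of the amplitude.

    Returns ``(amplitude, plateau, tau_s)``.
    """
    t = np.asarray(times_s, dtype=float)
    y = np.asarray(f, dtype=float)
    if t.shape != y.shape or t.ndim != 1:
        raise QuantError("times and values must be 1-d and equal length")
    if window < 4:
        raise QuantError("window must be >= 4 points")
    if len(t) < window:
        raise QuantError(f"need at least {window} points, got {len(t)}")
    t = t[:window] - t[0]
    y = y[:window]
    if np.any(np.diff(t) <= 0):
        raise QuantError("times must be strictly increasing")
    if np.ptp(y) == 0.0:
        raise QuantError("no decay: trace is constant")

    plateau0 = y[-1]
    amp0 = y[0] - y[-1]
    # 1/e crossing of the deviation from the plateau estimate
    dev = (y - plateau0) / amp0 if amp0 != 0 else np.zeros_like(y)
    tau0 = t[-1] / 2.0
    target = math.exp(-1.0)
    for i in range(1, len(t)):
        if dev[i] <= target:
            d0, d1 = dev[i - 1], dev[i]
            frac = (d0 - target) / (d0 - d1) if d0 != d1 else 0.5
            tau0 = t[i - 1] + frac * (t[i] - t[i - 1])
            break
    tau0 = max(tau0, 1e-6)

    tau_lo, tau_hi = 1e-6, 1e6
    try:
        popt, _ = curve_fit(
            lambda tt, a, p, tau: a * np.exp(-tt / tau) + p,
            t, y, p0=[amp0, plateau0, tau0],
            bounds=([-np.inf, -np.inf, tau_lo], [np.inf, np.inf, tau_hi]),
            maxfev=10000, xtol=1e-14, ftol=1e-14)
    except RuntimeError as exc:
        raise QuantError(f"off-decay fit did not converge: {exc}") from exc
    amp, plateau, tau = (float(v) for v in popt)
    if tau <= tau_lo * 1.01 or tau >= tau_hi * 0.99:
        raise QuantError(
            f"off-decay fit hit the tau bound (tau={tau:g} s, "
            f"amplitude={amp:g}, plateau={plateau:g})")
    return amp, plateau, tau


def contrast_from_plateau(f0: float, plateau: float) -> float:
    """Photochromism contrast with the extrapolated plateau as F_end."""
    if f0 <= 0:
        raise QuantError("f0 must be > 0")
    return (f0 - plateau) / f0


def segment_cycles(trace: TraceSet, schedule: IlluminationSchedule,
                   n_discard: int = 1, f_end_source: str = "last_frame",
                   decay_window: int = 10) -> list[CycleFeatures]:
    """Extract per-cycle photochromism features from every cell.

    The first ``n_discard`` cycles (default 1: the deviant initial cycle)
    are dropped.  ``F0`` is the first cyan camera frame of a cycle and
    ``F_end`` the last, unless ``f_end_source="exponential_plateau"``
    replaces ``F_end`` by the plateau of an exponential fit to the first
    ``decay_window`` frames.  Cycles whose ``F0`` is not positive after
    background correction are dropped with a warning.
    """
    if f_end_source not in ("last_frame", "exponential_plateau"):
        raise QuantError(f"unknown f_end_source {f_end_source!r}")
    cycle_ids = schedule.cycle_ids
    if len(cycle_ids) < n_discard + 1:
        raise QuantError(
            f"schedule defines {len(cycle_ids)} cycles; "
            f"need at least {n_discard + 1}")
    retained = set(cycle_ids[n_discard:])

    out: list[CycleFeatures] = []
    for cell_id in trace.cell_ids:
        sub = trace.cell(cell_id)
        cyc = sub.dropna(subset=["cycle_id"])
        for cid, grp in cyc.groupby("cycle_id", sort=True):
            cid = int(cid)
            if cid not in retained:
                continue
            grp = grp.sort_values("frame")
            f = grp["fluorescence"].to_numpy(dtype=float)
            t = grp["time_s"].to_numpy(dtype=float)
            if len(f) < 2:
                raise QuantError(f"cycle {cid} has fewer than 2 cyan frames")
            f0 = float(f[0])
            if f0 <= 0:
                warnings.warn(
                    f"cell {cell_id}: cycle {cid} dropped (F0 <= 0)")
                continue
            if f_end_source == "exponential_plateau":
                amp, plateau, tau = fit_off_decay(t, f, window=min(
                    decay_window, len(f)))
                feat = CycleFeatures(
                    cell_id=cell_id, cycle_id=cid, t_cycle_s=float(t[0]),
                    f0=f0, f_end=plateau,
                    contrast=contrast_from_plateau(f0, plateau),
                    f_end_source=f_end_source, decay_amplitude=amp,
                    decay_plateau=plateau, decay_tau_s=tau)
            else:
                f_end = float(f[-1])
                feat = CycleFeatures(
                    cell_id=cell_id, cycle_id=cid, t_cycle_s=float(t[0]),
                    f0=f0, f_end=f_end, contrast=(f0 - f_end) / f0)
            out.append(feat)
    return out


def acquisition_cycle_duration(schedule: IlluminationSchedule) -> float:
    """Duration (s) of one photochromism acquisition block: the summed
    violet-pulse and cyan-frame illumination of a single cycle."""
    return schedule.acquisition_cycle_duration_s()


def _invert_with_working_range(curve: CalibrationCurve, response: float
                               ) -> tuple[float, float, str]:
    """(ca_clipped, ca_raw, flag) for a response against a curve.

    Responses outside the central working band are flagged and clipped to
    the working-range edge concentration; the unclipped inversion is also
    returned (infinite when the response lies beyond the asymptote).
    """
    ca_raw, flag_raw = curve.invert(response)
    lo_resp, hi_resp = curve.response_band()
    ca_lo, ca_hi = curve.working_range()
    increasing = curve.fit.f_diff < 0
    if increasing:
        below = response < lo_resp
        above = response > hi_resp
    else:
        below = response > hi_resp
        above = response < lo_resp
    if below:
        return ca_lo, ca_raw, FLAG_BELOW
    if above:
        return ca_hi, ca_raw, FLAG_ABOVE
    return ca_raw, ca_raw, FLAG_OK


def check_fingerprint(curve: CalibrationCurve, fingerprint: dict | None,
                      override: bool = False) -> None:
    """Enforce that the calibration was measured with the instrument
    settings of the experiment; mismatches are refused unless overridden."""
    if override or curve.fingerprint is None or fingerprint is None:
        return
    if curve.fingerprint != fingerprint:
        raise QuantError(
            "calibration fingerprint does not match the experiment "
            f"({curve.fingerprint} vs {fingerprint}); pass override to force")


def quantify(features: list[CycleFeatures], curve: CalibrationCurve,
             trace_fingerprint: dict | None = None,
             override_fingerprint: bool = False,
             brightness_gate: float = DEFAULT_BRIGHTNESS_GATE
             ) -> list[QuantResult]:
    """Map per-cycle contrasts to absolute concentrations.

    Cells whose peak ``F0`` is below ``brightness_gate`` counts are
    excluded entirely (dim cells have unreliable contrast).
    """
    if curve.kind != "contrast":
        raise QuantError(
            f"contrast calibration required, got kind {curve.kind!r}")
    check_fingerprint(curve, trace_fingerprint, override_fingerprint)

    peak: dict[str, float] = {}
    for ft in features:
        peak[ft.cell_id] = max(peak.get(ft.cell_id, -math.inf), ft.f0)
    out: list[QuantResult] = []
    for ft in features:
        if peak[ft.cell_id] < brightness_gate:
            continue
        ca, ca_raw, flag = _invert_with_working_range(curve, ft.contrast)
        out.append(QuantResult(
            cell_id=ft.cell_id, time_s=ft.t_cycle_s, ca_nM=ca,
            ca_raw_nM=ca_raw, flag=flag, method="peaq"))
    return out


def features_to_frame(features: list[CycleFeatures]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": ft.cell_id, "cycle_id": ft.cycle_id,
        "time_s": ft.t_cycle_s, "f0": ft.f0, "f_end": ft.f_end,
        "contrast": ft.contrast, "f_end_source": ft.f_end_source,
    } for ft in features])


def results_to_frame(results: list[QuantResult]) -> pd.DataFrame:
    return pd.DataFrame([{
        "cell_id": r.cell_id, "time_s": r.time_s, "ca_nM": r.ca_nM,
        "ca_raw_nM": r.ca_raw_nM, "flag": r.flag, "method": r.method,
    } for r in results])
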