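"""Intermittent quantification (iPEAQ): fast frames between calibrations.

Occasional photochromism cycles provide absolute concentrations through
the contrast calibration; at each such calibration point the brightness
``F0`` and the known concentration fix a per-cell scale factor

    A = F0 / F_T(Ca)

where ``F_T`` is the normalized fluorescence titration curve.  The set of
``A_i`` values is fitted to a straight line in time (weighted by the
observed brightness: each point's standard deviation is taken as
``1/F0``), which absorbs slow drift of the local probe concentration from
bleaching or expression dynamics.  Every intermittent fluorescence frame
then yields an absolute concentration via ``Ca = F_T^-1(F0 / A(t))``.
The light-dose bookkeeping quantifies how much cyan exposure this saves
over running a full photochromism cycle at every timepoint.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .calibration import FLAG_OK, CalibrationCurve, CalibrationError
from .quantify import (CycleFeatures, QuantError, QuantResult,
                       _invert_with_working_range, check_fingerprint,
                       quantify)
from .schedule import IlluminationSchedule, ProtocolSpec
from .simulate import TraceSet


class IpeaqError(ValueError):
    pass


@dataclass
class ScaleFactorModel:
    """Per-cell brightness scale factors A_i and their linear time trend.

    ``points`` has columns ``time_s``, ``A``, ``f0``, ``ca_nM``.  The
    trend is a variance-weighted least-squares line with per-point
    standard deviation ``1/f0``; it is evaluated (and at the edges
    extrapolated) at arbitrary times within the trace.
    """

    points: pd.DataFrame
    intercept: float
    slope: float
    covariance: np.ndarray = field(repr=False)

    @property
    def intercept_stderr(self) -> float:
        return float(np.sqrt(self.covariance[0, 0]))

    @property
    def slope_stderr(self) -> float:
        return float(np.sqrt(self.covariance[1, 1]))

    def __call__(self, t: float) -> float:
        return self.intercept + self.slope * t


def scale_factor(f0: float, ca_nM: float, curve: CalibrationCurve) -> float:
    """Scale factor A = f0 / F_T(ca) from one calibration point."""
    if not curve.normalized:
        raise IpeaqError("scale factors require a normalized titration curve")
    ft = curve.eval(ca_nM)
    if ft <= 0.0:
        raise IpeaqError(
            f"F_T({ca_nM} nM) = {ft:g} is not positive; point unusable")
    return f0 / ft


def fit_scale_trend(times_s, a_values, f0_values) -> ScaleFactorModel:
    """Weighted least-squares line through the (t, A) calibration points.

    The standard deviation of each point is ``1/f0`` (bright points are
    trusted more), i.e. weights ``w = f0**2`` in the normal equations.
    The parameter covariance is ``(X' W X)^-1`` under that noise model.
    """
    t = np.asarray(times_s, dtype=float)
    a = np.asarray(a_values, dtype=float)
    f0 = np.asarray(f0_values, dtype=float)
    if not (t.shape == a.shape == f0.shape) or t.ndim != 1:
        raise IpeaqError("times, A values and f0 values must match in shape")
    if len(t) < 2:
        raise IpeaqError("at least 2 calibration points required")
    if np.all(t == t[0]):
        raise IpeaqError("rank deficient: all calibration points at one time")
    if np.any(f0 <= 0):
        raise IpeaqError("f0 weights must be > 0")
    w = f0 ** 2
    x = np.column_stack([np.ones_like(t), t])
    xtwx = x.T @ (w[:, None] * x)
    xtwy = x.T @ (w * a)
    coef = np.linalg.solve(xtwx, xtwy)
    cov = np.linalg.inv(xtwx)
    return ScaleFactorModel(
        points=pd.DataFrame({"time_s": t, "A": a, "f0": f0}),
        intercept=float(coef[0]), slope=float(coef[1]), covariance=cov)


def intermittent_quantify(f0: float, t_s: float, model: ScaleFactorModel,
                          curve: CalibrationCurve) -> tuple[float, str]:
    """Concentration at an intermittent frame: ``F_T^-1(f0 / A(t))``.

    Returns ``(ca_nM, flag)`` with the same working-range clipping and
    flags as photochromism-based quantification.
    """
    if not curve.normalized:
        raise IpeaqError("intermittent quantification needs a normalized curve")
    a_t = model(t_s)
    if a_t <= 0:
        raise IpeaqError(f"trend collapsed: A({t_s} s) = {a_t:g} <= 0")
    ca, _, flag = _invert_with_working_range(curve, f0 / a_t)
    return ca, flag


def repair_first_post_cycle_frame(values, post_cycle_indices
                                  ) -> tuple[np.ndarray, dict[int, float]]:
    """Replace each flagged frame by the mean of its two neighbours.

    The first intermittent frame after a photochromism cycle is depressed
    by a transient dark intermediate; linear interpolation between the
    neighbouring frames removes the dip.  Flagged frames at a trace
    boundary are left unrepaired with a warning.  Returns the repaired
    array and the original values of the repaired indices.
    """
    y = np.asarray(values, dtype=float).copy()
    originals: dict[int, float] = {}
    for i in post_cycle_indices:
        if i <= 0 or i >= len(y) - 1:
            warnings.warn(f"frame {i} at trace boundary left unrepaired")
            continue
        originals[i] = float(y[i])
        y[i] = 0.5 * (y[i - 1] + y[i + 1])
    return y, originals


# ---------------------------------------------------------------------------
# Light-dose accounting
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class DoseModel:
    """Cyan/violet light doses of the two acquisition types.

    Doses are exposure time x intensity (mJ) per photochromism cycle and
    per intermittent frame; ``n_intermittent`` is the number of
    intensiometric acquisitions between consecutive cycles.
    """

    cyan_per_cycle_mJ: float
    cyan_per_frame_mJ: float
    violet_per_cycle_mJ: float
    violet_per_frame_mJ: float
    n_intermittent: int

    def __post_init__(self) -> None:
        for name in ("cyan_per_cycle_mJ", "cyan_per_frame_mJ",
                     "violet_per_cycle_mJ", "violet_per_frame_mJ"):
            if getattr(self, name) < 0:
                raise IpeaqError(f"{name} must be >= 0")
        if self.n_intermittent < 0:
            raise IpeaqError("n_intermittent must be >= 0")

    @staticmethod
    def from_protocol(spec: ProtocolSpec) -> "DoseModel":
        return DoseModel(
            cyan_per_cycle_mJ=spec.n_off_frames * spec.exposure_s * spec.cyan_mW,
            cyan_per_frame_mJ=spec.exposure_s * spec.cyan_mW,
            violet_per_cycle_mJ=spec.violet_pulse_s * spec.violet_mW,
            violet_per_frame_mJ=spec.violet_pulse_s * spec.violet_mW,
            n_intermittent=spec.n_intermittent)


def light_dose_saving(dose: DoseModel) -> float:
    """Fraction of the cyan light dose saved by intermittent acquisition.

    With ``C`` the cyan dose of one photochromism cycle, ``c`` that of one
    intermittent frame and ``N`` intermittent frames per cycle::

        saved = 1 - (C + N c) / ((1 + N) C)

    i.e. the saving relative to running a full cycle at all 1+N
    timepoints.  Violet exposure shrinks correspondingly but is reported
    separately by :func:`dose_report`.
    """
    if dose.cyan_per_cycle_mJ <= 0:
        raise IpeaqError("cyan dose per cycle must be > 0")
    n = dose.n_intermittent
    c_cycle, c_frame = dose.cyan_per_cycle_mJ, dose.cyan_per_frame_mJ
    return 1.0 - (c_cycle + n * c_frame) / ((1 + n) * c_cycle)


def remaining_dose_fraction(dose: DoseModel) -> float:
    return 1.0 - light_dose_saving(dose)


def dose_report(dose: DoseModel) -> dict:
    n = dose.n_intermittent
    return {
        "n_intermittent": n,
        "cyan_per_cycle_mJ": dose.cyan_per_cycle_mJ,
        "cyan_per_frame_mJ": dose.cyan_per_frame_mJ,
        "violet_per_cycle_mJ": dose.violet_per_cycle_mJ,
        "violet_per_frame_mJ": dose.violet_per_frame_mJ,
        "cyan_saved_fraction": light_dose_saving(dose),
        "cyan_remaining_fraction": remaining_dose_fraction(dose),
        "violet_total_per_block_mJ":
            dose.violet_per_cycle_mJ + n * dose.violet_per_frame_mJ,
    }


# ---------------------------------------------------------------------------
# End-to-end intermittent pipeline
# ---------------------------------------------------------------------------

def run_ipeaq(trace: TraceSet, schedule: IlluminationSchedule,
              contrast_curve: CalibrationCurve,
              fluorescence_curve: CalibrationCurve,
              n_discard: int = 1,
              brightness_gate: float = 30.0,
              override_fingerprint: bool = False,
              ) -> tuple[list[QuantResult], dict[str, ScaleFactorModel]]:
    """Full intermittent quantification of a background-corrected trace set.

    Photochromism cycles are segmented and quantified through the contrast
    calibration; calibration points whose contrast falls outside the
    working range are excluded from the scale-factor trend (their inferred
    concentration, hence ``F_T``, is unreliable).  Intermittent frames are
    dip-repaired and inverted through the normalized fluorescence curve.
    Returns the merged, time-ordered results plus the per-cell scale
    models.
    """
    from .quantify import segment_cycles  # local to avoid cycle at import

    if not fluorescence_curve.normalized:
        raise IpeaqError("fluorescence curve must be normalized (F_T form)")
    if fluorescence_curve.kind != "fluorescence":
        raise IpeaqError("second curve must be a fluorescence calibration")
    check_fingerprint(fluorescence_curve, trace.fingerprint,
                      override_fingerprint)

    features = segment_cycles(trace, schedule, n_discard=n_discard)
    peaq_results = quantify(
        features, contrast_curve, trace_fingerprint=trace.fingerprint,
        override_fingerprint=override_fingerprint,
        brightness_gate=brightness_gate)
    by_cell_feat: dict[str, list[CycleFeatures]] = {}
    for ft in features:
        by_cell_feat.setdefault(ft.cell_id, []).append(ft)
    by_cell_res: dict[str, dict[float, QuantResult]] = {}
    for r in peaq_results:
        by_cell_res.setdefault(r.cell_id, {})[r.time_s] = r

    # The brightness series the intermittent analysis runs on consists of
    # the F0 frame of every cycle plus all intermittent frames; dip repair
    # interpolates between neighbours in THIS series (the raw-frame
    # neighbour of a post-cycle frame is a fully off-switched frame).
    frame_cycles = schedule.frame_cycle_ids()
    f0_series_idx: list[int] = []
    seen_cycles: set[int] = set()
    for i, c in enumerate(frame_cycles):
        if c is None:
            f0_series_idx.append(i)
        elif c not in seen_cycles:
            seen_cycles.add(c)
            f0_series_idx.append(i)
    pos_in_series = {fi: j for j, fi in enumerate(f0_series_idx)}
    post_series = [pos_in_series[i]
                   for i in schedule.post_cycle_frame_indices()]
    inter_idx = [i for i, c in enumerate(frame_cycles) if c is None]

    results: list[QuantResult] = list(peaq_results)
    models: dict[str, ScaleFactorModel] = {}
    for cell_id in trace.cell_ids:
        if cell_id not in by_cell_res:
            continue  # gated out or all cycles unusable
        pts_t, pts_a, pts_f0 = [], [], []
        for ft in by_cell_feat[cell_id]:
            res = by_cell_res[cell_id].get(ft.t_cycle_s)
            if res is None or res.flag != FLAG_OK:
                continue
            try:
                a = scale_factor(ft.f0, res.ca_nM, fluorescence_curve)
            except IpeaqError as exc:
                warnings.warn(f"cell {cell_id}: {exc}")
                continue
            pts_t.append(ft.t_cycle_s)
            pts_a.append(a)
            pts_f0.append(ft.f0)
        if len(pts_t) < 2:
            warnings.warn(
                f"cell {cell_id}: fewer than 2 usable calibration points; "
                "intermittent frames skipped")
            continue
        model = fit_scale_trend(pts_t, pts_a, pts_f0)
        models[cell_id] = model

        sub = trace.cell(cell_id)
        fvals = sub["fluorescence"].to_numpy(dtype=float)
        series, _ = repair_first_post_cycle_frame(
            fvals[f0_series_idx], post_series)
        repaired = fvals.copy()
        repaired[f0_series_idx] = series
        tvals = sub["time_s"].to_numpy(dtype=float)
        for i in inter_idx:
            a_t = model(float(tvals[i]))
            if a_t <= 0:
                raise IpeaqError(
                    f"trend collapsed: A({tvals[i]} s) = {a_t:g} <= 0")
            ca, ca_raw, flag = _invert_with_working_range(
                fluorescence_curve, float(repaired[i]) / a_t)
            results.append(QuantResult(
                cell_id=cell_id, time_s=float(tvals[i]), ca_nM=ca,
                ca_raw_nM=ca_raw, flag=flag, method="intermittent"))

    results.sort(key=lambda r: (r.cell_id, r.time_s))
    return results, models
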