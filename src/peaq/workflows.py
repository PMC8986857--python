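"""High-level workflows chaining simulation, calibration and quantification.

These functions are what the command-line interface wraps: simulate a
titration and fit both calibration curves, or quantify a trace set
against stored calibrations, returning tabular results plus a pipeline
report with record counts and provenance.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .calibration import CalibrationCurve, fit_hill, normalize_fit
from .config import RunConfig
from .intermittent import DoseModel, dose_report, run_ipeaq
from .io import config_hash
from .params import SensorParams
from .quantify import (background_correct, features_to_frame, quantify,
                       results_to_frame, segment_cycles)
from .schedule import IlluminationSchedule, ProtocolSpec, build_schedule
from .simulate import TraceSet, simulate_trace
from .trajectory import ConstantCa, make_titration_ladder


def simulate_run(config: RunConfig) -> tuple[TraceSet, IlluminationSchedule]:
    """Simulate one trace set from a run configuration."""
    params = config.sensor.build()
    spec = config.protocol.build()
    schedule = build_schedule(spec)
    trace = simulate_trace(
        params, schedule, config.trajectory.build(),
        cells=config.expression_scales(), noise=config.noise.build(),
        seed=config.seed, background_level=config.noise.background_level)
    trace.fingerprint = spec.fingerprint()
    trace.metadata["config_hash"] = config_hash(config.model_dump())
    return trace, schedule


def simulate_titration(params: SensorParams, protocol: ProtocolSpec,
                       concentrations=None, noise=None, seed: int = 0,
                       background_level: float = 0.0,
                       n_discard: int = 1) -> pd.DataFrame:
    """Simulate the in vitro titration: one well per concentration.

    Each well is measured with the full protocol; the contrast response is
    the photochromism contrast of the first retained cycle and the
    fluorescence response is that cycle's F0, matching how the two
    titrations are extracted from a real plate measurement.  Returns a
    table with columns ``ca_nM``, ``contrast``, ``fluorescence``.
    """
    if concentrations is None:
        concentrations = make_titration_ladder()
    rows = []
    for i, ca in enumerate(concentrations):
        trace = simulate_trace(
            params, build_schedule(protocol), ConstantCa(ca), noise=noise,
            seed=seed + i, background_level=background_level)
        feats = segment_cycles(trace, build_schedule(protocol),
                               n_discard=n_discard)
        ft = feats[0]
        rows.append({"ca_nM": ca, "contrast": ft.contrast,
                     "fluorescence": ft.f0})
    return pd.DataFrame(rows)


def calibrate_titration(titration: pd.DataFrame,
                        working_fraction: float = 0.05,
                        fingerprint: dict | None = None
                        ) -> dict[str, CalibrationCurve]:
    """Fit Hill calibrations for every response column present.

    Returns up to three curves: ``contrast``, ``fluorescence`` and
    ``fluorescence_normalized`` (the F_T form used by intermittent
    quantification).
    """
    out: dict[str, CalibrationCurve] = {}
    ca = titration["ca_nM"].to_numpy(dtype=float)
    for kind in ("contrast", "fluorescence"):
        if kind not in titration.columns:
            continue
        fit = fit_hill(ca, titration[kind].to_numpy(dtype=float), kind)
        out[kind] = CalibrationCurve(
            fit=fit, working_fraction=working_fraction,
            fingerprint=fingerprint)
        if kind == "fluorescence":
            norm = normalize_fit(fit)
            out["fluorescence_normalized"] = CalibrationCurve(
                fit=norm.fit, normalized=True,
                working_fraction=working_fraction, fingerprint=fingerprint)
    if not out:
        raise ValueError("titration table has no response columns")
    return out


def quantify_run(trace: TraceSet, schedule: IlluminationSchedule,
                 contrast_curve: CalibrationCurve, config: RunConfig,
                 override_fingerprint: bool = False):
    """PEAQ quantification of a trace set; returns (features, results,
    report)."""
    if not trace.background_corrected:
        trace = background_correct(trace)
    ana = config.analysis
    features = segment_cycles(
        trace, schedule, n_discard=ana.n_discard,
        f_end_source=ana.f_end_source, decay_window=ana.decay_window)
    results = quantify(
        features, contrast_curve, trace_fingerprint=trace.fingerprint,
        override_fingerprint=override_fingerprint,
        brightness_gate=ana.brightness_gate)
    n_cells = len(trace.cell_ids)
    cells_kept = len({r.cell_id for r in results})
    report = {
        "config_hash": config_hash(config.model_dump()),
        "seed": config.seed,
        "n_cells": n_cells,
        "n_cells_quantified": cells_kept,
        "n_cells_gated_out": n_cells - cells_kept,
        "n_cycles_retained": len(features),
        "n_results": len(results),
        "n_flagged": sum(1 for r in results if r.flag != "ok"),
    }
    return features, results, report


def ipeaq_run(trace: TraceSet, schedule: IlluminationSchedule,
              contrast_curve: CalibrationCurve,
              fluorescence_curve: CalibrationCurve, config: RunConfig,
              override_fingerprint: bool = False):
    """Intermittent quantification; returns (results, models, report)."""
    if not trace.background_corrected:
        trace = background_correct(trace)
    ana = config.analysis
    results, models = run_ipeaq(
        trace, schedule, contrast_curve, fluorescence_curve,
        n_discard=ana.n_discard, brightness_gate=ana.brightness_gate,
        override_fingerprint=override_fingerprint)
    dose = DoseModel.from_protocol(config.protocol.build())
    n_int = sum(1 for r in results if r.method == "intermittent")
    report = {
        "config_hash": config_hash(config.model_dump()),
        "seed": config.seed,
        "n_cells": len(trace.cell_ids),
        "n_cells_quantified": len({r.cell_id for r in results}),
        "n_results": len(results),
        "n_peaq_points": len(results) - n_int,
        "n_intermittent_points": n_int,
        "n_flagged": sum(1 for r in results if r.flag != "ok"),
        "dose": dose_report(dose),
    }
    return results, models, report
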