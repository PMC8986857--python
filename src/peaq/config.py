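"""Run configuration: one structured document driving a whole run.

A :class:`RunConfig` bundles sensor parameter overrides, the acquisition
protocol, the Ca2+ trajectory, the cell population and noise settings,
and the analysis options.  Unknown keys are rejected so typos fail loudly.
Loadable from YAML or JSON.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, Field, field_validator

from .params import NoiseModel, SensorParams, default_gcamp6s_q
from .schedule import ProtocolSpec
from .trajectory import ConstantCa, OscillatingCa, StepCa


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SensorConfig(_Strict):
    """Overrides applied on top of the default GCaMP6s-Q parameter set."""

    kd_occupancy: Optional[float] = None
    hill_h: Optional[float] = None
    brightness_sat_on: Optional[float] = None
    brightness_apo_on: Optional[float] = None
    residual_off_fraction: Optional[float] = None
    k_cyan_off_sat: Optional[float] = None
    k_cyan_on_sat: Optional[float] = None
    k_cyan_off_apo: Optional[float] = None
    k_cyan_on_apo: Optional[float] = None
    k_violet_on_sat: Optional[float] = None
    k_violet_off_apo: Optional[float] = None
    tau_thermal_sat: Optional[float] = None
    tau_thermal_apo: Optional[float] = None
    fatigue_retention: Optional[float] = None
    first_cycle_factor: Optional[float] = None
    post_cycle_dip_factor: Optional[float] = None

    def build(self) -> SensorParams:
        base = default_gcamp6s_q()
        overrides = {k: v for k, v in self.model_dump().items()
                     if v is not None}
        return base.replace(**overrides)


class ProtocolConfig(_Strict):
    n_off_frames: int = 10
    exposure_s: float = 0.1
    violet_pulse_s: float = 0.1
    period_s: float = 2.0
    n_intermittent: int = 0
    intermittent_period_s: float = 2.0
    cyan_mW: float = 46.7
    violet_mW: float = 59.3
    n_cycles: int = 3

    def build(self) -> ProtocolSpec:
        return ProtocolSpec(**self.model_dump())


class TrajectoryConfig(_Strict):
    kind: Literal["constant", "steps", "oscillation"] = "constant"
    ca_nM: float = 39000.0
    times_s: Optional[list[float]] = None
    values_nM: Optional[list[float]] = None
    end_s: Optional[float] = None
    baseline_nM: float = 60.0
    peak_nM: float = 1000.0
    period_s: float = 30.0
    spike_width_s: float = 6.0
    amplitude_decay: float = 0.85
    t_first_s: float = 10.0

    def build(self):
        if self.kind == "constant":
            return ConstantCa(self.ca_nM)
        if self.kind == "steps":
            if self.times_s is None or self.values_nM is None or self.end_s is None:
                raise ValueError("steps trajectory needs times_s, values_nM, end_s")
            return StepCa(tuple(self.times_s), tuple(self.values_nM), self.end_s)
        return OscillatingCa(
            baseline_nM=self.baseline_nM, peak_nM=self.peak_nM,
            period_s=self.period_s, spike_width_s=self.spike_width_s,
            amplitude_decay=self.amplitude_decay, t_first_s=self.t_first_s)


class CellsConfig(_Strict):
    n_cells: int = Field(default=1, ge=1)
    expression_mean: float = Field(default=1.0, gt=0)
    expression_cv: float = Field(default=0.0, ge=0)  # lognormal CV


class NoiseConfig(_Strict):
    enabled: bool = False
    gain: float = 1.0
    read_sigma: float = 1.0
    background_level: float = 4.0

    def build(self) -> NoiseModel:
        if not self.enabled:
            return NoiseModel.none()
        return NoiseModel(enabled=True, gain=self.gain,
                          read_sigma=self.read_sigma)


class AnalysisConfig(_Strict):
    n_discard: int = Field(default=1, ge=0)
    working_fraction: float = Field(default=0.05, gt=0, lt=0.5)
    f_end_source: Literal["last_frame", "exponential_plateau"] = "last_frame"
    brightness_gate: float = Field(default=30.0, ge=0)
    decay_window: int = Field(default=10, ge=4)


class RunConfig(_Strict):
    units: Literal["nM"] = "nM"
    seed: int = 0
    sensor: SensorConfig = SensorConfig()
    protocol: ProtocolConfig = ProtocolConfig()
    trajectory: TrajectoryConfig = TrajectoryConfig()
    cells: CellsConfig = CellsConfig()
    noise: NoiseConfig = NoiseConfig()
    analysis: AnalysisConfig = AnalysisConfig()

    @field_validator("seed")
    @classmethod
    def _seed_range(cls, v: int) -> int:
        if v < 0:
            raise ValueError("seed must be >= 0")
        return v

    def expression_scales(self) -> list[float]:
        """Per-cell lognormal expression scales, drawn from a stream
        decoupled from the measurement-noise streams."""
        import numpy as np
        if self.cells.expression_cv == 0:
            return [self.cells.expression_mean] * self.cells.n_cells
        rng = np.random.default_rng(
            np.random.SeedSequence([self.seed, 0x5CA1E]))
        sigma = float(np.sqrt(np.log(1.0 + self.cells.expression_cv ** 2)))
        mu = float(np.log(self.cells.expression_mean)) - 0.5 * sigma ** 2
        return list(rng.lognormal(mu, sigma, self.cells.n_cells))


def load_config(path) -> RunConfig:
    text = Path(path).read_text()
    if str(path).endswith(".json"):
        payload = json.loads(text)
    else:
        payload = yaml.safe_load(text)
    return RunConfig.model_validate(payload or {})
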