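"""Free-Ca2+ concentration trajectories driving a simulation.

Trajectories are callables ``ca(t) -> nM``.  Three shapes cover the assay
conditions the pipeline is built around: constant buffers, the step ladder
of a titration where the bath concentration is exchanged at fixed
intervals, and stylized agonist-evoked oscillations (repeated transient
spikes on a resting baseline).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


class TrajectoryError(ValueError):
    pass


@dataclass(frozen=True)
class ConstantCa:
    """Constant free-Ca2+ concentration (nM)."""

    ca_nM: float

    def __post_init__(self) -> None:
        if self.ca_nM < 0:
            raise TrajectoryError("concentration must be >= 0")

    duration_s: float | None = None  # covers any schedule

    def __call__(self, t: float) -> float:
        return self.ca_nM


@dataclass(frozen=True)
class StepCa:
    """Piecewise-constant ladder: ``values[i]`` holds from ``times[i]`` to
    ``times[i+1]`` (the last value holds until ``end_s``)."""

    times_s: tuple[float, ...]
    values_nM: tuple[float, ...]
    end_s: float

    def __post_init__(self) -> None:
        if len(self.times_s) != len(self.values_nM) or not self.times_s:
            raise TrajectoryError("times and values must be equal, non-empty")
        if self.times_s[0] != 0.0:
            raise TrajectoryError(
                f"uncovered interval [0, {self.times_s[0]}): steps must start at 0")
        if any(t1 <= t0 for t0, t1 in zip(self.times_s, self.times_s[1:])):
            raise TrajectoryError("step times must be strictly increasing")
        if any(v < 0 for v in self.values_nM):
            raise TrajectoryError("concentrations must be >= 0")
        if self.end_s <= self.times_s[-1]:
            raise TrajectoryError("end_s must exceed the last step time")

    @property
    def duration_s(self) -> float:
        return self.end_s

    def __call__(self, t: float) -> float:
        if t < 0 or t > self.end_s:
            raise TrajectoryError(
                f"time {t} s outside the covered interval [0, {self.end_s}]")
        i = 0
        for j, t0 in enumerate(self.times_s):
            if t >= t0:
                i = j
        return self.values_nM[i]


@dataclass(frozen=True)
class OscillatingCa:
    """Repeated rectangular Ca2+ spikes on a baseline.

    One spike of width ``spike_width_s`` starts at ``t_first_s`` and every
    ``period_s`` thereafter; the spike amplitude above baseline decays by
    ``amplitude_decay`` per successive spike.  The defaults are stylized
    plausibility values for agonist-evoked oscillations, not measured ones.
    """

    baseline_nM: float = 60.0
    peak_nM: float = 1000.0
    period_s: float = 30.0
    spike_width_s: float = 6.0
    amplitude_decay: float = 0.85
    t_first_s: float = 10.0

    duration_s: float | None = None

    def __post_init__(self) -> None:
        if self.baseline_nM < 0 or self.peak_nM < self.baseline_nM:
            raise TrajectoryError("need 0 <= baseline <= peak")
        if self.period_s <= 0 or not (0 < self.spike_width_s < self.period_s):
            raise TrajectoryError("need 0 < spike_width < period")
        if not (0 < self.amplitude_decay <= 1):
            raise TrajectoryError("amplitude_decay must be in (0, 1]")

    def __call__(self, t: float) -> float:
        if t < self.t_first_s:
            return self.baseline_nM
        k = math.floor((t - self.t_first_s) / self.period_s)
        phase = t - self.t_first_s - k * self.period_s
        if phase < self.spike_width_s:
            amp = (self.peak_nM - self.baseline_nM) * self.amplitude_decay ** k
            return self.baseline_nM + amp
        return self.baseline_nM

    def peak_at_spike(self, k: int) -> float:
        """Ground-truth peak concentration of the k-th spike (0-based)."""
        return self.baseline_nM + (
            self.peak_nM - self.baseline_nM) * self.amplitude_decay ** k


def check_coverage(traj, total_duration_s: float) -> None:
    """Raise if the trajectory does not cover ``[0, total_duration_s]``."""
    dur = getattr(traj, "duration_s", None)
    if dur is not None and dur < total_duration_s:
        raise TrajectoryError(
            f"trajectory covers [0, {dur}] s but the schedule runs to "
            f"{total_duration_s} s: interval ({dur}, {total_duration_s}] uncovered")


def make_titration_ladder(n_points: int = 11, ca_max_nM: float = 39000.0,
                          egta_kd_nM: float = 150.0) -> list[float]:
    """Free-Ca2+ values of a reciprocal CaEGTA/EGTA dilution series.

    Mixing a zero-Ca buffer (EGTA) with a saturating buffer (CaEGTA) at
    fraction R gives free Ca = ``egta_kd * R / (1 - R)``.  The first point
    is exactly 0 (pure EGTA) and the last is pinned to the saturating
    buffer's nominal free Ca ``ca_max_nM``.  ``egta_kd_nM`` is the
    effective EGTA dissociation constant under the kit's buffer conditions
    (pH 7.2, 100 mM KCl); the 150 nM default is a packaged constant.
    """
    if n_points < 2:
        raise ValueError("n_points must be >= 2")
    out = [0.0]
    for i in range(1, n_points - 1):
        r = i / (n_points - 1)
        out.append(egta_kd_nM * r / (1.0 - r))
    out.append(ca_max_nM)
    if any(b <= a for a, b in zip(out, out[1:])):
        raise ValueError(
            "ladder not strictly increasing; ca_max too small for egta_kd")
    return out
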