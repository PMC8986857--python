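"""Forward simulation of photochromic biosensor fluorescence traces.

The simulator propagates, for each of the two occupancy subpopulations
(Ca2+-bound *sat* and Ca2+-free *apo*), the fraction ``n`` of molecules in
the spectroscopic on-state.  Within one illumination event the kinetics
are linear with constant coefficients, so each event is propagated
analytically::

    light:  n(t) = n_eq + (n0 - n_eq) * exp(-(k_on + k_off) * I * t)
    dark:   n(t) = 1 - (1 - n0) * exp(-t / tau_thermal)

with ``n_eq = k_on / (k_on + k_off)`` and ``I`` the event intensity.  The
dark equilibrium is the fully-on state reached by thermal recovery.  No
ODE solver is involved; the propagation is exact per event.

At a camera frame (recorded at the start of the exposure) the relative
fluorescence is the occupancy-weighted mixture of the two subpopulations::

    F = theta(Ca) * B_sat * (n_sat + r (1 - n_sat))
      + (1 - theta) * B_apo * (n_apo + r (1 - n_apo))

scaled per cell by its expression level and by ``fatigue^completed``
(multiplicative fluorophore loss per completed photochromism cycle), with
the post-cycle dip applied to the first intermittent frame after each
cycle, plus background and optional shot/read noise.  Ca2+ binding is
treated as fast relative to a frame, so only the weighting theta varies
with the trajectory while each subpopulation keeps its own photochromic
state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import NoiseModel, SensorParams, default_gcamp6s_q
from .schedule import IlluminationSchedule, ProtocolSpec, build_schedule
from .trajectory import ConstantCa, check_coverage


class SimulationError(ValueError):
    pass


@dataclass
class TraceSet:
    """Per-cell fluorescence traces aligned to an illumination schedule.

    ``frames`` is a long-format table with columns ``cell_id``, ``frame``,
    ``time_s``, ``cycle_id`` (nullable integer) and ``fluorescence``.
    ``background`` is the trace of an empty sample region, one value per
    frame; cell fluorescence values include this background until
    :func:`peaq.quantify.background_correct` removes it.
    """

    frames: pd.DataFrame
    background: np.ndarray
    expression_scales: dict[str, float]
    seed: int | None
    fingerprint: dict | None = None
    background_corrected: bool = False
    metadata: dict = field(default_factory=dict)

    @property
    def cell_ids(self) -> list[str]:
        return list(dict.fromkeys(self.frames["cell_id"]))

    @property
    def n_frames(self) -> int:
        return int(self.frames.groupby("cell_id").size().iloc[0])

    def cell(self, cell_id: str) -> pd.DataFrame:
        sub = self.frames[self.frames["cell_id"] == cell_id]
        return sub.sort_values("frame").reset_index(drop=True)

    def validate(self) -> None:
        required = {"cell_id", "frame", "time_s", "cycle_id", "fluorescence"}
        missing = required - set(self.frames.columns)
        if missing:
            raise SimulationError(f"trace table missing columns {sorted(missing)}")
        sizes = self.frames.groupby("cell_id").size()
        if sizes.nunique() > 1:
            raise SimulationError("ragged trace set: unequal frames per cell")
        if len(self.background) != sizes.iloc[0]:
            raise SimulationError("background length differs from trace length")
        for cid, sub in self.frames.groupby("cell_id"):
            t = sub.sort_values("frame")["time_s"].to_numpy()
            if np.any(np.diff(t) <= 0):
                raise SimulationError(f"cell {cid}: time not strictly increasing")


def _propagate_light(n: float, k_on: float, k_off: float, intensity: float,
                     dt: float) -> float:
    rate = (k_on + k_off) * intensity
    if rate <= 0.0:
        return n
    n_eq = k_on / (k_on + k_off)
    return n_eq + (n - n_eq) * np.exp(-rate * dt)


def _relative_fluorescence(theta: float, n_sat: float, n_apo: float,
                           p: SensorParams) -> float:
    r = p.residual_off_fraction
    f_sat = p.brightness_sat_on * (n_sat + r * (1.0 - n_sat))
    f_apo = p.brightness_apo_on * (n_apo + r * (1.0 - n_apo))
    return theta * f_sat + (1.0 - theta) * f_apo


def simulate_trace(params: SensorParams, schedule: IlluminationSchedule,
                   ca, cells=(1.0,), noise: NoiseModel | None = None,
                   seed: int = 0, background_level: float = 4.0) -> TraceSet:
    """Simulate a :class:`TraceSet` for one sensor under a schedule.

    Parameters
    ----------
    ca:
        Trajectory callable ``ca(t) -> nM`` (see :mod:`peaq.trajectory`).
    cells:
        Per-cell expression scale factors; cell ids are ``cell_000`` ...
    noise:
        Shot/read noise settings; ``None`` disables noise.
    seed:
        Master seed; per-cell streams are spawned deterministically from
        it, so identical inputs give bit-identical output.
    background_level:
        Mean background (counts) added to every cell frame and recorded as
        the background trace.
    """
    if noise is None:
        noise = NoiseModel.none()
    if len(schedule) == 0:
        raise SimulationError("empty schedule")
    if not len(cells):
        raise SimulationError("at least one cell required")
    check_coverage(ca, schedule.total_duration_s)

    first_cycle = schedule.cycle_ids[0] if schedule.cycle_ids else None
    dip_frames = set(schedule.post_cycle_frame_indices())

    n_sat = 1.0
    n_apo = 1.0
    completed = 0
    open_cycle: int | None = None
    t = 0.0
    times: list[float] = []
    cycle_col: list[int | None] = []
    base: list[float] = []

    frame = 0
    for ev in schedule.events:
        if ev.cycle_id is None and open_cycle is not None:
            completed += 1
            open_cycle = None
        elif ev.cycle_id is not None and open_cycle is not None \
                and ev.cycle_id != open_cycle:
            completed += 1
            open_cycle = ev.cycle_id
        elif ev.cycle_id is not None and open_cycle is None:
            open_cycle = ev.cycle_id

        if ev.camera_read:
            theta = params.occupancy(ca(t))
            f = _relative_fluorescence(theta, n_sat, n_apo, params)
            f *= params.fatigue_retention ** completed
            if frame in dip_frames:
                f *= params.post_cycle_dip_factor
            times.append(t)
            cycle_col.append(ev.cycle_id)
            base.append(f)
            frame += 1

        # propagate state through the event
        if ev.channel == "cyan":
            new_sat = _propagate_light(
                n_sat, params.k_cyan_on_sat, params.k_cyan_off_sat,
                ev.intensity_mW, ev.duration_s)
            new_apo = _propagate_light(
                n_apo, params.k_cyan_on_apo, params.k_cyan_off_apo,
                ev.intensity_mW, ev.duration_s)
        elif ev.channel == "violet":
            new_sat = _propagate_light(
                n_sat, params.k_violet_on_sat, 0.0,
                ev.intensity_mW, ev.duration_s)
            new_apo = _propagate_light(
                n_apo, 0.0, params.k_violet_off_apo,
                ev.intensity_mW, ev.duration_s)
        else:  # dark: thermal recovery toward the fully-on equilibrium
            new_sat = 1.0 - (1.0 - n_sat) * np.exp(
                -ev.duration_s / params.tau_thermal_sat)
            new_apo = 1.0 - (1.0 - n_apo) * np.exp(
                -ev.duration_s / params.tau_thermal_apo)

        if ev.cycle_id == first_cycle and first_cycle is not None \
                and ev.channel != "dark":
            # deviant first cycle: amplitude of every switching step scaled
            new_sat = n_sat + params.first_cycle_factor * (new_sat - n_sat)
            new_apo = n_apo + params.first_cycle_factor * (new_apo - n_apo)
        n_sat = float(np.clip(new_sat, 0.0, 1.0))
        n_apo = float(np.clip(new_apo, 0.0, 1.0))
        t += ev.duration_s
    if open_cycle is not None:
        completed += 1

    base_arr = np.asarray(base)
    times_arr = np.asarray(times)
    n = len(base_arr)

    streams = np.random.SeedSequence(seed).spawn(len(cells) + 1)
    bg_rng = np.random.default_rng(streams[-1])
    if noise.enabled:
        bg = bg_rng.poisson(background_level * noise.gain, n) / noise.gain \
            + bg_rng.normal(0.0, noise.read_sigma, n)
        bg = np.clip(bg, 0.0, None)
    else:
        bg = np.full(n, float(background_level))

    records = []
    scales: dict[str, float] = {}
    for i, scale in enumerate(cells):
        if scale <= 0:
            raise SimulationError("expression scales must be > 0")
        cid = f"cell_{i:03d}"
        scales[cid] = float(scale)
        signal = scale * base_arr
        if noise.enabled:
            rng = np.random.default_rng(streams[i])
            counts = rng.poisson(signal * noise.gain) / noise.gain \
                + rng.normal(0.0, noise.read_sigma, n)
            counts = np.clip(counts, 0.0, None)
        else:
            counts = signal
        records.append(pd.DataFrame({
            "cell_id": cid,
            "frame": np.arange(n),
            "time_s": times_arr,
            "cycle_id": pd.array(
                [c if c is not None else pd.NA for c in cycle_col],
                dtype="Int64"),
            "fluorescence": counts + bg,
        }))

    ts = TraceSet(
        frames=pd.concat(records, ignore_index=True),
        background=bg,
        expression_scales=scales,
        seed=seed,
        metadata={
            "background_level": background_level,
            "noise": {"enabled": noise.enabled, "gain": noise.gain,
                      "read_sigma": noise.read_sigma},
            "post_cycle_frames": sorted(dip_frames),
        },
    )
    ts.validate()
    return ts


def _cycle_f0_fend(trace: TraceSet, cell_id: str) -> list[tuple[int, float, float]]:
    """(cycle_id, F0, Fend) per cycle, first/last cyan frame convention."""
    sub = trace.cell(cell_id)
    out = []
    cyc = sub.dropna(subset=["cycle_id"])
    for cid, grp in cyc.groupby("cycle_id", sort=True):
        f = grp.sort_values("frame")["fluorescence"].to_numpy()
        out.append((int(cid), float(f[0]), float(f[-1])))
    return out


def simulate_fatigue_series(params: SensorParams | None = None,
                            n_cycles: int = 1000, ca_nM: float = 39000.0,
                            protocol: ProtocolSpec | None = None,
                            ) -> list[tuple[float, float]]:
    """Per-cycle ``(F0, contrast)`` over consecutive photochromism cycles.

    Runs ``n_cycles`` default cycles at a fixed Ca2+ concentration without
    noise or background, applying the per-cycle fatigue retention; used to
    study how fluorophore loss affects brightness versus the ratiometric
    contrast.
    """
    if params is None:
        params = default_gcamp6s_q()
    if n_cycles < 1:
        raise ValueError("n_cycles must be >= 1")
    if protocol is None:
        protocol = ProtocolSpec(n_cycles=n_cycles)
    else:
        protocol = ProtocolSpec(**{**protocol.__dict__, "n_cycles": n_cycles})
    schedule = build_schedule(protocol)
    trace = simulate_trace(params, schedule, ConstantCa(ca_nM),
                           noise=NoiseModel.none(), background_level=0.0)
    out = []
    for _, f0, fend in _cycle_f0_fend(trace, trace.cell_ids[0]):
        out.append((f0, (f0 - fend) / f0))
    return out
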