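"""Illumination schedules: ordered light/camera events of a measurement.

A schedule is a strictly time-ordered list of events.  Each event applies
one illumination channel (cyan, violet, or dark) for a positive duration
and may record a camera frame (``camera_read``).  Events belonging to a
photochromism cycle carry the integer ``cycle_id`` of that cycle;
intermittent (purely intensiometric) frames carry no cycle id.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Sequence

CHANNELS = ("cyan", "violet", "dark")


class ScheduleError(ValueError):
    """Raised when an illumination schedule violates its invariants."""


@dataclass(frozen=True)
class IlluminationEvent:
    channel: str
    intensity_mW: float
    duration_s: float
    camera_read: bool = False
    cycle_id: int | None = None


@dataclass(frozen=True)
class ProtocolSpec:
    """Compact description of a (i)PEAQ acquisition protocol.

    One photochromism cycle is a violet recovery pulse followed by
    ``n_off_frames`` cyan camera frames; the block is padded with darkness
    to ``period_s``.  With ``n_intermittent > 0``, every pair of
    consecutive cycles is separated by that many intensiometric
    acquisitions (violet pulse + one cyan frame, padded to
    ``intermittent_period_s``).
    """

    n_off_frames: int = 10
    exposure_s: float = 0.1
    violet_pulse_s: float = 0.1
    period_s: float = 2.0
    n_intermittent: int = 0
    intermittent_period_s: float = 2.0
    cyan_mW: float = 46.7
    violet_mW: float = 59.3
    n_cycles: int = 3

    def __post_init__(self) -> None:
        if self.n_off_frames < 2:
            raise ScheduleError("a cycle needs at least 2 cyan camera frames")
        if self.n_cycles < 1:
            raise ScheduleError("n_cycles must be >= 1")
        if self.n_intermittent < 0:
            raise ScheduleError("n_intermittent must be >= 0")
        for name in ("exposure_s", "violet_pulse_s", "period_s",
                     "intermittent_period_s"):
            if getattr(self, name) <= 0:
                raise ScheduleError(f"{name} must be > 0")
        if self.cyan_mW < 0 or self.violet_mW < 0:
            raise ScheduleError("light powers must be >= 0")
        if self.period_s < self.cycle_light_duration_s:
            raise ScheduleError("period_s shorter than the illuminated block")
        if self.intermittent_period_s < self.violet_pulse_s + self.exposure_s:
            raise ScheduleError(
                "intermittent_period_s shorter than the illuminated block")

    @property
    def cycle_light_duration_s(self) -> float:
        """Summed illumination of one photochromism acquisition block."""
        return self.violet_pulse_s + self.n_off_frames * self.exposure_s

    def fingerprint(self) -> dict:
        """Instrument-settings fingerprint used to match calibrations to
        experiments acquired with the same protocol."""
        return {
            "n_off_frames": self.n_off_frames,
            "exposure_s": self.exposure_s,
            "violet_pulse_s": self.violet_pulse_s,
            "cyan_mW": self.cyan_mW,
            "violet_mW": self.violet_mW,
        }


class IlluminationSchedule:
    """Validated, strictly time-ordered sequence of illumination events."""

    def __init__(self, events: Sequence[IlluminationEvent]):
        self.events = list(events)
        self._validate()
        t = 0.0
        self._start_times = []
        for ev in self.events:
            self._start_times.append(t)
            t += ev.duration_s
        self._total = t

    def _validate(self) -> None:
        if not self.events:
            raise ScheduleError("schedule is empty")
        seen_cycles: dict[int, list[int]] = {}
        for i, ev in enumerate(self.events):
            if ev.channel not in CHANNELS:
                raise ScheduleError(f"event {i}: unknown channel {ev.channel!r}")
            if ev.duration_s <= 0:
                raise ScheduleError(f"event {i}: duration must be > 0")
            if ev.intensity_mW < 0:
                raise ScheduleError(f"event {i}: negative intensity")
            if ev.camera_read and ev.channel == "dark":
                raise ScheduleError(f"event {i}: camera read during darkness")
            if ev.cycle_id is not None:
                seen_cycles.setdefault(ev.cycle_id, []).append(i)
        for cid, idx in seen_cycles.items():
            if idx[-1] - idx[0] + 1 != len(idx):
                raise ScheduleError(f"cycle {cid} is not contiguous")
            n_reads = sum(
                1 for i in idx
                if self.events[i].camera_read and self.events[i].channel == "cyan")
            if n_reads < 2:
                raise ScheduleError(
                    f"cycle {cid} has {n_reads} cyan camera frames; >=2 needed")

    # -- basic structure ---------------------------------------------------
    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self) -> Iterator[IlluminationEvent]:
        return iter(self.events)

    @property
    def total_duration_s(self) -> float:
        return self._total

    def start_time(self, event_index: int) -> float:
        return self._start_times[event_index]

    @property
    def camera_event_indices(self) -> list[int]:
        return [i for i, ev in enumerate(self.events) if ev.camera_read]

    @property
    def n_frames(self) -> int:
        return len(self.camera_event_indices)

    def frame_times(self) -> list[float]:
        """Timestamps of camera frames (start of each exposure)."""
        return [self._start_times[i] for i in self.camera_event_indices]

    def frame_cycle_ids(self) -> list[int | None]:
        return [self.events[i].cycle_id for i in self.camera_event_indices]

    @property
    def cycle_ids(self) -> list[int]:
        out: list[int] = []
        for ev in self.events:
            if ev.cycle_id is not None and ev.cycle_id not in out:
                out.append(ev.cycle_id)
        return out

    @property
    def n_cycles(self) -> int:
        return len(self.cycle_ids)

    def frames_per_cycle(self) -> dict[int, int]:
        out: dict[int, int] = {}
        for ev in self.events:
            if ev.camera_read and ev.cycle_id is not None:
                out[ev.cycle_id] = out.get(ev.cycle_id, 0) + 1
        return out

    def dose_mJ(self, channel: str) -> float:
        """Total light dose of a channel (mW * s = mJ)."""
        return sum(ev.intensity_mW * ev.duration_s
                   for ev in self.events if ev.channel == channel)

    def acquisition_cycle_duration_s(self) -> float:
        """Summed illumination/exposure of one photochromism acquisition
        block (violet recovery pulse + cyan off-switching frames)."""
        if not self.cycle_ids:
            raise ScheduleError("schedule defines no photochromism cycle")
        cid = self.cycle_ids[0]
        return sum(ev.duration_s for ev in self.events
                   if ev.cycle_id == cid and ev.channel != "dark")

    def post_cycle_frame_indices(self) -> list[int]:
        """Frame indices (within the camera-frame sequence) of the first
        intermittent frame following each completed photochromism cycle.

        These are the frames affected by the transient dark intermediate
        (the post-cycle dip) and the ones the repair step interpolates.
        """
        out = []
        prev_cycle: int | None = None
        frame = 0
        armed = False
        for ev in self.events:
            if ev.cycle_id is not None:
                prev_cycle = ev.cycle_id
                armed = True
            if ev.camera_read:
                if ev.cycle_id is None and armed and prev_cycle is not None:
                    out.append(frame)
                    armed = False
                frame += 1
        return out


def build_schedule(spec: ProtocolSpec) -> IlluminationSchedule:
    """Expand a :class:`ProtocolSpec` into an explicit event list.

    Cycles are numbered from 1.  Intermittent blocks, when requested, are
    inserted between consecutive cycles so the run is bracketed by
    photochromism cycles (calibration points) on both ends.
    """
    events: list[IlluminationEvent] = []
    dark_fill = spec.period_s - spec.cycle_light_duration_s
    dark_fill_i = spec.intermittent_period_s - spec.violet_pulse_s - spec.exposure_s
    for k in range(1, spec.n_cycles + 1):
        events.append(IlluminationEvent(
            "violet", spec.violet_mW, spec.violet_pulse_s, False, k))
        for _ in range(spec.n_off_frames):
            events.append(IlluminationEvent(
                "cyan", spec.cyan_mW, spec.exposure_s, True, k))
        if dark_fill > 0:
            events.append(IlluminationEvent("dark", 0.0, dark_fill, False, None))
        if k < spec.n_cycles:
            for _ in range(spec.n_intermittent):
                events.append(IlluminationEvent(
                    "violet", spec.violet_mW, spec.violet_pulse_s, False, None))
                events.append(IlluminationEvent(
                    "cyan", spec.cyan_mW, spec.exposure_s, True, None))
                if dark_fill_i > 0:
                    events.append(IlluminationEvent(
                        "dark", 0.0, dark_fill_i, False, None))
    return IlluminationSchedule(events)


def validate_schedule(schedule: IlluminationSchedule) -> dict:
    """Diagnostics of a schedule: cycle structure and per-channel doses.

    Invariant violations raise :class:`ScheduleError` at construction, so
    an existing schedule always validates; this reports its structure.
    """
    return {
        "n_events": len(schedule),
        "n_frames": schedule.n_frames,
        "n_cycles": schedule.n_cycles,
        "frames_per_cycle": schedule.frames_per_cycle(),
        "n_intermittent_frames": sum(
            1 for c in schedule.frame_cycle_ids() if c is None),
        "total_duration_s": schedule.total_duration_s,
        "dose_cyan_mJ": schedule.dose_mJ("cyan"),
        "dose_violet_mJ": schedule.dose_mJ("violet"),
    }
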