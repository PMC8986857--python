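"""Photophysical and biochemical parameters of a photochromic Ca2+ sensor.

The sensor is described by an effective four-state scheme: the protein is
either Ca2+-bound (*sat*) or Ca2+-free (*apo*), and in either occupancy it
can be in the spectroscopic on- (fluorescent) or off-state.  Cyan light
drives the on/off photoswitching that is read out as the photochromism
contrast, violet light recovers the on-state of the sat form (and, with the
reversed directionality of the apo form, can depopulate its on-state), and
in the dark both forms slowly relax back to the fully-on equilibrium.

All switching rate coefficients are expressed per unit light power
(1 / (s * mW)), so that the instantaneous first-order rate during an
illumination event is ``k * intensity_mW``.  This makes the equilibrium
plateau of the off-switching independent of intensity while the relaxation
time scales inversely with it, which is the property the whole
quantification strategy rests on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace as _dc_replace


@dataclass(frozen=True)
class SensorParams:
    """Ground-truth parameters of a photochromic biosensor.

    Parameters
    ----------
    kd_occupancy:
        Dissociation constant (nM) of the Ca2+ occupancy Hill curve.
    hill_h:
        Hill cooperativity coefficient (dimensionless).
    brightness_sat_on, brightness_apo_on:
        Fluorescence per unit probe of the on-state of the sat / apo form
        (arbitrary camera counts).
    residual_off_fraction:
        Relative brightness of the off-state, in [0, 1).
    k_cyan_off_sat, k_cyan_on_sat:
        Cyan-driven off- and on-switching rate coefficients of the sat
        form (1/(s*mW)).  Their ratio sets the off-switching plateau.
    k_cyan_off_apo, k_cyan_on_apo:
        Same for the apo form (directionality may be reversed).
    k_violet_on_sat:
        Violet-driven on-switching of the sat form (1/(s*mW)).
    k_violet_off_apo:
        Violet-driven off-switching of the apo form (1/(s*mW)).
    tau_thermal_sat, tau_thermal_apo:
        Thermal (dark) recovery time constants (s) back to the fully-on
        state.
    fatigue_retention:
        Multiplicative fluorophore survival per completed photochromism
        cycle, in (0, 1].
    first_cycle_factor:
        Multiplier applied to the per-event switching amplitude during the
        first photochromism cycle, modelling the systematically deviant
        first cycle.
    post_cycle_dip_factor:
        Multiplier in (0, 1] applied to the first intermittent camera frame
        recorded after a completed photochromism cycle, modelling the
        transient dark intermediate that has not fully relaxed by the next
        frame.
    """

    kd_occupancy: float
    hill_h: float
    brightness_sat_on: float
    brightness_apo_on: float
    residual_off_fraction: float = 0.0
    k_cyan_off_sat: float = 0.0
    k_cyan_on_sat: float = 0.0
    k_cyan_off_apo: float = 0.0
    k_cyan_on_apo: float = 0.0
    k_violet_on_sat: float = 0.0
    k_violet_off_apo: float = 0.0
    tau_thermal_sat: float = 300.0
    tau_thermal_apo: float = 600.0
    fatigue_retention: float = 1.0
    first_cycle_factor: float = 1.0
    post_cycle_dip_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kd_occupancy <= 0:
            raise ValueError("kd_occupancy must be > 0")
        if self.hill_h <= 0:
            raise ValueError("hill_h must be > 0")
        for name in (
            "brightness_sat_on",
            "brightness_apo_on",
            "k_cyan_off_sat",
            "k_cyan_on_sat",
            "k_cyan_off_apo",
            "k_cyan_on_apo",
            "k_violet_on_sat",
            "k_violet_off_apo",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not (0.0 <= self.residual_off_fraction < 1.0):
            raise ValueError("residual_off_fraction must be in [0, 1)")
        if not (0.0 < self.fatigue_retention <= 1.0):
            raise ValueError("fatigue_retention must be in (0, 1]")
        if not (0.0 < self.post_cycle_dip_factor <= 1.0):
            raise ValueError("post_cycle_dip_factor must be in (0, 1]")
        if self.tau_thermal_sat <= 0 or self.tau_thermal_apo <= 0:
            raise ValueError("thermal recovery time constants must be > 0")
        if self.first_cycle_factor <= 0:
            raise ValueError("first_cycle_factor must be > 0")

    def occupancy(self, ca_nM: float) -> float:
        """Hill occupancy theta(Ca) = Ca^h / (Kd^h + Ca^h)."""
        if ca_nM < 0:
            raise ValueError("Ca concentration must be >= 0")
        if ca_nM == 0.0:
            return 0.0
        r = (self.kd_occupancy / ca_nM) ** self.hill_h
        return 1.0 / (1.0 + r)

    def replace(self, **changes) -> "SensorParams":
        return _dc_replace(self, **changes)


@dataclass(frozen=True)
class NoiseModel:
    """Measurement noise: Poisson shot noise plus Gaussian read noise.

    ``gain`` is photons per camera count; counts are drawn as
    ``Poisson(signal * gain) / gain``.  ``read_sigma`` is the standard
    deviation (counts) of additive Gaussian read noise.  Resulting counts
    are clipped at zero.
    """

    enabled: bool = True
    gain: float = 1.0
    read_sigma: float = 1.0

    def __post_init__(self) -> None:
        if self.gain <= 0:
            raise ValueError("gain must be > 0")
        if self.read_sigma < 0:
            raise ValueError("read_sigma must be >= 0")

    @staticmethod
    def none() -> "NoiseModel":
        return NoiseModel(enabled=False, gain=1.0, read_sigma=0.0)


# ---------------------------------------------------------------------------
# Packaged default parameter set (photochromic GCaMP6s-Q under the default
# 10 x 100 ms cyan / 1 x 100 ms violet protocol at 46.7 / 59.3 mW).
# ---------------------------------------------------------------------------

# Instrument anchors of the default measurement protocol.
CYAN_POWER_MW = 46.7
VIOLET_POWER_MW = 59.3
N_OFF_FRAMES = 10
EXPOSURE_S = 0.1
VIOLET_PULSE_S = 0.1
CYCLE_PERIOD_S = 2.0

# Observable anchors the default rate coefficients are back-calculated from.
TAU_OFF_SAT_S = 0.18         # off-switching time constant, Ca-saturated
TAU_OFF_APO_S = 0.50         # off-switching time constant, Ca-free
CONTRAST_SAT = 0.86          # second-cycle (F0-Fend)/F0, Ca-saturated
CONTRAST_APO = 0.0071        # second-cycle (F0-Fend)/F0, Ca-free
KD_FLUORESCENCE_NM = 266.0   # Kd of the fluorescence (occupancy) titration
KD_CONTRAST_NM = 51.0        # apparent Kd of the contrast titration
HILL_H = 2.1
FATIGUE_HALVING_CYCLES = 1000  # F0 halves after this many cycles
FIRST_CYCLE_FACTOR = 1.15
POST_CYCLE_DIP_FACTOR = 0.95
TAU_THERMAL_SAT_S = 300.0
TAU_THERMAL_APO_S = 600.0
# Violet recovery is essentially complete within a single 100 ms pulse; the
# pulse-referenced on-switching time constant is a packaged choice.
VIOLET_TAU_S = 0.01
BRIGHTNESS_SAT = 100.0       # on-state sat brightness, camera counts / probe


def _cycle2_equilibrium(tau_s: float, contrast: float, tau_thermal_s: float,
                        violet_deficit_factor: float,
                        first_cycle_factor: float = FIRST_CYCLE_FACTOR,
                        n_frames: int = N_OFF_FRAMES,
                        exposure_s: float = EXPOSURE_S,
                        dark_s: float | None = None) -> tuple[float, float]:
    """On-state equilibrium fraction under cyan light that reproduces a
    given second-cycle contrast.

    The per-event analytic propagation used by the simulator makes the
    second-cycle trace a pure exponential between frame starts, so the
    measured contrast is ``(n0 - neq) * (1 - exp(-t_meas/tau)) / n0`` with
    ``t_meas = (n_frames - 1) * exposure``.  ``n0`` follows from
    propagating the dark-adapted state through cycle 1 (with the deviant
    first-cycle amplitude applied per event), the dark gap, and the violet
    pulse, all of which are linear in the deficit ``1 - n``.  Inverting
    that relation for the equilibrium fraction is closed-form.

    Returns ``(neq, n0_cycle2)``.
    """
    if dark_s is None:
        dark_s = CYCLE_PERIOD_S - VIOLET_PULSE_S - n_frames * exposure_s
    e = math.exp(-exposure_s / tau_s)
    # per-frame contraction of (n - neq) during cycle 1, amplitude-scaled
    g = (1.0 - first_cycle_factor * (1.0 - e)) ** n_frames
    d = math.exp(-dark_s / tau_thermal_s)
    k = (1.0 - g) * d * violet_deficit_factor
    e_meas = math.exp(-(n_frames - 1) * exposure_s / tau_s)
    neq = (1.0 - k) * ((1.0 - e_meas) - contrast) / (
        contrast * k + (1.0 - k) * (1.0 - e_meas))
    n0 = 1.0 - (1.0 - neq) * k
    return neq, n0


def default_gcamp6s_q() -> SensorParams:
    """Default parameter set for the photochromic GCaMP6s-Q sensor.

    The rate coefficients are back-calculated so that, under the default
    protocol (10 x 100 ms cyan frames at 46.7 mW, one 100 ms violet pulse
    at 59.3 mW, repeated every 2 s), the simulation reproduces the measured
    anchors: off-switching time constants of 0.18 s (sat) and 0.50 s (apo),
    second-cycle photochromism contrasts of 0.86 (sat) and 0.0071 (apo),
    and titration curves with Kd 266 nM / h 2.1 (fluorescence) and an
    apparent Kd of 51 nM (contrast).  The contrast-titration shift follows
    from brightness weighting of the two forms: the apparent contrast Kd
    equals ``kd_occupancy * (b/a)^(1/h)`` with ``b/a`` the observed
    apo-to-sat brightness ratio, so the apo brightness is chosen as
    ``(51/266)^2.1`` of the sat brightness (observed at the second-cycle
    read-out state of each form).

    Thermal recovery constants and the violet pulse time constant are
    packaged choices, not back-calculated observables.
    """
    v_sat = math.exp(-VIOLET_PULSE_S / VIOLET_TAU_S)
    neq_sat, n0_sat = _cycle2_equilibrium(
        TAU_OFF_SAT_S, CONTRAST_SAT, TAU_THERMAL_SAT_S, v_sat)
    # the default apo form is violet-inert: the violet pulse leaves its
    # deficit unchanged (factor 1)
    neq_apo, n0_apo = _cycle2_equilibrium(
        TAU_OFF_APO_S, CONTRAST_APO, TAU_THERMAL_APO_S, 1.0)

    rate_sat = 1.0 / (TAU_OFF_SAT_S * CYAN_POWER_MW)   # total per-mW rate
    rate_apo = 1.0 / (TAU_OFF_APO_S * CYAN_POWER_MW)
    beta = (KD_CONTRAST_NM / KD_FLUORESCENCE_NM) ** HILL_H

    return SensorParams(
        kd_occupancy=KD_FLUORESCENCE_NM,
        hill_h=HILL_H,
        brightness_sat_on=BRIGHTNESS_SAT,
        brightness_apo_on=BRIGHTNESS_SAT * beta * n0_sat / n0_apo,
        residual_off_fraction=0.0,
        k_cyan_on_sat=neq_sat * rate_sat,
        k_cyan_off_sat=(1.0 - neq_sat) * rate_sat,
        k_cyan_on_apo=neq_apo * rate_apo,
        k_cyan_off_apo=(1.0 - neq_apo) * rate_apo,
        k_violet_on_sat=1.0 / (VIOLET_TAU_S * VIOLET_POWER_MW),
        k_violet_off_apo=0.0,
        tau_thermal_sat=TAU_THERMAL_SAT_S,
        tau_thermal_apo=TAU_THERMAL_APO_S,
        fatigue_retention=0.5 ** (1.0 / FATIGUE_HALVING_CYCLES),
        first_cycle_factor=FIRST_CYCLE_FACTOR,
        post_cycle_dip_factor=POST_CYCLE_DIP_FACTOR,
    )
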