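"""Hill-model titration curves: fitting, evaluation, inversion.

Both read-outs of a photochromic sensor titration — the photochromism
contrast (dF/F0)hv and the plain fluorescence brightness — are described
by the same four-parameter Hill model

    f(Ca) = F_diff * [1 - Ca^h / (Kd^h + Ca^h)] + F_max

where ``F_max`` is the asymptote at saturating Ca2+, ``F_diff`` the
difference between the zero-Ca2+ value and that asymptote (negative for a
curve that increases with Ca2+), ``h`` the Hill coefficient and ``Kd`` the
dissociation constant.  A fitted curve can be normalized so its response
spans [0, 1] (the form used by intermittent quantification) and inverted
in closed form to map a measured response back to a concentration.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
from scipy.optimize import least_squares

FLAG_OK = "ok"
FLAG_BELOW = "below_range"
FLAG_ABOVE = "above_range"


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class HillFit:
    """Fitted Hill parameters for one titration read-out."""

    f_diff: float
    f_max: float
    kd: float
    h: float
    kind: str  # "contrast" or "fluorescence"
    stderr: dict | None = None
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.kd <= 0 or self.h <= 0:
            raise CalibrationError("kd and h must be > 0")
        if self.kind not in ("contrast", "fluorescence"):
            raise CalibrationError(f"unknown titration kind {self.kind!r}")

    @property
    def response_at_zero(self) -> float:
        return self.f_max + self.f_diff

    @property
    def response_at_sat(self) -> float:
        return self.f_max


def hill_model(ca, f_diff: float, f_max: float, kd: float, h: float):
    ca = np.asarray(ca, dtype=float)
    with np.errstate(divide="ignore", over="ignore"):
        occ = np.where(ca > 0, 1.0 / (1.0 + (kd / np.maximum(ca, 1e-300)) ** h),
                       0.0)
    return f_diff * (1.0 - occ) + f_max


def eval_hill(fit: HillFit, ca_nM: float):
    """Evaluate the fitted model at a concentration (nM, >= 0)."""
    ca = np.asarray(ca_nM, dtype=float)
    if np.any(ca < 0):
        raise CalibrationError("concentration must be >= 0")
    out = hill_model(ca, fit.f_diff, fit.f_max, fit.kd, fit.h)
    return float(out) if np.isscalar(ca_nM) else out


def fit_hill(conc_nM, response, kind: str) -> HillFit:
    """Least-squares Hill fit of a titration.

    Initialization is deterministic and scale-free: ``f_max`` from the
    response at the largest concentration, ``f_diff`` from the smallest,
    ``kd`` from the concentration closest to the half-range crossing and
    ``h = 2``.  Bounds keep ``h`` in [0.2, 10] and ``kd`` within a factor
    100 of the sampled nonzero concentrations.  Residuals are unweighted.
    Standard errors come from the local curvature (Gauss-Newton
    approximation) at the optimum.
    """
    conc = np.asarray(conc_nM, dtype=float)
    resp = np.asarray(response, dtype=float)
    if conc.shape != resp.shape or conc.ndim != 1:
        raise CalibrationError("conc and response must be 1-d and equal length")
    if np.any(conc < 0):
        raise CalibrationError("concentrations must be >= 0")
    if not np.all(np.isfinite(resp)):
        raise CalibrationError("responses must be finite")
    if len(np.unique(conc)) < 4:
        raise CalibrationError("insufficient points: >=4 distinct concentrations")
    if np.ptp(resp) == 0.0:
        raise CalibrationError("degenerate titration: response is constant")

    order = np.argsort(conc)
    c_s, r_s = conc[order], resp[order]
    f_max0 = r_s[-1]
    f_diff0 = r_s[0] - f_max0
    half = f_max0 + 0.5 * f_diff0
    nonzero = c_s[c_s > 0]
    kd0 = nonzero[np.argmin(np.abs(r_s[c_s > 0] - half))]
    lo_kd, hi_kd = nonzero.min() / 100.0, nonzero.max() * 100.0
    kd0 = min(max(kd0, lo_kd), hi_kd)

    def residuals(p):
        return hill_model(conc, p[0], p[1], p[2], p[3]) - resp

    scale = max(np.ptp(resp), 1e-12)
    sol = least_squares(
        residuals,
        x0=[f_diff0 if f_diff0 != 0 else -scale, f_max0, kd0, 2.0],
        bounds=([-np.inf, -np.inf, lo_kd, 0.2], [np.inf, np.inf, hi_kd, 10.0]),
        xtol=1e-14, ftol=1e-14, gtol=1e-14)
    if not sol.success:
        raise CalibrationError(
            f"Hill fit did not converge (last iterate {sol.x.tolist()})")

    dof = max(len(conc) - 4, 1)
    s2 = 2.0 * sol.cost / dof
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj) * s2
        se = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    except np.linalg.LinAlgError:
        se = np.full(4, np.nan)
    return HillFit(
        f_diff=float(sol.x[0]), f_max=float(sol.x[1]), kd=float(sol.x[2]),
        h=float(sol.x[3]), kind=kind,
        stderr={"f_diff": float(se[0]), "f_max": float(se[1]),
                "kd": float(se[2]), "h": float(se[3])},
        residual_norm=float(np.sqrt(2.0 * sol.cost)))


def invert_hill(fit: HillFit, response: float) -> tuple[float, str]:
    """Closed-form inverse: concentration whose model response equals
    ``response``.

    With occupancy ``H = 1 - (response - f_max) / f_diff`` the inverse is
    ``kd * (H / (1 - H))**(1/h)``.  Responses at or beyond the model's
    open response range are clipped to the boundary: ``H <= 0`` maps to
    concentration 0 (flag ``below_range``), ``H >= 1`` to ``inf`` (flag
    ``above_range``).
    """
    if fit.f_diff == 0.0:
        raise CalibrationError("flat calibration: f_diff is zero")
    occ = 1.0 - (response - fit.f_max) / fit.f_diff
    if occ <= 0.0:
        return 0.0, FLAG_BELOW
    if occ >= 1.0:
        return math.inf, FLAG_ABOVE
    return fit.kd * (occ / (1.0 - occ)) ** (1.0 / fit.h), FLAG_OK


@dataclass(frozen=True)
class CalibrationCurve:
    """A Hill fit plus its working-range policy and provenance.

    ``working_fraction`` is the fraction of the normalized response range
    considered unreliable at either extreme (default 0.05: the extreme 5%
    bands are out of the working range).  ``fingerprint`` records the
    instrument settings of the schedule the calibration was measured with;
    quantification refuses mismatched fingerprints unless overridden.
    """

    fit: HillFit
    normalized: bool = False
    working_fraction: float = 0.05
    fingerprint: dict | None = None

    def __post_init__(self) -> None:
        if not (0.0 < self.working_fraction < 0.5):
            raise CalibrationError("working_fraction must be in (0, 0.5)")

    @property
    def kind(self) -> str:
        return self.fit.kind

    def eval(self, ca_nM):
        return eval_hill(self.fit, ca_nM)

    def invert(self, response: float) -> tuple[float, str]:
        return invert_hill(self.fit, response)

    def working_range(self, fraction: float | None = None) -> tuple[float, float]:
        return working_range(self, fraction)

    def response_band(self, fraction: float | None = None) -> tuple[float, float]:
        """Response values at the working-range edges, ordered (lo, hi)
        along the response axis."""
        q = self.working_fraction if fraction is None else fraction
        lo0, hi0 = sorted((self.fit.response_at_zero, self.fit.response_at_sat))
        span = hi0 - lo0
        return lo0 + q * span, hi0 - q * span


def normalize_fit(fit: HillFit) -> CalibrationCurve:
    """Affinely rescale responses so the model range over [0, inf) is [0, 1].

    ``kd`` and ``h`` are unchanged; orientation is preserved, so an
    increasing titration normalizes to ``F_T(0) = 0, F_T(inf) = 1`` (for a
    fluorescence curve, ``F_T`` is then exactly the Hill occupancy).
    Normalizing an already-normalized fit is the identity.
    """
    if fit.f_diff == 0.0:
        raise CalibrationError("flat calibration: cannot normalize")
    span = abs(fit.f_diff)
    if fit.f_diff < 0:  # increasing in Ca
        new = _dc_replace(fit, f_diff=-1.0, f_max=1.0, stderr=None,
                          residual_norm=fit.residual_norm / span)
    else:
        new = _dc_replace(fit, f_diff=1.0, f_max=0.0, stderr=None,
                          residual_norm=fit.residual_norm / span)
    return CalibrationCurve(fit=new, normalized=True)


def working_range(curve: CalibrationCurve,
                  fraction: float | None = None) -> tuple[float, float]:
    """Concentrations at which the normalized response equals ``fraction``
    and ``1 - fraction`` (curve oriented to be increasing in Ca2+)::

        ca(q) = kd * (q / (1 - q))**(1/h)

    Returns ``(ca_lo, ca_hi)``.
    """
    q = curve.working_fraction if fraction is None else fraction
    if not (0.0 < q < 0.5):
        raise CalibrationError("fraction must be in (0, 0.5)")
    kd, h = curve.fit.kd, curve.fit.h
    lo = kd * (q / (1.0 - q)) ** (1.0 / h)
    hi = kd * ((1.0 - q) / q) ** (1.0 / h)
    return lo, hi


def ca_sensitivity(f_sat: float, f_apo: float) -> float:
    """Ca2+ sensitivity of a read-out: (f_sat - f_apo) / f_sat."""
    if f_sat == 0:
        raise CalibrationError("f_sat must be nonzero")
    return (f_sat - f_apo) / f_sat
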