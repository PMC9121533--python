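"""Closed-form ASL signal models.

Two labelling schemes are covered:

* **singleTI pCASL** — the consensus single-delay quantification

      CBF = 6000 * lam * dM * exp(PLD / T1b)
            / (2 * alpha * T1b * M0 * (1 - exp(-tau / T1b)))      [mL/100g/min]

  together with its exact algebraic inverse (the forward model used for
  simulation).

* **multiTI PASL** — the general kinetic model for a pulsed label: a box-car
  arterial input of temporal width ``tau`` (clipped by Q2TIPS saturation),
  delayed by the bolus arrival time ``bat``, decaying with T1 of blood during
  transit, and relaxing with the apparent tissue T1 after delivery:

      dM(t) = 0                                                 t < bat
      dM(t) = 2*M0b*f*alpha*(t-bat)*exp(-t/T1b)*q_p(t)          bat <= t < bat+tau
      dM(t) = 2*M0b*f*alpha*tau*exp(-t/T1b)*q_s(t)              t >= bat+tau

  with ``f = CBF/6000`` (mL/g/s), ``1/T1app = 1/T1_tissue + f/lam``,
  ``k = 1/T1b - 1/T1app`` and

      q_p(t) = exp(k*t) * (exp(-k*bat) - exp(-k*t)) / (k * (t - bat))
      q_s(t) = exp(k*t) * (exp(-k*bat) - exp(-k*(bat+tau))) / (k * tau)

  The ``k -> 0`` degeneracy (T1b == T1app) is handled by its analytic limit.
  ``pasl_kinetic_numeric`` evaluates the same delivery/residue/decay
  convolution by adaptive quadrature and serves as an independent oracle.

Voxel signals fitted in venous structures (sagittal sinus) use the same
arterial kinetic model; fitted values there are relative, since labelled water
in a draining vein has not necessarily exchanged with tissue.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate

from .errors import ValidationError

__all__ = [
    "PCASLParams",
    "PASLKineticParams",
    "pcasl_forward",
    "pcasl_quantify",
    "pasl_kinetic_signal",
    "pasl_kinetic_numeric",
    "bolus_width_from_q2tips",
]

#: unit conversion between CBF in mL/100g/min and f in mL/g/s
CBF_TO_F = 1.0 / 6000.0
#: below this |k| (s^-1) the kinetic model switches to its k->0 series limit
K_DEGENERATE = 1e-8


def _require_positive_finite(**kwargs) -> None:
    for name, value in kwargs.items():
        v = float(value)
        if not np.isfinite(v) or v <= 0:
            raise ValidationError(f"{name} must be positive and finite, got {value!r}")


@dataclass(frozen=True)
class PCASLParams:
    """Single-delay pCASL quantification constants.

    lam : blood-brain partition coefficient, mL/g.
    alpha : labelling efficiency (pCASL).
    tau : labelling duration, s.
    pld : post-labelling delay, s.
    t1_blood : subject-specific blood T1, s.
    """
    t1_blood: float
    lam: float = 0.9
    alpha: float = 0.85
    tau: float = 1.8
    pld: float = 1.5

    def __post_init__(self):
        _require_positive_finite(t1_blood=self.t1_blood, lam=self.lam,
                                 alpha=self.alpha, tau=self.tau, pld=self.pld)
        if self.alpha > 1:
            raise ValidationError(f"alpha must be <= 1, got {self.alpha}")


@dataclass(frozen=True)
class PASLKineticParams:
    """Pulsed-ASL general-kinetic-model constants.

    tau is the bolus temporal width defined by the Q2TIPS saturation pulses.
    t1_tissue applies after delivery; it is a single value for all voxels.
    """
    t1_blood: float
    lam: float = 0.9
    alpha: float = 0.98
    tau: float = 0.7
    t1_tissue: float = 1.9

    def __post_init__(self):
        _require_positive_finite(t1_blood=self.t1_blood, lam=self.lam,
                                 alpha=self.alpha, tau=self.tau,
                                 t1_tissue=self.t1_tissue)
        if self.alpha > 1:
            raise ValidationError(f"alpha must be <= 1, got {self.alpha}")


def bolus_width_from_q2tips(saturation_delay_ms: float = 700.0) -> float:
    """Bolus temporal width tau (s) from the Q2TIPS saturation timing.

    Q2TIPS/QUIPSS-II saturation pulses applied ``saturation_delay_ms`` after the
    labelling pulse clip the labelled bolus to exactly that temporal width.
    """
    _require_positive_finite(saturation_delay_ms=saturation_delay_ms)
    return saturation_delay_ms / 1000.0


# ---------------------------------------------------------------------------
# singleTI pCASL
# ---------------------------------------------------------------------------

def _pcasl_scale(p: PCASLParams) -> float:
    # dM = cbf * scale * m0; scale collects every constant of the consensus equation
    return (2.0 * p.alpha * p.t1_blood * -np.expm1(-p.tau / p.t1_blood)
            * np.exp(-p.pld / p.t1_blood)) / (6000.0 * p.lam)


def pcasl_forward(cbf, m0, p: PCASLParams):
    """Difference signal dM for a given CBF (exact inverse of `pcasl_quantify`).

    Vectorised over ``cbf`` and ``m0``; dM = 0 iff cbf = 0.
    """
    cbf = np.asarray(cbf, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    return cbf * m0 * _pcasl_scale(p)


def pcasl_quantify(delta_m, m0, p: PCASLParams, m0_floor: float = 1e-6):
    """CBF (mL/100g/min) from a mean difference image and an M0 image.

    Voxels with ``m0 <= m0_floor`` are flagged invalid (NaN output), not raised.
    Negative difference signal yields negative CBF; masking is downstream.
    """
    delta_m = np.asarray(delta_m, dtype=float)
    m0 = np.asarray(m0, dtype=float)
    if m0_floor <= 0:
        raise ValidationError(f"m0_floor must be positive, got {m0_floor!r}")
    with np.errstate(divide="ignore", invalid="ignore"):
        cbf = delta_m / (m0 * _pcasl_scale(p))
    return np.where(m0 > m0_floor, cbf, np.nan)


# ---------------------------------------------------------------------------
# multiTI PASL general kinetic model
# ---------------------------------------------------------------------------

def _phi(x):
    """(1 - exp(-x)) / x, with its limit 1 at x = 0; accurate for small |x|."""
    x = np.asarray(x, dtype=float)
    small = np.abs(x) < K_DEGENERATE
    safe = np.where(small, 1.0, x)
    out = np.where(small, 1.0 - x / 2.0 + x * x / 6.0, -np.expm1(-safe) / safe)
    return out


def _gkm_curve(t: np.ndarray, cbf, bat, m0_blood, p: PASLKineticParams):
    """Unvalidated kinetic-curve kernel shared by the public model and the fitter."""
    f = np.asarray(cbf, dtype=float) * CBF_TO_F
    inv_t1app = 1.0 / p.t1_tissue + f / p.lam
    k = 1.0 / p.t1_blood - inv_t1app
    dur = t - bat
    delivered = np.clip(dur, 0.0, p.tau)
    out = (2.0 * m0_blood * f * p.alpha
           * np.exp(-t * inv_t1app - k * bat)
           * delivered * _phi(k * delivered))
    return np.where(dur > 0.0, out, 0.0)


def pasl_kinetic_signal(t, cbf, bat, m0_blood, p: PASLKineticParams):
    """General-kinetic-model difference signal dM(t) for a pulsed label.

    Parameters are broadcast together; ``t`` and ``bat`` in seconds, ``cbf`` in
    mL/100g/min, ``m0_blood`` the equilibrium magnetisation of arterial blood.
    Continuous in ``t`` at both regime boundaries.
    """
    t = np.asarray(t, dtype=float)
    cbf = np.asarray(cbf, dtype=float)
    bat = np.asarray(bat, dtype=float)
    m0_blood = np.asarray(m0_blood, dtype=float)
    if np.any(~np.isfinite(t)) or np.any(t < 0) or np.any(bat < 0) or np.any(cbf < 0):
        raise ValidationError("t, bat and cbf must be finite and non-negative")
    # dM = 2*M0b*f*alpha * exp(-t/T1app) * exp(-k*bat) * delivered * phi(k*delivered)
    # where 'delivered' = clip(t - bat, 0, tau): the integral of exp(-k*s) over
    # the delivered part of the bolus written via phi(), so the k -> 0 case
    # degrades smoothly to its analytic limit.
    return _gkm_curve(t, cbf, bat, m0_blood, p)


def pasl_kinetic_numeric(t: float, cbf: float, bat: float, m0_blood: float,
                         p: PASLKineticParams, tol: float = 1e-10) -> float:
    """dM(t) by adaptive quadrature of the delivery-residue-decay convolution.

    Independent numerical oracle for `pasl_kinetic_signal`:
    ``dM(t) = 2*M0b * ∫_0^t f * c(s) * r(t-s) * m(t-s) ds`` with box-car input
    ``c(s) = alpha*exp(-s/T1b)`` on [bat, bat+tau), residue ``r(u)=exp(-f*u/lam)``
    and decay ``m(u)=exp(-u/T1_tissue)``.
    """
    f = cbf * CBF_TO_F
    lo, hi = bat, min(t, bat + p.tau)
    if hi <= lo or f == 0.0:
        return 0.0

    def integrand(s):
        u = t - s
        return (p.alpha * np.exp(-s / p.t1_blood)
                * np.exp(-f * u / p.lam) * np.exp(-u / p.t1_tissue))

    val, err = integrate.quad(integrand, lo, hi, epsabs=0.0, epsrel=tol, limit=200)
    if not np.isfinite(val) or (val != 0 and err > 1e-6 * abs(val)):
        raise ArithmeticError(
            f"quadrature did not converge (value={val!r}, err={err!r})")
    return 2.0 * m0_blood * f * val
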