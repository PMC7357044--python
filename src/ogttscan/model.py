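"""Core kinetic model of the oral glucose tolerance test (OGTT).

The model extends Bergman's three-variable minimal model (MINMOD) of
glucose disappearance to the oral setting by

* adding a glucose rate-of-appearance forcing term ``GRA(t)`` — a
  truncated Gaussian flux of ingested glucose into the circulation,
  normalised so the whole dose ends up in the blood volume;
* adding a fourth state ``Is``, the readily-releasable pool (RRP) of
  insulin pre-docked in the beta cells, released with first-order rate
  ``p4`` to capture the fast first phase of secretion;
* scaling the insulin-dependent glucose withdrawal term by ``rCd``, an
  efficiency multiplier (``rCd < 1`` means insulin resistance) that is
  fixed at 1 for reference (control) animals.

States: ``G`` plasma glucose (mg/dL), ``X`` insulin-driven glucose
withdrawal rate (1/min), ``I`` plasma insulin (nU/dL), ``Is`` stored
insulin (nU/dL).  The full system is

    dG/dt  = -p1 (G - Gb) - rCd X G + GRA(t)
    dX/dt  = -p2 X + p3 (I - Ib)
    dI/dt  = -n I + gamma (G - h) t + p4 Is
    dIs/dt = -p4 Is

The ``gamma (G - h) t`` slow-phase secretion term is used exactly as
written, i.e. *without* clamping ``G - h`` at zero (classical minimal-model
formulations clamp it; see :func:`rhs_extended` for an optional clamp).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import NamedTuple

import numpy as np
from scipy.stats import norm

__all__ = [
    "ModelParameters",
    "InitialState",
    "PhysiologyRecord",
    "StateVector",
    "compute_K",
    "gra",
    "rhs_extended",
    "rhs_minmod",
    "PARAMETER_NAMES",
    "RATE_PARAMETERS",
]

#: The ten kinetic parameters, in conventional order.
PARAMETER_NAMES = ("p1", "Gb", "p2", "p3", "Ib", "n", "gamma", "h", "p4", "rCd")

#: First-order / gain parameters that must be nonnegative.
RATE_PARAMETERS = ("p1", "p2", "p3", "n", "gamma", "p4")

_SQRT_2PI = math.sqrt(2.0 * math.pi)


@dataclass(frozen=True)
class ModelParameters:
    """The ten kinetic parameters of the extended minimal model.

    Units: ``p1, p2, n, p4`` 1/min; ``p3`` (dL/nU)/min^2; ``gamma``
    (nU/dL)/min^2; ``Gb, h`` mg/dL; ``Ib`` nU/dL; ``rCd`` dimensionless.
    """

    p1: float
    Gb: float
    p2: float
    p3: float
    Ib: float
    n: float
    gamma: float
    h: float
    p4: float
    rCd: float = 1.0

    def __post_init__(self) -> None:
        for name in RATE_PARAMETERS:
            v = getattr(self, name)
            if not (np.isfinite(v) and v >= 0):
                raise ValueError(f"rate parameter {name} must be >= 0, got {v!r}")
        for name in ("Gb", "Ib", "h"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValueError(f"{name} must be > 0, got {v!r}")
        if not (np.isfinite(self.rCd) and self.rCd > 0):
            raise ValueError(f"rCd must be > 0, got {self.rCd!r}")

    def replace(self, **changes: float) -> "ModelParameters":
        """Return a copy with the given parameters replaced."""
        return replace(self, **changes)

    def as_dict(self) -> dict[str, float]:
        return {name: float(getattr(self, name)) for name in PARAMETER_NAMES}


@dataclass(frozen=True)
class InitialState:
    """State of the system at the moment of glucose gavage (t = 0).

    ``X0`` is fixed at zero by convention: the insulin-driven withdrawal
    machinery is assumed unengaged after the overnight fast.
    """

    G0: float
    I0: float
    Is0: float
    X0: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.G0) and self.G0 > 0):
            raise ValueError(f"G0 must be > 0, got {self.G0!r}")
        if not (np.isfinite(self.I0) and self.I0 >= 0):
            raise ValueError(f"I0 must be >= 0, got {self.I0!r}")
        if not (np.isfinite(self.Is0) and self.Is0 >= 0):
            raise ValueError(f"Is0 must be >= 0, got {self.Is0!r}")
        if self.X0 != 0.0:
            raise ValueError("X0 is fixed at 0 (post-fast convention)")

    def as_array(self) -> np.ndarray:
        return np.array([self.G0, self.X0, self.I0, self.Is0], dtype=float)

    def as_dict(self) -> dict[str, float]:
        return {
            "G0": float(self.G0),
            "X0": float(self.X0),
            "I0": float(self.I0),
            "Is0": float(self.Is0),
        }


def compute_K(
    body_mass_g: float,
    blood_volume_dl: float,
    dose_mg_per_g: float,
    mu_min: float,
    sigma_min: float,
) -> float:
    """Scale of the glucose rate-of-appearance curve, mg/(dL·min).

    ``K`` is fixed by mass balance: the ingested dose (mg glucose per g
    body mass, times body mass), expressed as a concentration over the
    blood volume, must equal the integral of ``GRA`` over [0, inf).  With
    a Gaussian kernel centred at ``mu`` with spread ``sigma`` that gives
    the closed form

        K = (m_glc / V_blood) / Phi(mu / sigma)

    where ``Phi`` is the standard normal CDF — the denominator corrects
    for the Gaussian mass that would fall before t = 0.
    """
    if sigma_min <= 0:
        raise ValueError(f"sigma must be > 0, got {sigma_min!r}")
    if blood_volume_dl <= 0:
        raise ValueError(f"blood volume must be > 0, got {blood_volume_dl!r}")
    if body_mass_g <= 0 or dose_mg_per_g <= 0:
        raise ValueError("body mass and dose must be > 0")
    concentration = body_mass_g * dose_mg_per_g / blood_volume_dl
    return float(concentration / norm.cdf(mu_min / sigma_min))


@dataclass(frozen=True)
class PhysiologyRecord:
    """Animal physiology and the derived dose-normalisation scale ``K``.

    ``K`` is computed from the other fields at construction
    (:func:`compute_K`); it is not an independent input.
    """

    body_mass_g: float
    blood_volume_dl: float
    dose_mg_per_g: float
    mu_min: float = 30.0
    sigma_min: float = 35.0
    K: float = field(init=False)

    def __post_init__(self) -> None:
        if self.mu_min < 0:
            raise ValueError(f"mu must be >= 0, got {self.mu_min!r}")
        object.__setattr__(
            self,
            "K",
            compute_K(
                self.body_mass_g,
                self.blood_volume_dl,
                self.dose_mg_per_g,
                self.mu_min,
                self.sigma_min,
            ),
        )

    @property
    def K_rounded(self) -> int:
        """``K`` rounded to the nearest integer, for table comparison."""
        return round(self.K)

    def as_dict(self) -> dict[str, float]:
        return {
            "body_mass_g": float(self.body_mass_g),
            "blood_volume_dl": float(self.blood_volume_dl),
            "dose_mg_per_g": float(self.dose_mg_per_g),
            "mu_min": float(self.mu_min),
            "sigma_min": float(self.sigma_min),
        }


class StateVector(NamedTuple):
    """One instantaneous value of the four model states."""

    G: float
    X: float
    I: float
    Is: float


def gra(t, phys: PhysiologyRecord):
    """Glucose rate of appearance in plasma, mg/(dL·min), at time ``t`` min.

    ``K`` times a Gaussian density centred at ``phys.mu_min``; strictly
    positive, maximal at t = mu.  Defined on t >= 0 only.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("GRA is defined on t >= 0 (t = 0 is the gavage)")
    sigma = phys.sigma_min
    z = (t_arr - phys.mu_min) / sigma
    out = phys.K / (sigma * _SQRT_2PI) * np.exp(-0.5 * z * z)
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def rhs_extended(
    t: float,
    s,
    k: ModelParameters,
    phys: PhysiologyRecord,
    clamp_threshold: bool = False,
) -> np.ndarray:
    """Right-hand side of the extended 4-state model at time ``t``.

    ``s`` is (G, X, I, Is).  ``phys=None`` disables the appearance
    forcing (GRA identically zero) — the closed-loop system used by the
    reduction check.  ``clamp_threshold=True`` replaces the slow-phase
    drive ``gamma (G - h) t`` by ``gamma max(G - h, 0) t`` (the
    classical minimal-model convention); default is the unclamped form.
    """
    G, X, I, Is = s
    drive = G - k.h
    if clamp_threshold and drive < 0:
        drive = 0.0
    appearance = 0.0 if phys is None else gra(t, phys)
    return np.array(
        [
            -k.p1 * (G - k.Gb) - k.rCd * X * G + appearance,
            -k.p2 * X + k.p3 * (I - k.Ib),
            -k.n * I + k.gamma * drive * t + k.p4 * Is,
            -k.p4 * Is,
        ]
    )


def rhs_minmod(t: float, s, k: ModelParameters) -> np.ndarray:
    """Right-hand side of the original three-variable minimal model.

    ``s`` is (G, X, I).  Kept as the reduction reference: the extended
    model with K = 0, rCd = 1, p4 = 0, Is = 0 restricts to this system.
    """
    G, X, I = s
    return np.array(
        [
            -k.p1 * (G - k.Gb) - X * G,
            -k.p2 * X + k.p3 * (I - k.Ib),
            -k.n * I + k.gamma * (G - k.h) * t,
        ]
    )


def make_rhs(k: ModelParameters, phys, clamp_threshold: bool = False):
    """Build a fast closure over plain floats for the ODE integrator.

    ``phys=None`` yields the closed-loop system (no glucose input).
    """
    p1, Gb, p2, p3, Ib = k.p1, k.Gb, k.p2, k.p3, k.Ib
    n, gamma_, h, p4, rCd = k.n, k.gamma, k.h, k.p4, k.rCd
    if phys is None:
        mu, amp, inv2s2 = 0.0, 0.0, 1.0
    else:
        mu, sigma = phys.mu_min, phys.sigma_min
        amp = phys.K / (sigma * _SQRT_2PI)
        inv2s2 = 0.5 / (sigma * sigma)
    exp = math.exp

    if clamp_threshold:

        def rhs(t, s):
            G, X, I, Is = s
            dt_mu = t - mu
            drive = G - h
            if drive < 0.0:
                drive = 0.0
            return (
                -p1 * (G - Gb) - rCd * X * G + amp * exp(-dt_mu * dt_mu * inv2s2),
                -p2 * X + p3 * (I - Ib),
                -n * I + gamma_ * drive * t + p4 * Is,
                -p4 * Is,
            )

    else:

        def rhs(t, s):
            G, X, I, Is = s
            dt_mu = t - mu
            return (
                -p1 * (G - Gb) - rCd * X * G + amp * exp(-dt_mu * dt_mu * inv2s2),
                -p2 * X + p3 * (I - Ib),
                -n * I + gamma_ * (G - h) * t + p4 * Is,
                -p4 * Is,
            )

    return rhs
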