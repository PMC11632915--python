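"""Closed-form evaluation of the empirical carbon-ion RBE model.

The model predicts a cell line's carbon-ion linear-quadratic (LQ) survival
curve ``SF(D) = exp(-alpha*D - beta*D^2)`` from three inputs: the photon
reference LQ parameters (``alpha_x``, ``beta_x``) and the carbon-ion
dose-weighted LET (``LET_d``, keV/um).  It does so in endpoint space: the
photon doses at the ``e^-3`` (~5%) and ``e^-1`` (~37%) survival levels are
mapped to their carbon-ion counterparts by LET-dependent slope/intercept
trends, and the two predicted endpoints are converted back to an LQ curve in
closed form, with non-negativity constraints on alpha and beta.

Units are fixed throughout: dose in Gy, LET_d in keV/um.  There is no unit
conversion layer.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "LQMParams",
    "RadiosensitivityEndpoint",
    "ModelParameters",
    "PredictionResult",
    "BRANCH_UNCONSTRAINED",
    "BRANCH_BETA_ZEROED",
    "BRANCH_ALPHA_ZEROED",
    "survival_fraction",
    "dose_at_survival",
    "slope_inverse_linear",
    "slope_inverse_linear_squared",
    "intercept_quadratic",
    "predict_endpoints",
    "alpha_beta_from_endpoints",
    "lqm_from_endpoint_set",
    "predict_cion_lqm",
    "rbe_at_survival",
    "rbe_at_dose",
    "poisson_lethal_lesion_mean",
]

# Constraint-branch labels for the endpoint -> LQ conversion.
BRANCH_UNCONSTRAINED = "unconstrained"
BRANCH_BETA_ZEROED = "beta_zeroed"
BRANCH_ALPHA_ZEROED = "alpha_zeroed"

# Parameter ordering used everywhere a (f1, m1, q1, f2) vector or its 4x4
# covariance appears.
PARAM_NAMES = ("f1", "m1", "q1", "f2")

_PARAM_RESOURCE = "published_parameters.json"


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LQMParams:
    """A linear-quadratic survival curve for one radiation quality.

    Attributes
    ----------
    alpha : float
        Linear coefficient [1/Gy]; must be >= 0.
    beta : float
        Quadratic coefficient [1/Gy^2]; must be >= 0.

    alpha and beta may not both be zero (the curve would be flat at SF = 1).
    """

    alpha: float
    beta: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.alpha) and math.isfinite(self.beta)):
            raise ValueError("LQ parameters must be finite")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError(
                f"LQ parameters must be non-negative, got alpha={self.alpha}, "
                f"beta={self.beta}"
            )
        if self.alpha == 0 and self.beta == 0:
            raise ValueError("degenerate LQ curve: alpha and beta both zero")


@dataclass(frozen=True)
class RadiosensitivityEndpoint:
    """A (survival fraction, dose) pair: the dose achieving that SF."""

    survival_fraction: float
    dose: float

    def __post_init__(self) -> None:
        if not 0.0 < self.survival_fraction < 1.0:
            raise ValueError(
                f"survival_fraction must lie in (0, 1), got {self.survival_fraction}"
            )
        if self.dose <= 0:
            raise ValueError(f"endpoint dose must be positive, got {self.dose}")


@dataclass(frozen=True)
class ModelParameters:
    """The four fitted model constants and their 4x4 covariance.

    ``f1`` [(keV/um)^-1] and ``q1`` [(keV/um)^-2], ``m1`` [Gy] parameterize
    the LET trend of the ``e^-3`` endpoint; ``f2`` [(keV/um)^-1] that of the
    ``e^-1`` endpoint.  The covariance is ordered (f1, m1, q1, f2); its
    diagonal holds the squared per-parameter uncertainties.
    """

    f1: float
    m1: float
    q1: float
    f2: float
    covariance: np.ndarray = field(
        default_factory=lambda: np.zeros((4, 4))
    )

    def __post_init__(self) -> None:
        if self.f1 <= 0 or self.f2 <= 0:
            raise ValueError("f1 and f2 must be positive")
        if self.m1 < 0 or self.q1 < 0:
            raise ValueError("m1 and q1 must be non-negative")
        cov = np.asarray(self.covariance, dtype=float)
        if cov.shape != (4, 4):
            raise ValueError(f"covariance must be 4x4, got shape {cov.shape}")
        if not np.allclose(cov, cov.T, rtol=0, atol=1e-12 * max(1.0, np.abs(cov).max())):
            raise ValueError("covariance must be symmetric")
        if np.any(np.diag(cov) < 0):
            raise ValueError("covariance diagonal must be non-negative")
        object.__setattr__(self, "covariance", cov)

    @property
    def theta(self) -> np.ndarray:
        """Parameter vector in the canonical (f1, m1, q1, f2) order."""
        return np.array([self.f1, self.m1, self.q1, self.f2])

    @property
    def uncertainties(self) -> np.ndarray:
        """Per-parameter standard uncertainties (sqrt of covariance diagonal)."""
        return np.sqrt(np.diag(self.covariance))

    @classmethod
    def from_theta(cls, theta: Sequence[float], covariance=None) -> "ModelParameters":
        f1, m1, q1, f2 = (float(v) for v in theta)
        cov = np.zeros((4, 4)) if covariance is None else covariance
        return cls(f1=f1, m1=m1, q1=q1, f2=f2, covariance=cov)

    @classmethod
    def published(cls) -> "ModelParameters":
        """The packaged published parameter set (full printed precision)."""
        raw = json.loads(
            resources.files("cirbe.data").joinpath(_PARAM_RESOURCE).read_text()
        )
        p = raw["parameters"]
        unc = raw["uncertainties"]
        cov = np.zeros((4, 4))
        idx = {name: i for i, name in enumerate(PARAM_NAMES)}
        for name in PARAM_NAMES:
            cov[idx[name], idx[name]] = unc[name] ** 2
        for key, val in raw["covariances"].items():
            a, b = key.split(",")
            cov[idx[a], idx[b]] = cov[idx[b], idx[a]] = val
        return cls(f1=p["f1"], m1=p["m1"], q1=p["q1"], f2=p["f2"], covariance=cov)

    def to_dict(self) -> dict:
        return {
            "parameters": dict(zip(PARAM_NAMES, (self.f1, self.m1, self.q1, self.f2))),
            "covariance": self.covariance.tolist(),
            "covariance_order": list(PARAM_NAMES),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParameters":
        p = d["parameters"]
        return cls(
            f1=p["f1"],
            m1=p["m1"],
            q1=p["q1"],
            f2=p["f2"],
            covariance=np.asarray(d.get("covariance", np.zeros((4, 4)))),
        )


@dataclass(frozen=True)
class PredictionResult:
    """Predicted carbon-ion LQ curve plus its endpoint intermediates.

    ``d_e3`` / ``d_e1`` are the predicted C-ion doses at the e^-3 and e^-1
    survival levels; ``branch`` records which arm of the non-negativity
    constraint produced the LQ parameters.
    """

    lqm_cion: LQMParams
    d_e3: float
    d_e1: float
    branch: str
    let_d: float


# ---------------------------------------------------------------------------
# LQ curve algebra
# ---------------------------------------------------------------------------


def survival_fraction(lqm: LQMParams, dose: float):
    """Surviving fraction ``exp(-alpha*D - beta*D^2)`` at dose ``D`` [Gy]."""
    dose = np.asarray(dose, dtype=float)
    if np.any(dose < 0):
        raise ValueError("dose must be non-negative")
    out = np.exp(-lqm.alpha * dose - lqm.beta * dose**2)
    return float(out) if out.ndim == 0 else out


def dose_at_survival(lqm: LQMParams, sf: float):
    """Dose [Gy] at which the curve reaches surviving fraction ``sf``.

    Solves ``beta*D^2 + alpha*D + ln(sf) = 0`` for its unique positive root
    using the cancellation-free form ``D = 2L / (alpha + sqrt(alpha^2 +
    4*beta*L))`` with ``L = -ln(sf)``, which reduces exactly to ``L/alpha``
    at beta = 0 and ``sqrt(L/beta)`` at alpha = 0.
    """
    sf_arr = np.asarray(sf, dtype=float)
    if np.any((sf_arr <= 0) | (sf_arr >= 1)):
        raise ValueError("survival fraction must lie in (0, 1)")
    lethality = -np.log(sf_arr)
    root = 2.0 * lethality / (lqm.alpha + np.sqrt(lqm.alpha**2 + 4.0 * lqm.beta * lethality))
    return float(root) if root.ndim == 0 else root


# ---------------------------------------------------------------------------
# LET trend families (slope and intercept of the photon/C-ion correlation)
# ---------------------------------------------------------------------------


def slope_inverse_linear(let_d, f: float):
    """Slope trend ``(1 + f*LET_d)^-1``; equals 1 at LET_d = 0."""
    let_d = np.asarray(let_d, dtype=float)
    if np.any(let_d < 0):
        raise ValueError("let_d must be non-negative")
    denom = 1.0 + f * let_d
    if np.any(denom <= 0):
        raise ValueError("1 + f*let_d must be positive")
    out = 1.0 / denom
    return float(out) if out.ndim == 0 else out


def slope_inverse_linear_squared(let_d, f: float):
    """Slope trend ``(1 + f*LET_d)^-2``; equals 1 at LET_d = 0."""
    s = slope_inverse_linear(let_d, f)
    return s * s


def intercept_quadratic(let_d, q: float, m: float):
    """Intercept trend ``q*LET_d^2 + m`` [Gy]."""
    let_d = np.asarray(let_d, dtype=float)
    if np.any(let_d < 0):
        raise ValueError("let_d must be non-negative")
    out = q * let_d**2 + m
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Endpoint prediction and endpoint -> LQ conversion
# ---------------------------------------------------------------------------


def predict_endpoints(d_e3_x: float, d_e1_x: float, let_d: float, params: ModelParameters):
    """Map photon endpoints to predicted carbon-ion endpoints at ``let_d``.

    ``D_e3,C = D_e3,X * (1 + f1*LET)^-1 + q1*LET^2 + m1`` and
    ``D_e1,C = D_e1,X * (1 + f2*LET)^-1``.
    """
    d3 = np.asarray(d_e3_x, dtype=float)
    d1 = np.asarray(d_e1_x, dtype=float)
    if np.any(d3 <= 0) or np.any(d1 <= 0):
        raise ValueError("photon endpoints must be positive")
    d_e3_c = d3 * slope_inverse_linear(let_d, params.f1) + intercept_quadratic(
        let_d, params.q1, params.m1
    )
    d_e1_c = d1 * slope_inverse_linear(let_d, params.f2)
    if np.ndim(d_e3_c) == 0:
        return float(d_e3_c), float(d_e1_c)
    return d_e3_c, d_e1_c


def _raw_alpha_beta(d_e3, d_e1):
    """Exact two-endpoint interpolant (may be negative); vector-safe."""
    denom = d_e1 * d_e3**2 - d_e3 * d_e1**2
    alpha = (d_e3**2 - 3.0 * d_e1**2) / denom
    beta = (3.0 * d_e1 - d_e3) / denom
    return alpha, beta


def _alpha_beta_zeroed(d_e3, d_e1):
    """Single-parameter least-squares fall-backs for the constrained arms."""
    alpha_b0 = (3.0 * d_e3 + d_e1) / (d_e3**2 + d_e1**2)
    beta_a0 = (3.0 * d_e3**2 + d_e1**2) / (d_e3**4 + d_e1**4)
    return alpha_b0, beta_a0


def alpha_beta_from_endpoints(d_e3: float, d_e1: float) -> tuple[LQMParams, str]:
    """Convert the (D_e3, D_e1) endpoint pair to a non-negative LQ curve.

    The unconstrained interpolant passes exactly through (D_e3, e^-3) and
    (D_e1, e^-1).  If its beta is negative (iff D_e3 > 3*D_e1) beta is pinned
    to zero and alpha refit alone; if its alpha is negative (iff
    D_e3 < sqrt(3)*D_e1) alpha is pinned and beta refit alone.  The two
    conditions are mutually exclusive.
    """
    d_e3 = float(d_e3)
    d_e1 = float(d_e1)
    if not d_e3 > d_e1 > 0:
        raise ValueError(
            f"endpoint ordering d_e3 > d_e1 > 0 violated: d_e3={d_e3}, d_e1={d_e1}"
        )
    alpha, beta = _raw_alpha_beta(d_e3, d_e1)
    if beta < 0:
        alpha_b0, _ = _alpha_beta_zeroed(d_e3, d_e1)
        return LQMParams(alpha=alpha_b0, beta=0.0), BRANCH_BETA_ZEROED
    if alpha < 0:
        _, beta_a0 = _alpha_beta_zeroed(d_e3, d_e1)
        return LQMParams(alpha=0.0, beta=beta_a0), BRANCH_ALPHA_ZEROED
    return LQMParams(alpha=alpha, beta=beta), BRANCH_UNCONSTRAINED


def lqm_from_endpoint_set(
    endpoints: Iterable[RadiosensitivityEndpoint],
) -> tuple[float, float]:
    """Raw (possibly negative) OLS fit of ``-ln SF_i = alpha*D_i + beta*D_i^2``.

    Uses the closed-form sum expressions; with exactly two endpoints this is
    the exact interpolant of :func:`alpha_beta_from_endpoints` (raw branch).
    """
    eps = list(endpoints)
    doses = np.array([e.dose for e in eps])
    if len(set(doses.tolist())) < 2:
        raise ValueError("need at least 2 endpoints with distinct doses")
    log_sf = np.log([e.survival_fraction for e in eps])
    s2 = np.sum(doses**2)
    s3 = np.sum(doses**3)
    s4 = np.sum(doses**4)
    sdl = np.sum(doses * log_sf)
    sd2l = np.sum(doses**2 * log_sf)
    denom = s3 * s3 - s2 * s4
    alpha = (s4 * sdl - s3 * sd2l) / denom
    beta = (s2 * sd2l - s3 * sdl) / denom
    return float(alpha), float(beta)


# ---------------------------------------------------------------------------
# Full prediction chain and RBE
# ---------------------------------------------------------------------------

E3 = math.exp(-3.0)
E1 = math.exp(-1.0)


def predict_cion_lqm(
    photon: LQMParams, let_d: float, params: ModelParameters
) -> PredictionResult:
    """Predict the carbon-ion LQ curve for a photon reference curve at ``let_d``.

    Composes photon endpoint extraction (doses at e^-3 and e^-1 survival),
    the LET endpoint trends, and the constrained endpoint -> LQ conversion.
    """
    let_d = float(let_d)
    if let_d < 0:
        raise ValueError("let_d must be non-negative")
    d_e3_x = dose_at_survival(photon, E3)
    d_e1_x = dose_at_survival(photon, E1)
    d_e3_c, d_e1_c = predict_endpoints(d_e3_x, d_e1_x, let_d, params)
    if d_e3_c <= d_e1_c:
        raise ValueError(
            f"predicted endpoints out of order (d_e3={d_e3_c:.6g} <= "
            f"d_e1={d_e1_c:.6g}) at let_d={let_d}; pathological parameterization"
        )
    lqm, branch = alpha_beta_from_endpoints(d_e3_c, d_e1_c)
    return PredictionResult(
        lqm_cion=lqm, d_e3=d_e3_c, d_e1=d_e1_c, branch=branch, let_d=let_d
    )


def rbe_at_survival(photon: LQMParams, cion: LQMParams, sf: float):
    """RBE at a fixed survival level: photon dose / C-ion dose at ``sf``."""
    return dose_at_survival(photon, sf) / dose_at_survival(cion, sf)


def rbe_at_dose(
    photon: LQMParams, cion: LQMParams, dose: float, fixed: str = "cion"
):
    """Iso-effect RBE at a dose level.

    With ``fixed="cion"`` (default), ``dose`` is the carbon-ion dose: the RBE
    is the photon dose producing the same surviving fraction, divided by
    ``dose``.  With ``fixed="photon"``, ``dose`` is the photon dose and the
    RBE is ``dose`` divided by the iso-survival C-ion dose.
    """
    if dose <= 0:
        raise ValueError("dose must be positive")
    if fixed == "cion":
        sf = survival_fraction(cion, dose)
        return dose_at_survival(photon, sf) / dose
    if fixed == "photon":
        sf = survival_fraction(photon, dose)
        return dose / dose_at_survival(cion, sf)
    raise ValueError(f"fixed must be 'cion' or 'photon', got {fixed!r}")


def poisson_lethal_lesion_mean(sf: float) -> float:
    """Mean lethal-lesion count per cell whose Poisson zero-class equals ``sf``.

    Under a Poisson lethal-lesion picture, the surviving fraction is the
    probability of zero lethal lesions, so the mean is ``-ln(sf)``; at 10%
    survival this is ~2.3 lesions per cell.
    """
    if not 0.0 < sf < 1.0:
        raise ValueError("survival fraction must lie in (0, 1)")
    return -math.log(sf)
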