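"""Confidence bands for survival curves via first-order error propagation.

Measured curves: the (alpha, beta) fit covariance propagates exactly on the
log-survival scale, ``var(ln SF) = D^2 var(a) + D^4 var(b) + 2 D^3 cov(a,b)``.

Predicted curves: the 4x4 model-parameter covariance propagates through the
full prediction chain by central finite differences of ``ln SF`` with respect
to (f1, m1, q1, f2), holding the constraint branch fixed at its central
value (the branch switch is a measure-zero discontinuity; crossings under
perturbation are logged).  Bands are formed on the ln SF scale and
exponentiated, which keeps them positive.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .core import (
    BRANCH_ALPHA_ZEROED,
    BRANCH_BETA_ZEROED,
    BRANCH_UNCONSTRAINED,
    E1,
    E3,
    LQMParams,
    ModelParameters,
    _alpha_beta_zeroed,
    _raw_alpha_beta,
    dose_at_survival,
    predict_cion_lqm,
)

__all__ = [
    "CovariantLQM",
    "ConfidenceBand",
    "measured_curve_band",
    "predicted_curve_band",
]

logger = logging.getLogger(__name__)

#: Coverage -> z factor; the stated conventions are exact.
_Z_FACTORS = {95.0: 1.96, 68.3: 1.0}

_FD_REL_STEP = 1e-5


def _z_factor(coverage: float) -> float:
    for cov, z in _Z_FACTORS.items():
        if abs(coverage - cov) < 1e-9:
            return z
    if not 0.0 < coverage < 100.0:
        raise ValueError(f"coverage must lie in (0, 100), got {coverage}")
    return float(norm.ppf(0.5 + coverage / 200.0))


@dataclass(frozen=True)
class CovariantLQM:
    """An LQ curve together with its fit covariance (alpha, beta)."""

    lqm: LQMParams
    se_alpha: float
    se_beta: float
    cov_alpha_beta: float = 0.0

    def __post_init__(self) -> None:
        if self.se_alpha < 0 or self.se_beta < 0:
            raise ValueError("standard errors must be non-negative")
        bound = self.se_alpha * self.se_beta
        if abs(self.cov_alpha_beta) > bound + 1e-15 * max(bound, 1.0):
            raise ValueError(
                "covariance violates Cauchy-Schwarz: "
                f"|{self.cov_alpha_beta}| > {bound}"
            )


@dataclass(frozen=True)
class ConfidenceBand:
    """Pointwise survival-fraction band at a stated nominal coverage."""

    doses: np.ndarray
    central: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    coverage: float

    def __post_init__(self) -> None:
        for name in ("doses", "central", "lower", "upper"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (
            np.all(self.lower <= self.central + 1e-12)
            and np.all(self.central <= self.upper + 1e-12)
        ):
            raise ValueError("band must satisfy lower <= central <= upper")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "dose": self.doses,
                "central": self.central,
                "lower": self.lower,
                "upper": self.upper,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _band_from_lnsf(doses, ln_sf, se_ln_sf, coverage) -> ConfidenceBand:
    z = _z_factor(coverage)
    return ConfidenceBand(
        doses=doses,
        central=np.clip(np.exp(ln_sf), 0.0, 1.0),
        lower=np.clip(np.exp(ln_sf - z * se_ln_sf), 0.0, 1.0),
        upper=np.clip(np.exp(ln_sf + z * se_ln_sf), 0.0, 1.0),
        coverage=coverage,
    )


def measured_curve_band(
    clqm: CovariantLQM, doses, coverage: float = 95.0
) -> ConfidenceBand:
    """Delta-method band for a measured LQ curve from its fit covariance."""
    doses = np.asarray(doses, dtype=float)
    if np.any(doses < 0):
        raise ValueError("doses must be non-negative")
    var = (
        doses**2 * clqm.se_alpha**2
        + doses**4 * clqm.se_beta**2
        + 2.0 * doses**3 * clqm.cov_alpha_beta
    )
    if np.any(var < -1e-12):
        raise ValueError("propagated variance is negative; covariance not PSD")
    ln_sf = -clqm.lqm.alpha * doses - clqm.lqm.beta * doses**2
    return _band_from_lnsf(doses, ln_sf, np.sqrt(np.maximum(var, 0.0)), coverage)


# ---------------------------------------------------------------------------
# Predicted-curve band
# ---------------------------------------------------------------------------


def _lnsf_fixed_branch(
    d3x: float, d1x: float, let_d: float, theta, branch: str, doses: np.ndarray
):
    """ln SF of the predicted curve with the constraint branch held fixed.

    ``theta`` components may be arrays (vectorized over parameter draws);
    output broadcasts to ``theta_shape + doses.shape``.  Also returns the
    branch each evaluation would naturally take, for crossing detection.
    """
    f1, m1, q1, f2 = (np.asarray(t, dtype=float) for t in theta)
    a = d3x / (1.0 + f1 * let_d) + q1 * let_d**2 + m1
    b = d1x / (1.0 + f2 * let_d)
    alpha_raw, beta_raw = _raw_alpha_beta(a, b)
    alpha_b0, beta_a0 = _alpha_beta_zeroed(a, b)
    if branch == BRANCH_UNCONSTRAINED:
        alpha, beta = alpha_raw, beta_raw
    elif branch == BRANCH_BETA_ZEROED:
        alpha, beta = alpha_b0, np.zeros_like(alpha_b0)
    elif branch == BRANCH_ALPHA_ZEROED:
        alpha, beta = np.zeros_like(beta_a0), beta_a0
    else:  # pragma: no cover - guarded upstream
        raise ValueError(f"unknown branch {branch!r}")
    natural = np.where(
        beta_raw < 0, 1, np.where(alpha_raw < 0, 2, 0)
    )  # 0=unconstrained, 1=beta_zeroed, 2=alpha_zeroed
    ln_sf = (
        -alpha[..., None] * doses[None, :] - beta[..., None] * doses[None, :] ** 2
    )
    return ln_sf, natural


def predicted_curve_band(
    photon: LQMParams,
    let_d: float,
    params: ModelParameters,
    doses,
    coverage: float = 95.0,
) -> ConfidenceBand:
    """Delta-method band for a model-predicted C-ion survival curve.

    The gradient of ``ln SF(D)`` with respect to (f1, m1, q1, f2) is taken by
    central finite differences (relative step 1e-5) through the prediction
    chain with the central constraint branch held fixed; the variance is
    ``g^T Sigma g`` with the model-parameter covariance.
    """
    doses = np.asarray(doses, dtype=float)
    cov = params.covariance
    if not np.allclose(cov, cov.T, rtol=0, atol=1e-12 * max(1.0, np.abs(cov).max())):
        raise ValueError("parameter covariance must be symmetric")
    eig_min = float(np.linalg.eigvalsh(cov).min())
    if eig_min < -1e-10 * max(1.0, float(np.abs(cov).max())):
        raise ValueError("parameter covariance is not positive semi-definite")

    central = predict_cion_lqm(photon, let_d, params)
    d3x = dose_at_survival(photon, E3)
    d1x = dose_at_survival(photon, E1)
    theta0 = params.theta
    ln_sf0, _ = _lnsf_fixed_branch(d3x, d1x, let_d, theta0, central.branch, doses)

    grad = np.zeros((4, doses.size))
    crossed = False
    for j in range(4):
        h = _FD_REL_STEP * (abs(theta0[j]) if theta0[j] != 0 else 1e-3)
        up = theta0.copy()
        dn = theta0.copy()
        up[j] += h
        dn[j] -= h
        ln_up, nat_up = _lnsf_fixed_branch(d3x, d1x, let_d, up, central.branch, doses)
        ln_dn, nat_dn = _lnsf_fixed_branch(d3x, d1x, let_d, dn, central.branch, doses)
        branch_code = {"unconstrained": 0, "beta_zeroed": 1, "alpha_zeroed": 2}[
            central.branch
        ]
        if np.any(nat_up != branch_code) or np.any(nat_dn != branch_code):
            crossed = True
        grad[j] = (ln_up[0] - ln_dn[0]) / (2.0 * h)
    if crossed:
        logger.warning(
            "finite-difference steps cross the constraint branch at LET %.3g; "
            "band computed with branch %r held fixed",
            let_d,
            central.branch,
        )
    var = np.einsum("jd,jk,kd->d", grad, cov, grad)
    return _band_from_lnsf(doses, ln_sf0[0], np.sqrt(np.maximum(var, 0.0)), coverage)
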