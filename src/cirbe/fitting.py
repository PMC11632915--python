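"""Model training: trend fits, information-criterion selection, global fit.

Three layers, in the order the method runs:

1. Per-endpoint LET trends (slope/intercept families) fit by relative
   least squares on endpoint doses, compared across families by BIC.
2. Endpoint-combination selection: for each 2-, 3-, and 4-endpoint subset of
   {e^-3, e^-2, e^-1, e^-1/2} the composed model is scored by the L2 curve
   distance over the training set and ranked by AICc.
3. The final 4-parameter model (f1, m1, q1, f2) fit globally by bounded
   multi-start least squares on per-record L2 distances, with a Gauss-Newton
   covariance estimate.

The L2 distance between two survival curves is the root-integrated squared
difference over [0.5, 4] Gy, normalized by the integral of the predicted
curve over the same window.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .core import (
    E1,
    E3,
    LQMParams,
    ModelParameters,
    PARAM_NAMES,
    dose_at_survival,
    survival_fraction,
)
from .data_io import TrainingDataset

__all__ = [
    "TrendFamily",
    "TrendFunctionSpec",
    "EndpointTrendFit",
    "FitConfig",
    "FitResult",
    "SLOPE_FAMILIES",
    "INTERCEPT_FAMILIES",
    "register_slope_family",
    "register_intercept_family",
    "l2_curve_distance",
    "relative_endpoint_residuals",
    "fit_endpoint_trend",
    "select_endpoint_combination",
    "fit_model",
    "estimate_parameter_covariance",
    "CANDIDATE_ENDPOINT_SFS",
]

logger = logging.getLogger(__name__)

E2 = float(np.exp(-2.0))
EHALF = float(np.exp(-0.5))

#: Candidate survival levels for endpoint-combination selection.
CANDIDATE_ENDPOINT_SFS = (E3, E2, E1, EHALF)

# Information criteria use the Gaussian concentrated log-likelihood with
# additive constants dropped.  RSS/n is floored so noiseless (RSS ~ 0) fits
# degenerate gracefully: ties are then broken purely by the k penalty.
_RSS_PER_N_FLOOR = 1e-16


def _bic(rss: float, n: int, k: int) -> float:
    return n * np.log(max(rss / n, _RSS_PER_N_FLOOR)) + k * np.log(n)


def _aicc(rss: float, n: int, k: int) -> float:
    if n - k - 1 <= 0:
        return np.nan
    return (
        n * np.log(max(rss / n, _RSS_PER_N_FLOOR))
        + 2 * k
        + 2 * k * (k + 1) / (n - k - 1)
    )


# ---------------------------------------------------------------------------
# L2 curve distance (fixed composite-Simpson grid)
# ---------------------------------------------------------------------------


def _simpson_weights(n_grid: int, h: float) -> np.ndarray:
    if n_grid < 3 or n_grid % 2 == 0:
        raise ValueError("Simpson grid needs an odd point count >= 3")
    w = np.ones(n_grid)
    w[1:-1:2] = 4.0
    w[2:-1:2] = 2.0
    return w * (h / 3.0)


def _curve_sf(curve, doses: np.ndarray) -> np.ndarray:
    """Evaluate a survival curve: an LQMParams or a callable SF(D)."""
    if callable(curve):
        return np.asarray(curve(doses), dtype=float)
    return survival_fraction(curve, doses)


def l2_curve_distance(
    measured,
    predicted,
    dose_range: tuple[float, float] = (0.5, 4.0),
    n_grid: int = 513,
) -> float:
    """Normalized L2 distance between two survival curves over ``dose_range``.

    ``sqrt(int (SF_meas - SF_pred)^2 dD) / int SF_pred dD``; note the
    normalization uses the *predicted* curve only, so the distance is not
    symmetric in its arguments.  Curves may be :class:`LQMParams` or callables.
    """
    lo, hi = dose_range
    doses = np.linspace(lo, hi, n_grid)
    w = _simpson_weights(n_grid, (hi - lo) / (n_grid - 1))
    sf_m = _curve_sf(measured, doses)
    sf_p = _curve_sf(predicted, doses)
    denom = float(w @ sf_p)
    if denom <= 0:
        raise ValueError("degenerate predicted curve: zero integral over dose range")
    return float(np.sqrt(w @ (sf_m - sf_p) ** 2) / denom)


# ---------------------------------------------------------------------------
# Trend-function registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TrendFamily:
    """One candidate slope or intercept function of LET_d."""

    family_id: str
    param_names: tuple[str, ...]
    fn: Callable[[np.ndarray, np.ndarray], np.ndarray]
    x0: tuple[float, ...]
    lower: tuple[float, ...]
    upper: tuple[float, ...]

    @property
    def k(self) -> int:
        return len(self.param_names)


SLOPE_FAMILIES: dict[str, TrendFamily] = {}
INTERCEPT_FAMILIES: dict[str, TrendFamily] = {}


def register_slope_family(family: TrendFamily) -> None:
    SLOPE_FAMILIES[family.family_id] = family


def register_intercept_family(family: TrendFamily) -> None:
    INTERCEPT_FAMILIES[family.family_id] = family


register_slope_family(
    TrendFamily(
        family_id="inverse_linear",
        param_names=("f",),
        fn=lambda let, p: 1.0 / (1.0 + p[0] * let),
        x0=(0.02,),
        lower=(0.0,),
        upper=(10.0,),
    )
)
register_slope_family(
    TrendFamily(
        family_id="inverse_linear_squared",
        param_names=("f",),
        fn=lambda let, p: 1.0 / (1.0 + p[0] * let) ** 2,
        x0=(0.01,),
        lower=(0.0,),
        upper=(10.0,),
    )
)
register_intercept_family(
    TrendFamily(
        family_id="quadratic_offset",
        param_names=("q", "m"),
        fn=lambda let, p: p[0] * let**2 + p[1],
        x0=(1e-6, 0.1),
        lower=(0.0, 0.0),
        upper=(1e-2, 20.0),
    )
)
register_intercept_family(
    TrendFamily(
        family_id="zero",
        param_names=(),
        fn=lambda let, p: np.zeros_like(let),
        x0=(),
        lower=(),
        upper=(),
    )
)


@dataclass(frozen=True)
class TrendFunctionSpec:
    """A (slope family, intercept family) pair with concrete parameter values."""

    slope_family: str
    intercept_family: str
    slope_params: tuple[float, ...]
    intercept_params: tuple[float, ...]

    def __post_init__(self) -> None:
        slope = SLOPE_FAMILIES[self.slope_family]
        intercept = INTERCEPT_FAMILIES[self.intercept_family]
        if len(self.slope_params) != slope.k:
            raise ValueError(
                f"slope family {self.slope_family!r} expects {slope.k} parameter(s)"
            )
        if len(self.intercept_params) != intercept.k:
            raise ValueError(
                f"intercept family {self.intercept_family!r} expects "
                f"{intercept.k} parameter(s)"
            )

    @property
    def k(self) -> int:
        return len(self.slope_params) + len(self.intercept_params)

    def predict(self, d_x: np.ndarray, let: np.ndarray) -> np.ndarray:
        slope = SLOPE_FAMILIES[self.slope_family].fn(let, np.asarray(self.slope_params))
        icpt = INTERCEPT_FAMILIES[self.intercept_family].fn(
            let, np.asarray(self.intercept_params)
        )
        return d_x * slope + icpt


# ---------------------------------------------------------------------------
# Per-endpoint trend fitting (relative residuals, BIC family selection)
# ---------------------------------------------------------------------------


def _endpoint_arrays(dataset: TrainingDataset, endpoint_sf: float):
    """Per-record (D_x, D_meas, LET) at one survival level; skips bad records."""
    d_x, d_meas, let = [], [], []
    for rec in dataset:
        try:
            dm = dose_at_survival(rec.cion, endpoint_sf)
        except ValueError as err:
            logger.warning(
                "skipping record %s (LET %.3g): %s", rec.cell_line, rec.let_d, err
            )
            continue
        if not np.isfinite(dm) or dm <= 0:
            logger.warning(
                "skipping record %s (LET %.3g): non-positive measured endpoint",
                rec.cell_line,
                rec.let_d,
            )
            continue
        d_x.append(dose_at_survival(rec.photon, endpoint_sf))
        d_meas.append(dm)
        let.append(rec.let_d)
    return np.asarray(d_x), np.asarray(d_meas), np.asarray(let)


def relative_endpoint_residuals(
    dataset: TrainingDataset, endpoint_sf: float, spec: TrendFunctionSpec
) -> np.ndarray:
    """Per-record relative residuals ``(D_pred - D_meas) / D_meas`` at one SF."""
    d_x, d_meas, let = _endpoint_arrays(dataset, endpoint_sf)
    return (spec.predict(d_x, let) - d_meas) / d_meas


@dataclass(frozen=True)
class EndpointTrendFit:
    """Best trend pair for one endpoint, with its BIC and the full family table."""

    endpoint_sf: float
    spec: TrendFunctionSpec
    rss: float
    bic: float
    n: int
    table: tuple[dict, ...] = ()

    @property
    def k(self) -> int:
        return self.spec.k


def _fit_trend_pair(
    d_x, d_meas, let, slope: TrendFamily, icpt: TrendFamily, rng, n_starts: int
):
    """Least-squares fit of one family pair from multiple jittered starts."""
    ks, ki = slope.k, icpt.k
    x0 = np.array(slope.x0 + icpt.x0, dtype=float)
    lower = np.array(slope.lower + icpt.lower, dtype=float)
    upper = np.array(slope.upper + icpt.upper, dtype=float)

    def resid(theta):
        pred = d_x * slope.fn(let, theta[:ks]) + icpt.fn(let, theta[ks:])
        return (pred - d_meas) / d_meas

    if x0.size == 0:  # no free parameters: nothing to optimize
        r = resid(x0)
        return x0, float(r @ r)
    best_theta, best_rss = None, np.inf
    starts = [x0]
    for _ in range(max(n_starts - 1, 0)):
        starts.append(np.clip(x0 * np.exp(rng.uniform(-1.5, 1.5, x0.size)), lower, upper))
    for start in starts:
        res = least_squares(
            resid, start, bounds=(lower, upper), method="trf", ftol=1e-12, xtol=1e-12
        )
        rss = float(res.fun @ res.fun)
        if rss < best_rss:
            best_rss, best_theta = rss, res.x
    return best_theta, best_rss


def fit_endpoint_trend(
    dataset: TrainingDataset,
    endpoint_sf: float,
    slope_families: Sequence[str] | None = None,
    intercept_families: Sequence[str] | None = None,
    n_starts: int = 8,
    seed: int = 0,
) -> EndpointTrendFit:
    """Fit every candidate (slope, intercept) family pair at one endpoint.

    Each pair is fit by least squares on the relative endpoint residuals; the
    pair minimizing BIC wins.  A design-degeneracy warning is raised when all
    records share a single LET value (slope and intercept are then confounded).
    """
    d_x, d_meas, let = _endpoint_arrays(dataset, endpoint_sf)
    n = len(d_meas)
    slope_ids = list(slope_families or SLOPE_FAMILIES)
    icpt_ids = list(intercept_families or INTERCEPT_FAMILIES)
    if len(np.unique(let)) < 2 and any(INTERCEPT_FAMILIES[i].k for i in icpt_ids):
        warnings.warn(
            "all records share a single LET value: slope and intercept trends "
            "are confounded (design degeneracy)",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    rows = []
    for sid in slope_ids:
        for iid in icpt_ids:
            slope, icpt = SLOPE_FAMILIES[sid], INTERCEPT_FAMILIES[iid]
            k = slope.k + icpt.k
            if n <= k + 1:
                rows.append(
                    {"slope": sid, "intercept": iid, "k": k, "n": n,
                     "rss": np.nan, "bic": np.nan, "feasible": False}
                )
                continue
            theta, rss = _fit_trend_pair(d_x, d_meas, let, slope, icpt, rng, n_starts)
            rows.append(
                {
                    "slope": sid,
                    "intercept": iid,
                    "k": k,
                    "n": n,
                    "rss": rss,
                    "bic": _bic(rss, n, k),
                    "feasible": True,
                    "theta": tuple(float(v) for v in np.atleast_1d(theta)),
                }
            )
    feasible = [r for r in rows if r["feasible"]]
    if not feasible:
        raise RuntimeError("no feasible trend family pair for this endpoint")
    best = min(feasible, key=lambda r: r["bic"])
    ks = SLOPE_FAMILIES[best["slope"]].k
    spec = TrendFunctionSpec(
        slope_family=best["slope"],
        intercept_family=best["intercept"],
        slope_params=best["theta"][:ks],
        intercept_params=best["theta"][ks:],
    )
    return EndpointTrendFit(
        endpoint_sf=endpoint_sf,
        spec=spec,
        rss=best["rss"],
        bic=best["bic"],
        n=n,
        table=tuple(rows),
    )


# ---------------------------------------------------------------------------
# Endpoint-combination selection (AICc)
# ---------------------------------------------------------------------------


def _constrained_ols_lqm(doses: np.ndarray, lethality: np.ndarray) -> LQMParams:
    """OLS of lethality ~ alpha*D + beta*D^2 with non-negativity fall-backs.

    Generalizes the two-endpoint closed forms: a negative raw beta pins
    beta = 0 and refits alpha alone (and symmetrically for alpha).
    """
    d2, d3, d4 = np.sum(doses**2), np.sum(doses**3), np.sum(doses**4)
    sdl, sd2l = np.sum(doses * lethality), np.sum(doses**2 * lethality)
    denom = d2 * d4 - d3 * d3
    alpha = (d4 * sdl - d3 * sd2l) / denom
    beta = (d2 * sd2l - d3 * sdl) / denom
    if beta < 0:
        return LQMParams(alpha=float(sdl / d2), beta=0.0)
    if alpha < 0:
        return LQMParams(alpha=0.0, beta=float(sd2l / d4))
    return LQMParams(alpha=float(alpha), beta=float(beta))


def select_endpoint_combination(
    dataset: TrainingDataset,
    candidate_sfs: Sequence[float] = CANDIDATE_ENDPOINT_SFS,
    trend_fits: Mapping[float, EndpointTrendFit] | None = None,
    seed: int = 0,
    n_grid: int = 513,
) -> pd.DataFrame:
    """Rank every 2-, 3-, and 4-endpoint combination by AICc.

    Each candidate endpoint gets its BIC-best trend fit; for every subset of
    size >= 2 the composed model (per-endpoint trends -> constrained OLS ->
    survival curve) is scored by the sum of squared L2 distances over the
    dataset.  Returns the selection table sorted by ascending AICc, with
    combinations failing the n > k + 1 sample-size requirement marked
    infeasible.
    """
    from itertools import combinations

    if trend_fits is None:
        trend_fits = {
            sf: fit_endpoint_trend(dataset, sf, seed=seed + i)
            for i, sf in enumerate(candidate_sfs)
        }
    records = list(dataset)
    n = len(records)
    # Per-record photon endpoint doses and measured curves, cached once.
    d_x = {
        sf: np.array([dose_at_survival(r.photon, sf) for r in records])
        for sf in candidate_sfs
    }
    lets = np.array([r.let_d for r in records])
    pred_endpoint = {
        sf: trend_fits[sf].spec.predict(d_x[sf], lets) for sf in candidate_sfs
    }
    rows = []
    for size in (2, 3, 4):
        if size > len(candidate_sfs):
            continue
        for combo in combinations(candidate_sfs, size):
            k = sum(trend_fits[sf].k for sf in combo)
            label = "+".join(f"{-np.log(sf):g}" for sf in combo)
            if n <= k + 1:
                rows.append(
                    {"endpoints": combo, "label": label, "k": k, "n": n,
                     "rss": np.nan, "aicc": np.nan, "feasible": False}
                )
                continue
            lethality = -np.log(np.asarray(combo))
            rss = 0.0
            for i, rec in enumerate(records):
                doses = np.array([pred_endpoint[sf][i] for sf in combo])
                lqm = _constrained_ols_lqm(doses, lethality)
                rss += l2_curve_distance(rec.cion, lqm, n_grid=n_grid) ** 2
            rows.append(
                {
                    "endpoints": combo,
                    "label": label,
                    "k": k,
                    "n": n,
                    "rss": rss,
                    "aicc": _aicc(rss, n, k),
                    "feasible": True,
                }
            )
    table = pd.DataFrame(rows)
    return table.sort_values(
        "aicc", na_position="last", kind="mergesort"
    ).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Global model fit (multi-start, analytic Jacobian)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FitConfig:
    """Configuration of the global fit (all knobs the procedure exposes)."""

    seed: int = 0
    n_starts: int = 10_000
    jitter: float = 0.10
    lower: tuple[float, float, float, float] = (1e-10, 0.0, 0.0, 1e-10)
    upper: tuple[float, float, float, float] = (1.0, 20.0, 1e-2, 1.0)
    dose_range: tuple[float, float] = (0.5, 4.0)
    n_grid: int = 513
    ftol: float = 1e-10
    xtol: float = 1e-8
    max_nfev: int = 200
    loocv_n_starts: int = 50

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "n_starts": self.n_starts,
            "jitter": self.jitter,
            "lower": list(self.lower),
            "upper": list(self.upper),
            "dose_range": list(self.dose_range),
            "n_grid": self.n_grid,
            "ftol": self.ftol,
            "xtol": self.xtol,
            "max_nfev": self.max_nfev,
            "loocv_n_starts": self.loocv_n_starts,
        }

    def hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class FitResult:
    """Outcome of the global multi-start fit."""

    params: ModelParameters
    objective: float
    n_starts: int
    converged_fraction: float
    seed: int
    n_records: int
    start_center: tuple[float, float, float, float]

    def to_dict(self, dataset_hash: str | None = None, config: FitConfig | None = None) -> dict:
        out = {
            "model": self.params.to_dict(),
            "objective": self.objective,
            "n_starts": self.n_starts,
            "converged_fraction": self.converged_fraction,
            "seed": self.seed,
            "n_records": self.n_records,
            "start_center": list(self.start_center),
        }
        if dataset_hash is not None:
            out["dataset_hash"] = dataset_hash
        if config is not None:
            out["config"] = config.to_dict()
            out["config_hash"] = config.hash()
        return out

    def save(self, path, dataset_hash: str | None = None, config: FitConfig | None = None) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(dataset_hash, config), fh, indent=2)

    @classmethod
    def load(cls, path) -> "FitResult":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            params=ModelParameters.from_dict(d["model"]),
            objective=d["objective"],
            n_starts=d["n_starts"],
            converged_fraction=d["converged_fraction"],
            seed=d["seed"],
            n_records=d["n_records"],
            start_center=tuple(d["start_center"]),
        )


def dataset_hash(dataset: TrainingDataset) -> str:
    """Content hash of a dataset (order-independent; used for provenance)."""
    keys = sorted(repr(r.key) for r in dataset)
    return hashlib.sha256("\n".join(keys).encode()).hexdigest()[:16]


_ORDER_PENALTY = 1e3


class _FitWorkspace:
    """Precomputed arrays for the per-record L2 residual and its Jacobian."""

    def __init__(self, dataset: TrainingDataset, config: FitConfig):
        records = list(dataset)
        self.n = len(records)
        lo, hi = config.dose_range
        self.doses = np.linspace(lo, hi, config.n_grid)
        self.w = _simpson_weights(config.n_grid, (hi - lo) / (config.n_grid - 1))
        self.let = np.array([r.let_d for r in records])
        self.d3x = np.array([dose_at_survival(r.photon, E3) for r in records])
        self.d1x = np.array([dose_at_survival(r.photon, E1) for r in records])
        self.sf_meas = np.array(
            [survival_fraction(r.cion, self.doses) for r in records]
        )
        self._cache_key = None
        self._cache_val = None

    def residual_and_jac(self, theta: np.ndarray):
        key = theta.tobytes()
        if key == self._cache_key:
            return self._cache_val
        f1, m1, q1, f2 = theta
        let, D = self.let, self.doses
        s1 = 1.0 / (1.0 + f1 * let)
        s2 = 1.0 / (1.0 + f2 * let)
        a = self.d3x * s1 + q1 * let**2 + m1
        b = self.d1x * s2
        da = np.zeros((self.n, 4))
        db = np.zeros((self.n, 4))
        da[:, 0] = -self.d3x * let * s1**2
        da[:, 1] = 1.0
        da[:, 2] = let**2
        db[:, 3] = -self.d1x * let * s2**2

        r = np.empty(self.n)
        jac = np.empty((self.n, 4))
        bad = a <= b
        if np.any(bad):
            # Smooth penalty steering the optimizer back to ordered endpoints.
            r[bad] = _ORDER_PENALTY * (1.0 + b[bad] - a[bad])
            jac[bad] = _ORDER_PENALTY * (db[bad] - da[bad])
        good = ~bad
        if np.any(good):
            ag, bg = a[good], b[good]
            dag, dbg = da[good], db[good]
            v = ag**2 * bg - ag * bg**2
            u_a = ag**2 - 3.0 * bg**2
            u_b = 3.0 * bg - ag
            alpha_raw = u_a / v
            beta_raw = u_b / v
            dv_da = 2.0 * ag * bg - bg**2
            dv_db = ag**2 - 2.0 * ag * bg

            alpha = np.empty_like(ag)
            beta = np.empty_like(ag)
            dal_da = np.empty_like(ag)
            dal_db = np.empty_like(ag)
            dbe_da = np.empty_like(ag)
            dbe_db = np.empty_like(ag)

            m_b0 = beta_raw < 0
            m_a0 = (~m_b0) & (alpha_raw < 0)
            m_un = ~(m_b0 | m_a0)

            if np.any(m_un):
                vv, aa, bb = v[m_un], ag[m_un], bg[m_un]
                ua, ub = u_a[m_un], u_b[m_un]
                dva, dvb = dv_da[m_un], dv_db[m_un]
                alpha[m_un] = ua / vv
                beta[m_un] = ub / vv
                dal_da[m_un] = (2.0 * aa * vv - ua * dva) / vv**2
                dal_db[m_un] = (-6.0 * bb * vv - ua * dvb) / vv**2
                dbe_da[m_un] = (-vv - ub * dva) / vv**2
                dbe_db[m_un] = (3.0 * vv - ub * dvb) / vv**2
            if np.any(m_b0):
                aa, bb = ag[m_b0], bg[m_b0]
                s = aa**2 + bb**2
                t = 3.0 * aa + bb
                alpha[m_b0] = t / s
                beta[m_b0] = 0.0
                dal_da[m_b0] = (3.0 * s - 2.0 * aa * t) / s**2
                dal_db[m_b0] = (s - 2.0 * bb * t) / s**2
                dbe_da[m_b0] = 0.0
                dbe_db[m_b0] = 0.0
            if np.any(m_a0):
                aa, bb = ag[m_a0], bg[m_a0]
                p = 3.0 * aa**2 + bb**2
                q = aa**4 + bb**4
                alpha[m_a0] = 0.0
                beta[m_a0] = p / q
                dal_da[m_a0] = 0.0
                dal_db[m_a0] = 0.0
                dbe_da[m_a0] = (6.0 * aa * q - 4.0 * aa**3 * p) / q**2
                dbe_db[m_a0] = (2.0 * bb * q - 4.0 * bb**3 * p) / q**2

            dalpha = dal_da[:, None] * dag + dal_db[:, None] * dbg
            dbeta = dbe_da[:, None] * dag + dbe_db[:, None] * dbg

            sf_p = np.exp(-np.outer(alpha, D) - np.outer(beta, D**2))
            diff = sf_p - self.sf_meas[good]
            S = (diff**2) @ self.w
            den = sf_p @ self.w
            N = np.sqrt(S)
            r[good] = N / den

            # dSF/dtheta = SF * (-D*dalpha_k - D^2*dbeta_k): dalpha/dbeta are
            # per-record scalars, so the grid contractions reduce to matvecs.
            wD = self.w * D
            wD2 = self.w * D**2
            ds_prod = diff * sf_p
            A1 = ds_prod @ wD
            A2 = ds_prod @ wD2
            B1 = sf_p @ wD
            B2 = sf_p @ wD2
            dS = -2.0 * (dalpha * A1[:, None] + dbeta * A2[:, None])
            dden = -(dalpha * B1[:, None] + dbeta * B2[:, None])
            safe_N = np.where(N > 1e-150, N, 1.0)
            dN = np.where((N > 1e-150)[:, None], dS / (2.0 * safe_N[:, None]), 0.0)
            jac[good] = dN / den[:, None] - (N / den**2)[:, None] * dden

        self._cache_key = key
        self._cache_val = (r, jac)
        return r, jac

    def residual(self, theta: np.ndarray) -> np.ndarray:
        return self.residual_and_jac(np.asarray(theta, dtype=float))[0]

    def jac(self, theta: np.ndarray) -> np.ndarray:
        return self.residual_and_jac(np.asarray(theta, dtype=float))[1]


def _seed_center(dataset: TrainingDataset, config: FitConfig, rng) -> np.ndarray:
    """Per-endpoint trend fits fixing the final model's structure.

    The e^-3 endpoint uses the inverse-linear slope with quadratic-offset
    intercept (f1, q1, m1); the e^-1 endpoint the inverse-linear slope with
    no intercept (f2).
    """
    fit3 = fit_endpoint_trend(
        dataset,
        E3,
        slope_families=("inverse_linear",),
        intercept_families=("quadratic_offset",),
        seed=int(rng.integers(2**31)),
    )
    fit1 = fit_endpoint_trend(
        dataset,
        E1,
        slope_families=("inverse_linear",),
        intercept_families=("zero",),
        seed=int(rng.integers(2**31)),
    )
    f1 = fit3.spec.slope_params[0]
    q1, m1 = fit3.spec.intercept_params
    f2 = fit1.spec.slope_params[0]
    return np.array([f1, m1, q1, f2])


def fit_model(dataset: TrainingDataset, config: FitConfig | None = None) -> FitResult:
    """Global multi-start fit of (f1, m1, q1, f2) to a training dataset.

    Minimizes the sum of squared L2 curve distances over all records under
    non-negativity bounds.  Starts are the per-endpoint seed fit jittered
    uniformly within +/-``config.jitter`` per parameter; the best local
    minimum wins.  Deterministic given ``config.seed``.  The returned
    parameters carry the Gauss-Newton covariance estimate.
    """
    config = config or FitConfig()
    ds = dataset.sorted()
    if len(ds) < 5:
        raise ValueError(f"need at least 5 records to fit, got {len(ds)}")
    rng = np.random.default_rng(config.seed)
    center = _seed_center(ds, config, rng)
    lower = np.asarray(config.lower)
    upper = np.asarray(config.upper)
    center = np.clip(center, lower, upper)
    ws = _FitWorkspace(ds, config)

    starts = [center]
    for _ in range(config.n_starts - 1):
        starts.append(
            np.clip(center * (1.0 + rng.uniform(-config.jitter, config.jitter, 4)),
                    lower, upper)
        )
    best_cost, best_x, n_ok = np.inf, None, 0
    for start in starts:
        if not np.all(np.isfinite(ws.residual(start))):
            logger.warning("discarding start with non-finite objective: %s", start)
            continue
        res = least_squares(
            ws.residual,
            start,
            jac=ws.jac,
            bounds=(lower, upper),
            method="trf",
            ftol=config.ftol,
            xtol=config.xtol,
            gtol=1e-12,
            max_nfev=config.max_nfev,
        )
        if res.status > 0:
            n_ok += 1
        if res.cost < best_cost:
            best_cost, best_x = res.cost, res.x
    if best_x is None:
        raise RuntimeError("all optimization starts failed")
    objective = 2.0 * best_cost  # least_squares cost = 0.5 * sum(r^2)
    theta = np.maximum(best_x, lower)
    cov = _gauss_newton_covariance(ws, theta)
    params = ModelParameters.from_theta(theta, covariance=cov)
    return FitResult(
        params=params,
        objective=float(objective),
        n_starts=len(starts),
        converged_fraction=n_ok / len(starts),
        seed=config.seed,
        n_records=len(ds),
        start_center=tuple(float(v) for v in center),
    )


def _gauss_newton_covariance(ws: _FitWorkspace, theta: np.ndarray) -> np.ndarray:
    r, J = ws.residual_and_jac(np.asarray(theta, dtype=float))
    n, k = len(r), 4
    sigma2 = float(r @ r) / max(n - k, 1)
    if sigma2 < 1e-24:
        # perfect (noiseless) fit: zero residual variance, zero covariance;
        # the sqrt-residual Jacobian is singular there by construction
        return np.zeros((4, 4))
    if np.linalg.matrix_rank(J) < k:
        raise ValueError("residual Jacobian is rank deficient; covariance undefined")
    cov = sigma2 * np.linalg.pinv(J.T @ J)
    return 0.5 * (cov + cov.T)


def estimate_parameter_covariance(
    fit: FitResult, dataset: TrainingDataset, config: FitConfig | None = None
) -> np.ndarray:
    """Gauss-Newton covariance ``sigma^2 (J^T J)^-1`` of the fitted parameters.

    ``J`` is the Jacobian of the per-record L2 residuals at the optimum and
    ``sigma^2 = RSS / (n - 4)``.
    """
    config = config or FitConfig()
    ws = _FitWorkspace(dataset.sorted(), config)
    return _gauss_newton_covariance(ws, fit.params.theta)
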