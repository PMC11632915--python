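"""Model validation: leave-one-out cross-validation and accuracy summaries.

LOOCV refits the full model with each record held out and predicts the
held-out record with the refit parameters, so no prediction is informed by
its own measurement.  Accuracy is summarized as relative RBE deviations at
the 0.5, 1, 2 and 4 Gy dose levels, bootstrap percentile intervals of those
deviations, deviations grouped into clinically motivated LET bins (beam
entrance through very-high-LET), and mean-absolute-deviation metrics for
the D10%/D50% endpoints and RBE at 1, 2, 4 Gy.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .core import (
    ModelParameters,
    PredictionResult,
    dose_at_survival,
    predict_cion_lqm,
    rbe_at_dose,
)
from .data_io import SurvivalRecord, TrainingDataset
from .fitting import FitConfig, dataset_hash, fit_model

__all__ = [
    "LoocvPrediction",
    "ValidationReport",
    "LET_BINS",
    "DOSE_LEVELS",
    "loocv",
    "rbe_deviations",
    "bootstrap_intervals",
    "let_bin_summary",
    "comparison_metrics",
    "validate_model",
]

logger = logging.getLogger(__name__)

#: Clinically motivated LET_d bins [keV/um), left-closed right-open, mapping
#: to entrance, proximal/mid/distal SOBP, distal edge, and very high LET.
LET_BINS = (
    ("entrance", 0.0, 20.0),
    ("proximal_sobp", 20.0, 40.0),
    ("mid_sobp", 40.0, 70.0),
    ("distal_sobp", 70.0, 100.0),
    ("distal_edge", 100.0, 200.0),
    ("very_high_let", 200.0, np.inf),
)

DOSE_LEVELS = (0.5, 1.0, 2.0, 4.0)


@dataclass(frozen=True)
class LoocvPrediction:
    """Held-out prediction for one record, with the refit parameters."""

    record: SurvivalRecord
    result: PredictionResult | None
    params: ModelParameters | None
    ok: bool
    message: str = ""


def _record_seed(base_seed: int, record: SurvivalRecord) -> int:
    """Stable per-record seed: invariant under dataset reordering, < 2^31."""
    return (base_seed + zlib.crc32(repr(record.key).encode())) % (2**31 - 1)


def loocv(
    dataset: TrainingDataset,
    fit_config: FitConfig | None = None,
    n_starts: int | None = None,
) -> list[LoocvPrediction]:
    """Leave-one-out cross-validation over a training dataset.

    Each record is predicted by a model refit on the other n-1 records, at a
    (default, scaled-down) multi-start budget of ``fit_config.loocv_n_starts``.
    Refit failures are flagged on the affected record and the run continues.
    Deterministic given the config seed and invariant under record order.
    """
    if len(dataset) < 10:
        raise ValueError(f"LOOCV needs at least 10 records, got {len(dataset)}")
    fit_config = fit_config or FitConfig()
    budget = n_starts if n_starts is not None else fit_config.loocv_n_starts
    out: list[LoocvPrediction] = []
    for rec in dataset.sorted():
        sub = dataset.without(rec.key)
        cfg = replace(
            fit_config, seed=_record_seed(fit_config.seed, rec), n_starts=budget
        )
        try:
            fit = fit_model(sub, cfg)
            result = predict_cion_lqm(rec.photon, rec.let_d, fit.params)
            out.append(
                LoocvPrediction(record=rec, result=result, params=fit.params, ok=True)
            )
        except Exception as err:  # refit failure: flag, continue
            logger.warning(
                "LOOCV refit failed for %s at LET %.3g: %s",
                rec.cell_line,
                rec.let_d,
                err,
            )
            out.append(
                LoocvPrediction(
                    record=rec, result=None, params=None, ok=False, message=str(err)
                )
            )
    return out


def predict_all(
    dataset: TrainingDataset, params: ModelParameters
) -> list[LoocvPrediction]:
    """Predict every record with one fixed parameter set (no held-out refits)."""
    out = []
    for rec in dataset.sorted():
        try:
            result = predict_cion_lqm(rec.photon, rec.let_d, params)
            out.append(LoocvPrediction(record=rec, result=result, params=params, ok=True))
        except ValueError as err:
            out.append(
                LoocvPrediction(record=rec, result=None, params=None, ok=False,
                                message=str(err))
            )
    return out


def rbe_deviations(
    predictions: Sequence[LoocvPrediction],
    dose_levels: Sequence[float] = DOSE_LEVELS,
) -> pd.DataFrame:
    """Per record x dose level relative RBE deviations (pred - meas) / meas.

    Both RBE values fix the C-ion dose at the level and compare against the
    record's photon curve; the measured RBE uses the record's measured C-ion
    LQ parameters.  Records with degenerate measured curves are skipped.
    """
    rows = []
    for pred in predictions:
        if not pred.ok or pred.result is None:
            continue
        rec = pred.record
        try:
            measured = rec.cion
        except ValueError as err:
            logger.warning(
                "skipping record %s at LET %.3g: %s", rec.cell_line, rec.let_d, err
            )
            continue
        photon = rec.photon
        for dose in dose_levels:
            rbe_meas = rbe_at_dose(photon, measured, dose)
            rbe_pred = rbe_at_dose(photon, pred.result.lqm_cion, dose)
            rows.append(
                {
                    "cell_line": rec.cell_line,
                    "let_d": rec.let_d,
                    "dose_level": dose,
                    "rbe_predicted": rbe_pred,
                    "rbe_measured": rbe_meas,
                    "relative_deviation": (rbe_pred - rbe_meas) / rbe_meas,
                }
            )
    return pd.DataFrame(
        rows,
        columns=[
            "cell_line",
            "let_d",
            "dose_level",
            "rbe_predicted",
            "rbe_measured",
            "relative_deviation",
        ],
    )


def bootstrap_intervals(
    deviations: pd.DataFrame,
    n_boot: int = 2000,
    levels: Sequence[float] = (68.3, 95.0),
    seed: int = 0,
) -> pd.DataFrame:
    """Bootstrap percentile intervals of the deviation distribution per dose level.

    For each dose level the deviations are resampled with replacement
    ``n_boot`` times; the reported interval endpoints are the bootstrap means
    of the empirical ((100-L)/2, (100+L)/2) percentiles.  Strata with fewer
    than 5 deviations are omitted with a warning.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for dose, group in deviations.groupby("dose_level", sort=True):
        vals = group["relative_deviation"].to_numpy()
        if len(vals) < 5:
            logger.warning(
                "dose level %.3g Gy has only %d deviations; stratum omitted",
                dose,
                len(vals),
            )
            continue
        resamples = rng.choice(vals, size=(n_boot, len(vals)), replace=True)
        for level in levels:
            lo_p, hi_p = (100.0 - level) / 2.0, (100.0 + level) / 2.0
            lo = float(np.mean(np.percentile(resamples, lo_p, axis=1)))
            hi = float(np.mean(np.percentile(resamples, hi_p, axis=1)))
            rows.append(
                {
                    "dose_level": dose,
                    "level": level,
                    "lower": lo,
                    "upper": hi,
                    "n": len(vals),
                    "n_boot": n_boot,
                }
            )
    return pd.DataFrame(
        rows, columns=["dose_level", "level", "lower", "upper", "n", "n_boot"]
    )


def let_bin_summary(deviations: pd.DataFrame) -> pd.DataFrame:
    """Mean (bias) and SD (accuracy) of deviations per clinical LET bin.

    Bins are left-closed, right-open; a record at exactly 20 keV/um falls in
    the proximal-SOBP bin. Requires a ``let_d`` column on the deviations.
    """
    rows = []
    let = deviations["let_d"].to_numpy()
    dev = deviations["relative_deviation"].to_numpy()
    for label, lo, hi in LET_BINS:
        mask = (let >= lo) & (let < hi)
        n = int(mask.sum())
        rows.append(
            {
                "bin": label,
                "let_lo": lo,
                "let_hi": hi,
                "n": n,
                "mean_deviation": float(np.mean(dev[mask])) if n else np.nan,
                "sd_deviation": float(np.std(dev[mask], ddof=1)) if n > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MetricValue:
    mean: float
    sem: float
    n: int


@dataclass(frozen=True)
class ComparisonMetrics:
    """Mean absolute relative deviations (with SEM): endpoints and RBE levels."""

    d10: MetricValue
    d50: MetricValue
    rbe_1gy: MetricValue
    rbe_2gy: MetricValue
    rbe_4gy: MetricValue

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name in ("d10", "d50", "rbe_1gy", "rbe_2gy", "rbe_4gy"):
            m: MetricValue = getattr(self, name)
            rows.append(
                {"metric": name, "mean_abs_rel_dev": m.mean, "sem": m.sem, "n": m.n}
            )
        return pd.DataFrame(rows)


def _metric(values: list[float]) -> MetricValue:
    arr = np.abs(np.asarray(values, dtype=float))
    n = len(arr)
    sem = float(np.std(arr, ddof=1) / np.sqrt(n)) if n > 1 else 0.0
    return MetricValue(mean=float(np.mean(arr)) if n else np.nan, sem=sem, n=n)


def comparison_metrics(predictions: Sequence[LoocvPrediction]) -> ComparisonMetrics:
    """Accuracy metrics: |rel. deviation| of D10%, D50%, and RBE at 1/2/4 Gy."""
    d10, d50, rbe1, rbe2, rbe4 = [], [], [], [], []
    for pred in predictions:
        if not pred.ok or pred.result is None:
            continue
        rec = pred.record
        try:
            measured = rec.cion
        except ValueError as err:
            logger.warning(
                "skipping record %s at LET %.3g: %s", rec.cell_line, rec.let_d, err
            )
            continue
        photon = rec.photon
        curve = pred.result.lqm_cion
        for store, sf in ((d10, 0.10), (d50, 0.50)):
            meas = dose_at_survival(measured, sf)
            store.append((dose_at_survival(curve, sf) - meas) / meas)
        for store, dose in ((rbe1, 1.0), (rbe2, 2.0), (rbe4, 4.0)):
            meas = rbe_at_dose(photon, measured, dose)
            store.append((rbe_at_dose(photon, curve, dose) - meas) / meas)
    return ComparisonMetrics(
        d10=_metric(d10),
        d50=_metric(d50),
        rbe_1gy=_metric(rbe1),
        rbe_2gy=_metric(rbe2),
        rbe_4gy=_metric(rbe4),
    )


@dataclass
class ValidationReport:
    """Bundle of LOOCV deviations, intervals, LET-bin summaries, and metrics."""

    deviations: pd.DataFrame
    intervals: pd.DataFrame
    bin_summary: pd.DataFrame
    metrics: ComparisonMetrics
    n_records: int
    n_failed: int
    seed: int
    dataset_hash: str

    def save(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.deviations.to_csv(out / "deviations.csv", index=False)
        self.intervals.to_csv(out / "bootstrap_intervals.csv", index=False)
        self.bin_summary.to_csv(out / "let_bin_summary.csv", index=False)
        self.metrics.to_frame().to_csv(out / "comparison_metrics.csv", index=False)
        summary = {
            "n_records": self.n_records,
            "n_failed": self.n_failed,
            "seed": self.seed,
            "dataset_hash": self.dataset_hash,
            "metrics": {
                row["metric"]: {"mean_abs_rel_dev": row["mean_abs_rel_dev"],
                                "sem": row["sem"], "n": row["n"]}
                for row in self.metrics.to_frame().to_dict("records")
            },
        }
        with open(out / "validation_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)


def validate_model(
    dataset: TrainingDataset,
    fit_config: FitConfig | None = None,
    n_boot: int = 2000,
    dose_levels: Sequence[float] = DOSE_LEVELS,
) -> ValidationReport:
    """Run the full validation pipeline: LOOCV -> deviations -> summaries."""
    fit_config = fit_config or FitConfig()
    predictions = loocv(dataset, fit_config)
    deviations = rbe_deviations(predictions, dose_levels)
    intervals = bootstrap_intervals(deviations, n_boot=n_boot, seed=fit_config.seed)
    bins = let_bin_summary(deviations)
    metrics = comparison_metrics(predictions)
    return ValidationReport(
        deviations=deviations,
        intervals=intervals,
        bin_summary=bins,
        metrics=metrics,
        n_records=len(predictions),
        n_failed=sum(1 for p in predictions if not p.ok),
        seed=fit_config.seed,
        dataset_hash=dataset_hash(dataset),
    )
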