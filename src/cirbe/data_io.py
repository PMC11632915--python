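"""Training-table I/O, curation filters, and the synthetic-data generator.

A training table is a CSV of cell-line/LET records, each pairing a photon
reference LQ curve with a measured carbon-ion LQ curve at one dose-weighted
LET.  Curation mirrors the published rules: drop records whose reference
photon source is softer than 200 kVp-equivalent, whose LET exceeds
350 keV/um, or whose reported C-ion beta is negative.

The synthetic generator emulates that table's structure from a known
ground-truth parameterization of the model: photon LQ parameters are drawn
uniformly, true C-ion endpoints computed through the model, multiplicative
lognormal noise applied in endpoint space, and the noisy endpoints converted
back to (alpha_c, beta_c) through the constrained closed forms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .core import (
    E1,
    E3,
    LQMParams,
    ModelParameters,
    alpha_beta_from_endpoints,
    dose_at_survival,
    predict_endpoints,
)

__all__ = [
    "SurvivalRecord",
    "TrainingDataset",
    "SyntheticConfig",
    "SchemaError",
    "read_training_csv",
    "write_training_csv",
    "apply_curation_filters",
    "generate_synthetic_dataset",
    "REQUIRED_COLUMNS",
]

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = (
    "cell_line",
    "let_d",
    "alpha_x",
    "beta_x",
    "alpha_c",
    "beta_c",
    "photon_source_kvp",
)

#: Photon sources reported in MV are stored as kVp-equivalent = 1000 * MV so
#: the "< 200 kVp" curation rule is a single numeric threshold.
MIN_PHOTON_SOURCE_KVP = 200.0
MAX_LET = 350.0


class SchemaError(ValueError):
    """A training CSV is missing required columns or has unparseable rows."""


@dataclass(frozen=True)
class SurvivalRecord:
    """One cell-line/LET observation: photon and C-ion LQ parameters."""

    cell_line: str
    let_d: float
    alpha_x: float
    beta_x: float
    alpha_c: float
    beta_c: float
    photon_source_kvp: float
    source: str = ""

    def __post_init__(self) -> None:
        if self.let_d <= 0:
            raise ValueError(f"let_d must be positive, got {self.let_d}")
        if self.alpha_x < 0 or self.beta_x < 0:
            raise ValueError("photon LQ parameters must be non-negative")
        if self.alpha_x == 0 and self.beta_x == 0:
            raise ValueError("degenerate photon LQ curve")
        # beta_c may be negative pre-filter; alpha_c unrestricted here.

    @property
    def photon(self) -> LQMParams:
        return LQMParams(alpha=self.alpha_x, beta=self.beta_x)

    @property
    def cion(self) -> LQMParams:
        """Measured C-ion curve; raises if beta_c is negative (pre-filter)."""
        return LQMParams(alpha=self.alpha_c, beta=self.beta_c)

    @property
    def key(self) -> tuple:
        """Content-based identity, stable under record reordering."""
        return (
            self.cell_line,
            round(self.let_d, 9),
            round(self.alpha_x, 12),
            round(self.beta_x, 12),
            round(self.alpha_c, 12),
            round(self.beta_c, 12),
        )


@dataclass
class TrainingDataset:
    """A list of survival records plus the per-rule curation removal log."""

    records: list[SurvivalRecord]
    filter_log: dict[str, int] | None = None

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SurvivalRecord]:
        return iter(self.records)

    def sorted(self) -> "TrainingDataset":
        """Canonically ordered copy (used to make fitting order-invariant)."""
        return TrainingDataset(
            records=sorted(self.records, key=lambda r: r.key),
            filter_log=self.filter_log,
        )

    def without(self, key: tuple) -> "TrainingDataset":
        """Copy excluding the record(s) with the given content key."""
        kept = [r for r in self.records if r.key != key]
        if len(kept) == len(self.records):
            raise KeyError(f"no record with key {key}")
        return TrainingDataset(records=kept, filter_log=self.filter_log)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "cell_line": r.cell_line,
                    "let_d": r.let_d,
                    "alpha_x": r.alpha_x,
                    "beta_x": r.beta_x,
                    "alpha_c": r.alpha_c,
                    "beta_c": r.beta_c,
                    "photon_source_kvp": r.photon_source_kvp,
                    "source": r.source,
                }
                for r in self.records
            ]
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "TrainingDataset":
        records = []
        for row in frame.itertuples(index=False):
            records.append(
                SurvivalRecord(
                    cell_line=str(row.cell_line),
                    let_d=float(row.let_d),
                    alpha_x=float(row.alpha_x),
                    beta_x=float(row.beta_x),
                    alpha_c=float(row.alpha_c),
                    beta_c=float(row.beta_c),
                    photon_source_kvp=float(row.photon_source_kvp),
                    source=str(getattr(row, "source", "") or ""),
                )
            )
        return cls(records=records)


def read_training_csv(path) -> TrainingDataset:
    """Read an (unfiltered) training table.

    Raises :class:`SchemaError` naming any missing required column, or citing
    the 1-based data row of the first unparseable numeric value.
    """
    frame = pd.read_csv(path, dtype={"cell_line": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"training CSV missing required column(s): {', '.join(missing)}")
    numeric_cols = [c for c in REQUIRED_COLUMNS if c != "cell_line"]
    for col in numeric_cols:
        parsed = pd.to_numeric(frame[col], errors="coerce")
        bad = frame.index[parsed.isna() & frame[col].notna()]
        if len(bad) or parsed.isna().any():
            row = int((frame.index[parsed.isna()])[0]) + 1
            raise SchemaError(f"unparseable numeric in column {col!r} at data row {row}")
        frame[col] = parsed
    if "source" not in frame.columns:
        frame["source"] = ""
    frame["source"] = frame["source"].fillna("")
    return TrainingDataset.from_frame(frame)


def write_training_csv(dataset: TrainingDataset, path) -> None:
    """Write a training table; floats at 12 significant digits (lossless round-trip)."""
    dataset.to_frame().to_csv(path, index=False, float_format="%.12g")


def apply_curation_filters(dataset: TrainingDataset) -> TrainingDataset:
    """Apply the published curation rules, in order, with first-rule-wins logging.

    Rules: photon source < 200 kVp-equivalent; LET_d > 350 keV/um; beta_c < 0.
    Boundary values (exactly 200 kVp, exactly 350 keV/um, beta_c exactly 0)
    are retained.  Idempotent.
    """
    log = {"photon_source_below_200kvp": 0, "let_above_350": 0, "negative_beta_c": 0}
    kept: list[SurvivalRecord] = []
    for rec in dataset.records:
        if rec.photon_source_kvp < MIN_PHOTON_SOURCE_KVP:
            log["photon_source_below_200kvp"] += 1
        elif rec.let_d > MAX_LET:
            log["let_above_350"] += 1
        elif rec.beta_c < 0:
            log["negative_beta_c"] += 1
        else:
            kept.append(rec)
    removed = sum(log.values())
    if removed:
        logger.info("curation removed %d of %d records: %s", removed, len(dataset), log)
    return TrainingDataset(records=kept, filter_log=log)


# ---------------------------------------------------------------------------
# Synthetic data
# ---------------------------------------------------------------------------


@dataclass
class SyntheticConfig:
    """Stated world for the synthetic training table.

    Defaults mirror the experimental design behind the model's correlation
    analysis: 8 cell lines at LET_d = 13.5, 27.9, 60.5 keV/um, photon
    radiosensitivity spanning alpha_x in [0.05, 0.8] /Gy and beta_x in
    [0.005, 0.1] /Gy^2, with C-ion responses generated from the published
    ground-truth parameterization and 5% multiplicative endpoint noise.
    Set ``lets=None`` to instead draw ``n_lets_per_line`` LET values
    uniformly from ``let_range`` for each line.
    """

    n_cell_lines: int = 8
    lets: Sequence[float] | None = (13.5, 27.9, 60.5)
    let_range: tuple[float, float] = (5.0, 200.0)
    n_lets_per_line: int = 3
    alpha_x_range: tuple[float, float] = (0.05, 0.8)
    beta_x_range: tuple[float, float] = (0.005, 0.1)
    ground_truth: ModelParameters = field(default_factory=ModelParameters.published)
    endpoint_noise_cv: float = 0.05
    photon_source_kvp: float = 6000.0  # 6 MV reference, kVp-equivalent
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cell_lines < 1:
            raise ValueError("n_cell_lines must be >= 1")
        if self.endpoint_noise_cv < 0:
            raise ValueError("endpoint_noise_cv must be >= 0")
        for lo, hi in (self.alpha_x_range, self.beta_x_range):
            if not (0 <= lo < hi):
                raise ValueError("parameter ranges must satisfy 0 <= lo < hi")
        if self.lets is None:
            lo, hi = self.let_range
            if not (0 < lo < hi):
                raise ValueError("let_range must satisfy 0 < lo < hi")
            if self.n_lets_per_line < 1:
                raise ValueError("n_lets_per_line must be >= 1")
        elif any(l <= 0 for l in self.lets):
            raise ValueError("all LET values must be positive")


_MAX_NOISE_RESAMPLES = 100


def generate_synthetic_dataset(cfg: SyntheticConfig) -> TrainingDataset:
    """Generate a synthetic training table from a known ground truth.

    Per cell line, photon LQ parameters are drawn uniformly; per (line, LET)
    the true C-ion endpoints follow the model with ``cfg.ground_truth``, each
    multiplied by an independent unit-mean lognormal factor with coefficient
    of variation ``endpoint_noise_cv``.  Noise draws violating the endpoint
    ordering d_e3 > d_e1 are resampled (never clamped), up to 100 attempts.
    Deterministic for a given seed.
    """
    rng = np.random.default_rng(cfg.seed)
    sigma = float(np.sqrt(np.log1p(cfg.endpoint_noise_cv**2)))
    mu = -0.5 * sigma * sigma  # unit mean
    records: list[SurvivalRecord] = []
    for j in range(cfg.n_cell_lines):
        name = f"SYN{j:03d}"
        alpha_x = float(rng.uniform(*cfg.alpha_x_range))
        beta_x = float(rng.uniform(*cfg.beta_x_range))
        photon = LQMParams(alpha=alpha_x, beta=beta_x)
        d3x = dose_at_survival(photon, E3)
        d1x = dose_at_survival(photon, E1)
        if cfg.lets is not None:
            lets = list(cfg.lets)
        else:
            lets = rng.uniform(*cfg.let_range, size=cfg.n_lets_per_line).tolist()
        for let in lets:
            d3_true, d1_true = predict_endpoints(d3x, d1x, float(let), cfg.ground_truth)
            for attempt in range(_MAX_NOISE_RESAMPLES):
                eps = np.exp(mu + sigma * rng.standard_normal(2)) if sigma > 0 else np.ones(2)
                d3n, d1n = d3_true * eps[0], d1_true * eps[1]
                if d3n > d1n:
                    break
            else:
                raise RuntimeError(
                    f"could not draw ordered endpoints for {name} at LET {let:.3g} "
                    f"after {_MAX_NOISE_RESAMPLES} attempts"
                )
            if attempt:
                logger.debug(
                    "resampled endpoint noise %d time(s) for %s at LET %.3g",
                    attempt, name, let,
                )
            lqm, _branch = alpha_beta_from_endpoints(d3n, d1n)
            records.append(
                SurvivalRecord(
                    cell_line=name,
                    let_d=float(let),
                    alpha_x=alpha_x,
                    beta_x=beta_x,
                    alpha_c=lqm.alpha,
                    beta_c=lqm.beta,
                    photon_source_kvp=cfg.photon_source_kvp,
                    source="synthetic",
                )
            )
    return TrainingDataset(records=records)
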