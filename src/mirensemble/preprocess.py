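"""Staged non-linear input transforms for the meta-predictor.

Three modes of increasing sophistication, each fitted on training data
and re-applicable to held-out folds:

* **Mode I** -- numericalize and scale: token outputs become +/-1 and each
  real-valued column is min-max mapped onto [-1, 1] using its training
  minimum and maximum.
* **Mode II** -- distribution shift for heavy-tailed score columns
  (ProMiR-like): ``NA`` becomes the sentinel -30, an exact 0 becomes
  -25, every positive score becomes its natural logarithm, and the
  column is then min-max scaled like mode I.  The sentinels sit strictly
  below the log of any score the dialect can produce (ln 1e-10 = -23.03),
  so the ordering NA < zero < genuine scores is preserved.
* **Mode III** -- mode II followed by a PCA rotation Y' = (Y - mean) . E,
  where E is the eigenvector matrix of the covariance of the mode-II
  features on the training fold.

Fitted state lives in :class:`TransformParams` so validation and test
folds are projected with training-fold parameters only (no leakage);
out-of-range values at apply time are clipped back into [-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import yaml

from .errors import (
    DegenerateCovarianceError,
    DomainError,
    FitError,
    RankError,
    SchemaError,
)
from .tables import PredictorSpec, ScoreTable

NA_SENTINEL = -30.0
ZERO_SENTINEL = -25.0


@dataclass
class ColumnTransform:
    """Fitted per-column state."""

    kind: str  # "binary" | "numeric"
    log_shift: bool = False
    na_sentinel: float = NA_SENTINEL
    zero_sentinel: float = ZERO_SENTINEL
    norm_lo: float | None = None
    norm_hi: float | None = None
    constant: bool = False


@dataclass
class TransformParams:
    """Fitted preprocessing pipeline (mode, per-column state, optional PCA)."""

    mode: str
    columns: dict[str, ColumnTransform]
    eigenmatrix: np.ndarray | None = None
    column_means: np.ndarray | None = None

    def to_dict(self) -> dict:
        d = {
            "mode": self.mode,
            "columns": {
                name: {
                    "kind": ct.kind,
                    "log_shift": ct.log_shift,
                    "na_sentinel": ct.na_sentinel,
                    "zero_sentinel": ct.zero_sentinel,
                    "norm_lo": ct.norm_lo,
                    "norm_hi": ct.norm_hi,
                    "constant": ct.constant,
                }
                for name, ct in self.columns.items()
            },
        }
        if self.eigenmatrix is not None:
            d["eigenmatrix"] = self.eigenmatrix.tolist()
            d["column_means"] = self.column_means.tolist()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TransformParams":
        cols = {
            name: ColumnTransform(**c) for name, c in d["columns"].items()
        }
        E = np.asarray(d["eigenmatrix"], dtype=float) if "eigenmatrix" in d else None
        means = np.asarray(d["column_means"], dtype=float) if "column_means" in d else None
        return cls(mode=d["mode"], columns=cols, eigenmatrix=E, column_means=means)

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "TransformParams":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class FeatureMatrix:
    """Numeric feature matrix aligned with sample ids and class labels."""

    sample_ids: list[str]
    X: np.ndarray
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.X.shape[0] != len(self.sample_ids) or len(self.labels) != len(self.sample_ids):
            raise ValueError("feature matrix misaligned with sample ids/labels")


def _premap_cell(value, ct: ColumnTransform, spec: PredictorSpec) -> float:
    """Map one raw cell to its pre-normalization numeric value."""
    if ct.kind == "binary":
        return 1.0 if value == spec.positive_token else -1.0
    if ct.log_shift:
        if isinstance(value, str):  # "NA"
            return ct.na_sentinel
        if value == 0:
            return ct.zero_sentinel
        if value < 0:
            raise DomainError(f"column {spec.name!r}: negative value {value} in a log column")
        return math.log(value)
    # plain numeric: NA pools with the 0-valued negatives before scaling
    if isinstance(value, str):
        return 0.0
    return float(value)


def _premap_column(table: ScoreTable, spec: PredictorSpec, ct: ColumnTransform) -> np.ndarray:
    return np.array(
        [_premap_cell(v, ct, spec) for v in table.raw[spec.name]], dtype=float
    )


def _fit(table: ScoreTable, mode: str, log_columns: Sequence[str]) -> tuple[TransformParams, FeatureMatrix]:
    log_set = set(log_columns)
    unknown = log_set - set(table.predictor_names)
    if unknown:
        raise SchemaError(f"log columns {sorted(unknown)} not in table")
    columns: dict[str, ColumnTransform] = {}
    X = np.empty((table.n_samples, table.n_predictors), dtype=float)
    for j, spec in enumerate(table.predictors):
        if spec.is_binary:
            if spec.name in log_set:
                raise SchemaError(f"log column {spec.name!r} is binary")
            ct = ColumnTransform(kind="binary")
            X[:, j] = _premap_column(table, spec, ct)
        else:
            ct = ColumnTransform(kind="numeric", log_shift=spec.name in log_set)
            col = _premap_column(table, spec, ct)
            if not np.all(np.isfinite(col)):
                raise FitError(f"column {spec.name!r}: no finite values to fit")
            if ct.log_shift:
                logged = col[(col != ct.na_sentinel) & (col != ct.zero_sentinel)]
                if logged.size and logged.min() <= ct.zero_sentinel:
                    raise FitError(
                        f"column {spec.name!r}: logged value {logged.min():.3f} does not "
                        f"sit above the zero sentinel {ct.zero_sentinel}"
                    )
            lo, hi = float(col.min()), float(col.max())
            ct.norm_lo, ct.norm_hi = lo, hi
            if lo == hi:
                ct.constant = True
                X[:, j] = 0.0
            else:
                X[:, j] = 2.0 * (col - lo) / (hi - lo) - 1.0
        columns[spec.name] = ct
    params = TransformParams(mode=mode, columns=columns)
    fm = FeatureMatrix(list(table.sample_ids), X, table.labels.copy())
    if mode == "III":
        E, means = fit_pca(fm.X)
        params.eigenmatrix, params.column_means = E, means
        fm = FeatureMatrix(fm.sample_ids, apply_pca(fm.X, E, means), fm.labels)
    return params, fm


def fit_transform_I(table: ScoreTable) -> tuple[TransformParams, FeatureMatrix]:
    """Mode I: tokens to +/-1, numeric columns min-max scaled to [-1, 1].

    Numeric ``NA`` cells are pooled with the raw value 0 (the dialect's
    negative-call score) before scaling.
    """
    return _fit(table, "I", ())


def fit_transform_II(table: ScoreTable, log_columns: Sequence[str]) -> tuple[TransformParams, FeatureMatrix]:
    """Mode II: log-shift the named heavy-tailed columns, then scale as mode I."""
    return _fit(table, "II", log_columns)


def fit_transform_III(table: ScoreTable, log_columns: Sequence[str]) -> tuple[TransformParams, FeatureMatrix]:
    """Mode III: mode II followed by a training-fold PCA rotation."""
    return _fit(table, "III", log_columns)


def fit_pca(X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigenvector matrix and column means of the covariance of *X*.

    Columns of the returned matrix are unit eigenvectors ordered by
    descending eigenvalue; each is sign-fixed so its largest-magnitude
    entry (first such entry on ties) is positive, making the rotation
    platform-deterministic.  Requires more samples than columns.
    """
    X = np.asarray(X, dtype=float)
    n, m = X.shape
    if n <= m:
        raise RankError(f"PCA needs N > M; got N={n}, M={m}")
    means = X.mean(axis=0)
    xc = X - means
    cov = xc.T @ xc / (n - 1)
    if float(np.trace(cov)) <= 0.0:
        raise DegenerateCovarianceError("zero total variance; PCA undefined")
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(-eigvals, kind="stable")
    E = eigvecs[:, order]
    for j in range(m):
        i = int(np.argmax(np.abs(E[:, j])))
        if E[i, j] < 0:
            E[:, j] = -E[:, j]
    return E, means


def apply_pca(X: np.ndarray, E: np.ndarray, means: np.ndarray) -> np.ndarray:
    """Center rows by *means* and rotate by *E*; row norms are preserved."""
    X = np.asarray(X, dtype=float)
    E = np.asarray(E, dtype=float)
    means = np.asarray(means, dtype=float)
    if X.ndim != 2 or E.shape != (X.shape[1], X.shape[1]) or means.shape != (X.shape[1],):
        raise ValueError(
            f"shape mismatch: X {X.shape}, E {E.shape}, means {means.shape}"
        )
    return (X - means) @ E


def apply_transform(params: TransformParams, table: ScoreTable) -> FeatureMatrix:
    """Apply a fitted pipeline to new data without refitting.

    Numeric values outside the fitted training range are clipped to
    [-1, 1] after the affine map so the network's input domain stays
    closed; binary tokens map to +/-1 unconditionally.
    """
    if table.predictor_names != list(params.columns):
        raise SchemaError(
            f"table columns {table.predictor_names} do not match fitted "
            f"columns {list(params.columns)}"
        )
    X = np.empty((table.n_samples, table.n_predictors), dtype=float)
    for j, spec in enumerate(table.predictors):
        ct = params.columns[spec.name]
        col = _premap_column(table, spec, ct)
        if ct.kind == "binary":
            X[:, j] = col
        elif ct.constant:
            X[:, j] = 0.0
        else:
            scaled = 2.0 * (col - ct.norm_lo) / (ct.norm_hi - ct.norm_lo) - 1.0
            X[:, j] = np.clip(scaled, -1.0, 1.0)
    if params.eigenmatrix is not None:
        X = apply_pca(X, params.eigenmatrix, params.column_means)
    return FeatureMatrix(list(table.sample_ids), X, table.labels.copy())


def fit_transform(table: ScoreTable, mode: str,
                  log_columns: Sequence[str] | None = None) -> tuple[TransformParams, FeatureMatrix]:
    """Dispatch on mode ("I", "II", "III"); log columns default to the
    sentinel-accepting numeric dialects (ProMiR-like)."""
    if mode == "I":
        return fit_transform_I(table)
    if log_columns is None:
        log_columns = [
            s.name for s in table.predictors
            if not s.is_binary and s.na_policy == "sentinel"
        ]
    if mode == "II":
        return fit_transform_II(table, log_columns)
    if mode == "III":
        return fit_transform_III(table, log_columns)
    raise ValueError(f"unknown preprocessing mode {mode!r}")
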