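"""Multivariate calibration of plate color features against concentration.

The calibration chain is: column-wise standardization of the 10-channel
feature matrix and of y, a NIPALS partial-least-squares regression with a
small number of latent components (default 4), leave-one-out cross-validation
with standardization re-estimated inside every fold, a working-range scan
over candidate upper concentration bounds, and LOD/LOQ from the
cross-validated residual spread:

    LOD = 3.3 * s / |m|,   LOQ = 10 * s / |m|

with s the SD of out-of-fold residuals and m the slope of predicted vs
measured; LOQ is additionally floored at the lowest non-zero calibration
standard. A PCA-style biplot (first two PLS components) and signed
channel-concentration correlations support interpretation, and small helpers
cover repeatability statistics and standard-addition estimation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .colorimetry import FEATURE_COLUMNS

__all__ = [
    "StandardizationParams",
    "PLSModel",
    "CalibrationMetrics",
    "CVResult",
    "RangeScanResult",
    "BiplotResult",
    "RepeatabilitySummary",
    "standardize",
    "pls_fit",
    "pls_predict",
    "cross_validate",
    "calibration_metrics",
    "select_working_range",
    "lod_loq",
    "pca_biplot",
    "repeatability_summary",
    "standard_addition_estimate",
]

SCHEMA_VERSION = "1.0"


# ---------------------------------------------------------------------------
# standardization


@dataclass
class StandardizationParams:
    """Training-set means and SDs used to autoscale features and y.

    Columns with zero SD carry no information and are dropped; their names
    are recorded so the transformation stays reproducible.
    """

    columns: list[str]
    x_mean: np.ndarray
    x_sd: np.ndarray
    dropped: list[str] = field(default_factory=list)
    y_mean: float = 0.0
    y_sd: float = 1.0

    def transform_x(self, table: pd.DataFrame) -> np.ndarray:
        X = table[self.columns].to_numpy(dtype=float)
        return (X - self.x_mean) / self.x_sd

    def transform_y(self, y: np.ndarray) -> np.ndarray:
        return (np.asarray(y, dtype=float) - self.y_mean) / self.y_sd

    def inverse_y(self, y_std: np.ndarray) -> np.ndarray:
        return np.asarray(y_std, dtype=float) * self.y_sd + self.y_mean


def standardize(
    table: pd.DataFrame,
    feature_columns: list[str] | None = None,
    y_column: str = "conc_mg_per_L",
) -> tuple[np.ndarray, StandardizationParams]:
    """Autoscale features (and y) to zero mean and unit SD (ddof=1).

    Returns the standardized feature matrix and the parameters needed to
    apply the identical transformation to new data. Constant columns are
    dropped and listed in ``params.dropped``.
    """
    cols = feature_columns if feature_columns is not None else FEATURE_COLUMNS
    if len(table) < 2:
        raise ValueError(f"need at least 2 rows to standardize, got {len(table)}")
    if table[cols].isna().any().any():
        raise ValueError("feature table contains missing cells")
    X = table[cols].to_numpy(dtype=float)
    mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.any():
        raise ValueError("all feature columns are constant; nothing to calibrate on")
    kept_cols = [c for c, k in zip(cols, keep) if k]
    dropped = [c for c, k in zip(cols, keep) if not k]

    y_mean, y_sd = 0.0, 1.0
    if y_column in table.columns:
        y = table[y_column].to_numpy(dtype=float)
        y_mean = float(y.mean())
        y_sd = float(y.std(ddof=1))

    params = StandardizationParams(
        columns=kept_cols,
        x_mean=mean[keep],
        x_sd=sd[keep],
        dropped=dropped,
        y_mean=y_mean,
        y_sd=y_sd,
    )
    return params.transform_x(table), params


# ---------------------------------------------------------------------------
# NIPALS PLS (univariate y)


@dataclass
class PLSModel:
    """NIPALS PLS1 regression on standardized features.

    ``coef`` maps standardized X to standardized y-hat; predictions in
    concentration units go through the stored standardization parameters.
    Weight-vector signs follow the convention that the first non-zero
    element of each weight vector is positive.
    """

    n_components: int
    weights: np.ndarray  # (p, a)
    x_loadings: np.ndarray  # (p, a)
    y_loadings: np.ndarray  # (a,)
    scores: np.ndarray  # (n, a), training scores
    coef: np.ndarray  # (p,)
    standardization: StandardizationParams
    fitted_values: np.ndarray | None = None  # training-set predictions, y units
    schema_version: str = SCHEMA_VERSION

    def to_json(self, path: str | Path) -> None:
        payload = {
            "schema_version": self.schema_version,
            "n_components": self.n_components,
            "weights": self.weights.tolist(),
            "x_loadings": self.x_loadings.tolist(),
            "y_loadings": self.y_loadings.tolist(),
            "coef": self.coef.tolist(),
            "standardization": {
                "columns": self.standardization.columns,
                "x_mean": self.standardization.x_mean.tolist(),
                "x_sd": self.standardization.x_sd.tolist(),
                "dropped": self.standardization.dropped,
                "y_mean": self.standardization.y_mean,
                "y_sd": self.standardization.y_sd,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "PLSModel":
        payload = json.loads(Path(path).read_text())
        major = str(payload.get("schema_version", "0")).split(".")[0]
        if int(major) > int(SCHEMA_VERSION.split(".")[0]):
            raise ValueError(
                f"model schema {payload['schema_version']} is newer than "
                f"supported {SCHEMA_VERSION}"
            )
        sp = payload["standardization"]
        params = StandardizationParams(
            columns=list(sp["columns"]),
            x_mean=np.asarray(sp["x_mean"], dtype=float),
            x_sd=np.asarray(sp["x_sd"], dtype=float),
            dropped=list(sp["dropped"]),
            y_mean=float(sp["y_mean"]),
            y_sd=float(sp["y_sd"]),
        )
        return cls(
            n_components=int(payload["n_components"]),
            weights=np.asarray(payload["weights"], dtype=float),
            x_loadings=np.asarray(payload["x_loadings"], dtype=float),
            y_loadings=np.asarray(payload["y_loadings"], dtype=float),
            scores=np.empty((0, int(payload["n_components"]))),
            coef=np.asarray(payload["coef"], dtype=float),
            standardization=params,
            schema_version=str(payload["schema_version"]),
        )


def _sign_fix(w: np.ndarray) -> float:
    nz = np.flatnonzero(np.abs(w) > 1e-12)
    if nz.size == 0:
        return 1.0
    return 1.0 if w[nz[0]] > 0 else -1.0


def pls_fit(
    X: np.ndarray,
    y: np.ndarray,
    n_components: int,
    standardization: StandardizationParams | None = None,
) -> PLSModel:
    """Fit a univariate-response PLS by NIPALS.

    Per component: weight w proportional to X'y (unit norm), score t = Xw,
    X-loading p = X't/(t't), y-loading q = y't/(t't), then deflation of both
    X and y. For a single response no inner iteration is needed; each
    component is exact in one pass.
    """
    X = np.asarray(X, dtype=float).copy()
    y = np.asarray(y, dtype=float).copy()
    n, p = X.shape
    if y.shape != (n,):
        raise ValueError(f"y must have shape ({n},), got {y.shape}")
    if np.allclose(y, y[0]):
        raise ValueError("y has zero variance; cannot calibrate")
    rank = np.linalg.matrix_rank(X)
    if not 1 <= n_components <= rank:
        raise ValueError(
            f"n_components must be in [1, rank(X)={rank}], got {n_components}"
        )

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    T = np.zeros((n, n_components))
    for a in range(n_components):
        w = X.T @ y
        norm = np.linalg.norm(w)
        if norm < 1e-14:
            raise ValueError(
                f"component {a + 1}: X carries no remaining covariance with y"
            )
        w = w / norm
        w = w * _sign_fix(w)
        t = X @ w
        tt = t @ t
        p_a = X.T @ t / tt
        q_a = y @ t / tt
        X -= np.outer(t, p_a)
        y -= q_a * t
        W[:, a], P[:, a], Q[a], T[:, a] = w, p_a, q_a, t

    # B = W (P'W)^-1 q  maps standardized X to standardized y-hat
    coef = W @ np.linalg.solve(P.T @ W, Q)
    model = PLSModel(
        n_components=n_components,
        weights=W,
        x_loadings=P,
        y_loadings=Q,
        scores=T,
        coef=coef,
        standardization=standardization
        if standardization is not None
        else StandardizationParams(
            columns=[f"x{i}" for i in range(p)],
            x_mean=np.zeros(p),
            x_sd=np.ones(p),
        ),
    )
    return model


def pls_predict(model: PLSModel, features: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Predict concentrations for new feature rows.

    DataFrame input is matched to the model's stored column names, so the
    caller's column order is immaterial. Predictions are de-standardized and
    returned as-is — negative values are possible and left for the caller to
    flag, never clipped.
    """
    sp = model.standardization
    if isinstance(features, pd.DataFrame):
        missing = [c for c in sp.columns if c not in features.columns]
        if missing:
            raise ValueError(f"feature table missing model columns {missing}")
        Xs = sp.transform_x(features)
    else:
        X = np.asarray(features, dtype=float)
        if X.ndim == 1:
            X = X[None, :]
        Xs = (X - sp.x_mean) / sp.x_sd
    return sp.inverse_y(Xs @ model.coef)


# ---------------------------------------------------------------------------
# validation and metrics


@dataclass
class CVResult:
    """Leave-one-out predictions with their residuals."""

    measured: np.ndarray
    predicted: np.ndarray
    rmsecv: float

    @property
    def residuals(self) -> np.ndarray:
        return self.predicted - self.measured


def cross_validate(
    table: pd.DataFrame,
    n_components: int = 4,
    feature_columns: list[str] | None = None,
    y_column: str = "conc_mg_per_L",
) -> CVResult:
    """Leave-one-out cross-validation of the full calibration chain.

    Standardization parameters are re-estimated inside each fold, so the
    held-out sample never leaks into the preprocessing.
    """
    n = len(table)
    if n < n_components + 2:
        raise ValueError(
            f"need at least n_components + 2 = {n_components + 2} samples, got {n}"
        )
    measured = table[y_column].to_numpy(dtype=float)
    predicted = np.empty(n)
    idx = np.arange(n)
    for i in range(n):
        train = table.iloc[idx != i]
        Xs, params = standardize(train, feature_columns, y_column)
        ys = params.transform_y(train[y_column].to_numpy(dtype=float))
        model = pls_fit(Xs, ys, n_components, standardization=params)
        predicted[i] = pls_predict(model, table.iloc[[i]])[0]
    rmsecv = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    return CVResult(measured=measured, predicted=predicted, rmsecv=rmsecv)


@dataclass
class CalibrationMetrics:
    r2: float
    slope: float
    intercept: float
    rmse: float


def calibration_metrics(measured: np.ndarray, predicted: np.ndarray) -> CalibrationMetrics:
    """Least-squares line of predicted on measured, plus RMSE of residuals."""
    measured = np.asarray(measured, dtype=float)
    predicted = np.asarray(predicted, dtype=float)
    if measured.shape != predicted.shape or measured.size < 3:
        raise ValueError("measured and predicted must be equal-length with n >= 3")
    if np.allclose(measured, measured[0]):
        raise ValueError("measured values have zero variance")
    fit = stats.linregress(measured, predicted)
    rmse = float(np.sqrt(np.mean((predicted - measured) ** 2)))
    return CalibrationMetrics(
        r2=float(fit.rvalue**2),
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        rmse=rmse,
    )


# ---------------------------------------------------------------------------
# working range and detection limits


@dataclass
class RangeScanResult:
    chosen_upper: float
    chosen_lower: float
    metrics: pd.DataFrame  # one row per candidate upper bound
    cv: CVResult  # CV result of the chosen range


def select_working_range(
    table: pd.DataFrame,
    n_components: int = 4,
    candidate_uppers: list[float] | None = None,
    y_column: str = "conc_mg_per_L",
) -> RangeScanResult:
    """Scan candidate upper concentration bounds and pick a working range.

    For each candidate, the calibration is refit and leave-one-out
    cross-validated on the samples at or below the bound. The chosen range
    maximizes a lexicographic score on the cross-validated predicted-vs-
    measured line: slope closest to 1, then highest R^2, then lowest RMSECV.
    Every candidate's metrics are reported, feasible or not.
    """
    if candidate_uppers is None:
        candidate_uppers = [5.0, 7.0, 10.0, 14.0, 20.0]
    if len(candidate_uppers) < 1:
        raise ValueError("need at least one candidate upper bound")
    y = table[y_column].to_numpy(dtype=float)
    rows = []
    cvs: dict[float, CVResult] = {}
    for upper in candidate_uppers:
        sub = table[y <= upper]
        feasible = len(sub) >= n_components + 2 and sub[y_column].nunique() >= 2
        row = {"upper": float(upper), "n": int(len(sub)), "feasible": feasible}
        if feasible:
            try:
                cv = cross_validate(sub, n_components, y_column=y_column)
            except ValueError:
                row["feasible"] = False
                rows.append(row)
                continue
            m = calibration_metrics(cv.measured, cv.predicted)
            cvs[float(upper)] = cv
            row.update(
                {"slope": m.slope, "r2": m.r2, "rmsecv": cv.rmsecv}
            )
        rows.append(row)
    metrics = pd.DataFrame(rows)
    feasible = metrics[metrics["feasible"]]
    if feasible.empty:
        raise ValueError("no candidate upper bound leaves enough samples to fit")
    scored = feasible.assign(_s=np.abs(feasible["slope"] - 1.0))
    best = scored.sort_values(["_s", "r2", "rmsecv"], ascending=[True, False, True]).iloc[0]
    chosen = float(best["upper"])
    lowers = y[y > 0]
    chosen_lower = float(lowers.min()) if lowers.size else 0.0
    return RangeScanResult(
        chosen_upper=chosen,
        chosen_lower=chosen_lower,
        metrics=metrics.drop(columns=[c for c in metrics.columns if c.startswith("_")]),
        cv=cvs[chosen],
    )


@dataclass
class DetectionLimits:
    lod: float
    loq: float
    loq_unfloored: float
    floored: bool
    residual_sd: float
    degenerate: bool = False


def lod_loq(
    cv: CVResult | np.ndarray,
    slope: float,
    lowest_nonzero_standard: float | None = None,
) -> DetectionLimits:
    """Detection and quantification limits from cross-validated residuals.

    LOD = 3.3 s/|m| and LOQ = 10 s/|m| with s the SD (ddof=1) of out-of-fold
    residuals and m the predicted-vs-measured slope. When the lowest
    non-zero calibration standard exceeds the computed LOQ, the LOQ is
    floored there (one cannot claim quantification below the lowest standard
    actually calibrated); the flag records whether flooring was applied.
    """
    residuals = cv.residuals if isinstance(cv, CVResult) else np.asarray(cv, dtype=float)
    s = float(np.std(residuals, ddof=1))
    if s == 0.0:
        return DetectionLimits(0.0, 0.0, 0.0, False, 0.0, degenerate=True)
    if slope == 0:
        raise ValueError("slope must be non-zero")
    lod = 3.3 * s / abs(slope)
    loq = 10.0 * s / abs(slope)
    floored = False
    loq_final = loq
    if lowest_nonzero_standard is not None and loq < lowest_nonzero_standard:
        loq_final = float(lowest_nonzero_standard)
        floored = True
    return DetectionLimits(
        lod=lod,
        loq=loq_final,
        loq_unfloored=loq,
        floored=floored,
        residual_sd=s,
    )


# ---------------------------------------------------------------------------
# biplot and summaries


@dataclass
class BiplotResult:
    scores: np.ndarray  # (n, 2)
    loadings: np.ndarray  # (p, 2)
    columns: list[str]
    correlations: dict[str, float]  # raw channel vs concentration, signed


def pca_biplot(
    table: pd.DataFrame,
    y_column: str = "conc_mg_per_L",
) -> BiplotResult:
    """Scores and loadings of the first two latent components, plus the
    signed Pearson correlation of each raw channel with concentration."""
    if len(table) < 3:
        raise ValueError(f"need at least 3 samples, got {len(table)}")
    feature_cols = [c for c in table.columns if c not in (y_column, "sample_id")]
    Xs, params = standardize(table, feature_cols, y_column=y_column)
    ys = params.transform_y(table[y_column].to_numpy(dtype=float))
    model = pls_fit(Xs, ys, n_components=2, standardization=params)
    y = table[y_column].to_numpy(dtype=float)
    corr = {
        c: float(stats.pearsonr(table[c].to_numpy(dtype=float), y)[0])
        for c in params.columns
    }
    return BiplotResult(
        scores=model.scores,
        loadings=model.x_loadings,
        columns=params.columns,
        correlations=corr,
    )


@dataclass
class RepeatabilitySummary:
    n: int
    mean: float
    sd: float
    rsd_percent: float
    accuracy_percent: float
    nominal: float


def repeatability_summary(values: list[float], nominal: float) -> RepeatabilitySummary:
    """Mean, sample SD, RSD% and accuracy% of replicate determinations."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise ValueError(f"need at least 2 replicate values, got {v.size}")
    if nominal <= 0:
        raise ValueError(f"nominal concentration must be > 0, got {nominal}")
    mean = float(v.mean())
    sd = float(v.std(ddof=1))
    return RepeatabilitySummary(
        n=int(v.size),
        mean=mean,
        sd=sd,
        rsd_percent=100.0 * sd / mean,
        accuracy_percent=100.0 * mean / nominal,
        nominal=float(nominal),
    )


def standard_addition_estimate(
    added_concs: np.ndarray, responses: np.ndarray
) -> float:
    """Analyte concentration by the standard-addition method.

    Fits response = a + b * added and returns a/b, the magnitude of the
    x-intercept. Requires at least three addition levels including zero and
    a positive slope.
    """
    added = np.asarray(added_concs, dtype=float)
    resp = np.asarray(responses, dtype=float)
    if added.size < 3 or added.size != resp.size:
        raise ValueError("need >= 3 addition levels with matching responses")
    if not np.any(added == 0):
        raise ValueError("addition levels must include zero (the unspiked sample)")
    fit = stats.linregress(added, resp)
    if fit.slope <= 0:
        raise ValueError(f"standard-addition slope must be > 0, got {fit.slope}")
    return float(fit.intercept / fit.slope)
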