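"""LASSO regression of consciousness scores on FC features.

The model is min_w ||y - Xw||_2^2 + k ||w||_1 on fold-standardized
features.  Evaluation uses nested leave-one-out cross-validation: the
outer loop holds out one PATIENT (both their scans), the inner loop runs
leave-one-patient-out over the training patients to grid-search the
penalty k, the model is refit on all training scans with the chosen k and
the held-out patient's scans are predicted.  Out-of-sample quality is
summarized by Pearson CC, MSE and R^2.

Discriminative features are those whose |w| exceeds the mean |w| over all
coefficients; they are reported with region-pair names and each feature's
marginal Pearson correlation with the score (raw two-sided p-values).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import Lasso

__all__ = [
    "LassoModel",
    "lasso_fit",
    "lasso_path_kmax",
    "default_k_grid",
    "nested_loocv",
    "regression_metrics",
    "select_features",
]


@dataclass
class LassoModel:
    coef: np.ndarray        # on the standardized-feature scale
    intercept: float        # in y units (y is not standardized)
    penalty: float          # k of the ||.||_1 term
    feature_mean: np.ndarray
    feature_scale: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X) - self.feature_mean) / self.feature_scale
        return Z @ self.coef + self.intercept


def _standardize(X):
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    const = sd == 0
    if const.any():
        warnings.warn(
            f"{int(const.sum())} constant feature column(s); their"
            " coefficients are fixed at zero"
        )
    sd = np.where(const, 1.0, sd)
    return (X - mu) / sd, mu, sd


def lasso_fit(X: np.ndarray, y: np.ndarray, k: float) -> LassoModel:
    """Minimize ||y - Xw||_2^2 + k||w||_1 on standardized features.

    The solver is coordinate descent (scikit-learn's Lasso) with its
    objective (1/2n)||y - Xw||^2 + alpha||w||_1 mapped via
    alpha = k / (2n).  Deterministic given the inputs.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if X.ndim != 2 or X.shape[0] != len(y):
        raise ValueError("X rows must match len(y)")
    if X.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    if k < 0:
        raise ValueError("penalty k must be >= 0")
    Z, mu, sd = _standardize(X)
    y_mean = float(y.mean())
    yc = y - y_mean
    if k == 0:
        coef, *_ = np.linalg.lstsq(Z, yc, rcond=None)
    else:
        n = X.shape[0]
        est = Lasso(
            alpha=k / (2.0 * n),
            fit_intercept=False,
            max_iter=50_000,
            tol=1e-10,
        )
        est.fit(Z, yc)
        coef = est.coef_.astype(np.float64)
    return LassoModel(
        coef=coef,
        intercept=y_mean,
        penalty=float(k),
        feature_mean=mu,
        feature_scale=sd,
    )


def lasso_path_kmax(X: np.ndarray, y: np.ndarray) -> float:
    """Smallest k that forces w = 0: k_max = 2 max|Z^T (y - mean(y))| on
    standardized features (subgradient condition of the ||.||_2^2 + k||.||_1
    objective)."""
    Z, _, _ = _standardize(np.asarray(X, dtype=np.float64))
    yc = np.asarray(y, dtype=np.float64) - np.mean(y)
    return float(2.0 * np.max(np.abs(Z.T @ yc)))


def default_k_grid(X, y, num: int = 30) -> np.ndarray:
    """Log-spaced penalties spanning [1e-3, 1] * k_max."""
    kmax = lasso_path_kmax(X, y)
    if kmax == 0:
        return np.array([0.0])
    return np.geomspace(1e-3 * kmax, kmax, num=num)


# ---------------------------------------------------------------------------
# nested LOOCV

@dataclass
class LoocvResult:
    predictions: pd.DataFrame  # patient_id, timepoint, y_true, y_pred, fold_k
    metrics: dict              # cc, mse, r2
    chosen_k: dict             # patient_id -> k
    fold_models: dict          # patient_id -> LassoModel trained without them


def nested_loocv(
    X: np.ndarray,
    y: np.ndarray,
    patient_ids: np.ndarray,
    timepoints: np.ndarray | None = None,
    k_grid=None,
) -> LoocvResult:
    """Nested leave-one-patient-out cross-validation.

    Outer loop: each patient's scans form the test set.  Inner loop:
    leave-one-patient-out over the remaining patients; the penalty
    minimizing the mean validation squared error is chosen, the model is
    refit on all training scans, and the held-out scans are predicted.
    The held-out patient never influences standardization, fitting or the
    penalty choice.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    patient_ids = np.asarray(patient_ids)
    if timepoints is None:
        timepoints = np.array(["scan"] * len(y))
    patients = pd.unique(patient_ids)
    if len(patients) < 4:
        raise ValueError("nested LOOCV needs at least 4 patients")
    if k_grid is None:
        k_grid = default_k_grid(X, y)
    k_grid = np.asarray(list(k_grid), dtype=np.float64)
    if k_grid.size == 0:
        raise ValueError("k_grid must be nonempty")

    rows = []
    chosen = {}
    fold_models = {}
    for test_p in patients:
        test_rows = patient_ids == test_p
        train_rows = ~test_rows
        Xtr, ytr, ptr = X[train_rows], y[train_rows], patient_ids[train_rows]
        inner_patients = pd.unique(ptr)
        errs = np.zeros(len(k_grid))
        with warnings.catch_warnings():
            # the smallest grid penalties on near-noiseless folds converge
            # slowly; their validation error is what disqualifies them
            from sklearn.exceptions import ConvergenceWarning

            warnings.simplefilter("ignore", ConvergenceWarning)
            for val_p in inner_patients:
                val = ptr == val_p
                for j, k in enumerate(k_grid):
                    m = lasso_fit(Xtr[~val], ytr[~val], k)
                    errs[j] += float(
                        np.mean((m.predict(Xtr[val]) - ytr[val]) ** 2)
                    )
        best_k = float(k_grid[int(np.argmin(errs))])
        chosen[test_p] = best_k
        model = lasso_fit(Xtr, ytr, best_k)
        fold_models[test_p] = model
        preds = model.predict(X[test_rows])
        for tp, yt, yp in zip(timepoints[test_rows], y[test_rows], preds):
            rows.append(
                {
                    "patient_id": test_p,
                    "timepoint": tp,
                    "y_true": float(yt),
                    "y_pred": float(yp),
                    "fold_k": best_k,
                }
            )
    pred_df = pd.DataFrame(rows)
    metrics = regression_metrics(
        pred_df["y_true"].to_numpy(), pred_df["y_pred"].to_numpy()
    )
    return LoocvResult(
        predictions=pred_df, metrics=metrics, chosen_k=chosen,
        fold_models=fold_models,
    )


def regression_metrics(y_true, y_pred) -> dict:
    """Pearson CC between prediction and truth, MSE, and R^2 = 1 -
    SS_res/SS_tot.  CC is reported as nan (flagged) for a constant
    prediction; constant truth is an error."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if len(y_true) != len(y_pred):
        raise ValueError("length mismatch")
    if len(y_true) < 3:
        raise ValueError("need at least 3 values")
    if np.std(y_true) == 0:
        raise ValueError("zero-variance y_true: CC undefined")
    if np.std(y_pred) == 0:
        cc = float("nan")
        warnings.warn("constant prediction: CC undefined, reported as nan")
    else:
        cc = float(stats.pearsonr(y_true, y_pred)[0])
    mse = float(np.mean((y_true - y_pred) ** 2))
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    return {"cc": cc, "mse": mse, "r2": 1.0 - ss_res / ss_tot}


def select_features(
    model: LassoModel,
    region_pair_names=None,
    X: np.ndarray | None = None,
    y: np.ndarray | None = None,
) -> pd.DataFrame:
    """Features with |w| above the mean |w| over ALL coefficients, ranked
    by |w|; with X and y given, each selected feature's marginal Pearson
    correlation with the score and its (uncorrected, two-sided) p-value
    are included."""
    w = np.asarray(model.coef)
    t = np.mean(np.abs(w))
    idx = np.nonzero(np.abs(w) > t)[0]
    if len(idx) == 0:
        warnings.warn("all coefficients at or below threshold: empty selection")
    rows = []
    for i in idx:
        row = {"feature_index": int(i), "w": float(w[i])}
        if region_pair_names is not None:
            row["feature_name"] = region_pair_names[i]
        if X is not None and y is not None:
            xi = np.asarray(X)[:, i]
            if np.std(xi) == 0:
                row["cc"], row["p_value"] = float("nan"), float("nan")
            else:
                r, p = stats.pearsonr(xi, np.asarray(y))
                row["cc"], row["p_value"] = float(r), float(p)
        rows.append(row)
    df = pd.DataFrame(rows)
    if len(df):
        df = df.reindex(df["w"].abs().sort_values(ascending=False).index)
        df = df.reset_index(drop=True)
    return df
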