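"""OLS and coordinate-descent elastic-net fitting with repeated-split eval.

The elastic net minimizes

    (1 / 2n) * sum_i (y_i - b - x_i . w)^2
        + alpha * (l1_ratio * ||w||_1 + (1 - l1_ratio) / 2 * ||w||_2^2)

by cyclic coordinate descent with soft-thresholding. Features are
standardized internally by default and coefficients reported on the
original scale; the intercept is never penalized.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from clockaudit.io import ClockAuditError, ClockModel

logger = logging.getLogger(__name__)

#: named penalty presets; "ols_like" makes the EN behave like OLS,
#: "lasso_heavy" uses an 0.8/0.2 L1/L2 mix, "under_tuned" over-penalizes
#: to expose shrinkage under multicollinearity
PRESETS = {
    "ols_like": {"alpha": 0.001, "l1_ratio": 0.5},
    "lasso_heavy": {"alpha": 0.01, "l1_ratio": 0.8},
    # pure-L1 limit: any L2 share splits weight across exactly collinear
    # columns instead of zeroing one of them
    "under_tuned": {"alpha": 5.0, "l1_ratio": 1.0},
}


@dataclass(frozen=True)
class ENConfig:
    """Elastic-net hyperparameters and solver settings."""

    alpha: float = 0.01
    l1_ratio: float = 0.5
    max_iter: int = 10_000
    tol: float = 1e-6
    standardize: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.alpha < 0:
            raise ClockAuditError("alpha must be >= 0")
        if not 0.0 <= self.l1_ratio <= 1.0:
            raise ClockAuditError("l1_ratio must be in [0, 1]")
        if self.tol <= 0:
            raise ClockAuditError("tol must be > 0")

    @classmethod
    def preset(cls, name: str, **overrides) -> "ENConfig":
        if name not in PRESETS:
            raise ClockAuditError(f"unknown preset {name!r}; have {sorted(PRESETS)}")
        return cls(**{**PRESETS[name], **overrides})


@dataclass
class FitResult:
    """Fitted linear model with training diagnostics."""

    weights: dict[str, float]
    intercept: float
    objective_path: list[float] = field(default_factory=list)
    converged: bool = True
    method: str = "ols"
    split_scheme: str | None = None

    @property
    def n_selected(self) -> int:
        return sum(1 for w in self.weights.values() if w != 0.0)

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        w = np.array([self.weights.get(c, 0.0) for c in X.columns])
        return self.intercept + X.to_numpy(dtype=float) @ w

    def to_clock_model(self, name: str) -> ClockModel:
        return ClockModel(name=name, intercept=self.intercept,
                          coefficients={c: w for c, w in self.weights.items()
                                        if w != 0.0})


@dataclass
class EvalResult:
    """Held-out evaluation metrics."""

    mae: float
    pearson_r: float
    residuals: pd.Series   # predicted - actual, per test sample

    def __post_init__(self) -> None:
        if self.mae < 0:
            raise ClockAuditError("MAE must be >= 0")


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"x{j}" for j in range(X.shape[1])])


def _find_collinear_pair(Xc: np.ndarray, cols: list[str]) -> tuple[str, str] | None:
    # report the most correlated column pair as the offending one
    sd = Xc.std(axis=0)
    ok = sd > 0
    if ok.sum() >= 2:
        sub = Xc[:, ok] / sd[ok]
        corr = np.abs(sub.T @ sub) / len(Xc)
        np.fill_diagonal(corr, 0.0)
        i, j = np.unravel_index(np.argmax(corr), corr.shape)
        names = [c for c, keep in zip(cols, ok) if keep]
        return names[i], names[j]
    return None


def fit_ols(X, y) -> FitResult:
    """Ordinary least squares via the normal equations (lstsq).

    Errors on rank-deficient designs, naming the most collinear column pair:
    OLS is not identifiable under exact collinearity.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    if n <= p + 1:
        raise ClockAuditError(
            f"OLS needs n_samples > n_features + 1 (got {n} <= {p + 1}); "
            "use ridge or the elastic net"
        )
    A = np.column_stack([np.ones(n), X.to_numpy(dtype=float)])
    if np.linalg.matrix_rank(A) < p + 1:
        pair = _find_collinear_pair(X.to_numpy() - X.to_numpy().mean(0),
                                    list(X.columns))
        detail = f" (e.g. columns {pair[0]!r} and {pair[1]!r})" if pair else ""
        raise ClockAuditError(f"design is rank deficient{detail}; OLS is "
                              "non-identifiable")
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    weights = dict(zip(X.columns, coef[1:]))
    return FitResult(weights=weights, intercept=float(coef[0]), method="ols")


def _soft_threshold(z: float, gamma: float) -> float:
    return np.sign(z) * max(abs(z) - gamma, 0.0)


def en_objective(Xs: np.ndarray, y_centered: np.ndarray, w: np.ndarray,
                 alpha: float, l1_ratio: float) -> float:
    n = len(y_centered)
    resid = y_centered - Xs @ w
    return float(
        0.5 / n * resid @ resid
        + alpha * (l1_ratio * np.abs(w).sum() + 0.5 * (1 - l1_ratio) * w @ w)
    )


def fit_elastic_net(X, y, config: ENConfig = ENConfig()) -> FitResult:
    """Elastic net via cyclic coordinate descent with soft-thresholding.

    Convergence: max absolute coefficient update < ``config.tol``. On
    non-convergence the result is returned with ``converged=False`` and a
    warning. The per-sweep objective path is recorded in
    ``FitResult.objective_path`` (non-increasing by construction).
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    Xv = X.to_numpy(dtype=float)
    x_mean = Xv.mean(axis=0)
    y_mean = y.mean()
    Xc = Xv - x_mean
    yc = y - y_mean

    if config.standardize:
        scale = Xv.std(axis=0)
    else:
        scale = np.ones(p)
    zero_var = scale == 0
    scale_safe = np.where(zero_var, 1.0, scale)
    Xs = Xc / scale_safe

    # per-coordinate curvature of the quadratic part: (1/n) sum x_j^2
    sq = (Xs ** 2).sum(axis=0) / n
    denom = sq + config.alpha * (1.0 - config.l1_ratio)
    gamma = config.alpha * config.l1_ratio

    w = np.zeros(p)
    resid = yc.copy()
    path: list[float] = []
    converged = False
    for _ in range(config.max_iter):
        max_delta = 0.0
        for j in range(p):
            if zero_var[j] or denom[j] == 0.0:
                continue
            xj = Xs[:, j]
            rho = (xj @ resid) / n + sq[j] * w[j]
            w_new = _soft_threshold(rho, gamma) / denom[j]
            delta = w_new - w[j]
            if delta != 0.0:
                resid -= delta * xj
                w[j] = w_new
                max_delta = max(max_delta, abs(delta))
        path.append(en_objective(Xs, yc, w, config.alpha, config.l1_ratio))
        if max_delta < config.tol:
            converged = True
            break
    if not converged:
        warnings.warn(
            f"elastic net did not converge in {config.max_iter} sweeps "
            f"(tol={config.tol})", stacklevel=2)

    w_orig = w / scale_safe
    w_orig[zero_var] = 0.0
    intercept = float(y_mean - w_orig @ x_mean)
    return FitResult(weights=dict(zip(X.columns, w_orig)), intercept=intercept,
                     objective_path=path, converged=converged, method="elastic_net")


def evaluate(pred: np.ndarray, y: np.ndarray,
             index: pd.Index | None = None) -> EvalResult:
    """MAE, Pearson r and residuals (predicted - actual)."""
    pred = np.asarray(pred, dtype=float)
    y = np.asarray(y, dtype=float)
    mae = float(np.mean(np.abs(pred - y)))
    if np.std(pred) == 0 or np.std(y) == 0:
        r = 0.0
    else:
        r = float(np.corrcoef(pred, y)[0, 1])
    residuals = pd.Series(pred - y, index=index)
    return EvalResult(mae=mae, pearson_r=r, residuals=residuals)


def repeated_split_eval(
    X, y, fitter, n_repeats: int = 5, test_fraction: float = 0.2,
    seed: int = 0,
) -> tuple[list[EvalResult], EvalResult]:
    """Repeat independent train/test splits; report per-repeat and pooled metrics.

    ``fitter`` maps ``(X_train, y_train) -> FitResult``. Deterministic under a
    fixed seed.
    """
    X = _as_frame(X)
    y = np.asarray(y, dtype=float)
    if n_repeats < 1:
        raise ClockAuditError("n_repeats must be >= 1")
    if not 0.0 < test_fraction < 1.0:
        raise ClockAuditError("test_fraction must be in (0, 1)")
    n = len(X)
    n_test = int(round(n * test_fraction))
    if n_test < 2:
        raise ClockAuditError(f"test fold would have {n_test} (< 2) samples")
    rng = np.random.default_rng(seed)
    per_repeat: list[EvalResult] = []
    pooled_pred: list[np.ndarray] = []
    pooled_y: list[np.ndarray] = []
    pooled_idx: list[pd.Index] = []
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        test_idx, train_idx = perm[:n_test], perm[n_test:]
        fit = fitter(X.iloc[train_idx], y[train_idx])
        pred = fit.predict(X.iloc[test_idx])
        per_repeat.append(evaluate(pred, y[test_idx], X.index[test_idx]))
        pooled_pred.append(pred)
        pooled_y.append(y[test_idx])
        pooled_idx.append(X.index[test_idx])
    pooled = evaluate(np.concatenate(pooled_pred), np.concatenate(pooled_y),
                      pooled_idx[0].append(pooled_idx[1:]) if n_repeats > 1
                      else pooled_idx[0])
    return per_repeat, pooled


@dataclass
class UnderTunedDemo:
    """Side-by-side EN vs OLS comparison on the 5-CpG archetype block."""

    en_fit: FitResult
    ols_fit: FitResult
    en_pred: pd.Series
    ols_pred: pd.Series
    ages: pd.Series
    zeroed_collinear: list[str]          # collinear CpGs the EN drove to 0
    ols_columns: list[str]               # columns used for the OLS fit
    slope_recovery: pd.DataFrame         # per-CpG beta-on-age slope and SE

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age": self.ages, "en_pred": self.en_pred,
                             "ols_pred": self.ols_pred})


def _beta_on_age_slopes(block: pd.DataFrame, ages: np.ndarray) -> pd.DataFrame:
    """Univariate OLS of each CpG's beta on age: slope and its standard error."""
    rows = []
    ac = ages - ages.mean()
    sxx = float(ac @ ac)
    n = len(ages)
    for col in block.columns:
        b = block[col].to_numpy(dtype=float)
        slope = float(ac @ (b - b.mean())) / sxx
        resid = (b - b.mean()) - slope * ac
        se = float(np.sqrt((resid @ resid) / (n - 2) / sxx))
        rows.append({"cpg": col, "slope": slope, "se": se})
    return pd.DataFrame(rows).set_index("cpg")


def under_tuned_en_demo(cohort, config: ENConfig | None = None) -> UnderTunedDemo:
    """Fit an over-penalized EN and an OLS on the archetype block.

    EN runs on all five archetype CpGs; OLS runs on a full-rank subset
    (dropping the exactly collinear duplicate when present). The record lists
    which of the three collinear CpGs EN zeroed, plus per-CpG recovery of the
    generative beta-on-age slope.
    """
    config = config or ENConfig.preset("under_tuned")
    arch_ids = cohort.cpgs_of("archetype_1", "archetype_2", "archetype_3",
                              "archetype_4", "archetype_5")
    if len(arch_ids) != 5:
        raise ClockAuditError("cohort does not contain the 5-CpG archetype block")
    block = cohort.beta.data[arch_ids]
    ages = cohort.ages
    labels = cohort.archetype_labels[arch_ids]

    en_fit = fit_elastic_net(block, ages, config)

    by_arch = {lab: cid for cid, lab in labels.items()}
    c1, c3 = block[by_arch["archetype_1"]], block[by_arch["archetype_3"]]
    exactly_collinear = bool(np.allclose(c3.to_numpy(), 0.5 * c1.to_numpy()))
    ols_cols = [c for c in arch_ids
                if not (exactly_collinear and labels[c] == "archetype_3")]
    ols_fit = fit_ols(block[ols_cols], ages)

    collinear_ids = [by_arch[k] for k in ("archetype_1", "archetype_2",
                                          "archetype_3")]
    zeroed = [c for c in collinear_ids if en_fit.weights.get(c, 0.0) == 0.0]

    age_corr_cols = [by_arch["archetype_1"], by_arch["archetype_2"]]
    slope_recovery = _beta_on_age_slopes(block[age_corr_cols], ages)

    idx = cohort.beta.data.index
    return UnderTunedDemo(
        en_fit=en_fit, ols_fit=ols_fit,
        en_pred=pd.Series(en_fit.predict(block), index=idx),
        ols_pred=pd.Series(ols_fit.predict(block[ols_cols]), index=idx),
        ages=pd.Series(ages, index=idx),
        zeroed_collinear=zeroed, ols_columns=ols_cols,
        slope_recovery=slope_recovery,
    )
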