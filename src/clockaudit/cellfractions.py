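"""Leukocyte-fraction deconvolution and collinearity (VIF) auditing.

Deconvolution solves, per sample, nonnegative least squares against the
cell-type reference profiles followed by sum-to-one renormalization — a
documented stand-in for reference-based deconvolution tools; an alternative
estimator can be plugged via the ``solver`` hook.

The VIF audit regresses each model CpG on the other model CpGs (baseline
VIF = 1/(1-R^2)), then re-runs the regression with one cell-type fraction
appended; the per-cell-type VIF change is binned by configurable thresholds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from clockaudit.io import BetaMatrix, ClockAuditError, ClockModel

logger = logging.getLogger(__name__)

DEFAULT_THRESHOLDS = (0.025, 0.05, 0.1)
BIN_LABELS = ("small", "moderate", "large", "very large")

#: R^2 above this is treated as perfect collinearity -> infinite VIF sentinel
_R2_CAP = 1.0 - 1e-12


def _nnls_solver(A: np.ndarray, b: np.ndarray) -> np.ndarray:
    x, _ = optimize.nnls(A, b)
    return x


def deconvolve(beta: BetaMatrix, reference: pd.DataFrame,
               solver=_nnls_solver) -> tuple[pd.DataFrame, pd.Series]:
    """Estimate per-sample cell fractions from bulk beta values.

    ``reference`` is cell_type x CpG. Returns ``(fractions, residual_norm)``
    with fractions on the simplex (nonnegative, summing to 1 per sample).
    """
    shared = [c for c in reference.columns if c in beta.data.columns]
    n_cells = len(reference)
    if len(shared) < n_cells:
        raise ClockAuditError(
            f"only {len(shared)} reference CpGs shared with the matrix; "
            f"need >= {n_cells}")
    R = reference[shared].to_numpy(dtype=float)
    if np.linalg.matrix_rank(R) < n_cells:
        # name rows loading on the null space of R R^T
        _, _, vt = np.linalg.svd(R @ R.T)
        null = np.abs(vt[-1])
        dep = [reference.index[i] for i in np.argsort(null)[::-1][:2]]
        raise ClockAuditError(f"degenerate reference: dependent rows {dep}")
    A = R.T                                      # CpGs x cell types
    B = beta.data[shared].to_numpy(dtype=float)
    fractions = np.empty((len(B), n_cells))
    resid = np.empty(len(B))
    for i, b in enumerate(B):
        x = solver(A, b)
        total = x.sum()
        fractions[i] = x / total if total > 0 else np.full(n_cells, 1.0 / n_cells)
        resid[i] = float(np.linalg.norm(A @ x - b))
    frac = pd.DataFrame(fractions, index=beta.data.index, columns=reference.index)
    return frac, pd.Series(resid, index=beta.data.index, name="residual_norm")


def fraction_correlations(beta: BetaMatrix, fractions: pd.DataFrame,
                          report_threshold: float = 0.4
                          ) -> tuple[pd.DataFrame, dict]:
    """Spearman rho per (CpG, cell type), with a low-correlation summary.

    Constant fraction columns are flagged (rho = NaN) and excluded from the
    summary, which reports the share of CpGs whose max |rho| over cell types
    stays below ``report_threshold``.
    """
    common = fractions.index.intersection(beta.data.index)
    if len(common) < 5:
        raise ClockAuditError(f"need >= 5 samples in common (got {len(common)})")
    B = beta.data.loc[common]
    F = fractions.loc[common]
    constant = [c for c in F.columns if F[c].nunique() <= 1]
    if constant:
        logger.warning("constant fraction columns excluded from summary: %s",
                       constant)
    rho = pd.DataFrame(index=B.columns, columns=F.columns, dtype=float)
    for cell in F.columns:
        if cell in constant:
            rho[cell] = np.nan
            continue
        r, _ = stats.spearmanr(B.to_numpy(), F[cell].to_numpy())
        # spearmanr over a matrix returns the full correlation matrix
        if B.shape[1] == 1:
            rho[cell] = [float(r)]
        else:
            rho[cell] = np.asarray(r)[:-1, -1]
    usable = rho.drop(columns=constant) if constant else rho
    max_abs = usable.abs().max(axis=1)
    summary = {
        "n_cpgs": int(len(rho)),
        "report_threshold": report_threshold,
        "share_below_threshold": float((max_abs < report_threshold).mean()),
        "constant_cell_types": constant,
    }
    return rho, summary


def _r_squared(X: np.ndarray, y: np.ndarray) -> float:
    """R^2 of y ~ 1 + X via least squares."""
    A = np.column_stack([np.ones(len(y)), X])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    tss = float(((y - y.mean()) ** 2).sum())
    if tss == 0:
        return 0.0
    return 1.0 - float((resid ** 2).sum()) / tss


def bin_delta(delta: float, thresholds=DEFAULT_THRESHOLDS) -> str:
    """Bin a VIF change: small < t0 <= moderate < t1 <= large < t2 <= very large."""
    t0, t1, t2 = thresholds
    if delta < t0:
        return BIN_LABELS[0]
    if delta < t1:
        return BIN_LABELS[1]
    if delta < t2:
        return BIN_LABELS[2]
    return BIN_LABELS[3]


@dataclass
class VIFAudit:
    """Per-CpG baseline VIF, per-cell-type VIF changes, and their bins."""

    baseline: pd.Series          # per CpG; np.inf marks perfect collinearity
    delta: pd.DataFrame          # CpG x cell type VIF change
    bins: pd.DataFrame           # CpG x cell type bin label (NaN if infinite)
    n_infinite: int
    thresholds: tuple[float, float, float]

    def bin_distribution(self) -> pd.DataFrame:
        """Share of finite CpGs per bin, per cell type."""
        out = {}
        for cell in self.bins.columns:
            counts = self.bins[cell].value_counts(dropna=True)
            total = counts.sum()
            out[cell] = {lab: (counts.get(lab, 0) / total if total else np.nan)
                         for lab in BIN_LABELS}
        return pd.DataFrame(out).T[list(BIN_LABELS)]


def vif_audit(beta: BetaMatrix, fractions: pd.DataFrame,
              thresholds=DEFAULT_THRESHOLDS,
              max_cpgs: int | None = None, seed: int = 0) -> VIFAudit:
    """Baseline-vs-augmented VIF per model CpG and cell type.

    Baseline VIF_j uses the other model CpGs as predictors (no fractions,
    no age); the augmented run appends one cell-type fraction at a time.
    When n_samples <= n_CpGs + 1 the audit runs on a seeded random CpG
    subsample (size ``min(p, n // 5)`` unless ``max_cpgs`` is given), logged.
    """
    t = tuple(float(x) for x in thresholds)
    if len(t) != 3 or not (t[0] < t[1] < t[2]):
        raise ClockAuditError("thresholds must be 3 ascending values")
    common = fractions.index.intersection(beta.data.index)
    B = beta.data.loc[common]
    F = fractions.loc[common]
    n, p = B.shape
    cpgs = list(B.columns)
    if n <= p + 1:
        k = max_cpgs if max_cpgs is not None else max(2, min(p, n // 5))
        rng = np.random.default_rng(seed)
        cpgs = sorted(rng.choice(cpgs, size=k, replace=False))
        logger.warning("n_samples (%d) <= n_CpGs + 1 (%d); auditing a random "
                       "subsample of %d CpGs", n, p + 1, k)
        B = B[cpgs]
    Bv = B.to_numpy(dtype=float)
    Fv = F.to_numpy(dtype=float)

    baseline = {}
    delta = pd.DataFrame(index=cpgs, columns=F.columns, dtype=float)
    n_inf = 0
    for j, cpg in enumerate(cpgs):
        others = np.delete(Bv, j, axis=1)
        y = Bv[:, j]
        r2 = _r_squared(others, y)
        if r2 >= _R2_CAP:
            baseline[cpg] = np.inf
            delta.loc[cpg] = np.nan
            n_inf += 1
            continue
        vif0 = 1.0 / (1.0 - r2)
        baseline[cpg] = vif0
        for k_, cell in enumerate(F.columns):
            r2a = _r_squared(np.column_stack([others, Fv[:, k_]]), y)
            if r2a >= _R2_CAP:
                delta.at[cpg, cell] = np.nan
                continue
            delta.at[cpg, cell] = 1.0 / (1.0 - r2a) - vif0
    bins = delta.map(lambda d: bin_delta(d, t) if np.isfinite(d) else np.nan)
    return VIFAudit(baseline=pd.Series(baseline, name="baseline_vif"),
                    delta=delta, bins=bins, n_infinite=n_inf, thresholds=t)


def model_cpg_beta(model: ClockModel, beta: BetaMatrix) -> BetaMatrix:
    """Restrict a beta matrix to the CpGs a model selects."""
    cols = [c for c in model.coefficients if c in beta.data.columns]
    if not cols:
        raise ClockAuditError(f"model {model.name!r}: no CpGs in the matrix")
    return BetaMatrix(beta.data[cols])


def compare_models_vif(models: list[ClockModel], beta: BetaMatrix,
                       fractions: pd.DataFrame,
                       thresholds=DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Per-model share of CpGs per VIF-change bin per cell type.

    Long-format frame with columns ``model, cell_type, bin, share`` — the
    machine-readable clock-comparison table.
    """
    rows = []
    for model in models:
        audit = vif_audit(model_cpg_beta(model, beta), fractions, thresholds)
        dist = audit.bin_distribution()
        for cell in dist.index:
            for lab in BIN_LABELS:
                rows.append({"model": model.name, "cell_type": cell,
                             "bin": lab, "share": dist.at[cell, lab]})
    return pd.DataFrame(rows)
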