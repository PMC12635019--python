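"""Coefficient-sign coherence audit of linear clock models.

A model CpG is *misaligned* when the sign of its model coefficient opposes
the sign of its univariate Pearson correlation with age in a reference
cohort. The audit reports the misaligned share of features and of total
absolute model weight, supports rectification (dropping or sign-constraining
misaligned features), and measures the accuracy-vs-separation trade-off the
rectification induces.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from clockaudit.io import BetaMatrix, ClockAuditError, ClockModel, apply_clock
from clockaudit.models import ENConfig, fit_elastic_net

logger = logging.getLogger(__name__)


def univariate_stats(beta: BetaMatrix, metadata: pd.DataFrame,
                     subset: str = "healthy") -> pd.DataFrame:
    """Per-CpG Pearson correlation of beta with age, plus mean/SD.

    ``subset`` is ``healthy`` (healthy-labeled samples only, the default
    reference convention) or ``all``. Zero-variance CpGs get r = 0 and a
    ``degenerate`` flag. Returns a frame indexed by CpG with columns
    ``pearson_r, mean_beta, sd_beta, n_used, degenerate``.
    """
    if subset not in ("healthy", "all"):
        raise ClockAuditError(f"unknown subset {subset!r}")
    meta = metadata.loc[metadata.index.intersection(beta.data.index)]
    if subset == "healthy":
        meta = meta[meta["status"] == "healthy"]
    if len(meta) < 3:
        raise ClockAuditError(f"need >= 3 samples after subsetting (got {len(meta)})")
    ages = meta["age"].to_numpy(dtype=float)
    if np.ptp(ages) == 0:
        raise ClockAuditError("constant ages: correlation undefined")

    B = beta.data.loc[meta.index].to_numpy(dtype=float)
    n = len(meta)
    ac = ages - ages.mean()
    bc = B - B.mean(axis=0)
    sd_b = B.std(axis=0, ddof=1)
    sd_a = ages.std(ddof=1)
    cov = bc.T @ ac / (n - 1)
    degenerate = sd_b == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(degenerate, 0.0, cov / (sd_b * sd_a))
    return pd.DataFrame({
        "pearson_r": np.clip(r, -1.0, 1.0),
        "mean_beta": B.mean(axis=0),
        "sd_beta": sd_b,
        "n_used": n,
        "degenerate": degenerate,
    }, index=beta.data.columns)


@dataclass
class CoherenceReport:
    """Per-model misalignment statistics plus the per-CpG audit table.

    ``per_cpg`` columns: ``coefficient, max_norm_coefficient, univariate_r,
    flag`` with flag in {coherent, misaligned, neutral, unmatched}.
    """

    model_name: str
    n_audited: int
    n_misaligned: int
    n_coherent: int
    n_neutral: int
    n_unmatched: int
    total_abs_weight: float
    misaligned_abs_weight: float
    per_cpg: pd.DataFrame
    neutral_band: float

    @property
    def pct_misaligned(self) -> float:
        return 100.0 * self.n_misaligned / self.n_audited

    @property
    def pct_weight_misaligned(self) -> float:
        return 100.0 * self.misaligned_abs_weight / self.total_abs_weight

    def misaligned_cpgs(self) -> list[str]:
        flag = self.per_cpg["flag"]
        return list(self.per_cpg.index[flag == "misaligned"])

    def summary(self) -> dict:
        return {
            "model": self.model_name,
            "n_audited": self.n_audited,
            "n_misaligned": self.n_misaligned,
            "n_coherent": self.n_coherent,
            "n_neutral": self.n_neutral,
            "n_unmatched": self.n_unmatched,
            "pct_misaligned": self.pct_misaligned,
            "pct_weight_misaligned": self.pct_weight_misaligned,
            "neutral_band": self.neutral_band,
        }


def audit_model(model: ClockModel, stats_table: pd.DataFrame,
                neutral_band: float = 0.0) -> CoherenceReport:
    """Audit a clock model's coefficient signs against univariate correlations.

    A CpG is misaligned iff ``sign(coefficient) * sign(r) < 0`` and
    ``|r| >= neutral_band``; coherent iff the signs agree under the same
    band; neutral when ``|r| < neutral_band`` or r is exactly 0. CpGs absent
    from the stats table are ``unmatched`` and excluded from all
    denominators. Coefficients are max-normalized by the largest
    ``|coefficient|`` among audited CpGs.
    """
    if neutral_band < 0:
        raise ClockAuditError("neutral_band must be >= 0")
    if model.n_features == 0:
        raise ClockAuditError(f"model {model.name!r} has no nonzero coefficients")
    rows = []
    for cpg, coef in model.coefficients.items():
        if cpg in stats_table.index:
            r = float(stats_table.at[cpg, "pearson_r"])
            prod = np.sign(coef) * np.sign(r)
            if abs(r) < neutral_band or r == 0.0:
                flag = "neutral"
            elif prod < 0:
                flag = "misaligned"
            else:
                flag = "coherent"
        else:
            r, flag = np.nan, "unmatched"
        rows.append({"cpg": cpg, "coefficient": coef, "univariate_r": r,
                     "flag": flag})
    per_cpg = pd.DataFrame(rows).set_index("cpg")
    audited = per_cpg[per_cpg["flag"] != "unmatched"]
    if audited.empty:
        raise ClockAuditError(
            f"model {model.name!r}: no overlap with the reference stats")
    max_abs = audited["coefficient"].abs().max()
    per_cpg["max_norm_coefficient"] = per_cpg["coefficient"] / max_abs
    per_cpg = per_cpg[["coefficient", "max_norm_coefficient", "univariate_r",
                       "flag"]]
    counts = per_cpg["flag"].value_counts()
    mis_mask = per_cpg["flag"] == "misaligned"
    return CoherenceReport(
        model_name=model.name,
        n_audited=len(audited),
        n_misaligned=int(counts.get("misaligned", 0)),
        n_coherent=int(counts.get("coherent", 0)),
        n_neutral=int(counts.get("neutral", 0)),
        n_unmatched=int(counts.get("unmatched", 0)),
        total_abs_weight=float(audited["coefficient"].abs().sum()),
        misaligned_abs_weight=float(per_cpg.loc[mis_mask, "coefficient"].abs().sum()),
        per_cpg=per_cpg,
        neutral_band=neutral_band,
    )


def rectify_model(
    model: ClockModel,
    stats_table: pd.DataFrame,
    mode: str = "drop",
    neutral_band: float = 0.0,
    beta: BetaMatrix | None = None,
    ages: pd.Series | None = None,
    refit_weights: bool = False,
) -> ClockModel:
    """Return a sign-coherent version of the model.

    ``drop`` removes misaligned CpGs and refits the intercept on the supplied
    training data (weights optionally refit by OLS on the coherent set);
    ``sign-constrained-refit`` refits every audited weight by bounded least
    squares with each weight constrained to the sign of its univariate r.
    The returned model re-audits with ``pct_misaligned == 0``.
    """
    report = audit_model(model, stats_table, neutral_band)
    if mode == "drop":
        drop = set(report.misaligned_cpgs())
        kept = {c: w for c, w in model.coefficients.items() if c not in drop}
        if not kept:
            raise ClockAuditError(f"model {model.name!r}: all features misaligned")
        intercept = model.intercept
        if beta is not None and ages is not None:
            cols = [c for c in kept if c in beta.data.columns]
            sub = beta.data[cols].to_numpy(dtype=float)
            y = ages.loc[beta.data.index].to_numpy(dtype=float)
            if refit_weights:
                A = np.column_stack([np.ones(len(sub)), sub])
                coef, *_ = np.linalg.lstsq(A, y, rcond=None)
                intercept = float(coef[0])
                kept = {**kept, **dict(zip(cols, coef[1:]))}
            else:
                w = np.array([kept[c] for c in cols])
                intercept = float(np.mean(y - sub @ w))
        return ClockModel(name=f"{model.name}_rectified", intercept=intercept,
                          coefficients=kept)
    if mode == "sign-constrained-refit":
        if beta is None or ages is None:
            raise ClockAuditError("sign-constrained refit needs beta and ages")
        cols = [c for c in model.coefficients if c in beta.data.columns]
        sub = beta.data[cols].to_numpy(dtype=float)
        y = ages.loc[beta.data.index].to_numpy(dtype=float)
        lo, hi = np.empty(len(cols)), np.empty(len(cols))
        for j, c in enumerate(cols):
            r = float(stats_table.at[c, "pearson_r"]) if c in stats_table.index else 0.0
            if r > 0:
                lo[j], hi[j] = 0.0, np.inf
            elif r < 0:
                lo[j], hi[j] = -np.inf, 0.0
            else:
                lo[j], hi[j] = -np.inf, np.inf
        Xc = sub - sub.mean(axis=0)
        yc = y - y.mean()
        sol = optimize.lsq_linear(Xc, yc, bounds=(lo, hi))
        weights = dict(zip(cols, sol.x))
        intercept = float(y.mean() - sol.x @ sub.mean(axis=0))
        if all(w == 0.0 for w in weights.values()):
            raise ClockAuditError("sign-constrained refit produced an empty model")
        return ClockModel(name=f"{model.name}_rectified", intercept=intercept,
                          coefficients=weights)
    raise ClockAuditError(f"unknown rectification mode {mode!r}")


@dataclass
class SeparationResult:
    """Healthy-vs-disease residual separation plus prediction accuracy."""

    mean_residual_healthy: float
    mean_residual_disease: float
    difference: float              # disease - healthy, years
    effect_size: float             # standardized mean difference (Cohen's d)
    u_statistic: float             # Mann-Whitney U (rank-based)
    p_value: float
    mae: float                     # |prediction - age| over all samples


def residual_separation(model: ClockModel, beta: BetaMatrix,
                        metadata: pd.DataFrame) -> SeparationResult:
    """Compare clock residuals (prediction - age) between status groups."""
    pred, _ = apply_clock(model, beta)
    meta = metadata.loc[beta.data.index]
    resid = pred - meta["age"]
    h = resid[meta["status"] == "healthy"].to_numpy()
    d = resid[meta["status"] == "disease"].to_numpy()
    if len(h) < 3 or len(d) < 3:
        raise ClockAuditError(
            f"both groups need >= 3 samples (healthy={len(h)}, disease={len(d)})")
    diff = float(d.mean() - h.mean())
    pooled_var = (((len(h) - 1) * h.var(ddof=1) + (len(d) - 1) * d.var(ddof=1))
                  / (len(h) + len(d) - 2))
    effect = diff / np.sqrt(pooled_var) if pooled_var > 0 else 0.0
    if np.ptp(np.concatenate([h, d])) == 0:
        u, p = len(h) * len(d) / 2.0, 1.0
    else:
        u, p = stats.mannwhitneyu(d, h, alternative="two-sided")
    return SeparationResult(
        mean_residual_healthy=float(h.mean()),
        mean_residual_disease=float(d.mean()),
        difference=diff, effect_size=float(effect),
        u_statistic=float(u), p_value=float(p),
        mae=float(np.abs(resid).mean()),
    )


@dataclass
class TradeoffResult:
    """Paired original-vs-rectified evaluation on held-out samples."""

    original: SeparationResult
    rectified: SeparationResult
    original_model: ClockModel
    rectified_model: ClockModel
    n_misaligned_dropped: int


def tradeoff_experiment(cohort, en_config: ENConfig | None = None,
                        test_fraction: float = 0.3,
                        neutral_band: float = 0.0,
                        seed: int = 0) -> TradeoffResult:
    """Train an EN clock, rectify it, and compare both on held-out samples.

    The EN is trained to predict age from all cohort CpGs using the healthy
    training samples; univariate reference correlations come from the same
    healthy training subset. Rectification drops misaligned features and
    refits the intercept. Both models are then evaluated (MAE and residual
    separation) on the held-out samples, healthy and diseased alike.
    """
    en_config = en_config or ENConfig(alpha=0.02, l1_ratio=0.5, tol=1e-5)
    meta = cohort.metadata
    rng = np.random.default_rng(seed)
    n = len(meta)
    perm = rng.permutation(n)
    n_test = int(round(n * test_fraction))
    test_ids = meta.index[perm[:n_test]]
    train_ids = meta.index[perm[n_test:]]
    train_healthy = [s for s in train_ids if meta.at[s, "status"] == "healthy"]

    X_train = cohort.beta.data.loc[train_healthy]
    y_train = meta.loc[train_healthy, "age"].to_numpy(dtype=float)
    fit = fit_elastic_net(X_train, y_train, en_config)
    original = fit.to_clock_model("en_clock")

    train_beta = BetaMatrix(X_train)
    stats_table = univariate_stats(train_beta, meta.loc[train_healthy],
                                   subset="healthy")
    rectified = rectify_model(original, stats_table, mode="drop",
                              neutral_band=neutral_band, beta=train_beta,
                              ages=meta["age"])
    report = audit_model(original, stats_table, neutral_band)

    test_beta = BetaMatrix(cohort.beta.data.loc[test_ids])
    sep_orig = residual_separation(original, test_beta, meta)
    sep_rect = residual_separation(rectified, test_beta, meta)
    return TradeoffResult(original=sep_orig, rectified=sep_rect,
                          original_model=original, rectified_model=rectified,
                          n_misaligned_dropped=report.n_misaligned)
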