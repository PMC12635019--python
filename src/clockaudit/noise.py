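"""Variability-based aging metrics: windowed SD/CV and noise trajectories.

Per CpG, samples are grouped into sliding age windows and summarized by
mean, unbiased SD and coefficient of variation. Loci with a stable mean but
rising SD are flagged; an aggregate noise score across CpGs is fitted by a
continuous piecewise-linear trajectory with free breakpoints searched
exhaustively on the window-midpoint grid.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from clockaudit.io import BetaMatrix, ClockAuditError

logger = logging.getLogger(__name__)

#: below this mean beta the CV is reported as undefined (NaN), not 0
DEFAULT_MEAN_FLOOR = 0.05


@dataclass
class NoiseProfile:
    """Windowed per-CpG noise metrics.

    ``table`` is long-format with columns ``cpg, midpoint, n, mean_beta,
    sd_beta, cv`` (cv NaN when the windowed mean is at or below the floor).
    """

    table: pd.DataFrame
    window_width: float
    step: float
    mean_floor: float

    @property
    def midpoints(self) -> np.ndarray:
        return np.sort(self.table["midpoint"].unique())

    def pivot(self, value: str) -> pd.DataFrame:
        """CpG x window-midpoint matrix of one metric."""
        return self.table.pivot(index="cpg", columns="midpoint", values=value)


def windowed_noise(beta: BetaMatrix, metadata: pd.DataFrame,
                   window_width: float = 6.0, step: float = 3.0,
                   min_per_window: int = 20,
                   mean_floor: float = DEFAULT_MEAN_FLOOR) -> NoiseProfile:
    """Sliding-window mean/SD/CV per CpG over age.

    Windows start at the youngest age and advance by ``step``; windows with
    fewer than ``min_per_window`` samples are skipped (logged). Errors when
    no window meets the floor.
    """
    meta = metadata.loc[beta.data.index]
    ages = meta["age"].to_numpy(dtype=float)
    B = beta.data.to_numpy(dtype=float)
    lo, hi = ages.min(), ages.max()
    starts = np.arange(lo, hi - window_width + step * 0.5 + 1e-9, step)
    rows = []
    skipped = 0
    for start in starts:
        in_win = (ages >= start) & (ages < start + window_width)
        n_win = int(in_win.sum())
        if n_win < min_per_window:
            skipped += 1
            continue
        sub = B[in_win]
        mean = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            cv = np.where(mean > mean_floor, sd / mean, np.nan)
        mid = start + window_width / 2.0
        for cpg, m, s, c in zip(beta.data.columns, mean, sd, cv):
            rows.append({"cpg": cpg, "midpoint": mid, "n": n_win,
                         "mean_beta": m, "sd_beta": s, "cv": c})
    if skipped:
        logger.info("skipped %d windows below the %d-sample floor",
                    skipped, min_per_window)
    if not rows:
        raise ClockAuditError(
            "no age window met the sample floor; widen the windows")
    return NoiseProfile(table=pd.DataFrame(rows), window_width=window_width,
                        step=step, mean_floor=mean_floor)


def flag_stable_mean_rising_sd(profile: NoiseProfile,
                               mean_slope_tol: float = 0.001,
                               sd_trend_threshold: float = 0.5) -> pd.DataFrame:
    """Flag CpGs whose windowed mean is flat but windowed SD trends upward.

    stable_mean: |OLS slope of mean vs midpoint| <= ``mean_slope_tol``.
    rising_sd: Spearman rho of SD vs midpoint >= ``sd_trend_threshold``.
    Returns a per-CpG frame with both flags plus the underlying statistics.
    """
    means = profile.pivot("mean_beta")
    sds = profile.pivot("sd_beta")
    if means.shape[1] < 3:
        raise ClockAuditError("need >= 3 windows to assess trends")
    mids = means.columns.to_numpy(dtype=float)
    rows = []
    for cpg in means.index:
        m = means.loc[cpg].to_numpy(dtype=float)
        s = sds.loc[cpg].to_numpy(dtype=float)
        slope = float(np.polyfit(mids, m, 1)[0])
        if np.ptp(s) == 0:
            rho = 0.0
        else:
            rho = float(stats.spearmanr(mids, s).statistic)
        rows.append({
            "cpg": cpg, "mean_slope": slope, "sd_spearman": rho,
            "stable_mean": abs(slope) <= mean_slope_tol,
            "rising_sd": rho >= sd_trend_threshold,
        })
    out = pd.DataFrame(rows).set_index("cpg")
    out["flagged"] = out["stable_mean"] & out["rising_sd"]
    return out


def aggregate_noise_score(profile: NoiseProfile) -> pd.Series:
    """Median-across-CpGs of the per-CpG z-scored windowed SD, per window.

    z-scoring each CpG's SD trace across windows removes per-locus scale
    before the robust cross-CpG summary.
    """
    sds = profile.pivot("sd_beta")
    mu = sds.mean(axis=1)
    sigma = sds.std(axis=1, ddof=0).replace(0.0, np.nan)
    z = sds.sub(mu, axis=0).div(sigma, axis=0)
    score = z.median(axis=0, skipna=True)
    score.name = "noise_score"
    return score.sort_index()


@dataclass
class TrajectoryFit:
    """Continuous piecewise-linear fit of a noise score vs age."""

    breakpoints: tuple[float, ...]
    slopes: tuple[float, ...]       # one per segment
    intercept: float
    rss: float
    n_points: int

    def predict(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = self.intercept + self.slopes[0] * x
        prev = self.slopes[0]
        for b, s in zip(self.breakpoints, self.slopes[1:]):
            out = out + (s - prev) * np.clip(x - b, 0.0, None)
            prev = s
        return out


def _hinge_fit(x: np.ndarray, y: np.ndarray,
               breaks: tuple[float, ...]) -> tuple[np.ndarray, float]:
    cols = [np.ones_like(x), x] + [np.clip(x - b, 0.0, None) for b in breaks]
    A = np.column_stack(cols)
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    rss = float(((y - A @ coef) ** 2).sum())
    return coef, rss


def fit_noise_trajectory(x, y, n_breakpoints: int = 3) -> TrajectoryFit:
    """Least-squares continuous piecewise-linear fit with free breakpoints.

    Candidate breakpoints are the interior observed x values; all
    combinations of ``n_breakpoints`` of them are searched exhaustively.
    With 0 breakpoints this is simple linear regression.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    order = np.argsort(x)
    x, y = x[order], y[order]
    if len(x) < 2 * (n_breakpoints + 1) + 1:
        raise ClockAuditError(
            f"{n_breakpoints} breakpoints need >= {2 * (n_breakpoints + 1) + 1} "
            f"points (got {len(x)})")
    if n_breakpoints == 0:
        coef, rss = _hinge_fit(x, y, ())
        return TrajectoryFit(breakpoints=(), slopes=(float(coef[1]),),
                             intercept=float(coef[0]), rss=rss, n_points=len(x))
    candidates = np.unique(x)[1:-1]
    best: tuple[float, tuple, np.ndarray] | None = None
    for breaks in itertools.combinations(candidates, n_breakpoints):
        coef, rss = _hinge_fit(x, y, breaks)
        if best is None or rss < best[0]:
            best = (rss, breaks, coef)
    rss, breaks, coef = best
    slopes = tuple(np.cumsum(coef[1:]).astype(float))
    return TrajectoryFit(breakpoints=tuple(float(b) for b in breaks),
                         slopes=slopes, intercept=float(coef[0]), rss=rss,
                         n_points=len(x))


def compare_noise_by_status(profile_healthy: NoiseProfile,
                            profile_disease: NoiseProfile,
                            metric: str = "sd_beta",
                            n_bootstrap: int = 500,
                            seed: int = 0) -> pd.DataFrame:
    """Per-window disease-minus-healthy noise difference with bootstrap CI.

    Both profiles must share the same windows; the difference is the
    cross-CpG mean of the per-CpG metric difference, and the interval comes
    from a seeded bootstrap over CpGs.
    """
    ph = profile_healthy.pivot(metric)
    pd_ = profile_disease.pivot(metric)
    if list(ph.columns) != list(pd_.columns):
        raise ClockAuditError("profiles were computed on different windows")
    common = ph.index.intersection(pd_.index)
    diff = pd_.loc[common] - ph.loc[common]
    rng = np.random.default_rng(seed)
    n_cpg = len(common)
    boots = np.empty((n_bootstrap, diff.shape[1]))
    vals = diff.to_numpy(dtype=float)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n_cpg, n_cpg)
        boots[b] = np.nanmean(vals[idx], axis=0)
    lo, hi = np.nanpercentile(boots, [2.5, 97.5], axis=0)
    return pd.DataFrame({
        "midpoint": ph.columns.to_numpy(dtype=float),
        "difference": np.nanmean(vals, axis=0),
        "ci_low": lo, "ci_high": hi,
    })
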