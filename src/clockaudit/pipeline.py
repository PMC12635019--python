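"""Run configuration, seeded stage orchestration, and the end-to-end demo.

A single global seed is expanded into per-stage substreams via
``SeedSequence([seed, stage_index])`` (stage order: simulate=0, train=1,
audit=2, cellaudit=3, noise=4), so each stage is reproducible in isolation.
All outputs are delimited text or JSON; the manifest records seed, config
hash, package version and a content hash per file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

import clockaudit
from clockaudit import cellfractions, coherence, models, noise, synthetic
from clockaudit.io import BetaMatrix, ClockAuditError, write_clock_table

logger = logging.getLogger(__name__)

STAGES = ("simulate", "train", "audit", "cellaudit", "noise")

_FLOAT_FMT = "%.10g"

DEFAULTS = {
    "seed": 0,
    "stages": list(STAGES),
    "cohort": {},            # CohortSpec field overrides
    "neutral_band": 0.0,
    "subset": "healthy",
    "alpha": 0.02,
    "l1_ratio": 0.5,
    "repeats": 5,
    "test_fraction": 0.2,
    "vif_thresholds": [0.025, 0.05, 0.1],
    "window": 6.0,
    "step": 3.0,
    "min_per_window": 20,
    "breakpoints": 3,
    "log_level": "INFO",
}

_COHORT_FIELDS = {f.name for f in dataclasses.fields(synthetic.CohortSpec)}


@dataclasses.dataclass
class RunConfig:
    """Fully-defaulted configuration for a pipeline run."""

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    cohort: dict = dataclasses.field(default_factory=dict)
    neutral_band: float = 0.0
    subset: str = "healthy"
    alpha: float = 0.02
    l1_ratio: float = 0.5
    repeats: int = 5
    test_fraction: float = 0.2
    vif_thresholds: tuple[float, float, float] = (0.025, 0.05, 0.1)
    window: float = 6.0
    step: float = 3.0
    min_per_window: int = 20
    breakpoints: int = 3
    log_level: str = "INFO"

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    def cohort_spec(self, seed: int) -> synthetic.CohortSpec:
        kwargs = dict(self.cohort)
        for key in ("age_range",):
            if key in kwargs:
                kwargs[key] = tuple(kwargs[key])
        if "noise_trajectory" in kwargs:
            nt = dict(kwargs["noise_trajectory"])
            for k in ("breakpoints", "slopes"):
                if k in nt:
                    nt[k] = tuple(nt[k])
            kwargs["noise_trajectory"] = synthetic.PiecewiseNoiseSpec(**nt)
        return synthetic.CohortSpec(seed=seed, **kwargs)


def stage_seed(seed: int, stage: str) -> int:
    """Derive the deterministic substream seed for one stage."""
    idx = STAGES.index(stage)
    return int(np.random.SeedSequence([seed, idx]).generate_state(1)[0])


def validate_config(path: str | Path) -> RunConfig:
    """Load a YAML config, applying defaults; report every error at once."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ClockAuditError(f"{path}: config must be a mapping")
    errors: list[str] = []
    unknown = set(raw) - set(DEFAULTS)
    if unknown:
        errors.append(f"unknown keys: {sorted(unknown)}")
    merged = {**DEFAULTS, **{k: v for k, v in raw.items() if k in DEFAULTS}}

    if not isinstance(merged["seed"], int):
        errors.append("seed must be an integer")
    bad_stages = set(merged["stages"]) - set(STAGES)
    if bad_stages:
        errors.append(f"unknown stages: {sorted(bad_stages)}")
    if not merged["stages"]:
        errors.append("no stages selected")
    if not isinstance(merged["cohort"], dict):
        errors.append("cohort must be a mapping of CohortSpec fields")
    else:
        bad_cohort = set(merged["cohort"]) - _COHORT_FIELDS
        if bad_cohort:
            errors.append(f"unknown cohort fields: {sorted(bad_cohort)}")
    if not 0.0 <= float(merged["neutral_band"]) <= 1.0:
        errors.append("neutral_band must be in [0, 1]")
    if merged["subset"] not in ("healthy", "all"):
        errors.append("subset must be 'healthy' or 'all'")
    if float(merged["alpha"]) < 0:
        errors.append("alpha must be >= 0")
    if not 0.0 <= float(merged["l1_ratio"]) <= 1.0:
        errors.append("l1_ratio must be in [0, 1]")
    if int(merged["repeats"]) < 1:
        errors.append("repeats must be >= 1")
    if not 0.0 < float(merged["test_fraction"]) < 1.0:
        errors.append("test_fraction must be in (0, 1)")
    thr = list(merged["vif_thresholds"])
    if len(thr) != 3 or not (thr[0] < thr[1] < thr[2]):
        errors.append("vif_thresholds must be 3 ascending values")
    if float(merged["window"]) <= 0 or float(merged["step"]) <= 0:
        errors.append("window and step must be > 0")
    if int(merged["min_per_window"]) < 2:
        errors.append("min_per_window must be >= 2")
    if int(merged["breakpoints"]) < 0:
        errors.append("breakpoints must be >= 0")
    if errors:
        raise ClockAuditError(f"{path}: " + "; ".join(errors))

    merged["stages"] = tuple(merged["stages"])
    merged["vif_thresholds"] = tuple(float(x) for x in thr)
    return RunConfig(**merged)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, **kwargs) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, **kwargs)


def _write_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=float) + "\n")


def run_demo(config: RunConfig, out_dir: str | Path) -> dict:
    """Run the selected stages on one seeded cohort; return the manifest.

    Stage failures abort with the stage name; a partial manifest is never
    left behind.
    """
    if not config.stages:
        raise ClockAuditError("no stages selected")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    files: list[Path] = []
    stage = "simulate"
    try:
        # the cohort feeds every later stage even when simulate output is off
        cohort = synthetic.generate_cohort(
            config.cohort_spec(stage_seed(config.seed, "simulate")))
        if "simulate" in config.stages:
            files.extend(synthetic.write_cohort(cohort, out / "cohort").values())

        if "train" in config.stages:
            stage = "train"
            demo = models.under_tuned_en_demo(cohort)
            _write_tsv(demo.to_frame(), out / "en_vs_ols_predictions.tsv",
                       index_label="sample_id")
            weights = pd.DataFrame({
                "en_weight": pd.Series(demo.en_fit.weights),
                "ols_weight": pd.Series(demo.ols_fit.weights),
            })
            _write_tsv(weights, out / "en_vs_ols_weights.tsv", index_label="cpg")
            _write_tsv(demo.slope_recovery, out / "slope_recovery.tsv")
            files += [out / "en_vs_ols_predictions.tsv",
                      out / "en_vs_ols_weights.tsv", out / "slope_recovery.tsv"]

        trade = None
        if "audit" in config.stages:
            stage = "audit"
            trade = coherence.tradeoff_experiment(
                cohort,
                en_config=models.ENConfig(alpha=config.alpha,
                                          l1_ratio=config.l1_ratio, tol=1e-5),
                neutral_band=config.neutral_band,
                seed=stage_seed(config.seed, "audit"))
            stats_table = coherence.univariate_stats(cohort.beta, cohort.metadata,
                                                     subset=config.subset)
            report = coherence.audit_model(trade.original_model, stats_table,
                                           config.neutral_band)
            _write_tsv(report.per_cpg, out / "coherence_per_cpg.tsv",
                       index_label="cpg")
            _write_json(report.summary(), out / "coherence_summary.json")
            write_clock_table(trade.original_model, out / "en_clock.tsv")
            write_clock_table(trade.rectified_model, out / "en_clock_rectified.tsv")
            _write_json({
                "original": dataclasses.asdict(trade.original),
                "rectified": dataclasses.asdict(trade.rectified),
                "n_misaligned_dropped": trade.n_misaligned_dropped,
            }, out / "tradeoff.json")
            files += [out / "coherence_per_cpg.tsv", out / "coherence_summary.json",
                      out / "en_clock.tsv", out / "en_clock_rectified.tsv",
                      out / "tradeoff.json"]

        if "cellaudit" in config.stages:
            stage = "cellaudit"
            fractions, resid = cellfractions.deconvolve(
                cohort.beta, cohort.reference_profiles)
            _write_tsv(fractions, out / "cell_fractions.tsv",
                       index_label="sample_id")
            mix_beta = BetaMatrix(cohort.beta.data[cohort.cpgs_of("mixture")])
            rho, summary = cellfractions.fraction_correlations(mix_beta, fractions)
            _write_tsv(rho, out / "fraction_spearman.tsv", index_label="cpg")
            audit = cellfractions.vif_audit(mix_beta, fractions,
                                            config.vif_thresholds)
            _write_tsv(audit.delta, out / "vif_delta.tsv", index_label="cpg")
            _write_tsv(audit.bin_distribution(), out / "vif_bins.tsv",
                       index_label="cell_type")
            _write_json(summary, out / "fraction_summary.json")
            files += [out / "cell_fractions.tsv", out / "fraction_spearman.tsv",
                      out / "vif_delta.tsv", out / "vif_bins.tsv",
                      out / "fraction_summary.json"]

        if "noise" in config.stages:
            stage = "noise"
            healthy = cohort.metadata[cohort.metadata["status"] == "healthy"]
            hbeta = BetaMatrix(cohort.beta.data.loc[healthy.index])
            profile = noise.windowed_noise(hbeta, healthy, config.window,
                                           config.step,
                                           min_per_window=config.min_per_window)
            _write_tsv(profile.table, out / "noise_profile.tsv", index=False)
            flags = noise.flag_stable_mean_rising_sd(profile)
            _write_tsv(flags, out / "noise_flags.tsv")
            # the trajectory is only meaningful on the stable-mean/rising-SD
            # loci; fall back to all CpGs when too few are flagged
            flagged = flags.index[flags["flagged"]]
            if len(flagged) >= 3:
                sub = profile.table[profile.table["cpg"].isin(flagged)]
                profile_for_fit = noise.NoiseProfile(
                    table=sub, window_width=profile.window_width,
                    step=profile.step, mean_floor=profile.mean_floor)
            else:
                profile_for_fit = profile
            score = noise.aggregate_noise_score(profile_for_fit)
            fit = noise.fit_noise_trajectory(score.index.to_numpy(),
                                             score.to_numpy(),
                                             config.breakpoints)
            _write_json(dataclasses.asdict(fit), out / "noise_trajectory.json")
            files += [out / "noise_profile.tsv", out / "noise_flags.tsv",
                      out / "noise_trajectory.json"]
    except Exception as exc:
        if manifest_path.exists():
            manifest_path.unlink()
        raise ClockAuditError(f"stage {stage!r} failed: {exc}") from exc

    manifest = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "version": clockaudit.__version__,
        "stages": list(config.stages),
        "files": {str(p.relative_to(out)): _sha256(p) for p in sorted(files)},
    }
    _write_json(manifest, manifest_path)
    return manifest
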