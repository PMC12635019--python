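"""Synthetic DNA-methylation cohorts with known generative truth.

The generator produces beta-value matrices whose columns follow named
archetypes, so every downstream audit can be checked against planted
parameters:

``archetype_1..5``
    The five illustrative CpGs: columns 1 and 2 equal ``0.008 * age`` plus
    independent Gaussian noise, column 3 is half of column 1 (exactly, or
    noisily), column 4 is Gaussian and column 5 uniform, both age-independent.
``age_linear``
    Beta rises linearly with age at a per-CpG slope, homoscedastic noise.
``mixture``
    Bulk beta = cell-fraction-weighted average of per-cell-type reference
    profiles; tracks leukocyte composition by construction.
``homeostatic``
    Constant mean, noise SD following a piecewise-linear age trajectory
    (the "stable mean, rising dispersion" loci).
``confounded_x1`` / ``confounded_x2``
    Pairs sharing a per-sample nuisance term that also carries the disease
    shift; a regression can cancel the nuisance (and the disease signal)
    by weighting x2 opposite to its univariate age correlation.
``normal`` / ``uniform``
    Age-independent fillers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from clockaudit.io import (
    BetaMatrix,
    ClockAuditError,
    read_beta_matrix,
    read_metadata,
    write_beta_matrix,
    write_metadata,
)

logger = logging.getLogger(__name__)

#: the 12 leukocyte types of the immune reference used for deconvolution
CELL_TYPES = (
    "CD4T_naive", "CD4T_memory", "CD8T_naive", "CD8T_memory",
    "B_naive", "B_memory", "Treg", "NK",
    "Monocytes", "Neutrophils", "Eosinophils", "Basophils",
)

_BASE_FRACTIONS = {
    "CD4T_naive": 0.06, "CD4T_memory": 0.08, "CD8T_naive": 0.04,
    "CD8T_memory": 0.05, "B_naive": 0.02, "B_memory": 0.02,
    "Treg": 0.02, "NK": 0.05, "Monocytes": 0.08, "Neutrophils": 0.55,
    "Eosinophils": 0.02, "Basophils": 0.01,
}

# per-year change of the mean fraction; naive subsets decline with age,
# neutrophils stay flat
_AGE_SLOPES = {
    "CD4T_naive": -8e-4, "CD8T_naive": -5e-4, "B_naive": -3e-4,
    "CD4T_memory": 6e-4, "CD8T_memory": 4e-4, "NK": 2e-4,
    "Treg": 0.0, "B_memory": 1e-4, "Monocytes": 0.0, "Neutrophils": 0.0,
    "Eosinophils": 0.0, "Basophils": 0.0,
}

# additive myeloid shift applied to disease samples (sums to zero)
_DISEASE_SHIFT = {
    "Neutrophils": 0.06, "Monocytes": 0.02,
    "CD4T_naive": -0.03, "CD8T_naive": -0.02, "B_naive": -0.01, "NK": -0.02,
    "CD4T_memory": 0.0, "CD8T_memory": 0.0, "Treg": 0.0, "B_memory": 0.0,
    "Eosinophils": 0.0, "Basophils": 0.0,
}

_REFERENCE_AGE = 50.0
_FRACTION_FLOOR = 1e-4


@dataclass(frozen=True)
class PiecewiseNoiseSpec:
    """Noise SD as a continuous piecewise-linear function of age.

    SD is constant at ``base_sd`` below ``anchor_age`` and accumulates
    ``slopes[s]`` per year across each segment delimited by ``breakpoints``
    (the final slope applies beyond the last breakpoint).
    """

    breakpoints: tuple[float, ...] = (36.0, 48.0, 60.0)
    slopes: tuple[float, ...] = (0.004, 0.0, 0.005, 0.0)
    base_sd: float = 0.02
    anchor_age: float = 25.0
    disease_sd_multiplier: float = 1.0

    def __post_init__(self) -> None:
        bp = tuple(float(b) for b in self.breakpoints)
        if any(b2 <= b1 for b1, b2 in zip(bp, bp[1:])):
            raise ClockAuditError("breakpoints must be strictly increasing")
        if len(self.slopes) != len(bp) + 1:
            raise ClockAuditError(
                f"need {len(bp) + 1} segment slopes for {len(bp)} breakpoints"
            )
        if self.base_sd <= 0:
            raise ClockAuditError("base_sd must be > 0")
        if self.disease_sd_multiplier < 1:
            raise ClockAuditError("disease_sd_multiplier must be >= 1")

    def sd(self, ages: np.ndarray) -> np.ndarray:
        """Evaluate the SD trajectory at the given ages."""
        ages = np.asarray(ages, dtype=float)
        edges = (self.anchor_age, *self.breakpoints, np.inf)
        out = np.full(ages.shape, self.base_sd)
        for slope, lo, hi in zip(self.slopes, edges[:-1], edges[1:]):
            out = out + slope * np.clip(np.minimum(ages, hi) - lo, 0.0, None)
        return out


@dataclass(frozen=True)
class CellMixSpec:
    """Parameters of the 12-type leukocyte mixture."""

    cell_types: tuple[str, ...] = CELL_TYPES
    base_fractions: dict[str, float] = field(default_factory=lambda: dict(_BASE_FRACTIONS))
    age_slopes: dict[str, float] = field(default_factory=lambda: dict(_AGE_SLOPES))
    disease_shift: dict[str, float] = field(default_factory=lambda: dict(_DISEASE_SHIFT))
    dirichlet_concentration: float = 200.0

    def __post_init__(self) -> None:
        if len(self.cell_types) != 12:
            raise ClockAuditError("exactly 12 cell types are required")
        if self.dirichlet_concentration <= 0:
            raise ClockAuditError("dirichlet_concentration must be > 0")

    def mean_fractions(self, age: float, diseased: bool) -> np.ndarray:
        """Age- and status-adjusted mean fraction vector (on the simplex)."""
        f = np.array([
            self.base_fractions[c]
            + self.age_slopes.get(c, 0.0) * (age - _REFERENCE_AGE)
            + (self.disease_shift.get(c, 0.0) if diseased else 0.0)
            for c in self.cell_types
        ])
        if (f < 0).any():
            warnings.warn("negative mean fractions floored and renormalized",
                          stacklevel=2)
            f = np.maximum(f, _FRACTION_FLOOR)
        return f / f.sum()


#: default number of CpGs per archetype (the 5-column block is implicit)
DEFAULT_ARCHETYPE_COUNTS = {
    "age_linear": 15,
    "mixture": 25,
    "homeostatic": 15,
    "confounded_pair": 5,   # pairs: emits 2 CpGs each
    "normal": 5,
    "uniform": 5,
}


@dataclass(frozen=True)
class CohortSpec:
    """Full parameterization of a synthetic cohort."""

    n_samples: int = 500
    age_range: tuple[float, float] = (20.0, 80.0)
    disease_fraction: float = 0.0
    n_cpgs_by_archetype: dict[str, int] = field(
        default_factory=lambda: dict(DEFAULT_ARCHETYPE_COUNTS))
    include_archetype_block: bool = True
    archetype_noise_sd: float = 0.02
    collinear_mode: str = "exact"      # "exact" | "noisy" for archetype_3
    age_linear_noise_sd: float = 0.03
    mixture_noise_sd: float = 0.01
    confounded_shared_sd: float = 0.05
    confounded_private_sd: float = 0.01
    disease_beta_shift: float = 0.03   # added to the shared confounder term
    noise_trajectory: PiecewiseNoiseSpec = field(default_factory=PiecewiseNoiseSpec)
    cell_mix: CellMixSpec = field(default_factory=CellMixSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_samples < 2:
            raise ClockAuditError("n_samples must be >= 2")
        lo, hi = self.age_range
        if not lo < hi:
            raise ClockAuditError("age_range low must be < high")
        if not 0.0 <= self.disease_fraction <= 1.0:
            raise ClockAuditError("disease_fraction must be in [0, 1]")
        if any(v < 0 for v in self.n_cpgs_by_archetype.values()):
            raise ClockAuditError("archetype counts must be >= 0")
        unknown = set(self.n_cpgs_by_archetype) - set(DEFAULT_ARCHETYPE_COUNTS)
        if unknown:
            raise ClockAuditError(f"unknown archetypes: {sorted(unknown)}")
        if self.collinear_mode not in ("exact", "noisy"):
            raise ClockAuditError("collinear_mode must be 'exact' or 'noisy'")


@dataclass
class SyntheticCohort:
    """Generated cohort plus all generative ground truth."""

    beta: BetaMatrix
    metadata: pd.DataFrame                 # index sample_id; age, status
    true_fractions: pd.DataFrame           # samples x 12 cell types
    archetype_labels: pd.Series            # per CpG
    truth: pd.DataFrame                    # per CpG generative parameters
    reference_profiles: pd.DataFrame       # cell types x mixture CpGs
    spec: CohortSpec | None = None

    @property
    def ages(self) -> np.ndarray:
        return self.metadata["age"].to_numpy()

    def cpgs_of(self, *archetypes: str) -> list[str]:
        mask = self.archetype_labels.isin(archetypes)
        return list(self.archetype_labels.index[mask])


def generate_archetype_cpgs(
    ages: np.ndarray,
    seed: int | np.random.Generator = 0,
    noise_sd: float = 0.02,
    collinear_mode: str = "exact",
) -> tuple[np.ndarray, list[str]]:
    """Generate the five illustrative CpG columns for the given ages.

    Columns 1 and 2 equal ``0.008 * age`` plus independent Gaussian noise;
    column 3 is half of column 1 (plus noise when ``collinear_mode='noisy'``);
    column 4 is Gaussian and column 5 uniform, both independent of age and
    both with added Gaussian noise. All columns are clipped to [0, 1].
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size == 0:
        raise ClockAuditError("ages must be non-empty")
    if (ages < 0).any() or (ages > 120).any():
        raise ClockAuditError("ages must lie in [0, 120]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = ages.size
    c1 = 0.008 * ages + rng.normal(0.0, noise_sd, n)
    c2 = 0.008 * ages + rng.normal(0.0, noise_sd, n)
    c3 = 0.5 * c1
    if collinear_mode == "noisy":
        c3 = c3 + rng.normal(0.0, noise_sd / 2.0, n)
    c4 = rng.normal(0.5, 0.08, n) + rng.normal(0.0, noise_sd, n)
    c5 = rng.uniform(0.1, 0.9, n) + rng.normal(0.0, noise_sd, n)
    block = np.clip(np.column_stack([c1, c2, c3, c4, c5]), 0.0, 1.0)
    labels = [f"archetype_{k}" for k in range(1, 6)]
    return block, labels


def _draw_fractions(spec: CohortSpec, ages: np.ndarray, diseased: np.ndarray,
                    rng: np.random.Generator) -> np.ndarray:
    mix = spec.cell_mix
    n = ages.size
    out = np.empty((n, len(mix.cell_types)))
    conc = mix.dirichlet_concentration
    for i in range(n):
        mean = mix.mean_fractions(float(ages[i]), bool(diseased[i]))
        out[i] = rng.dirichlet(conc * mean)
    return out


def generate_cohort(spec: CohortSpec) -> SyntheticCohort:
    """Generate a fully specified cohort; identical spec -> identical cohort."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_samples
    lo, hi = spec.age_range
    ages = rng.uniform(lo, hi, n)
    diseased = rng.random(n) < spec.disease_fraction
    sample_ids = [f"S{i:05d}" for i in range(n)]

    fractions = _draw_fractions(spec, ages, diseased, rng)
    traj_sd = spec.noise_trajectory.sd(ages)
    traj_sd = np.where(diseased,
                       traj_sd * spec.noise_trajectory.disease_sd_multiplier,
                       traj_sd)

    columns: list[np.ndarray] = []
    labels: list[str] = []
    truth_rows: list[dict] = []

    if spec.include_archetype_block:
        block, block_labels = generate_archetype_cpgs(
            ages, rng, noise_sd=spec.archetype_noise_sd,
            collinear_mode=spec.collinear_mode)
        for k, lab in enumerate(block_labels):
            columns.append(block[:, k])
            labels.append(lab)
            truth_rows.append({
                "archetype": lab,
                "age_slope": 0.008 if lab in ("archetype_1", "archetype_2")
                else (0.004 if lab == "archetype_3" else 0.0),
                "noise_sd": spec.archetype_noise_sd,
            })

    counts = {**DEFAULT_ARCHETYPE_COUNTS, **spec.n_cpgs_by_archetype}

    for _ in range(counts["age_linear"]):
        slope = rng.uniform(0.002, 0.006)
        b0 = rng.uniform(0.05, 0.30)
        col = b0 + slope * ages + rng.normal(0.0, spec.age_linear_noise_sd, n)
        columns.append(col)
        labels.append("age_linear")
        truth_rows.append({"archetype": "age_linear", "age_slope": slope,
                           "noise_sd": spec.age_linear_noise_sd})

    n_mix = counts["mixture"]
    ref = rng.uniform(0.05, 0.95, size=(len(spec.cell_mix.cell_types), n_mix))
    mix_block = fractions @ ref + rng.normal(0.0, spec.mixture_noise_sd, (n, n_mix))
    for k in range(n_mix):
        columns.append(mix_block[:, k])
        labels.append("mixture")
        truth_rows.append({"archetype": "mixture", "age_slope": np.nan,
                           "noise_sd": spec.mixture_noise_sd})

    for _ in range(counts["homeostatic"]):
        mu = rng.uniform(0.3, 0.7)
        col = mu + rng.normal(0.0, 1.0, n) * traj_sd
        columns.append(col)
        labels.append("homeostatic")
        truth_rows.append({"archetype": "homeostatic", "age_slope": 0.0,
                           "noise_sd": spec.noise_trajectory.base_sd})

    for _ in range(counts["confounded_pair"]):
        u = rng.normal(0.0, spec.confounded_shared_sd, n)
        u = u + np.where(diseased, spec.disease_beta_shift, 0.0)
        x1 = 0.20 + 0.004 * ages + u + rng.normal(0.0, spec.confounded_private_sd, n)
        x2 = 0.35 + 0.001 * ages + u + rng.normal(0.0, spec.confounded_private_sd, n)
        columns.extend([x1, x2])
        labels.extend(["confounded_x1", "confounded_x2"])
        truth_rows.append({"archetype": "confounded_x1", "age_slope": 0.004,
                           "noise_sd": spec.confounded_shared_sd})
        truth_rows.append({"archetype": "confounded_x2", "age_slope": 0.001,
                           "noise_sd": spec.confounded_shared_sd})

    for _ in range(counts["normal"]):
        mu = rng.uniform(0.3, 0.7)
        columns.append(rng.normal(mu, 0.05, n))
        labels.append("normal")
        truth_rows.append({"archetype": "normal", "age_slope": 0.0, "noise_sd": 0.05})

    for _ in range(counts["uniform"]):
        columns.append(rng.uniform(0.1, 0.9, n))
        labels.append("uniform")
        truth_rows.append({"archetype": "uniform", "age_slope": 0.0, "noise_sd": np.nan})

    if not columns:
        raise ClockAuditError("cohort spec produced zero CpGs")

    cpg_ids = [f"cg{i + 1:08d}" for i in range(len(columns))]
    values = np.clip(np.column_stack(columns), 0.0, 1.0)
    beta = BetaMatrix(pd.DataFrame(values, index=sample_ids, columns=cpg_ids))

    metadata = pd.DataFrame({
        "age": ages,
        "status": np.where(diseased, "disease", "healthy"),
    }, index=pd.Index(sample_ids, name="sample_id"))
    true_fractions = pd.DataFrame(fractions, index=sample_ids,
                                  columns=list(spec.cell_mix.cell_types))
    archetype_labels = pd.Series(labels, index=cpg_ids, name="archetype")
    truth = pd.DataFrame(truth_rows, index=cpg_ids)
    mix_ids = [c for c, lab in zip(cpg_ids, labels) if lab == "mixture"]
    reference_profiles = pd.DataFrame(ref, index=list(spec.cell_mix.cell_types),
                                      columns=mix_ids)
    return SyntheticCohort(beta=beta, metadata=metadata,
                           true_fractions=true_fractions,
                           archetype_labels=archetype_labels, truth=truth,
                           reference_profiles=reference_profiles, spec=spec)


_FILES = {
    "beta": "beta.tsv",
    "metadata": "metadata.tsv",
    "fractions": "true_fractions.tsv",
    "labels": "archetype_labels.tsv",
    "truth": "truth.tsv",
    "reference": "reference_profiles.tsv",
}


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> dict[str, Path]:
    """Write the cohort as delimited text files; returns the file map."""
    if cohort.beta.shape[1] == 0:
        raise ClockAuditError("refusing to write a cohort with zero CpGs")
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {k: directory / v for k, v in _FILES.items()}
    write_beta_matrix(cohort.beta, paths["beta"])
    write_metadata(cohort.metadata, paths["metadata"])
    cohort.true_fractions.to_csv(paths["fractions"], sep="\t",
                                 index_label="sample_id", float_format="%.12g")
    cohort.archetype_labels.to_frame().to_csv(paths["labels"], sep="\t",
                                              index_label="cpg")
    cohort.truth.to_csv(paths["truth"], sep="\t", index_label="cpg",
                        float_format="%.12g")
    cohort.reference_profiles.to_csv(paths["reference"], sep="\t",
                                     index_label="cell_type", float_format="%.12g")
    return paths


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Read back a cohort written by :func:`write_cohort`."""
    directory = Path(directory)
    beta = read_beta_matrix(directory / _FILES["beta"], orientation="cpgs-in-rows")
    metadata = read_metadata(directory / _FILES["metadata"])
    fractions = pd.read_csv(directory / _FILES["fractions"], sep="\t",
                            index_col="sample_id")
    labels = pd.read_csv(directory / _FILES["labels"], sep="\t",
                         index_col="cpg")["archetype"]
    truth = pd.read_csv(directory / _FILES["truth"], sep="\t", index_col="cpg")
    reference = pd.read_csv(directory / _FILES["reference"], sep="\t",
                            index_col="cell_type")
    return SyntheticCohort(beta=beta, metadata=metadata, true_fractions=fractions,
                           archetype_labels=labels, truth=truth,
                           reference_profiles=reference, spec=None)


def spec_with_seed(spec: CohortSpec, seed: int) -> CohortSpec:
    """Copy of ``spec`` with a different seed (convenience for replicates)."""
    return replace(spec, seed=seed)
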