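"""Readers/writers for clock coefficient tables, beta matrices and metadata.

File conventions
----------------
Clock table     : delimited, columns ``cpg,coefficient``; an optional row with
                  cpg ``(Intercept)`` carries the model intercept.
Beta matrix     : delimited; header row of sample ids, first column CpG ids
                  (series-matrix body convention, "cpgs-in-rows"), or the
                  transpose when declared ``samples-in-rows``.
Sample metadata : delimited, columns ``sample_id,age,status[,disease_name]``.

Delimiter (tab or comma) is sniffed from the header line; UTF-8; ``.`` decimal.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

INTERCEPT_KEY = "(Intercept)"
VALID_STATUS = ("healthy", "disease", "unknown")

_PROBE_RE = re.compile(r"^(cg\d+|ch\.\S+)$")


class ClockAuditError(Exception):
    """Base error for clockaudit I/O and validation failures."""


@dataclass(frozen=True)
class ClockModel:
    """A named sparse linear model: intercept plus CpG -> weight map.

    ``coefficients`` holds only nonzero weights; ``n_features`` is their count.
    """

    name: str
    intercept: float
    coefficients: Mapping[str, float]
    response_proxy: str = "chronological age (years)"

    def __post_init__(self) -> None:
        if not self.name:
            raise ClockAuditError("clock model name must be non-empty")
        coefs = {str(k): float(v) for k, v in self.coefficients.items() if v != 0.0}
        if len(coefs) != len(self.coefficients):
            dropped = len(self.coefficients) - len(coefs)
            logger.info("dropped %d zero-coefficient entries from %s", dropped, self.name)
        object.__setattr__(self, "coefficients", coefs)

    @property
    def n_features(self) -> int:
        return len(self.coefficients)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.coefficients)


@dataclass
class BetaMatrix:
    """Samples x CpGs matrix of methylation beta values in [0, 1].

    ``data`` is indexed by sample id with CpG ids as columns. NaN marks a
    missing value; construction rejects out-of-range finite values.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ClockAuditError(f"duplicate sample ids: {dups[:5]}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ClockAuditError(f"duplicate CpG ids: {dups[:5]}")
        vals = self.data.to_numpy(dtype=float)
        bad = np.isfinite(vals) & ((vals < 0.0) | (vals > 1.0))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ClockAuditError(
                f"beta value out of [0,1] at sample {self.data.index[i]!r}, "
                f"CpG {self.data.columns[j]!r}: {vals[i, j]}"
            )

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape


def _sniff_sep(path: Path) -> str:
    header = Path(path).open("r", encoding="utf-8").readline()
    return "\t" if header.count("\t") >= header.count(",") else ","


def read_clock_table(path: str | Path, name: str | None = None) -> ClockModel:
    """Read a delimited ``cpg,coefficient`` table into a :class:`ClockModel`.

    An optional ``(Intercept)`` row supplies the intercept (default 0 with a
    warning). Duplicate CpG ids and non-numeric coefficients are errors.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype=str)
    cols = {c.lower(): c for c in df.columns}
    cpg_col = cols.get("cpg", df.columns[0])
    coef_col = cols.get("coefficient", df.columns[1])

    coefs: dict[str, float] = {}
    intercept: float | None = None
    for rownum, (cpg, raw) in enumerate(zip(df[cpg_col], df[coef_col]), start=2):
        cpg = str(cpg).strip()
        try:
            value = float(raw)
        except (TypeError, ValueError):
            raise ClockAuditError(
                f"{path}: non-numeric coefficient {raw!r} at line {rownum}"
            ) from None
        if cpg == INTERCEPT_KEY:
            intercept = value
            continue
        if cpg in coefs:
            raise ClockAuditError(f"{path}: duplicate CpG id {cpg!r}")
        coefs[cpg] = value
    if intercept is None:
        logger.warning("%s: no (Intercept) row; intercept set to 0", path)
        intercept = 0.0
    n_zero = sum(1 for v in coefs.values() if v == 0.0)
    if n_zero:
        logger.info("%s: dropping %d zero-coefficient rows", path, n_zero)
    return ClockModel(name=name or path.stem, intercept=intercept, coefficients=coefs)


def write_clock_table(model: ClockModel, path: str | Path) -> None:
    path = Path(path)
    rows = [{"cpg": INTERCEPT_KEY, "coefficient": model.intercept}]
    rows += [{"cpg": c, "coefficient": w} for c, w in model.coefficients.items()]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_beta_matrix(
    path: str | Path,
    orientation: str = "auto",
    strict: bool = True,
) -> BetaMatrix:
    """Read a delimited beta table; normalize to samples x CpGs internally.

    orientation: ``cpgs-in-rows`` | ``samples-in-rows`` | ``auto``. Auto keeps
    the cpgs-in-rows convention when the first-column ids look like array
    probe names (``cg...``/``ch....``), otherwise assumes samples in rows.
    With ``strict=False`` out-of-range values become NaN instead of erroring.
    """
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    try:
        df = df.astype(float)
    except ValueError as exc:
        raise ClockAuditError(f"{path}: non-numeric beta value ({exc})") from None

    if orientation == "auto":
        looks_probe = all(_PROBE_RE.match(i) for i in df.index[: min(len(df), 20)])
        orientation = "cpgs-in-rows" if looks_probe else "samples-in-rows"
    if orientation == "cpgs-in-rows":
        df = df.T
    elif orientation != "samples-in-rows":
        raise ClockAuditError(f"unknown orientation {orientation!r}")
    df.index.name = None
    df.columns.name = None

    vals = df.to_numpy()
    bad = np.isfinite(vals) & ((vals < 0.0) | (vals > 1.0))
    if bad.any() and not strict:
        df = df.mask(pd.DataFrame(bad, index=df.index, columns=df.columns))
        logger.warning("%s: flagged %d out-of-range values as missing", path, int(bad.sum()))

    all_missing = df.columns[df.isna().all(axis=0)]
    if len(all_missing):
        logger.warning("%s: dropping %d all-missing CpG columns", path, len(all_missing))
        df = df.drop(columns=all_missing)
    return BetaMatrix(df)


def write_beta_matrix(beta: BetaMatrix, path: str | Path) -> None:
    """Write in the cpgs-in-rows convention (CpG ids in the first column)."""
    beta.data.T.to_csv(Path(path), sep="\t", float_format="%.12g")


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read sample metadata; returns a frame indexed by ``sample_id``."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={"sample_id": str})
    required = {"sample_id", "age", "status"}
    missing = required - set(df.columns)
    if missing:
        raise ClockAuditError(f"{path}: missing metadata columns {sorted(missing)}")
    df = df.set_index("sample_id")
    if df.index.has_duplicates:
        raise ClockAuditError(f"{path}: duplicate sample ids")
    df["age"] = df["age"].astype(float)
    if not np.isfinite(df["age"]).all():
        raise ClockAuditError(f"{path}: non-finite ages")
    bad_status = set(df["status"].unique()) - set(VALID_STATUS)
    if bad_status:
        raise ClockAuditError(f"{path}: unknown status values {sorted(bad_status)}")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(Path(path), sep="\t", index=True, index_label="sample_id",
                    float_format="%.12g")


@dataclass
class CoverageReport:
    """Which model CpGs the matrix covered when applying a clock."""

    model_name: str
    used_cpgs: list[str] = field(default_factory=list)
    missing_cpgs: list[str] = field(default_factory=list)
    policy: str = "zero"

    @property
    def n_used(self) -> int:
        return len(self.used_cpgs)

    @property
    def n_missing(self) -> int:
        return len(self.missing_cpgs)


def apply_clock(
    model: ClockModel,
    beta: BetaMatrix,
    missing_policy: str = "zero",
) -> tuple[pd.Series, CoverageReport]:
    """Predict ``intercept + sum_j w_j * beta_ij`` per sample.

    missing_policy: ``zero`` (missing model CpGs contribute 0, warning),
    ``error`` (any missing CpG raises), or ``mean`` (impute the matrix-wide
    mean beta of covered CpGs... unavailable CpGs still contribute 0).
    NaN betas of covered CpGs contribute 0 under ``zero``, the per-CpG mean
    under ``mean``.
    """
    if missing_policy not in ("zero", "error", "mean"):
        raise ClockAuditError(f"unknown missing policy {missing_policy!r}")
    present = [c for c in model.coefficients if c in beta.data.columns]
    missing = [c for c in model.coefficients if c not in beta.data.columns]
    if not present:
        raise ClockAuditError(
            f"model {model.name!r}: no overlap between model CpGs and beta matrix"
        )
    if missing:
        if missing_policy == "error":
            raise ClockAuditError(
                f"model {model.name!r}: {len(missing)} CpGs missing from matrix "
                f"(e.g. {missing[:3]})"
            )
        logger.warning(
            "model %s: %d/%d CpGs missing from matrix; contributing 0",
            model.name, len(missing), model.n_features,
        )
    sub = beta.data[present]
    if missing_policy == "mean":
        sub = sub.fillna(sub.mean(axis=0))
    sub = sub.fillna(0.0)
    w = np.array([model.coefficients[c] for c in present])
    pred = pd.Series(model.intercept + sub.to_numpy() @ w, index=beta.data.index,
                     name=model.name)
    report = CoverageReport(model_name=model.name, used_cpgs=present,
                            missing_cpgs=missing, policy=missing_policy)
    return pred, report
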