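"""Typed containers and I/O for cohort expression + clinical data.

A cohort is an expression matrix (genes x samples) paired with a clinical
table carrying right-censored disease-free survival (DFS).  The binary
early-relapse endpoint dichotomizes DFS at a threshold (default one year):
patients relapsing at or before the threshold are ``high``, patients with
follow-up beyond it are ``low``, and patients censored at or before it are
``undefined`` and excluded from binary evaluation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger("odfsp")

#: days per month used when clinical time is given in months
DAYS_PER_MONTH = 30.44

#: default early-relapse dichotomization threshold ("within a year", inclusive)
DEFAULT_THRESHOLD_DAYS = 365


class Platform(str, Enum):
    SEQUENCING = "sequencing"
    ARRAY = "array"


class RelapseLabel(str, Enum):
    HIGH = "high"
    LOW = "low"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class SurvivalRecord:
    """Right-censored DFS observation with its derived binary label."""

    dfs_time: float  # days, > 0
    dfs_event: bool  # True = relapse/progression observed
    early_relapse_label: RelapseLabel = RelapseLabel.UNDEFINED

    def __post_init__(self):
        if not np.isfinite(self.dfs_time) or self.dfs_time <= 0:
            raise ValueError(f"dfs_time must be positive and finite, got {self.dfs_time}")


@dataclass(frozen=True)
class ClinicalRecord:
    sample_id: str
    survival: SurvivalRecord
    age: float | None = None  # years; None = absent (never imputed)
    figo_stage: int | None = None  # ordinal 1..4; None = absent
    cohort: str = ""
    platform: Platform = Platform.ARRAY


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix with unique string identifiers."""

    gene_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray  # shape (n_genes, n_samples), finite

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample identifiers")
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError(
                f"value shape {self.values.shape} does not match "
                f"({len(self.gene_ids)} genes, {len(self.sample_ids)} samples)"
            )
        if not np.all(np.isfinite(self.values)):
            g, s = np.argwhere(~np.isfinite(self.values))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.gene_ids[g]!r}, "
                f"sample {self.sample_ids[s]!r}"
            )

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {s: i for i, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return ExpressionMatrix(list(self.gene_ids), list(sample_ids), self.values[:, cols])

    def subset_genes(self, gene_ids: Sequence[str]) -> "ExpressionMatrix":
        idx = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in gene_ids if g not in idx]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing[:5]}")
        rows = [idx[g] for g in gene_ids]
        return ExpressionMatrix(list(gene_ids), list(self.sample_ids), self.values[rows, :])


@dataclass
class CohortProfile:
    """One cohort: expression matrix + aligned clinical records + platform."""

    name: str
    expression: ExpressionMatrix
    clinical: list[ClinicalRecord]
    platform: Platform

    def __post_init__(self):
        expr_ids = set(self.expression.sample_ids)
        clin_ids = {r.sample_id for r in self.clinical}
        if expr_ids != clin_ids:
            raise ValueError(
                f"cohort {self.name!r}: expression/clinical sample mismatch "
                f"({len(expr_ids ^ clin_ids)} unmatched ids)"
            )
        # keep clinical records in expression column order
        by_id = {r.sample_id: r for r in self.clinical}
        self.clinical = [by_id[s] for s in self.expression.sample_ids]

    @property
    def n_samples(self) -> int:
        return self.expression.n_samples

    def labels(self) -> list[RelapseLabel]:
        return [r.survival.early_relapse_label for r in self.clinical]

    def binary_labels(self) -> np.ndarray:
        """1 = high (early relapse), 0 = low.  Raises if any label undefined."""
        labs = self.labels()
        if any(l is RelapseLabel.UNDEFINED for l in labs):
            raise ValueError("cohort contains undefined labels; filter_for_binary_eval first")
        return np.array([1 if l is RelapseLabel.HIGH else 0 for l in labs], dtype=int)

    def survival_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        times = np.array([r.survival.dfs_time for r in self.clinical], dtype=float)
        events = np.array([r.survival.dfs_event for r in self.clinical], dtype=bool)
        return times, events


# ---------------------------------------------------------------------------
# dichotomization & filtering
# ---------------------------------------------------------------------------

def dichotomize(
    survival: SurvivalRecord,
    threshold_days: float = DEFAULT_THRESHOLD_DAYS,
    inclusive: bool = True,
) -> RelapseLabel:
    """Binary early-relapse label from a right-censored DFS observation.

    ``high``      event observed at or before the threshold;
    ``low``       follow-up (event or censoring) beyond the threshold;
    ``undefined`` censored at or before the threshold (outcome unknowable).

    ``inclusive`` controls whether an event exactly at the threshold counts
    as early relapse (default: "within a year" read as <= threshold).
    """
    within = survival.dfs_time <= threshold_days if inclusive else survival.dfs_time < threshold_days
    if within:
        return RelapseLabel.HIGH if survival.dfs_event else RelapseLabel.UNDEFINED
    return RelapseLabel.LOW


def apply_dichotomization(
    cohort: CohortProfile,
    threshold_days: float = DEFAULT_THRESHOLD_DAYS,
    inclusive: bool = True,
) -> CohortProfile:
    """Return a cohort whose records carry freshly computed labels."""
    new = []
    for rec in cohort.clinical:
        lab = dichotomize(rec.survival, threshold_days, inclusive)
        new.append(replace(rec, survival=replace(rec.survival, early_relapse_label=lab)))
    return CohortProfile(cohort.name, cohort.expression, new, cohort.platform)


def filter_for_binary_eval(cohort: CohortProfile) -> CohortProfile:
    """Drop samples with undefined labels (censored before threshold).

    The input cohort is unchanged; the number of exclusions is logged.
    Raises if no evaluable sample remains.
    """
    keep = [r.sample_id for r in cohort.clinical
            if r.survival.early_relapse_label is not RelapseLabel.UNDEFINED]
    n_excl = cohort.n_samples - len(keep)
    if not keep:
        raise ValueError(f"cohort {cohort.name!r}: no evaluable samples after filtering")
    if n_excl:
        logger.info("cohort %s: excluded %d sample(s) censored before threshold",
                    cohort.name, n_excl)
    kept_ids = set(keep)
    return CohortProfile(
        cohort.name,
        cohort.expression.subset_samples(keep),
        [r for r in cohort.clinical if r.sample_id in kept_ids],
        cohort.platform,
    )


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------

CLINICAL_COLUMNS = ["sample_id", "dfs_time_days", "dfs_event",
                    "age", "figo_stage", "cohort", "platform"]


def load_expression(path: str | Path) -> ExpressionMatrix:
    """Read a tab-delimited genes x samples matrix (first column gene_id)."""
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    gene_ids = [str(g) for g in df.index]
    sample_ids = [str(s) for s in df.columns]
    try:
        values = df.to_numpy(dtype=float)
    except ValueError:
        arr = df.to_numpy()
        for i in range(arr.shape[0]):
            for j in range(arr.shape[1]):
                try:
                    float(arr[i, j])
                except (TypeError, ValueError):
                    raise ValueError(
                        f"non-numeric expression value {arr[i, j]!r} at gene "
                        f"{gene_ids[i]!r}, sample {sample_ids[j]!r} in {path}"
                    ) from None
        raise
    if not np.all(np.isfinite(values)):
        g, s = np.argwhere(~np.isfinite(values))[0]
        raise ValueError(
            f"missing/non-finite expression value at gene {gene_ids[g]!r}, "
            f"sample {sample_ids[s]!r} in {path}"
        )
    return ExpressionMatrix(gene_ids, sample_ids, values)


def save_expression(expr: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(expr.values, index=expr.gene_ids, columns=expr.sample_ids)
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t", float_format="%.12g")


def load_clinical(
    path: str | Path,
    time_unit: str = "days",
    threshold_days: float = DEFAULT_THRESHOLD_DAYS,
    inclusive: bool = True,
) -> list[ClinicalRecord]:
    """Read the clinical CSV; empty string = absent covariate.

    ``time_unit`` 'days' or 'months' (months converted at 30.44 d/month).
    """
    if time_unit not in ("days", "months"):
        raise ValueError(f"time_unit must be 'days' or 'months', got {time_unit!r}")
    df = pd.read_csv(path, dtype={"sample_id": str})
    for col in ("sample_id", "dfs_time_days", "dfs_event"):
        if col not in df.columns:
            raise ValueError(f"clinical file {path} missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df["sample_id"][df["sample_id"].duplicated()].iloc[0]
        raise ValueError(f"duplicate sample_id {dup!r} in {path}")
    records = []
    for _, row in df.iterrows():
        t = float(row["dfs_time_days"])
        if time_unit == "months":
            t *= DAYS_PER_MONTH
        if t <= 0:
            raise ValueError(f"non-positive dfs_time for sample {row['sample_id']!r}")
        surv = SurvivalRecord(dfs_time=t, dfs_event=bool(int(row["dfs_event"])))
        surv = replace(surv, early_relapse_label=dichotomize(surv, threshold_days, inclusive))

        def _opt(col, cast):
            if col not in row or pd.isna(row[col]) or str(row[col]).strip() == "":
                return None
            return cast(row[col])

        records.append(ClinicalRecord(
            sample_id=str(row["sample_id"]),
            survival=surv,
            age=_opt("age", float),
            figo_stage=_opt("figo_stage", lambda v: int(float(v))),
            cohort=str(row.get("cohort", "") or ""),
            platform=Platform(str(row["platform"])) if _opt("platform", str) else Platform.ARRAY,
        ))
    return records


def save_clinical(records: list[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "sample_id": r.sample_id,
            "dfs_time_days": f"{r.survival.dfs_time:.12g}",
            "dfs_event": int(r.survival.dfs_event),
            "age": "" if r.age is None else f"{r.age:.12g}",
            "figo_stage": "" if r.figo_stage is None else r.figo_stage,
            "cohort": r.cohort,
            "platform": r.platform.value,
        })
    pd.DataFrame(rows, columns=CLINICAL_COLUMNS).to_csv(path, index=False)


def load_gene_map(path: str | Path) -> dict[str, str]:
    """Two-column TSV (source_id, target_id) for caller-side ID harmonization."""
    df = pd.read_csv(path, sep="\t", header=None, dtype=str)
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def load_cohort(
    expression_path: str | Path,
    clinical_path: str | Path,
    platform: Platform | str,
    name: str | None = None,
    time_unit: str = "days",
    threshold_days: float = DEFAULT_THRESHOLD_DAYS,
    inclusive: bool = True,
    gene_map: dict[str, str] | None = None,
) -> CohortProfile:
    """Load and align one cohort; samples present in only one file are dropped
    (count logged).  Duplicate ids and non-numeric cells are hard errors."""
    platform = Platform(platform)
    expr = load_expression(expression_path)
    if gene_map:
        expr = ExpressionMatrix(
            [gene_map.get(g, g) for g in expr.gene_ids], expr.sample_ids, expr.values
        )
    clinical = load_clinical(clinical_path, time_unit, threshold_days, inclusive)
    expr_ids = set(expr.sample_ids)
    clin_ids = {r.sample_id for r in clinical}
    shared = [s for s in expr.sample_ids if s in clin_ids]
    dropped = len(expr_ids ^ clin_ids)
    if dropped:
        logger.warning("cohort %s: dropped %d sample(s) missing from one of the files",
                       name or clinical_path, dropped)
    if not shared:
        raise ValueError("no overlapping samples between expression and clinical files")
    expr = expr.subset_samples(shared)
    clinical = [r for r in clinical if r.sample_id in set(shared)]
    return CohortProfile(
        name=name or Path(expression_path).stem,
        expression=expr,
        clinical=clinical,
        platform=platform,
    )
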