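"""Random-effects pooling of per-cohort performance estimates.

DerSimonian–Laird: fixed-effect weights w = 1/v give the heterogeneity
statistic Q and the method-of-moments tau^2; random-effect weights
w* = 1/(v + tau^2) give the pooled estimate and its SE.  AUROC and C-index
pool on the raw scale (null 0.5); the D-index pools on the log scale
(null 0).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .survstats import PerfEstimate, Z95

_NULL_VALUE = {"auroc": 0.5, "cindex": 0.5, "dindex_log": 0.0}


@dataclass
class MetaEstimate:
    statistic: str
    pooled: float
    se: float
    ci95: tuple[float, float]
    p_value: float
    tau2: float
    Q: float
    cohort_estimates: list[PerfEstimate]
    scale: str = "raw"  # raw | log
    label: str = ""

    @property
    def display_pooled(self) -> float:
        return float(np.exp(self.pooled)) if self.statistic == "dindex_log" else self.pooled

    @property
    def display_ci95(self) -> tuple[float, float]:
        if self.statistic == "dindex_log":
            return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))
        return self.ci95


def pool_random_effects(
    estimates: list[PerfEstimate], scale: str | None = None, label: str = ""
) -> MetaEstimate:
    """DerSimonian–Laird random-effects pooling of >= 2 cohort estimates."""
    if len(estimates) < 2:
        raise ValueError("need at least two cohort estimates to pool")
    stats = {e.statistic for e in estimates}
    if len(stats) != 1:
        raise ValueError(f"cannot pool mixed statistics {stats}")
    statistic = stats.pop()
    if scale is None:
        scale = "log" if statistic == "dindex_log" else "raw"
    theta = np.array([e.value for e in estimates], dtype=float)
    se = np.array([e.se for e in estimates], dtype=float)
    if np.any(~np.isfinite(se)) or np.any(se <= 0):
        raise ValueError("all estimates must have finite positive SE")
    v = se**2
    w = 1.0 / v
    theta_fe = float((w * theta).sum() / w.sum())
    q = float((w * (theta - theta_fe) ** 2).sum())
    k = len(estimates)
    denom = w.sum() - (w**2).sum() / w.sum()
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_star = 1.0 / (v + tau2)
    pooled = float((w_star * theta).sum() / w_star.sum())
    pooled_se = float(1.0 / np.sqrt(w_star.sum()))
    null = _NULL_VALUE.get(statistic, 0.0)
    z = (pooled - null) / pooled_se
    p = float(2.0 * norm.sf(abs(z)))
    return MetaEstimate(
        statistic=statistic, pooled=pooled, se=pooled_se,
        ci95=(pooled - Z95 * pooled_se, pooled + Z95 * pooled_se),
        p_value=p, tau2=float(tau2), Q=q,
        cohort_estimates=list(estimates), scale=scale, label=label,
    )


def leave_one_out(estimates: list[PerfEstimate], scale: str | None = None) -> list[MetaEstimate]:
    """Pooled estimate with each cohort omitted in turn (influence check)."""
    if len(estimates) < 3:
        raise ValueError("leave-one-out needs at least three cohorts")
    out = []
    for i, omitted in enumerate(estimates):
        rest = estimates[:i] + estimates[i + 1:]
        out.append(pool_random_effects(rest, scale=scale,
                                       label=f"omit:{omitted.cohort}"))
    return out


def compare_meta(
    a: MetaEstimate, b: MetaEstimate, alternative: str = "a_greater",
    paired_differences: list[tuple[float, float]] | None = None,
) -> tuple[float, float]:
    """One-sided superiority test of pooled estimate a over b.

    Default treats the two meta-estimates as independent:
    z = (a - b)/sqrt(se_a^2 + se_b^2).  Because the same cohorts usually
    underlie both models this is anti-conservative; passing per-cohort
    ``paired_differences`` [(diff, se_diff), ...] instead pools the
    differences and tests their pooled mean against 0.
    """
    if alternative != "a_greater":
        raise ValueError("only alternative='a_greater' is supported")
    if a.statistic != b.statistic or a.scale != b.scale:
        raise ValueError("meta-estimates must share statistic and scale")
    if paired_differences is not None:
        diffs = [
            PerfEstimate("diff", d, s, (d - Z95 * s, d + Z95 * s), float("nan"), 0)
            for d, s in paired_differences
        ]
        pooled = pool_random_effects(diffs, scale=a.scale)
        z = pooled.pooled / pooled.se
    else:
        z = (a.pooled - b.pooled) / np.sqrt(a.se**2 + b.se**2)
    return float(z), float(norm.sf(z))


def forest_table(meta: MetaEstimate) -> pd.DataFrame:
    """Forest-plot data: one row per cohort plus the flagged pooled row."""
    w_star = np.array([1.0 / (e.se**2 + meta.tau2) for e in meta.cohort_estimates])
    w_star = w_star / w_star.sum()
    rows = [
        {
            "cohort": e.cohort,
            "estimate": e.display_value,
            "lo": e.display_ci95[0],
            "hi": e.display_ci95[1],
            "weight": float(w),
            "pooled": False,
        }
        for e, w in zip(meta.cohort_estimates, w_star)
    ]
    rows.append({
        "cohort": "POOLED",
        "estimate": meta.display_pooled,
        "lo": meta.display_ci95[0],
        "hi": meta.display_ci95[1],
        "weight": 1.0,
        "pooled": True,
    })
    return pd.DataFrame(rows)
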