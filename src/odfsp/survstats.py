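"""Discrimination and survival statistics.

AUROC (Mann–Whitney formulation, Hanley–McNeil SE), balanced accuracy,
Harrell's concordance index with Noether SE, the Royston–Sauerbrei D-index
(exponentiated Cox coefficient of the scaled-rankit risk score — a robust
hazard-ratio analogue), Kaplan–Meier curves, the two-group log-rank test,
and the median risk-score split used to define low/high-risk groups.

The D-index is pooled across cohorts on the log scale, so estimators
return log D in ``value`` with ``display_value`` giving exp(log D).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.utils import qth_survival_times
from scipy.stats import norm, rankdata

Z95 = 1.959963984540054

KAPPA = float(np.sqrt(8.0 / np.pi))  # rankit scaling for the D-index


@dataclass
class PerfEstimate:
    statistic: str  # auroc | cindex | dindex_log
    value: float  # on the pooling scale (log for the D-index)
    se: float
    ci95: tuple[float, float]
    p_value: float
    n: int
    cohort: str = ""
    extras: dict = field(default_factory=dict)

    @property
    def display_value(self) -> float:
        """Value on the reporting scale (exp for the D-index)."""
        return float(np.exp(self.value)) if self.statistic == "dindex_log" else self.value

    @property
    def display_ci95(self) -> tuple[float, float]:
        if self.statistic == "dindex_log":
            return (float(np.exp(self.ci95[0])), float(np.exp(self.ci95[1])))
        return self.ci95


def _normal_ci(value: float, se: float) -> tuple[float, float]:
    return (value - Z95 * se, value + Z95 * se)


# ---------------------------------------------------------------------------
# AUROC & balanced accuracy
# ---------------------------------------------------------------------------

def auroc(scores, labels, cohort: str = "") -> PerfEstimate:
    """Area under the ROC curve by the rank (Mann–Whitney) formulation.

    AUROC = P(score_high > score_low) + 0.5 P(tie); the p-value is the
    two-sided tie-corrected normal-approximation Mann–Whitney test of
    AUROC != 0.5, and the SE is Hanley–McNeil.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n1 = int((labels == 1).sum())
    n0 = int((labels == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("auroc requires both classes present")
    n = n1 + n0
    ranks = rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2.0
    a = u / (n1 * n0)

    # tie-corrected MW variance
    _, counts = np.unique(scores, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (n * (n - 1.0)) if n > 1 else 0.0
    var_u = n1 * n0 / 12.0 * ((n + 1) - tie_term)
    if var_u > 0:
        z = (u - n1 * n0 / 2.0) / np.sqrt(var_u)
        p = 2.0 * norm.sf(abs(z))
    else:
        p = 1.0

    q1 = a / (2.0 - a)
    q2 = 2.0 * a * a / (1.0 + a)
    se = float(np.sqrt(max(
        (a * (1 - a) + (n1 - 1) * (q1 - a * a) + (n0 - 1) * (q2 - a * a)) / (n1 * n0),
        0.0)))
    # perfect separation gives SE 0; floor at the smallest resolvable AUROC
    # increment so the estimate stays usable in inverse-variance pooling
    se = max(se, 1.0 / (n1 * n0))
    return PerfEstimate("auroc", float(a), se, _normal_ci(float(a), se),
                        float(p), n, cohort)


def balanced_accuracy(pred_labels, true_labels) -> float:
    """(sensitivity + specificity) / 2."""
    pred = np.asarray(pred_labels, dtype=int)
    truth = np.asarray(true_labels, dtype=int)
    if (truth == 1).sum() == 0 or (truth == 0).sum() == 0:
        raise ValueError("balanced accuracy requires both classes in truth")
    sens = float((pred[truth == 1] == 1).mean())
    spec = float((pred[truth == 0] == 0).mean())
    return (sens + spec) / 2.0


# ---------------------------------------------------------------------------
# Harrell's C-index
# ---------------------------------------------------------------------------

def concordance_index(scores, times, events, cohort: str = "") -> PerfEstimate:
    """Harrell's C: fraction of comparable patient pairs whose risk ordering
    matches survival ordering, ties in risk counting one half.

    A pair is comparable when the shorter time is an observed event (for
    tied times, when exactly one member has an event, whose risk should be
    higher).  SE via Noether's U-statistic approximation; p two-sided
    against C = 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = scores.size
    if n < 2:
        raise ValueError("need at least two observations")

    dt = times[:, None] - times[None, :]
    ds = scores[:, None] - scores[None, :]
    ev_i = events[:, None]
    ev_j = events[None, :]
    # ordered pair (i, j): i experienced the event strictly first, or at a
    # tied time only i had the event
    comp = (ev_i & (dt < 0)) | (ev_i & ~ev_j & (dt == 0))
    np.fill_diagonal(comp, False)
    conc = comp & (ds > 0)
    disc = comp & (ds < 0)
    tie = comp & (ds == 0)

    n_comp = int(comp.sum())
    if n_comp == 0:
        raise ValueError("no comparable pairs")
    c_pairs = conc.sum() + 0.5 * tie.sum()
    cval = float(c_pairs / n_comp)

    # Noether variance from per-subject concordant/discordant counts
    # (pairs counted symmetrically; risk ties split half/half)
    ch = (conc.sum(axis=1) + conc.sum(axis=0) + 0.5 * (tie.sum(axis=1) + tie.sum(axis=0)))
    dh = (disc.sum(axis=1) + disc.sum(axis=0) + 0.5 * (tie.sum(axis=1) + tie.sum(axis=0)))
    denom = n * (n - 1.0)
    pc = ch.sum() / denom
    pd_ = dh.sum() / denom
    if n > 2 and (pc + pd_) > 0:
        d3 = denom * (n - 2.0)
        pcc = (ch * (ch - 1)).sum() / d3
        pdd = (dh * (dh - 1)).sum() / d3
        pcd = (ch * dh).sum() / d3
        varp = 4.0 * ((pd_**2 * pcc - 2 * pc * pd_ * pcd + pc**2 * pdd)
                      / (pc + pd_) ** 4) / n
        se = float(np.sqrt(max(varp, 0.0)))
    else:
        se = float("nan")
    if se and np.isfinite(se) and se > 0:
        z = (cval - 0.5) / se
        p = float(2.0 * norm.sf(abs(z)))
    else:
        p = float("nan")
    return PerfEstimate("cindex", cval, se, _normal_ci(cval, se), p, n, cohort,
                        extras={"n_comparable": n_comp})


# ---------------------------------------------------------------------------
# Royston–Sauerbrei D-index
# ---------------------------------------------------------------------------

def scaled_rankits(scores: np.ndarray) -> np.ndarray:
    """Blom rankits Phi^{-1}((r - 3/8)/(n + 1/4)) of the scores, divided by
    kappa = sqrt(8/pi)."""
    scores = np.asarray(scores, dtype=float)
    r = rankdata(scores)  # average ranks for ties
    return norm.ppf((r - 0.375) / (scores.size + 0.25)) / KAPPA


def _cox_univariate_breslow(
    x: np.ndarray, times: np.ndarray, events: np.ndarray,
    tol: float = 1e-8, max_iter: int = 100,
) -> tuple[float, float]:
    """Newton–Raphson fit of a one-covariate Cox model with Breslow ties.

    Returns (beta, se_beta).  Raises on non-convergence.
    """
    order = np.argsort(times, kind="stable")
    t, xo, ev = times[order], x[order], events[order]
    n = t.size
    # index of the first observation with time == t[i] (risk set boundary)
    first = np.searchsorted(t, t, side="left")
    ev_idx = np.flatnonzero(ev)
    beta = 0.0
    for _ in range(max_iter):
        w = np.exp(beta * xo)
        s0 = np.cumsum(w[::-1])[::-1]
        s1 = np.cumsum((w * xo)[::-1])[::-1]
        s2 = np.cumsum((w * xo * xo)[::-1])[::-1]
        r0 = s0[first[ev_idx]]
        r1 = s1[first[ev_idx]]
        r2 = s2[first[ev_idx]]
        mean = r1 / r0
        grad = float((xo[ev_idx] - mean).sum())
        info = float((r2 / r0 - mean**2).sum())
        if abs(grad) < tol:
            break
        if info <= 0:
            raise RuntimeError("singular information matrix in Cox fit")
        step = grad / info
        step = float(np.clip(step, -5.0, 5.0))  # damped step for stability
        beta += step
    else:
        raise RuntimeError("Cox Newton-Raphson did not converge in "
                           f"{max_iter} iterations")
    return beta, float(1.0 / np.sqrt(info)) if info > 0 else float("nan")


def d_index(scores, times, events, cohort: str = "") -> PerfEstimate:
    """Royston–Sauerbrei D: exp of the Cox coefficient of the scaled-rankit
    transform of the risk scores.  Returned on the log scale (``value`` =
    log D); constant scores give D = 1 with an undefined-SE flag."""
    scores = np.asarray(scores, dtype=float)
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    n = scores.size
    if n < 10:
        raise ValueError("d_index requires n >= 10")
    if events.sum() < 2:
        raise ValueError("d_index requires at least 2 events")
    if np.ptp(scores) == 0:
        return PerfEstimate("dindex_log", 0.0, float("nan"),
                            (float("nan"), float("nan")), float("nan"), n,
                            cohort, extras={"se_undefined": True})
    z = scaled_rankits(scores)
    beta, se = _cox_univariate_breslow(z, times, events)
    p = float(2.0 * norm.sf(abs(beta / se))) if se > 0 else float("nan")
    return PerfEstimate("dindex_log", float(beta), se, _normal_ci(beta, se), p,
                        n, cohort)


# ---------------------------------------------------------------------------
# Kaplan-Meier, log-rank, median split
# ---------------------------------------------------------------------------

@dataclass
class KmCurve:
    times: np.ndarray  # distinct event times, increasing
    survival: np.ndarray  # S(t) just after each event time, non-increasing
    n_at_risk: np.ndarray
    median: float | None  # first time S(t) <= 0.5; None if never reached


def km_curve(times, events) -> KmCurve:
    """Product-limit (Kaplan-Meier) survival estimate."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size < 1:
        raise ValueError("need at least one observation")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    event_rows = tab[tab["observed"] > 0]
    ts = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[ts, "KM_estimate"].to_numpy(dtype=float)
    at_risk = event_rows["at_risk"].to_numpy(dtype=int)
    med = qth_survival_times(0.5, kmf.survival_function_)
    median = None if np.isinf(med) else float(med)
    return KmCurve(ts, surv, at_risk, median)


def logrank(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test: (chi-square on 1 df, p-value)."""
    res = _ll_logrank(
        np.asarray(times_a, dtype=float), np.asarray(times_b, dtype=float),
        event_observed_A=np.asarray(events_a, dtype=bool),
        event_observed_B=np.asarray(events_b, dtype=bool),
    )
    return float(res.test_statistic), float(res.p_value)


def median_split(scores) -> np.ndarray:
    """Within-cohort split at the median score: 1 = high risk iff
    score > median (ties at the median go low)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size < 2:
        raise ValueError("need at least two scores")
    if np.ptp(scores) == 0:
        raise ValueError("degenerate split: all scores equal")
    return (scores > np.median(scores)).astype(int)
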