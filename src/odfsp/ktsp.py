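"""k-Top-Scoring-Disjoint-Pairs classifier and resampled ensemble.

A pair rule (i, j) votes from the binary indicator I(x_i < x_j) computed
within a single sample, so predictions depend only on the within-sample
gene ordering and are invariant to any strictly increasing per-sample
transform — the property that lets one model cross platforms and batches.

The primary pair score is the between-class difference in ordering
probability, Delta_ij = |P(X_i < X_j | high) - P(X_i < X_j | low)|; ties in
Delta break on the secondary rank-difference score gamma, then on the
lexicographic pair id, so builds are deterministic.  A model is k disjoint
pairs (no shared gene) voting by majority; the ensemble averages the votes
of B models trained on class-balanced resamples, yielding a continuous
risk score in [0, 1].
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.stats import rankdata

from .data_model import CohortProfile, ExpressionMatrix, filter_for_binary_eval

# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairRule:
    gene_i: str
    gene_j: str
    score_delta: float
    orientation: bool  # True => I(x_i < x_j) votes high
    tiebreak_gamma: float = 0.0

    def __post_init__(self):
        if self.gene_i == self.gene_j:
            raise ValueError("pair genes must differ")
        if not (0.0 <= self.score_delta <= 1.0):
            raise ValueError("score_delta must be in [0, 1]")


@dataclass
class KtspModel:
    pairs: list[PairRule]
    k: int
    training_meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.k != len(self.pairs):
            raise ValueError("k must equal the number of pairs")
        if self.k < 1 or self.k % 2 == 0:
            raise ValueError("k must be an odd positive integer")
        genes = [g for p in self.pairs for g in (p.gene_i, p.gene_j)]
        if len(set(genes)) != len(genes):
            raise ValueError("pairs must be gene-disjoint within a model")

    @property
    def genes(self) -> set[str]:
        return {g for p in self.pairs for g in (p.gene_i, p.gene_j)}


@dataclass
class OdfspEnsemble:
    models: list[KtspModel]

    def __post_init__(self):
        if len(self.models) < 1:
            raise ValueError("ensemble needs at least one model")

    @property
    def B(self) -> int:
        return len(self.models)

    @property
    def distinct_pairs(self) -> set[tuple[str, str]]:
        return {tuple(sorted((p.gene_i, p.gene_j)))
                for m in self.models for p in m.pairs}

    @property
    def distinct_genes(self) -> set[str]:
        return {g for m in self.models for g in m.genes}


@dataclass(frozen=True)
class Barcode:
    sample_id: str
    bits: tuple[int, ...]


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

def _check_classes(labels: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    labels = np.asarray(labels, dtype=int)
    hi, lo = labels == 1, labels == 0
    if hi.sum() == 0 or lo.sum() == 0:
        raise ValueError("both classes must be non-empty")
    return hi, lo


def pair_score_matrices(
    values: np.ndarray, labels: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorised pair scores for a genes x samples matrix.

    Returns (delta, orientation, gamma), each genes x genes; entry (i, j)
    scores the ordered pair (i, j) with indicator I(x_i < x_j).
    """
    hi, lo = _check_classes(labels)
    less = values[:, None, :] < values[None, :, :]  # (g, g, n)
    p_hi = less[:, :, hi].mean(axis=2)
    p_lo = less[:, :, lo].mean(axis=2)
    delta = np.abs(p_hi - p_lo)
    orientation = p_hi > p_lo
    # secondary score: between-class difference of mean within-sample
    # rank differences of the two genes
    ranks = rankdata(values, axis=0)  # within-sample gene ranks
    mean_hi = ranks[:, hi].mean(axis=1)
    mean_lo = ranks[:, lo].mean(axis=1)
    gamma = np.abs((mean_hi[:, None] - mean_hi[None, :])
                   - (mean_lo[:, None] - mean_lo[None, :]))
    return delta, orientation, gamma


def pair_score(
    expr: ExpressionMatrix, labels: np.ndarray, gene_i: str, gene_j: str
) -> tuple[float, bool, float]:
    """Score one ordered gene pair: (score_delta, orientation, gamma).

    gamma uses within-sample ranks over the full gene set of ``expr``, as
    in the matrix form.
    """
    hi, lo = _check_classes(labels)
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    i, j = gidx[gene_i], gidx[gene_j]
    less = expr.values[i, :] < expr.values[j, :]
    p_hi, p_lo = less[hi].mean(), less[lo].mean()
    ranks = rankdata(expr.values, axis=0)
    d = ranks[i, :] - ranks[j, :]
    gamma = abs(d[hi].mean() - d[lo].mean())
    return float(abs(p_hi - p_lo)), bool(p_hi > p_lo), float(gamma)


def wilcoxon_filter(expr: ExpressionMatrix, labels: np.ndarray, m: int) -> list[str]:
    """The m genes most associated with the class label by the standardized
    Wilcoxon rank-sum statistic (tie-corrected normal standardisation),
    ordered by |z| descending then gene id ascending."""
    if m <= 0:
        raise ValueError("m must be positive")
    if m > expr.n_genes:
        raise ValueError(f"m={m} exceeds {expr.n_genes} genes")
    z = wilcoxon_z(expr.values, labels)
    order = sorted(range(expr.n_genes), key=lambda g: (-abs(z[g]), expr.gene_ids[g]))
    return [expr.gene_ids[g] for g in order[:m]]


def wilcoxon_z(values: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Standardized rank-sum statistic per gene (row), tie-robust.

    Var(W) = n1*n2/(n*(n-1)) * sum_s (r_s - (n+1)/2)^2 reduces to the usual
    tie-corrected variance; constant genes get z = 0.
    """
    hi, lo = _check_classes(labels)
    n1, n = int(hi.sum()), values.shape[1]
    ranks = rankdata(values, axis=1)
    w = ranks[:, hi].sum(axis=1)
    expect = n1 * (n + 1) / 2.0
    ss = ((ranks - (n + 1) / 2.0) ** 2).sum(axis=1)
    var = n1 * (n - n1) / (n * (n - 1.0)) * ss
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0, (w - expect) / np.sqrt(var), 0.0)
    return z


# ---------------------------------------------------------------------------
# pair selection & training
# ---------------------------------------------------------------------------

def select_disjoint_pairs(
    expr: ExpressionMatrix, labels: np.ndarray, k_max: int
) -> list[PairRule]:
    """Greedy disjoint selection over all pairs of ``expr``'s genes, in the
    order (delta desc, gamma desc, lexicographic pair id asc)."""
    delta, orientation, gamma = pair_score_matrices(expr.values, labels)
    g = expr.n_genes
    iu, ju = np.triu_indices(g, k=1)
    id_rank = rankdata(np.array(expr.gene_ids, dtype=object), method="ordinal")
    lo_id = np.minimum(id_rank[iu], id_rank[ju])
    hi_id = np.maximum(id_rank[iu], id_rank[ju])
    order = np.lexsort((hi_id, lo_id, -gamma[iu, ju], -delta[iu, ju]))
    used = np.zeros(g, dtype=bool)
    out: list[PairRule] = []
    for idx in order:
        i, j = int(iu[idx]), int(ju[idx])
        if used[i] or used[j]:
            continue
        used[i] = used[j] = True
        # canonical storage: gene_i/gene_j in lexicographic id order, with
        # the orientation flipped accordingly
        gi, gj = expr.gene_ids[i], expr.gene_ids[j]
        ori = bool(orientation[i, j])
        if gj < gi:
            gi, gj, ori = gj, gi, not ori
        out.append(PairRule(gi, gj, float(delta[i, j]), ori, float(gamma[i, j])))
        if len(out) == k_max:
            break
    return out


def _majority_votes(values: np.ndarray, gene_index: dict[str, int],
                    pairs: list[PairRule]) -> np.ndarray:
    """High-votes count per sample for a pair list (columns = samples)."""
    votes = np.zeros(values.shape[1], dtype=int)
    for p in pairs:
        bit = values[gene_index[p.gene_i], :] < values[gene_index[p.gene_j], :]
        votes += (bit == p.orientation)
    return votes


def _stratified_folds(labels: np.ndarray, n_folds: int,
                      rng: np.random.Generator) -> list[np.ndarray]:
    folds: list[list[int]] = [[] for _ in range(n_folds)]
    for cls in (0, 1):
        idx = np.flatnonzero(labels == cls)
        rng.shuffle(idx)
        for pos, i in enumerate(idx):
            folds[pos % n_folds].append(int(i))
    return [np.array(sorted(f), dtype=int) for f in folds]


def train_ktsp(
    expr: ExpressionMatrix,
    labels: np.ndarray,
    m: int = 200,
    k_grid: tuple[int, ...] = tuple(range(3, 26, 2)),
    cv_folds: int = 5,
    seed: int = 0,
) -> KtspModel:
    """Train one k-TSP model.

    Filter to the top-m Wilcoxon genes, score all pairs, greedily select
    disjoint pairs, pick k from ``k_grid`` by stratified cross-validated
    balanced accuracy (smallest k on ties), and emit the top-k pairs
    selected on the full data.
    """
    labels = np.asarray(labels, dtype=int)
    if min((labels == 0).sum(), (labels == 1).sum()) < 2:
        raise ValueError("need at least 2 samples per class")
    k_grid = tuple(sorted(set(int(k) for k in k_grid)))
    if any(k < 1 or k % 2 == 0 for k in k_grid):
        raise ValueError("k_grid must contain odd positive integers")
    m_eff = min(m, expr.n_genes)
    filtered = expr.subset_genes(wilcoxon_filter(expr, labels, m_eff))
    k_max = max(k_grid)
    full_pairs = select_disjoint_pairs(filtered, labels, k_max)
    feasible = [k for k in k_grid if k <= len(full_pairs)]
    if not feasible:
        raise ValueError(
            f"only {len(full_pairs)} disjoint pairs available; "
            f"cannot reach the smallest requested k={min(k_grid)}")

    if len(feasible) == 1:
        k_best = feasible[0]
    else:
        rng = np.random.default_rng(seed)
        folds = _stratified_folds(labels, cv_folds, rng)
        bac_sum = {k: 0.0 for k in feasible}
        for test_idx in folds:
            test_mask = np.zeros(labels.size, dtype=bool)
            test_mask[test_idx] = True
            tr, te = ~test_mask, test_mask
            if min((labels[te] == 0).sum(), (labels[te] == 1).sum()) == 0:
                continue
            if min((labels[tr] == 0).sum(), (labels[tr] == 1).sum()) < 2:
                continue
            sub = ExpressionMatrix(list(expr.gene_ids),
                                   [expr.sample_ids[i] for i in np.flatnonzero(tr)],
                                   expr.values[:, tr])
            filt = sub.subset_genes(wilcoxon_filter(sub, labels[tr], m_eff))
            pairs = select_disjoint_pairs(filt, labels[tr], k_max)
            gidx = {g: i for i, g in enumerate(expr.gene_ids)}
            te_vals = expr.values[:, te]
            for k in feasible:
                if k > len(pairs):
                    continue
                votes = _majority_votes(te_vals, gidx, pairs[:k])
                pred = (votes > k / 2).astype(int)
                truth = labels[te]
                sens = (pred[truth == 1] == 1).mean()
                spec = (pred[truth == 0] == 0).mean()
                bac_sum[k] += (sens + spec) / 2.0
        k_best = min(feasible, key=lambda k: (-round(bac_sum[k], 12), k))

    return KtspModel(
        pairs=full_pairs[:k_best],
        k=k_best,
        training_meta={"n_samples": int(labels.size), "m": int(m_eff), "seed": int(seed)},
    )


# ---------------------------------------------------------------------------
# barcodes & prediction
# ---------------------------------------------------------------------------

def barcode_transform(expr: ExpressionMatrix, pairs: list[PairRule]) -> list[Barcode]:
    """Binary pair-order indicators per sample; ties (equal values) give 0."""
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    for p in pairs:
        for g in (p.gene_i, p.gene_j):
            if g not in gidx:
                raise KeyError(f"gene {g!r} missing from expression matrix")
    bits = np.stack([
        expr.values[gidx[p.gene_i], :] < expr.values[gidx[p.gene_j], :]
        for p in pairs
    ], axis=0).astype(int)  # (pairs, samples)
    return [Barcode(sid, tuple(bits[:, s])) for s, sid in enumerate(expr.sample_ids)]


def predict_model(model: KtspModel, expr: ExpressionMatrix) -> np.ndarray:
    """Per-sample binary vote (1 = high risk) by pair majority."""
    gidx = {g: i for i, g in enumerate(expr.gene_ids)}
    missing = [g for g in model.genes if g not in gidx]
    if missing:
        raise KeyError(f"genes missing from expression matrix: {sorted(missing)[:5]}")
    votes = _majority_votes(expr.values, gidx, model.pairs)
    return (votes > model.k / 2).astype(int)


def score_ensemble(ens: OdfspEnsemble, expr: ExpressionMatrix) -> np.ndarray:
    """Continuous risk score in [0, 1]: fraction of models voting high."""
    votes = np.zeros(expr.n_samples, dtype=float)
    for model in ens.models:
        votes += predict_model(model, expr)
    return votes / ens.B


# ---------------------------------------------------------------------------
# ensemble training on (possibly dual-platform) cohorts
# ---------------------------------------------------------------------------

def stack_training_instances(
    training: list[CohortProfile],
) -> tuple[ExpressionMatrix, np.ndarray, list[str]]:
    """Stack per-platform profiles into one instance matrix.

    Cohorts are first restricted to samples with defined early-relapse
    labels; each patient contributes one instance per platform profile with
    the same label.  Genes are intersected across cohorts (first cohort's
    order).  Returns (matrix, labels, patient ids per instance).
    """
    if not training:
        raise ValueError("no training cohorts")
    filtered = [filter_for_binary_eval(c) for c in training]
    genes = [g for g in filtered[0].expression.gene_ids
             if all(g in set(c.expression.gene_ids) for c in filtered[1:])]
    if not genes:
        raise ValueError("no shared genes across training cohorts")
    blocks, labels, patients, col_ids = [], [], [], []
    for c in filtered:
        sub = c.expression.subset_genes(genes)
        blocks.append(sub.values)
        labels.append(c.binary_labels())
        patients.extend(sub.sample_ids)
        col_ids.extend(f"{c.name}::{s}" for s in sub.sample_ids)
    expr = ExpressionMatrix(genes, col_ids, np.concatenate(blocks, axis=1))
    return expr, np.concatenate(labels), patients


def train_ensemble(
    training: list[CohortProfile],
    B: int = 20,
    resample_fraction: float = 0.8,
    m: int = 200,
    k_grid: tuple[int, ...] = tuple(range(3, 26, 2)),
    cv_folds: int = 5,
    seed: int = 0,
) -> OdfspEnsemble:
    """Train B k-TSP models on class-balanced resamples of the stacked
    training instances (without replacement within a resample)."""
    if B < 1:
        raise ValueError("B must be >= 1")
    if not (0 < resample_fraction <= 1):
        raise ValueError("resample_fraction must be in (0, 1]")
    expr, labels, _ = stack_training_instances(training)
    rng = np.random.default_rng(seed)
    models = []
    for b in range(B):
        if B == 1 and resample_fraction == 1.0:
            idx = np.arange(labels.size)
        else:
            parts = []
            for cls in (0, 1):
                cls_idx = np.flatnonzero(labels == cls)
                n_take = max(2, int(round(resample_fraction * cls_idx.size)))
                n_take = min(n_take, cls_idx.size)
                parts.append(rng.choice(cls_idx, size=n_take, replace=False))
            idx = np.sort(np.concatenate(parts))
        sub = ExpressionMatrix(list(expr.gene_ids),
                               [expr.sample_ids[i] for i in idx],
                               expr.values[:, idx])
        models.append(train_ktsp(sub, labels[idx], m=m, k_grid=k_grid,
                                 cv_folds=cv_folds,
                                 seed=int(rng.integers(0, 2**31 - 1))))
    return OdfspEnsemble(models=models)


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------

def ensemble_to_dict(ens: OdfspEnsemble, meta: dict | None = None) -> dict:
    return {
        "models": [
            {
                "k": m.k,
                "pairs": [
                    {"i": p.gene_i, "j": p.gene_j, "orientation": p.orientation,
                     "delta": p.score_delta, "gamma": p.tiebreak_gamma}
                    for p in m.pairs
                ],
                "training_meta": m.training_meta,
            }
            for m in ens.models
        ],
        "meta": dict(meta or {}),
    }


def save_ensemble(ens: OdfspEnsemble, path: str | Path, meta: dict | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(ensemble_to_dict(ens, meta), fh, indent=1, sort_keys=True)


def load_ensemble(path: str | Path) -> OdfspEnsemble:
    with open(path) as fh:
        doc = json.load(fh)
    models = [
        KtspModel(
            pairs=[PairRule(p["i"], p["j"], p["delta"], p["orientation"],
                            p.get("gamma", 0.0)) for p in m["pairs"]],
            k=m["k"],
            training_meta=m.get("training_meta", {}),
        )
        for m in doc["models"]
    ]
    return OdfspEnsemble(models=models)
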