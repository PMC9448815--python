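"""IQ-correlated edge sets and subdomain regressions.

The unified model's strongest ``k`` edges (by absolute weight, default
500) form the "IQ-correlated" set; the remainder is the control pool.
In-sample multiple linear regression (MLR) of FSIQ and its five
subdomain indices on the correlated set quantifies how much of each
score the signature carries, and a controlled permutation — refitting
on ``k`` edges drawn at random from the uncorrelated pool — provides a
null that shares the fit's dimensionality, so in-sample R^2 inflation
cancels out of the comparison.

Pattern similarity between subdomains is the inner product of their
unit-normalized MLR weight vectors; ROI-level regressions replace the
``k`` edge regressors with per-subject weighted incident-edge sums.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import ConnectomeDataset, EdgeIndexMap, UnifiedModel

logger = logging.getLogger(__name__)

__all__ = ["EdgeSetPartition", "SubdomainFit", "top_k_edges", "mlr_fit",
           "controlled_permutation", "pattern_similarity",
           "roi_level_regression"]


@dataclass
class EdgeSetPartition:
    """Disjoint, exhaustive split into correlated / uncorrelated edges."""

    correlated: np.ndarray
    uncorrelated: np.ndarray
    n_edges: int

    def __post_init__(self) -> None:
        self.correlated = np.asarray(self.correlated, dtype=int)
        self.uncorrelated = np.asarray(self.uncorrelated, dtype=int)
        both = np.concatenate([self.correlated, self.uncorrelated])
        if np.intersect1d(self.correlated, self.uncorrelated).size:
            raise ValueError("correlated/uncorrelated sets overlap")
        if not np.array_equal(np.sort(both), np.arange(self.n_edges)):
            raise ValueError("partition must cover all edges exactly once")


@dataclass
class SubdomainFit:
    """One MLR fit: weights, fitted values, and the true-fitted r."""

    target: str
    weights: np.ndarray  # regressor coefficients (no intercept entry)
    intercept: float
    fitted: np.ndarray
    r: float
    p: float
    rank_deficient: bool = False
    null_r: np.ndarray | None = None
    null_p: float | None = None


def top_k_edges(model: UnifiedModel, k: int = 500) -> EdgeSetPartition:
    """Rank edges by |unified weight| and keep the top ``k``.

    Ties break by edge id ascending so the partition is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if k > model.n_edges:
        raise ValueError(f"k={k} exceeds n_edges={model.n_edges}")
    # stable sort on (-|w|, id): mergesort keeps id order within ties
    order = np.argsort(-np.abs(model.weights), kind="stable")
    corr = np.sort(order[:k])
    uncorr = np.sort(order[k:])
    return EdgeSetPartition(correlated=corr, uncorrelated=uncorr,
                            n_edges=model.n_edges)


def mlr_fit(x: np.ndarray, y: np.ndarray, target: str = "fsiq",
            ) -> SubdomainFit:
    """In-sample least squares of ``y`` on the columns of ``x``.

    Uses the minimum-norm solution when the design is rank-deficient
    (flagged and logged).  The reported r is the Pearson correlation
    between fitted and true values, which for OLS with intercept equals
    sqrt(R^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x must be subjects x features aligned with y")
    if x.shape[0] < 2:
        raise ValueError("need more than one subject")
    if y.std() == 0:
        raise ValueError("constant target; regression undefined")
    design = np.column_stack([np.ones(x.shape[0]), x])
    coef, _, rank, _ = np.linalg.lstsq(design, y, rcond=None)
    deficient = rank < design.shape[1]
    if deficient:
        logger.warning("rank-deficient MLR design (rank %d of %d); "
                       "minimum-norm solution used", rank, design.shape[1])
    fitted = design @ coef
    if fitted.std() == 0:
        r, p = 0.0, 1.0
    else:
        r, p = stats.pearsonr(fitted, y)
    return SubdomainFit(target=target, weights=coef[1:],
                        intercept=float(coef[0]), fitted=fitted,
                        r=float(r), p=float(p), rank_deficient=bool(deficient))


def _subject_design(dataset: ConnectomeDataset, edges: np.ndarray,
                    target: str) -> tuple[np.ndarray, np.ndarray]:
    subs, fc = dataset.subject_fc()
    y = dataset.phenotypes.loc[subs, target].to_numpy(dtype=float)
    return fc[:, edges], y


def controlled_permutation(dataset: ConnectomeDataset,
                           partition: EdgeSetPartition, target: str,
                           n_trials: int = 1000, seed: int = 0,
                           ) -> SubdomainFit:
    """Observed MLR on the correlated set vs. random uncorrelated sets.

    Each trial refits the same-size MLR on ``k`` edges sampled without
    replacement from the uncorrelated pool and records its true-fitted
    r; ``p = (1 + #{null >= observed}) / (1 + n_trials)``.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    k = partition.correlated.size
    if partition.uncorrelated.size < k:
        raise ValueError("uncorrelated pool smaller than the edge set")
    x_obs, y = _subject_design(dataset, partition.correlated, target)
    fit = mlr_fit(x_obs, y, target=target)
    rng = np.random.default_rng(seed)
    _, fc = dataset.subject_fc()
    null_r = np.empty(n_trials)
    for t in range(n_trials):
        pick = rng.choice(partition.uncorrelated, size=k, replace=False)
        null_r[t] = mlr_fit(fc[:, pick], y, target=target).r
    fit.null_r = null_r
    fit.null_p = float((1 + np.sum(null_r >= fit.r)) / (1 + n_trials))
    return fit


def pattern_similarity(fits: list[SubdomainFit]) -> pd.DataFrame:
    """Inner products of unit-normalized MLR weight vectors.

    All fits must share the same regressor set; the matrix is symmetric
    with unit diagonal and entries in [-1, 1].
    """
    if not fits:
        raise ValueError("no fits to compare")
    sizes = {f.weights.size for f in fits}
    if len(sizes) != 1:
        raise ValueError("fits use different edge sets")
    mat = np.empty((len(fits), len(fits)))
    unit = []
    for f in fits:
        norm = np.linalg.norm(f.weights)
        if norm == 0:
            raise ValueError(f"zero weight vector for {f.target!r}")
        unit.append(f.weights / norm)
    for i, u in enumerate(unit):
        for j, v in enumerate(unit):
            mat[i, j] = float(u @ v)
    labels = [f.target for f in fits]
    return pd.DataFrame(mat, index=labels, columns=labels)


def roi_scores(dataset: ConnectomeDataset, model: UnifiedModel,
               edges: np.ndarray) -> np.ndarray:
    """Per-subject, per-ROI weighted incident-edge sums.

    Score of ROI R for subject i = sum over scope edges incident to R
    of (unified weight x subject FC value).  This is the
    subject-varying reading of "ROI importance as regressor": the
    static importance vector itself is constant across subjects and
    could not regress anything.
    """
    _, fc = dataset.subject_fc()
    emap = EdgeIndexMap(dataset.n_roi)
    pairs = emap.pairs()[edges]
    contrib = fc[:, edges] * model.weights[edges]  # subjects x scope edges
    scores = np.zeros((fc.shape[0], dataset.n_roi))
    for col, (a, b) in enumerate(pairs):
        scores[:, a] += contrib[:, col]
        scores[:, b] += contrib[:, col]
    return scores


def roi_level_regression(dataset: ConnectomeDataset, model: UnifiedModel,
                         partition: EdgeSetPartition, scope: str,
                         target: str) -> SubdomainFit:
    """MLR of a subdomain on per-subject ROI scores.

    ``scope`` selects which edges feed the scores: ``"correlated"``
    (the top-k set) or ``"full"`` (all edges), so the concentrated
    vs. diffuse contrast can be tested.
    """
    if scope == "correlated":
        edges = partition.correlated
    elif scope == "full":
        edges = np.arange(partition.n_edges)
    else:
        raise ValueError("scope must be 'correlated' or 'full'")
    scores = roi_scores(dataset, model, edges)
    if not np.any(scores):
        raise ValueError("all ROI scores are zero; nothing to regress")
    subs, _ = dataset.subject_fc()
    y = dataset.phenotypes.loc[subs, target].to_numpy(dtype=float)
    fit = mlr_fit(scores, y, target=target)
    fit.target = f"{target}[{scope}]"
    return fit
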