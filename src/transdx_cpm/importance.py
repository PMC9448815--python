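"""Edge-, ROI-, and network-level importance of the consensus model.

Importance decompositions reshape the per-edge weight vector of the
unified model into interpretable summaries:

* *edge importance* — the signed cross-fold mean weight per edge;
* *ROI importance* — absolute weights aggregated (mean or sum) over all
  edges incident to a region;
* *network importance* — mean absolute weight within and between each
  pair of networks;
* *leave-one-network-out* — zero every fold-model weight on edges
  touching one network, regenerate the out-of-fold predictions, and
  measure the drop in prediction r (paired with the standard model on
  exactly the same prediction set).

"Edges involving a network" means incident to at least one ROI of that
network, so a between-network edge is removed by either endpoint's
removal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .cpm import CVResult, evaluate
from .data_model import EdgeIndexMap, NetworkMap

logger = logging.getLogger(__name__)

__all__ = ["ImportanceReport", "edge_importance", "roi_importance",
           "network_importance", "leave_network_out",
           "leave_network_out_table", "fisher_z_compare", "steiger_z_compare",
           "bh_fdr", "importance_report"]


@dataclass
class ImportanceReport:
    """Bundle of the three decompositions plus the removal table."""

    edge_importance: np.ndarray
    roi_importance: np.ndarray
    network_matrix: pd.DataFrame
    lno_table: pd.DataFrame


def edge_importance(cv: CVResult) -> np.ndarray:
    """Signed mean weight per edge across fold models (zeros included)."""
    if not cv.fold_models:
        raise ValueError("no fold models")
    return np.mean([fm.weights for fm in cv.fold_models], axis=0)


def roi_importance(weights: np.ndarray, n_roi: int,
                   edge_subset=None,
                   aggregation: str = "mean_abs") -> np.ndarray:
    """Aggregate |weight| over the edges incident to each ROI.

    ``mean_abs`` averages and ``sum_abs`` sums over the incident edges
    inside ``edge_subset`` (default: all edges).  Both are exposed
    because displays use either convention.  ROIs with no incident
    subset edges score 0.
    """
    if aggregation not in ("mean_abs", "sum_abs"):
        raise ValueError("aggregation must be 'mean_abs' or 'sum_abs'")
    weights = np.asarray(weights, dtype=float)
    emap = EdgeIndexMap(n_roi)
    if weights.size != emap.n_edges:
        raise ValueError("weight length does not match n_roi")
    if edge_subset is None:
        subset = np.arange(emap.n_edges)
    else:
        subset = np.asarray(sorted(set(int(e) for e in edge_subset)), dtype=int)
    pairs = emap.pairs()[subset]
    absw = np.abs(weights[subset])
    total = np.zeros(n_roi)
    count = np.zeros(n_roi)
    for (a, b), w in zip(pairs, absw):
        total[a] += w
        total[b] += w
        count[a] += 1
        count[b] += 1
    if aggregation == "sum_abs":
        return total
    with np.errstate(invalid="ignore"):
        out = np.where(count > 0, total / np.where(count == 0, 1, count), 0.0)
    return out


def network_importance(weights: np.ndarray,
                       networks: NetworkMap) -> pd.DataFrame:
    """Mean |weight| per network block, as a symmetric labeled matrix.

    Entry (A, B) averages over edges with one endpoint in A and the
    other in B; the diagonal covers within-network edges.  A network
    with a single ROI has no within-network edges: its diagonal entry
    is NaN (flagged by a warning).
    """
    weights = np.asarray(weights, dtype=float)
    labels = networks.networks
    la, lb = networks.edge_labels()
    absw = np.abs(weights)
    mat = pd.DataFrame(np.nan, index=labels, columns=labels, dtype=float)
    for i, a in enumerate(labels):
        for b in labels[i:]:
            sel = ((la == a) & (lb == b)) | ((la == b) & (lb == a))
            if not sel.any():
                if a == b:
                    logger.warning(
                        "network %r has no within-network edges", a)
                continue
            v = float(absw[sel].mean())
            mat.loc[a, b] = v
            mat.loc[b, a] = v
    return mat


def _oof_subject_predictions(cv: CVResult,
                             weights_of) -> pd.DataFrame:
    """Regenerate round-averaged per-subject predictions with modified
    fold weights; ``weights_of(fm)`` maps a fold model to its weight
    vector."""
    ds = cv.dataset
    records = []
    for fm in cv.fold_models:
        w = weights_of(fm)
        run_pred = fm.intercept + ds.fc[fm.test_rows] @ w
        run_sub = ds.subject_id[fm.test_rows]
        df = pd.DataFrame({"subject_id": run_sub, "y_pred": run_pred})
        df = df.groupby("subject_id", sort=False)["y_pred"].mean()
        for s, yp in df.items():
            records.append({"round": fm.round_id, "subject_id": s,
                            "y_pred": yp})
    df = pd.DataFrame(records)
    return df.groupby("subject_id", sort=False)["y_pred"].mean().to_frame()


def leave_network_out(cv: CVResult, network: str, networks: NetworkMap,
                      grouping: str | None = None,
                      min_n: int = 3) -> pd.DataFrame:
    """Predictability drop when one network's edges are removed.

    Every fold model's weights on edges incident to the network are set
    to zero, out-of-fold predictions are regenerated, and the paired
    r_standard / r_removed / delta_r are reported overall and (if
    ``grouping`` is given) per phenotype group.
    """
    removed_edges = networks.incident_edges(network)  # validates the label
    keep = np.ones(cv.dataset.n_edges, dtype=bool)
    keep[removed_edges] = False

    sp_std = _oof_subject_predictions(cv, lambda fm: fm.weights)
    sp_rem = _oof_subject_predictions(cv, lambda fm: fm.weights * keep)
    y = cv.dataset.phenotypes.loc[sp_std.index, cv.target]

    def one_group(idx, label) -> dict:
        ev_s = evaluate(sp_std.loc[idx, "y_pred"], y.loc[idx])
        ev_r = evaluate(sp_rem.loc[idx, "y_pred"], y.loc[idx])
        return {"network": network, "group": label, "n": int(idx.sum()),
                "r_standard": ev_s.r, "r_removed": ev_r.r,
                "delta_r": ev_s.r - ev_r.r,
                "status": ev_r.status}

    all_idx = pd.Series(True, index=sp_std.index)
    rows = [one_group(all_idx, "all")]
    if grouping is not None:
        if grouping not in cv.dataset.phenotypes.columns:
            raise KeyError(f"unknown grouping column {grouping!r}")
        gcol = cv.dataset.phenotypes.loc[sp_std.index, grouping]
        for level in pd.unique(gcol):
            idx = gcol == level
            if int(idx.sum()) < min_n:
                continue
            rows.append(one_group(idx, level))
    return pd.DataFrame(rows)


def fisher_z_compare(r1: float, n1: int, r2: float, n2: int,
                     ) -> tuple[float, float]:
    """Two-sample Fisher r-to-z comparison of two correlations.

    ``z = (atanh(r1) - atanh(r2)) / sqrt(1/(n1-3) + 1/(n2-3))`` with a
    two-sided normal p.  This treats the samples as independent; see
    :func:`steiger_z_compare` for correlations sharing subjects.
    """
    for r in (r1, r2):
        if not abs(r) < 1:
            raise ValueError("|r| must be < 1 for the z transform")
    for n in (n1, n2):
        if n <= 3:
            raise ValueError("need n > 3 per sample")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(
        1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def steiger_z_compare(r1: float, r2: float, r12: float, n: int,
                      ) -> tuple[float, float]:
    """Dependent-correlations z test (Steiger) for r1 vs r2 sharing one
    variable, with ``r12`` the correlation of the two predictors."""
    for r in (r1, r2, r12):
        if not abs(r) < 1:
            raise ValueError("|r| must be < 1")
    if n <= 3:
        raise ValueError("need n > 3")
    rbar2 = ((r1 + r2) / 2.0) ** 2
    # Steiger's pooled covariance of the two z-transformed correlations
    s = (r12 * (1 - 2 * rbar2) - 0.5 * rbar2
         * (1 - 2 * rbar2 - r12 ** 2)) / ((1 - rbar2) ** 2)
    z = (np.arctanh(r1) - np.arctanh(r2)) * np.sqrt(
        (n - 3) / (2.0 * (1.0 - s)))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, <= 1)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def leave_network_out_table(cv: CVResult, networks: NetworkMap,
                            grouping: str | None = None) -> pd.DataFrame:
    """Removal analysis over every network, with Fisher z and FDR.

    The Fisher comparison treats r_standard and r_removed with the same
    n (the group size); FDR is Benjamini-Hochberg across the networks
    within each group.
    """
    parts = [leave_network_out(cv, net, networks, grouping=grouping)
             for net in networks.networks]
    table = pd.concat(parts, ignore_index=True)
    zs, ps = [], []
    for _, row in table.iterrows():
        if row["status"] != "ok" or row["n"] <= 3:
            zs.append(np.nan)
            ps.append(np.nan)
            continue
        z, p = fisher_z_compare(row["r_standard"], row["n"],
                                row["r_removed"], row["n"])
        zs.append(z)
        ps.append(p)
    table["fisher_z"] = zs
    table["p"] = ps
    table["p_fdr"] = np.nan
    for grp in pd.unique(table["group"]):
        idx = (table["group"] == grp) & table["p"].notna()
        if idx.any():
            table.loc[idx, "p_fdr"] = bh_fdr(table.loc[idx, "p"].to_numpy())
    return table


def importance_report(cv: CVResult, networks: NetworkMap,
                      grouping: str | None = None) -> ImportanceReport:
    """The full decomposition bundle for one CV result."""
    ew = edge_importance(cv)
    return ImportanceReport(
        edge_importance=ew,
        roi_importance=roi_importance(ew, cv.dataset.n_roi),
        network_matrix=network_importance(ew, networks),
        lno_table=leave_network_out_table(cv, networks, grouping=grouping),
    )
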