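"""Edge screening, sparse regression, and run-grouped nested CV.

The "standard model" is built in three stages inside every
cross-validation fold:

1. *screening* — each edge is correlated with the target across the
   training rows (Pearson) and only edges with a two-sided p below the
   threshold (default 0.05) are retained;
2. *sparse regression* — a LASSO fit on the retained edges, with the
   penalty chosen by an inner subject-grouped cross-validation;
3. *prediction* — held-out runs are scored and a subject's prediction
   is the mean over their available runs.

Both runs of a subject always travel together between the training and
test side of every split, so repeated scans never leak a test subject
into training.  Ten rounds of five-fold CV give 50 fold models whose
weights (zeros included for unselected edges) average into the unified
consensus model.

Features are z-scored with training-fold statistics before the LASSO
and the weights are mapped back to original FC units, so that fold
models live on a common scale and can be averaged.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import Lasso, lasso_path

from .data_model import ConnectomeDataset, UnifiedModel

logger = logging.getLogger(__name__)

__all__ = [
    "ScreeningResult", "FoldModel", "CVResult", "EvalResult",
    "screen_edges", "fit_lasso", "lambda_grid", "select_lambda",
    "nested_cv", "unify", "predict", "evaluate", "evaluate_subgroups",
    "leave_group_out_fit", "restrict_model",
]


# ---------------------------------------------------------------------------
# Screening
# ---------------------------------------------------------------------------

@dataclass
class ScreeningResult:
    """Per-edge Pearson r, two-sided p, and the retained-edge mask."""

    r: np.ndarray
    p: np.ndarray
    mask: np.ndarray
    threshold: float

    @property
    def n_retained(self) -> int:
        return int(self.mask.sum())


def screen_edges(fc_train: np.ndarray, y_train: np.ndarray,
                 p_threshold: float = 0.05) -> ScreeningResult:
    """Univariate Pearson screen of every edge against the target.

    p-values come from the exact t transform ``t = r sqrt((n-2)/(1-r^2))``
    with ``n - 2`` degrees of freedom.  Constant edge columns get r = 0
    and are never retained (logged); a constant target is an error.
    """
    x = np.asarray(fc_train, dtype=float)
    y = np.asarray(y_train, dtype=float)
    n = x.shape[0]
    if n < 4:
        raise ValueError(f"need >= 4 training rows for screening, got {n}")
    if y.std() == 0:
        raise ValueError("target is constant; screening undefined")

    xc = x - x.mean(axis=0)
    yc = y - y.mean()
    sx = np.sqrt((xc * xc).sum(axis=0))
    sy = np.sqrt((yc * yc).sum())
    const = sx == 0
    if const.any():
        logger.warning("%d constant edge column(s) excluded from screening",
                       int(const.sum()))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xc.T @ yc) / (sx * sy)
    r[const] = 0.0
    r = np.clip(r, -1.0, 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r * r))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.abs(r) >= 1.0, 0.0, p)
    p[const] = 1.0
    mask = p < p_threshold
    mask[const] = False
    return ScreeningResult(r=r, p=p, mask=mask, threshold=p_threshold)


# ---------------------------------------------------------------------------
# LASSO
# ---------------------------------------------------------------------------

def _standardize(x: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    mu = x.mean(axis=0)
    sd = x.std(axis=0)
    sd_safe = np.where(sd == 0, 1.0, sd)
    return (x - mu) / sd_safe, mu, sd

def lambda_max(x: np.ndarray, y: np.ndarray) -> float:
    """Smallest penalty at which the standardized LASSO is all-zero."""
    xs, _, _ = _standardize(np.asarray(x, dtype=float))
    yc = np.asarray(y, dtype=float) - np.mean(y)
    return float(np.max(np.abs(xs.T @ yc)) / x.shape[0])


def lambda_grid(x: np.ndarray, y: np.ndarray, n_lambdas: int = 50,
                min_ratio: float = 1e-3) -> np.ndarray:
    """Log-spaced penalty grid from lambda_max down to min_ratio*lambda_max."""
    lmax = lambda_max(x, y)
    if lmax == 0:
        return np.asarray([0.0])
    return np.geomspace(lmax, lmax * min_ratio, num=n_lambdas)


def fit_lasso(x: np.ndarray, y: np.ndarray, lam: float,
              tol: float = 1e-8, max_iter: int = 100_000,
              ) -> tuple[np.ndarray, float]:
    """LASSO minimizing ``(1/2n)||y - b - Xw||^2 + lam * ||w||_1``.

    Features are z-scored internally (training statistics); the returned
    weights are back-transformed to original units and the intercept is
    chosen so predictions are ``b + X @ w``.  ``lam = 0`` reduces to
    least squares.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 2 or x.shape[0] != y.shape[0]:
        raise ValueError("x must be rows x features aligned with y")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values in LASSO inputs")
    if lam < 0:
        raise ValueError("penalty must be nonnegative")

    xs, mu, sd = _standardize(x)
    yc = y - y.mean()
    if lam == 0:
        w_std, *_ = np.linalg.lstsq(xs, yc, rcond=None)
    else:
        model = Lasso(alpha=lam, fit_intercept=False, tol=tol,
                      max_iter=max_iter)
        model.fit(xs, yc)
        w_std = model.coef_
    w = np.where(sd == 0, 0.0, w_std / np.where(sd == 0, 1.0, sd))
    intercept = float(y.mean() - w @ mu)
    return w, intercept


def select_lambda(x: np.ndarray, y: np.ndarray, grid: np.ndarray,
                  inner_folds: int, groups: np.ndarray,
                  screen_p_threshold: float | None = None,
                  ) -> tuple[float, np.ndarray]:
    """Choose the penalty by subject-grouped inner cross-validation.

    Returns the grid value minimizing mean held-out squared error; ties
    go to the largest (sparsest) penalty.  Also returns the per-lambda
    mean validation MSE for auditing.

    When ``screen_p_threshold`` is given, every inner fold re-runs the
    univariate screen on its own training rows before the path fit.
    Without this, features screened on the full set leak the inner
    validation rows into feature selection, which biases the error
    estimate toward dense models.
    """
    grid = np.sort(np.asarray(grid, dtype=float))[::-1]
    if grid.size == 0:
        raise ValueError("empty penalty grid")
    if inner_folds < 2:
        raise ValueError("need >= 2 inner folds")
    groups = np.asarray(groups)
    uniq = pd.unique(groups)
    if uniq.size < inner_folds:
        raise ValueError(
            f"{uniq.size} distinct subjects < {inner_folds} inner folds")

    # deterministic contiguous split of the (already randomized) subject order
    fold_of = {g: k % inner_folds for k, g in enumerate(uniq)}
    assign = np.asarray([fold_of[g] for g in groups])

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sse = np.zeros(grid.size)
    cnt = 0
    for k in range(inner_folds):
        val = assign == k
        tr = ~val
        x_tr = x[tr]
        if screen_p_threshold is not None:
            scr = screen_edges(x_tr, y[tr], screen_p_threshold)
            cols = np.nonzero(scr.mask)[0]
        else:
            cols = np.arange(x.shape[1])
        ym = y[tr].mean()
        if cols.size == 0:
            preds = np.full((int(val.sum()), grid.size), ym)
        else:
            xs, mu, sd = _standardize(x_tr[:, cols])
            sd_safe = np.where(sd == 0, 1.0, sd)
            xv = (x[val][:, cols] - mu) / sd_safe
            # loose tolerance is fine here: the path is only ranked, not
            # reported; the dense end never wins and need not fully converge
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", category=ConvergenceWarning)
                _, coefs, _ = lasso_path(xs, y[tr] - ym, alphas=grid,
                                         tol=1e-4)
            preds = xv @ coefs + ym  # (n_val, n_lambdas)
        resid = preds - y[val][:, None]
        sse += (resid * resid).sum(axis=0)
        cnt += int(val.sum())
    mse = sse / cnt
    best = np.nonzero(mse == mse.min())[0]
    return float(grid[best[0]]), mse  # grid descending: first min = largest lam


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class FoldModel:
    """One trained fold: screening mask, weights, and its test rows."""

    round_id: int
    fold_id: int
    mask: np.ndarray
    weights: np.ndarray  # full n_edges length, original FC units
    intercept: float
    lam: float
    test_rows: np.ndarray  # row indices into the dataset's fc matrix

    def predict_rows(self, fc: np.ndarray) -> np.ndarray:
        return self.intercept + fc @ self.weights


@dataclass
class EvalResult:
    """Pearson r (with parametric p) and coefficient of determination."""

    r: float
    p: float
    r2: float
    n: int
    status: str = "ok"


@dataclass
class CVResult:
    """All fold models plus out-of-fold predictions and summaries."""

    fold_models: list[FoldModel]
    predictions: pd.DataFrame  # columns: round, subject_id, y_true, y_pred
    round_performance: pd.DataFrame  # columns: round, r, r2, p
    dataset: ConnectomeDataset
    target: str
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def mean_r(self) -> float:
        return float(self.round_performance["r"].mean())

    @property
    def sd_r(self) -> float:
        return float(self.round_performance["r"].std(ddof=1))

    def subject_predictions(self) -> pd.DataFrame:
        """Per-subject out-of-fold prediction averaged over rounds."""
        g = (self.predictions
             .groupby("subject_id", sort=False)[["y_true", "y_pred"]]
             .mean())
        return g


def evaluate(pred: np.ndarray, actual: np.ndarray) -> EvalResult:
    """Pearson r (two-sided t-based p) and R^2 = 1 - SS_res/SS_tot.

    R^2 is the raw coefficient of determination of the predictions, not
    the square of r, so miscalibrated predictions are penalized.
    Constant predictions leave r undefined (NaN, flagged) but R^2 is
    still reported.
    """
    pred = np.asarray(pred, dtype=float)
    actual = np.asarray(actual, dtype=float)
    if pred.size != actual.size or pred.size < 3:
        raise ValueError("need >= 3 aligned prediction/target pairs")
    if actual.std() == 0:
        raise ValueError("target is constant; evaluation undefined")
    ss_res = float(((actual - pred) ** 2).sum())
    ss_tot = float(((actual - actual.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot
    if pred.std() == 0:
        return EvalResult(r=float("nan"), p=float("nan"), r2=r2,
                          n=pred.size, status="constant_predictions")
    r, p = stats.pearsonr(pred, actual)
    return EvalResult(r=float(r), p=float(p), r2=r2, n=pred.size)


def _round_folds(subjects: list, outer_folds: int,
                 rng: np.random.Generator) -> list[np.ndarray]:
    order = rng.permutation(len(subjects))
    return [np.sort(chunk) for chunk in np.array_split(order, outer_folds)]


def _fit_fold(x_tr: np.ndarray, y_tr: np.ndarray, groups: np.ndarray,
              test_rows: np.ndarray, round_id: int, fold_id: int,
              p_threshold: float, n_lambdas: int, lambda_min_ratio: float,
              inner_folds: int) -> FoldModel:
    """Train one fold on run-averaged subject rows."""
    screening = screen_edges(x_tr, y_tr, p_threshold)
    weights = np.zeros(x_tr.shape[1])
    if screening.n_retained == 0:
        logger.warning("round %d fold %d: no edges survived screening; "
                       "predicting the training mean", round_id, fold_id)
        return FoldModel(round_id, fold_id, screening.mask, weights,
                         float(y_tr.mean()), float("nan"), test_rows)
    sel = np.nonzero(screening.mask)[0]
    xs = x_tr[:, sel]
    grid = lambda_grid(xs, y_tr, n_lambdas=n_lambdas,
                       min_ratio=lambda_min_ratio)
    # inner folds re-screen on their own rows so the validation error is
    # an unbiased guide for the penalty choice
    lam, _ = select_lambda(x_tr, y_tr, grid, inner_folds=inner_folds,
                           groups=groups, screen_p_threshold=p_threshold)
    w_sel, intercept = fit_lasso(xs, y_tr, lam, tol=1e-6)
    weights[sel] = w_sel
    return FoldModel(round_id, fold_id, screening.mask, weights,
                     intercept, lam, test_rows)


def nested_cv(dataset: ConnectomeDataset, rounds: int = 10,
              outer_folds: int = 5, p_threshold: float = 0.05,
              n_lambdas: int = 50, lambda_min_ratio: float = 1e-3,
              inner_folds: int = 5, seed: int = 0,
              target: str = "fsiq") -> CVResult:
    """Repeated run-grouped k-fold CV of the screen -> LASSO pipeline.

    Subjects (not runs) are partitioned into ``outer_folds`` groups per
    round, so a subject's runs are always jointly in training or test.
    Each training subject contributes their run-averaged connectome as
    one training row (so repeated identical runs change nothing); test
    runs are scored separately and a subject's prediction is the mean
    over their runs.  Each round is evaluated on its pooled per-subject
    predictions and the result is summarized as mean +/- SD across
    rounds.
    """
    subjects = dataset.subjects
    if len(subjects) < outer_folds:
        raise ValueError("fewer subjects than outer folds")
    y_sub = dataset.target(target)
    if np.isnan(y_sub).any():
        raise ValueError(f"missing values in target {target!r}")
    _, sub_fc = dataset.subject_fc()
    rows_by_sub = {s: dataset.rows_of(s) for s in subjects}

    rng = np.random.default_rng(seed)
    fold_models: list[FoldModel] = []
    pred_records = []
    perf_records = []
    for rnd in range(rounds):
        folds = _round_folds(subjects, outer_folds, rng)
        round_preds: dict = {}
        for fid, test_sub_idx in enumerate(folds):
            test_subjects = [subjects[k] for k in test_sub_idx]
            test_rows = np.concatenate([rows_by_sub[s] for s in test_subjects])
            train_sub = np.ones(len(subjects), dtype=bool)
            train_sub[test_sub_idx] = False
            fm = _fit_fold(sub_fc[train_sub], y_sub[train_sub],
                           np.asarray(subjects, dtype=object)[train_sub],
                           np.sort(test_rows), rnd, fid, p_threshold,
                           n_lambdas, lambda_min_ratio, inner_folds)
            fold_models.append(fm)
            run_pred = fm.predict_rows(dataset.fc[fm.test_rows])
            run_sub = dataset.subject_id[fm.test_rows]
            for s in test_subjects:
                round_preds[s] = float(run_pred[run_sub == s].mean())
        y_pred = np.asarray([round_preds[s] for s in subjects])
        ev = evaluate(y_pred, y_sub)
        perf_records.append({"round": rnd, "r": ev.r, "r2": ev.r2, "p": ev.p})
        for s, yt, yp in zip(subjects, y_sub, y_pred):
            pred_records.append({"round": rnd, "subject_id": s,
                                 "y_true": yt, "y_pred": yp})

    return CVResult(
        fold_models=fold_models,
        predictions=pd.DataFrame(pred_records),
        round_performance=pd.DataFrame(perf_records),
        dataset=dataset,
        target=target,
        seed=seed,
        params={"rounds": rounds, "outer_folds": outer_folds,
                "p_threshold": p_threshold, "n_lambdas": n_lambdas,
                "lambda_min_ratio": lambda_min_ratio,
                "inner_folds": inner_folds},
    )


def unify(cv: CVResult) -> UnifiedModel:
    """Average fold models into the consensus predictor.

    Unselected edges count as zero in the average (divide by the number
    of fold models, not the number of selecting folds).
    """
    if not cv.fold_models:
        raise ValueError("no fold models to unify")
    n_edges = cv.fold_models[0].weights.size
    if any(fm.weights.size != n_edges for fm in cv.fold_models):
        raise ValueError("inconsistent edge counts across fold models")
    w = np.mean([fm.weights for fm in cv.fold_models], axis=0)
    b = float(np.mean([fm.intercept for fm in cv.fold_models]))
    freq = np.mean([fm.weights != 0 for fm in cv.fold_models], axis=0)
    return UnifiedModel(
        n_roi=cv.dataset.n_roi, weights=w, intercept=b,
        selection_frequency=freq,
        provenance={"scheme": cv.params, "seed": cv.seed,
                    "target": cv.target,
                    "n_fold_models": len(cv.fold_models)})


def predict(model: UnifiedModel, dataset: ConnectomeDataset) -> pd.DataFrame:
    """Per-subject predictions (runs scored separately, then averaged)."""
    if dataset.n_edges != model.n_edges:
        raise ValueError(
            f"model has {model.n_edges} edges, dataset {dataset.n_edges}")
    run_pred = model.intercept + dataset.fc @ model.weights
    df = pd.DataFrame({"subject_id": dataset.subject_id, "y_pred": run_pred})
    return df.groupby("subject_id", sort=False)["y_pred"].mean().to_frame()


def evaluate_subgroups(cv: CVResult, grouping: str,
                       min_n: int = 3) -> pd.DataFrame:
    """Out-of-fold evaluation within each level of a phenotype column."""
    if grouping not in cv.dataset.phenotypes.columns:
        raise KeyError(f"unknown grouping column {grouping!r}")
    sp = cv.subject_predictions()
    groups = cv.dataset.phenotypes.loc[sp.index, grouping]
    rows = []
    for level in pd.unique(groups):
        idx = groups == level
        n = int(idx.sum())
        if n < min_n:
            logger.warning("group %s=%r has %d subjects (< %d); skipped",
                           grouping, level, n, min_n)
            continue
        ev = evaluate(sp.loc[idx, "y_pred"], sp.loc[idx, "y_true"])
        rows.append({"group": level, "n": n, "r": ev.r, "r2": ev.r2,
                     "p": ev.p, "status": ev.status})
    return pd.DataFrame(rows)


def leave_group_out_fit(dataset: ConnectomeDataset, grouping: str,
                        held_out, target: str = "fsiq",
                        **cv_kwargs) -> tuple[UnifiedModel, EvalResult, pd.DataFrame]:
    """Train on all other groups, test on the held-out group.

    Returns the unified model from the retained subjects, the held-out
    evaluation, and the held-out per-subject prediction table.
    """
    if grouping not in dataset.phenotypes.columns:
        raise KeyError(f"unknown grouping column {grouping!r}")
    col = dataset.phenotypes[grouping]
    held_subjects = col.index[col == held_out].tolist()
    if not held_subjects:
        raise ValueError(f"no subjects with {grouping}={held_out!r}")
    train_subjects = col.index[col != held_out].tolist()
    train_ds = dataset.select_subjects(train_subjects)
    test_ds = dataset.select_subjects(held_subjects)
    cv = nested_cv(train_ds, target=target, **cv_kwargs)
    model = unify(cv)
    preds = predict(model, test_ds)
    preds["y_true"] = test_ds.phenotypes.loc[preds.index, target]
    ev = evaluate(preds["y_pred"], preds["y_true"])
    return model, ev, preds


def restrict_model(model: UnifiedModel, edge_subset,
                   reference: ConnectomeDataset) -> UnifiedModel:
    """Zero weights outside ``edge_subset``, recentering the intercept.

    The intercept shifts so the mean in-sample prediction on the
    reference cohort is unchanged; an empty subset yields a constant
    model at the reference mean (warned).
    """
    subset = np.asarray(sorted(set(int(e) for e in edge_subset)), dtype=int)
    if subset.size and (subset.min() < 0 or subset.max() >= model.n_edges):
        raise ValueError("edge subset out of range")
    if subset.size == 0:
        logger.warning("empty edge subset: restricted model is constant")
    w = np.zeros_like(model.weights)
    if subset.size:
        w[subset] = model.weights[subset]
    _, sub_fc = reference.subject_fc()
    shift = float(((model.weights - w) @ sub_fc.T).mean())
    freq = np.zeros_like(model.selection_frequency)
    if subset.size:
        freq[subset] = model.selection_frequency[subset]
    return UnifiedModel(
        n_roi=model.n_roi, weights=w,
        intercept=model.intercept + shift,
        selection_frequency=freq,
        provenance={**model.provenance, "restricted_to": int(subset.size)})
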