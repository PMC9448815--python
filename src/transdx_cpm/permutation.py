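"""Label-permutation inference for the CV pipeline and model transfer.

Permutations always act at the subject level: a subject's runs keep that
subject's (permuted) target value, so the run-grouping structure of the
pipeline is preserved under the null.  Each permutation re-runs the full
screen -> select -> fit -> predict pipeline, so the null distribution
reflects every data-dependent choice the observed model made.

p-values use the add-one estimator ``(1 + #{null >= observed}) / (1 + n_perm)``,
one-sided in the direction "larger r is better"; it is never zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .cpm import CVResult, evaluate, nested_cv, predict, unify
from .data_model import ConnectomeDataset, UnifiedModel

__all__ = ["PermutationNull", "permute_target", "cv_permutation_null",
           "unified_permutation_models", "external_permutation_test"]


@dataclass
class PermutationNull:
    """Null r distribution, observed r, and the add-one p-value."""

    null_r: np.ndarray
    observed_r: float
    p: float
    scheme: str
    seed: int


def _perm_p(null_r: np.ndarray, observed_r: float) -> float:
    return float((1 + np.sum(null_r >= observed_r)) / (1 + null_r.size))


def permute_target(dataset: ConnectomeDataset, rng: np.random.Generator,
                   target: str = "fsiq") -> ConnectomeDataset:
    """Shuffle the target across subjects; runs follow their subject."""
    ph = dataset.phenotypes.copy()
    vals = ph[target].to_numpy().copy()
    ph[target] = vals[rng.permutation(vals.size)]
    return ConnectomeDataset(fc=dataset.fc, subject_id=dataset.subject_id,
                             run_id=dataset.run_id, phenotypes=ph,
                             n_roi=dataset.n_roi)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


def cv_permutation_null(dataset: ConnectomeDataset, n_perm: int = 1000,
                        seed: int = 0, target: str = "fsiq",
                        observed_cv: CVResult | None = None,
                        **cv_kwargs) -> PermutationNull:
    """Null distribution of mean CV r under subject-level label shuffles.

    ``observed_cv`` may pass in a pre-computed CV of the unpermuted data
    (it must share ``cv_kwargs``); otherwise one is run here.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    cv_seeds = _spawn_seeds(seed, n_perm + 1)
    if observed_cv is None:
        observed_cv = nested_cv(dataset, seed=cv_seeds[0], target=target,
                                **cv_kwargs)
    null_r = np.empty(n_perm)
    for k in range(n_perm):
        permuted = permute_target(dataset, rng, target=target)
        cv = nested_cv(permuted, seed=cv_seeds[k + 1], target=target,
                       **cv_kwargs)
        null_r[k] = cv.mean_r
    obs = observed_cv.mean_r
    return PermutationNull(null_r=null_r, observed_r=obs,
                           p=_perm_p(null_r, obs), scheme="cv", seed=seed)


def unified_permutation_models(dataset: ConnectomeDataset, n_perm: int = 1000,
                               seed: int = 0, target: str = "fsiq",
                               **cv_kwargs) -> list[UnifiedModel]:
    """Unified models trained on permuted labels (CV + averaging each)."""
    if n_perm < 0:
        raise ValueError("n_perm must be >= 0")
    rng = np.random.default_rng(seed)
    cv_seeds = _spawn_seeds(seed, max(n_perm, 1))
    models = []
    for k in range(n_perm):
        permuted = permute_target(dataset, rng, target=target)
        cv = nested_cv(permuted, seed=cv_seeds[k], target=target, **cv_kwargs)
        models.append(unify(cv))
    return models


def external_permutation_test(perm_models: list[UnifiedModel],
                              real_model: UnifiedModel,
                              external: ConnectomeDataset,
                              target: str = "fsiq",
                              seed: int = 0) -> PermutationNull:
    """Transfer-r of the real model vs. permuted models on a new cohort."""
    for m in perm_models + [real_model]:
        if m.n_edges != external.n_edges:
            raise ValueError("model/cohort edge-count mismatch")
    y = external.phenotypes.loc[
        list(dict.fromkeys(external.subject_id.tolist())), target].to_numpy()

    def transfer_r(model: UnifiedModel) -> float:
        pred = predict(model, external)["y_pred"].to_numpy()
        r = evaluate(pred, y).r
        # (near-)constant models have no defined r; they cannot beat anything
        return r if np.isfinite(r) else float("-inf")

    null_r = np.asarray([transfer_r(m) for m in perm_models])
    obs = transfer_r(real_model)
    return PermutationNull(null_r=null_r, observed_r=obs,
                           p=_perm_p(null_r, obs), scheme="external",
                           seed=seed)
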