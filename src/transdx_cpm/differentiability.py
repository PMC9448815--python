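"""Individual differentiability: L1 deviation from the mean connectome.

A subject's differentiability is the sum over all edges of the absolute
difference between their (run-averaged) connectome and the cohort mean
connectome:

    ID_i = sum_j | FC_ij - mean_i'(FC_i'j) |

The mean connectome is taken over *all* subjects regardless of
diagnosis, so the statistic measures deviation from the whole
transdiagnostic cohort, not from a healthy norm.  Larger values mean a
more atypical connectome; a subject identical to the mean scores 0.
The sum is not normalized by the edge count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import ConnectomeDataset

__all__ = ["IDResult", "mean_connectome", "individual_differentiability",
           "age_band"]


@dataclass
class IDResult:
    """Per-subject ID values plus optional group summaries."""

    mean_connectome: np.ndarray
    id_values: pd.Series  # indexed by subject_id
    group_summaries: pd.DataFrame | None = None


def mean_connectome(dataset: ConnectomeDataset) -> np.ndarray:
    """Per-edge mean over subjects (runs averaged within subject first)."""
    _, fc = dataset.subject_fc()
    if fc.shape[0] == 0:
        raise ValueError("empty dataset")
    return fc.mean(axis=0)


def individual_differentiability(dataset: ConnectomeDataset,
                                 grouping: str | None = None) -> IDResult:
    """Compute ID for every subject, optionally summarized by group."""
    subs, fc = dataset.subject_fc()
    mean = fc.mean(axis=0)
    ids = pd.Series(np.abs(fc - mean).sum(axis=1), index=pd.Index(subs, name="subject_id"),
                    name="id")
    summaries = None
    if grouping is not None:
        if grouping not in dataset.phenotypes.columns:
            raise KeyError(f"unknown grouping column {grouping!r}")
        groups = dataset.phenotypes.loc[subs, grouping]
        summaries = (pd.DataFrame({"id": ids.to_numpy(), "group": groups.to_numpy()})
                     .groupby("group")["id"]
                     .agg(n="size", mean="mean", sd="std", median="median",
                          q25=lambda s: s.quantile(0.25),
                          q75=lambda s: s.quantile(0.75))
                     .reset_index())
    return IDResult(mean_connectome=mean, id_values=ids,
                    group_summaries=summaries)


def age_band(phenotypes: pd.DataFrame) -> pd.Series:
    """Age groups used for subgroup analyses: <9, 9-12, >12 years."""
    age = phenotypes["age"]
    return pd.cut(age, bins=[-np.inf, 9.0, 12.0, np.inf],
                  labels=["<9", "9-12", ">12"], right=False).astype(str)
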