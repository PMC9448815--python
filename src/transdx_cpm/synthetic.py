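"""Synthetic transdiagnostic cohorts with a planted edge-IQ structure.

The generator emulates the statistical skeleton the prediction pipeline
assumes: a mean connectome with stronger within- than between-network
connectivity, a standard-normal latent ability trait ``g`` per subject,
a sparse set of "true" edges whose FC shifts linearly with ``g``, a
full-scale IQ built from ``g`` plus independent noise on the usual
mean-100 / SD-15 scale, five correlated subdomain scores, diagnosis
groups with small FSIQ and network-FC offsets, study-site shifts, and
one or two noisy runs per subject.

Because the planted coefficient vector is known, every downstream stage
(screening, sparse regression, importance decompositions, permutation
nulls) can be tested as a parameter-recovery problem.

Generative model, per subject i and edge j:

    FC_ij = M_j + gamma * s_j * 1[j in true] * g_i
            + diagnosis/site edge shifts + N(0, edge_noise_sd^2)
    run r: FC_ij + N(0, run_noise_sd^2)
    FSIQ_i = 100 + 15 * (sqrt(h) * g_i + sqrt(1-h) * eps_i) + shifts
    subdomain k: 100 + 15 * (a_k * g_i + sqrt(1-a_k^2) * u_ik)

with ``s_j`` a random sign per true edge.  ``h`` is the fraction of
FSIQ variance carried by the latent trait; the oracle linear predictor
beta . FC therefore attains population R^2 ~= h when the per-edge noise
is small relative to the pooled signal (kept so by the defaults).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .data_model import (
    NETWORK_LABELS,
    SUBDOMAIN_COLUMNS,
    ConnectomeDataset,
    EdgeIndexMap,
    NetworkMap,
    n_edges_for,
)

__all__ = ["SimulationConfig", "GroundTruth", "simulate_cohort",
           "simulate_external_cohort"]


def _default_diagnosis_proportions() -> dict[str, float]:
    # roughly the discovery-cohort case mix (ADHD-heavy, few MDD)
    return {"HC": 0.09, "ADHD": 0.47, "ASD": 0.05, "MDD": 0.02,
            "Anxiety": 0.11, "Other": 0.26}


def _default_diagnosis_fsiq_shift() -> dict[str, float]:
    return {"HC": 4.0, "ADHD": -2.0, "ASD": -4.0, "MDD": -2.0,
            "Anxiety": 1.0, "Other": -1.0}


def _default_diagnosis_network_shift() -> dict[str, tuple[str, float]]:
    # (network, additive FC shift on that network's within-network edges)
    return {"ADHD": ("DAN", -0.02), "ASD": ("DMN", -0.02)}


def _default_site_proportions() -> dict[str, float]:
    # four sites with very uneven enrolment, as in multi-site pediatric studies
    return {"S1": 0.39, "S2": 0.03, "S3": 0.49, "S4": 0.09}


def _default_site_edge_shift() -> dict[str, float]:
    return {"S1": 0.0, "S2": 0.01, "S3": -0.005, "S4": 0.005}


def _default_site_fsiq_shift() -> dict[str, float]:
    return {"S1": 0.0, "S2": -1.0, "S3": 0.5, "S4": -0.5}


@dataclass
class SimulationConfig:
    """Knobs of the generative model; defaults are the stated world.

    gamma (``effect_scale``) and the noise SDs are set so the pooled
    50-edge oracle correlates with the latent trait at ~0.996, i.e. the
    oracle predictor achieves population R^2 ~= h against FSIQ.
    """

    n_subjects: int = 600
    n_roi: int = 100
    network_sizes: tuple[int, ...] | None = None  # default: near-even split
    n_true_edges: int = 50
    true_edge_network: str | None = None  # confine true edges within one network
    effect_scale: float = 0.15  # FC z-units per latent SD
    edge_noise_sd: float = 0.08
    run_noise_sd: float = 0.08
    runs_per_subject: int = 2
    h: float = 0.35  # fraction of FSIQ variance from the latent trait
    subdomain_loadings: tuple[float, ...] = (0.75, 0.80, 0.70, 0.72, 0.55)
    within_network_mean: float = 0.35
    between_network_mean: float = 0.10
    baseline_sd: float = 0.05
    diagnosis_proportions: dict = field(default_factory=_default_diagnosis_proportions)
    diagnosis_fsiq_shift: dict = field(default_factory=_default_diagnosis_fsiq_shift)
    diagnosis_network_shift: dict = field(default_factory=_default_diagnosis_network_shift)
    site_proportions: dict = field(default_factory=_default_site_proportions)
    site_edge_shift: dict = field(default_factory=_default_site_edge_shift)
    site_fsiq_shift: dict = field(default_factory=_default_site_fsiq_shift)
    seed: int = 0

    def resolved_network_sizes(self) -> tuple[int, ...]:
        if self.network_sizes is not None:
            return tuple(self.network_sizes)
        k = len(NETWORK_LABELS)
        base, extra = divmod(self.n_roi, k)
        return tuple(base + (1 if i < extra else 0) for i in range(k))

    def validate(self) -> None:
        sizes = self.resolved_network_sizes()
        if len(sizes) != len(NETWORK_LABELS):
            raise ValueError("network_sizes must give one size per network")
        if sum(sizes) != self.n_roi:
            raise ValueError(
                f"network_sizes sum to {sum(sizes)}, expected n_roi={self.n_roi}")
        if not 0.0 <= self.h < 1.0:
            raise ValueError("h must lie in [0, 1)")
        if len(self.subdomain_loadings) != len(SUBDOMAIN_COLUMNS):
            raise ValueError("need one loading per subdomain")
        if any(not 0.0 < a < 1.0 for a in self.subdomain_loadings):
            raise ValueError("subdomain loadings must lie in (0, 1)")
        if self.n_true_edges > n_edges_for(self.n_roi):
            raise ValueError("more true edges than edges")
        for name, props in (("diagnosis", self.diagnosis_proportions),
                            ("site", self.site_proportions)):
            if abs(sum(props.values()) - 1.0) > 1e-9:
                raise ValueError(f"{name} proportions must sum to 1")
        if self.runs_per_subject not in (1, 2):
            raise ValueError("runs_per_subject must be 1 or 2")

    def without_group_effects(self) -> "SimulationConfig":
        """Copy with all diagnosis/site shifts zeroed (exchangeable world)."""
        return replace(
            self,
            diagnosis_fsiq_shift={k: 0.0 for k in self.diagnosis_proportions},
            diagnosis_network_shift={},
            site_edge_shift={k: 0.0 for k in self.site_proportions},
            site_fsiq_shift={k: 0.0 for k in self.site_proportions},
        )


@dataclass
class GroundTruth:
    """What the simulator planted, for recovery checks.

    ``beta`` is the true per-edge coefficient (gamma * sign on planted
    edges, 0 elsewhere); ``mean_connectome`` is the noise-free baseline
    M needed to regenerate matched external cohorts.
    """

    beta: np.ndarray
    latent_g: np.ndarray
    true_edge_ids: np.ndarray
    mean_connectome: np.ndarray
    config: SimulationConfig

    @property
    def n_roi(self) -> int:
        return self.config.n_roi


def _network_labels(config: SimulationConfig) -> np.ndarray:
    sizes = config.resolved_network_sizes()
    return np.asarray(
        [lab for lab, s in zip(NETWORK_LABELS, sizes) for _ in range(s)],
        dtype=object)


def _within_network_edge_mask(labels: np.ndarray) -> np.ndarray:
    p = EdgeIndexMap(labels.size).pairs()
    return labels[p[:, 0]] == labels[p[:, 1]]


def _choose_true_edges(config: SimulationConfig, labels: np.ndarray,
                       rng: np.random.Generator) -> np.ndarray:
    n_edges = n_edges_for(config.n_roi)
    if config.true_edge_network is None:
        pool = np.arange(n_edges)
    else:
        p = EdgeIndexMap(config.n_roi).pairs()
        inside = ((labels[p[:, 0]] == config.true_edge_network)
                  & (labels[p[:, 1]] == config.true_edge_network))
        pool = np.nonzero(inside)[0]
    if config.n_true_edges > pool.size:
        raise ValueError(
            f"{config.n_true_edges} true edges requested but only "
            f"{pool.size} available in network "
            f"{config.true_edge_network!r}")
    return np.sort(rng.choice(pool, size=config.n_true_edges, replace=False))


def _subject_table(config: SimulationConfig, g: np.ndarray,
                   diagnosis: np.ndarray, site: np.ndarray,
                   rng: np.random.Generator,
                   fsiq_mean: float = 100.0, fsiq_sd: float = 15.0,
                   ) -> pd.DataFrame:
    n = config.n_subjects
    h = config.h
    eps = rng.standard_normal(n)
    fsiq = fsiq_mean + fsiq_sd * (np.sqrt(h) * g + np.sqrt(1.0 - h) * eps)
    fsiq = fsiq + np.asarray(
        [config.diagnosis_fsiq_shift.get(d, 0.0) for d in diagnosis])
    fsiq = fsiq + np.asarray([config.site_fsiq_shift.get(s, 0.0) for s in site])

    sub = {}
    for col, a in zip(SUBDOMAIN_COLUMNS, config.subdomain_loadings):
        u = rng.standard_normal(n)
        sub[col] = 100.0 + 15.0 * (a * g + np.sqrt(1.0 - a * a) * u)

    age = np.clip(rng.normal(10.3, 2.6, size=n), 5.0, 21.0)
    gender = rng.choice(["M", "F"], size=n, p=[0.64, 0.36])
    return pd.DataFrame(
        {"fsiq": fsiq, **sub, "age": age, "gender": gender,
         "diagnosis": diagnosis, "site": site},
        index=pd.Index([f"sub-{k:04d}" for k in range(n)], name="subject_id"))


def _subject_fc_matrix(config: SimulationConfig, truth_beta: np.ndarray,
                       mean_connectome: np.ndarray, labels: np.ndarray,
                       g: np.ndarray, diagnosis: np.ndarray, site: np.ndarray,
                       rng: np.random.Generator,
                       extra_edge_shift: float = 0.0) -> np.ndarray:
    n = g.size
    n_edges = mean_connectome.size
    fc = np.tile(mean_connectome, (n, 1))
    fc += np.outer(g, truth_beta)
    # diagnosis-specific within-network FC offsets
    within = _within_network_edge_mask(labels)
    p = EdgeIndexMap(config.n_roi).pairs()
    for dx, (net, delta) in config.diagnosis_network_shift.items():
        edge_sel = within & (labels[p[:, 0]] == net)
        rows = np.nonzero(diagnosis == dx)[0]
        if rows.size and edge_sel.any():
            fc[np.ix_(rows, np.nonzero(edge_sel)[0])] += delta
    site_shift = np.asarray([config.site_edge_shift.get(s, 0.0) for s in site])
    fc += site_shift[:, None] + extra_edge_shift
    fc += rng.normal(0.0, config.edge_noise_sd, size=(n, n_edges))
    return fc


def _runs_from_subject_fc(config: SimulationConfig, subject_fc: np.ndarray,
                          subject_ids: list[str],
                          rng: np.random.Generator,
                          ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n, n_edges = subject_fc.shape
    r = config.runs_per_subject
    fc_rows = np.repeat(subject_fc, r, axis=0)
    if config.run_noise_sd > 0:
        fc_rows = fc_rows + rng.normal(0.0, config.run_noise_sd,
                                       size=fc_rows.shape)
    sid = np.repeat(np.asarray(subject_ids, dtype=object), r)
    rid = np.asarray([f"run-{k + 1}" for _ in range(n) for k in range(r)],
                     dtype=object)
    return fc_rows, sid, rid


def simulate_cohort(config: SimulationConfig,
                    ) -> tuple[ConnectomeDataset, NetworkMap, GroundTruth]:
    """Draw a full cohort from the generative model (seeded, reproducible)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    labels = _network_labels(config)
    n_edges = n_edges_for(config.n_roi)

    within = _within_network_edge_mask(labels)
    mean_conn = np.where(
        within,
        rng.normal(config.within_network_mean, config.baseline_sd, n_edges),
        rng.normal(config.between_network_mean, config.baseline_sd, n_edges))

    true_ids = _choose_true_edges(config, labels, rng)
    signs = rng.choice([-1.0, 1.0], size=true_ids.size)
    beta = np.zeros(n_edges)
    beta[true_ids] = config.effect_scale * signs

    g = rng.standard_normal(config.n_subjects)
    diagnosis = rng.choice(list(config.diagnosis_proportions),
                           size=config.n_subjects,
                           p=list(config.diagnosis_proportions.values()))
    site = rng.choice(list(config.site_proportions), size=config.n_subjects,
                      p=list(config.site_proportions.values()))

    phenotypes = _subject_table(config, g, diagnosis, site, rng)
    subject_fc = _subject_fc_matrix(config, beta, mean_conn, labels, g,
                                    diagnosis, site, rng)
    fc_rows, sid, rid = _runs_from_subject_fc(
        config, subject_fc, list(phenotypes.index), rng)

    dataset = ConnectomeDataset(fc=fc_rows, subject_id=sid, run_id=rid,
                                phenotypes=phenotypes, n_roi=config.n_roi)
    truth = GroundTruth(beta=beta, latent_g=g, true_edge_ids=true_ids,
                        mean_connectome=mean_conn, config=config)
    return dataset, NetworkMap(labels=labels), truth


def simulate_external_cohort(truth: GroundTruth,
                             n_subjects: int | None = None,
                             fsiq_mean_shift: float = 0.0,
                             fsiq_sd_scale: float = 1.0,
                             site_edge_shift: float = 0.0,
                             h: float | None = None,
                             seed: int = 1,
                             ) -> ConnectomeDataset:
    """New subjects from the same planted mechanism, optionally shifted.

    Emulates replication cohorts whose demographics, IQ distribution and
    acquisition differ from the discovery cohort: the FSIQ location and
    scale can move, and a global edge offset mimics a site/scanner
    effect.  ``h=0`` regenerates a null external cohort (FC carries no
    IQ information) for calibration tests.
    """
    base = truth.config
    config = replace(
        base,
        n_subjects=n_subjects if n_subjects is not None else base.n_subjects,
        h=h if h is not None else base.h,
        seed=seed,
        site_proportions={"EXT": 1.0},
        site_edge_shift={"EXT": 0.0},
        site_fsiq_shift={"EXT": 0.0},
    )
    config.validate()
    rng = np.random.default_rng(seed)
    labels = _network_labels(config)

    g = rng.standard_normal(config.n_subjects)
    diagnosis = rng.choice(list(config.diagnosis_proportions),
                           size=config.n_subjects,
                           p=list(config.diagnosis_proportions.values()))
    site = np.asarray(["EXT"] * config.n_subjects, dtype=object)

    phenotypes = _subject_table(
        config, g, diagnosis, site, rng,
        fsiq_mean=100.0 + fsiq_mean_shift, fsiq_sd=15.0 * fsiq_sd_scale)
    phenotypes.index = pd.Index(
        [f"ext-{k:04d}" for k in range(config.n_subjects)], name="subject_id")

    subject_fc = _subject_fc_matrix(
        config, truth.beta, truth.mean_connectome, labels, g, diagnosis, site,
        rng, extra_edge_shift=site_edge_shift)
    fc_rows, sid, rid = _runs_from_subject_fc(
        config, subject_fc, list(phenotypes.index), rng)

    return ConnectomeDataset(fc=fc_rows, subject_id=sid, run_id=rid,
                             phenotypes=phenotypes, n_roi=config.n_roi)
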