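"""Core data structures for connectome-based phenotype prediction.

A *connectome* here is the vector of Fisher-z-transformed Pearson
correlations between the resting-state time series of every unordered
pair of regions of interest (ROIs).  With ``n_roi`` regions there are
``n_roi * (n_roi - 1) / 2`` edges, serialized in a fixed upper-triangle
row-major order so that edge vectors are comparable across modules and
across files.

FC values are stored on the Fisher-z (atanh) scale throughout: the
unbounded support suits linear modeling and L1 deviation sums.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Canonical seven-network cortical parcellation labels.
NETWORK_LABELS = ("Visual", "Motor", "DAN", "VAN", "Limbic", "FPCN", "DMN")

#: Phenotype table columns, in file order.
PHENOTYPE_COLUMNS = (
    "subject_id",
    "fsiq",
    "wmi",
    "fri",
    "vci",
    "vsi",
    "psi",
    "age",
    "gender",
    "diagnosis",
    "site",
)

#: IQ subdomain score columns (working memory, fluid reasoning, verbal
#: comprehension, visual-spatial, processing speed).
SUBDOMAIN_COLUMNS = ("wmi", "fri", "vci", "vsi", "psi")


def n_edges_for(n_roi: int) -> int:
    """Number of unordered ROI pairs for an ``n_roi``-region parcellation."""
    if n_roi < 2:
        raise ValueError(f"need at least 2 ROIs, got {n_roi}")
    return n_roi * (n_roi - 1) // 2


def edge_id(a: int, b: int, n_roi: int) -> int:
    """Map an unordered ROI pair to its 0-based edge id.

    The ordering is row-major over the strict upper triangle:
    (0,1), (0,2), ..., (0,n-1), (1,2), ... so that
    ``id = i*n_roi - i*(i+1)/2 + (j - i - 1)`` with ``i = min(a, b)``,
    ``j = max(a, b)``.
    """
    if a == b:
        raise ValueError(f"self-pair ({a}, {b}) is not an edge")
    if not (0 <= a < n_roi and 0 <= b < n_roi):
        raise ValueError(f"ROI pair ({a}, {b}) out of range for n_roi={n_roi}")
    i, j = (a, b) if a < b else (b, a)
    return i * n_roi - i * (i + 1) // 2 + (j - i - 1)


def edge_pair(eid: int, n_roi: int) -> tuple[int, int]:
    """Inverse of :func:`edge_id`: recover the (low, high) ROI pair."""
    m = n_edges_for(n_roi)
    if not (0 <= eid < m):
        raise ValueError(f"edge id {eid} out of range for n_roi={n_roi}")
    # closed-form inversion of the triangular offset
    i = int(n_roi - 2 - np.floor(
        np.sqrt(-8.0 * eid + 4.0 * n_roi * (n_roi - 1) - 7.0) / 2.0 - 0.5))
    j = eid + i + 1 - i * n_roi + i * (i + 1) // 2
    return i, j


@dataclass(frozen=True)
class EdgeIndexMap:
    """Bijection between edge ids and unordered ROI pairs."""

    n_roi: int

    @property
    def n_edges(self) -> int:
        return n_edges_for(self.n_roi)

    def id(self, a: int, b: int) -> int:
        return edge_id(a, b, self.n_roi)

    def pair(self, eid: int) -> tuple[int, int]:
        return edge_pair(eid, self.n_roi)

    def pairs(self) -> np.ndarray:
        """(n_edges, 2) array of (low, high) ROI indices, id order."""
        iu = np.triu_indices(self.n_roi, k=1)
        return np.column_stack(iu)

    def incident_edges(self, roi: int) -> np.ndarray:
        """Edge ids of all edges touching ``roi``."""
        p = self.pairs()
        return np.nonzero((p[:, 0] == roi) | (p[:, 1] == roi))[0]


def compute_fc(timeseries: np.ndarray) -> np.ndarray:
    """Fisher-z functional connectivity vector from a T x n_roi series.

    Entry for edge (i, j) is ``atanh(Pearson r)`` between ROI columns i
    and j, in :func:`edge_id` order.

    Raises
    ------
    ValueError
        If fewer than 3 timepoints, an ROI column is constant, or a pair
        correlates at exactly |r| = 1 (atanh diverges).
    """
    ts = np.asarray(timeseries, dtype=float)
    if ts.ndim != 2:
        raise ValueError("timeseries must be a 2-D (T x n_roi) array")
    t, n_roi = ts.shape
    if t < 3:
        raise ValueError(f"need at least 3 timepoints, got {t}")
    sd = ts.std(axis=0)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant time series for ROI(s) {bad.tolist()}")
    r = np.corrcoef(ts, rowvar=False)
    iu = np.triu_indices(n_roi, k=1)
    rv = r[iu]
    sat = np.nonzero(np.abs(rv) >= 1.0 - 1e-12)[0]
    if sat.size:
        a, b = edge_pair(int(sat[0]), n_roi)
        raise ValueError(
            f"|r| = 1 between ROIs ({a}, {b}); Fisher z is undefined")
    return np.arctanh(rv)


@dataclass
class NetworkMap:
    """Assignment of every ROI to one brain network label."""

    labels: np.ndarray  # (n_roi,) array of str

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=object)
        if self.labels.ndim != 1 or self.labels.size < 2:
            raise ValueError("labels must be a 1-D array covering all ROIs")
        if any(not isinstance(x, str) or not x for x in self.labels):
            raise ValueError("every ROI needs a non-empty network label")

    @property
    def n_roi(self) -> int:
        return self.labels.size

    @property
    def networks(self) -> list[str]:
        """Unique labels, canonical seven-network order first."""
        present = set(self.labels.tolist())
        ordered = [l for l in NETWORK_LABELS if l in present]
        extra = [l for l in dict.fromkeys(self.labels.tolist())
                 if l not in NETWORK_LABELS]
        return ordered + extra

    def rois_of(self, network: str) -> np.ndarray:
        idx = np.nonzero(self.labels == network)[0]
        if idx.size == 0:
            raise ValueError(f"unknown network label {network!r}")
        return idx

    def incident_edges(self, network: str) -> np.ndarray:
        """Edge ids of edges with >= 1 endpoint in ``network``."""
        rois = set(self.rois_of(network).tolist())
        p = EdgeIndexMap(self.n_roi).pairs()
        hit = np.fromiter(((a in rois) or (b in rois) for a, b in p),
                          dtype=bool, count=p.shape[0])
        return np.nonzero(hit)[0]

    def edge_labels(self) -> tuple[np.ndarray, np.ndarray]:
        """Per-edge (network of low ROI, network of high ROI)."""
        p = EdgeIndexMap(self.n_roi).pairs()
        return self.labels[p[:, 0]], self.labels[p[:, 1]]


@dataclass
class ConnectomeDataset:
    """Run-level FC matrix plus per-subject phenotypes.

    ``fc`` has one row per scan run; ``subject_id`` / ``run_id`` label the
    rows.  ``phenotypes`` is indexed by subject_id and carries fsiq, the
    five subdomain indices, age, gender, diagnosis and site.
    """

    fc: np.ndarray
    subject_id: np.ndarray
    run_id: np.ndarray
    phenotypes: pd.DataFrame
    n_roi: int

    def __post_init__(self) -> None:
        self.fc = np.asarray(self.fc, dtype=float)
        self.subject_id = np.asarray(self.subject_id, dtype=object)
        self.run_id = np.asarray(self.run_id, dtype=object)
        self.validate()

    def validate(self) -> None:
        if self.fc.ndim != 2:
            raise ValueError("fc must be 2-D (rows x edges)")
        if self.fc.shape[1] != n_edges_for(self.n_roi):
            raise ValueError(
                f"fc has {self.fc.shape[1]} columns but n_roi={self.n_roi} "
                f"implies {n_edges_for(self.n_roi)} edges")
        if not (self.fc.shape[0] == self.subject_id.size == self.run_id.size):
            raise ValueError("fc rows, subject_id and run_id lengths differ")
        missing = set(self.subject_id.tolist()) - set(self.phenotypes.index)
        if missing:
            raise ValueError(
                f"subjects in FC table absent from phenotypes: {sorted(missing)[:5]}")
        modeled = self.phenotypes.loc[self.subjects]
        if modeled["fsiq"].isna().any():
            raise ValueError("missing FSIQ for modeled subjects; drop them first")

    @property
    def n_edges(self) -> int:
        return self.fc.shape[1]

    @property
    def subjects(self) -> list:
        """Unique subject ids in first-appearance order."""
        return list(dict.fromkeys(self.subject_id.tolist()))

    def rows_of(self, subject) -> np.ndarray:
        return np.nonzero(self.subject_id == subject)[0]

    def subject_fc(self) -> tuple[list, np.ndarray]:
        """Run-averaged FC per subject: (subjects, subjects x edges)."""
        subs = self.subjects
        out = np.empty((len(subs), self.n_edges))
        for k, s in enumerate(subs):
            out[k] = self.fc[self.rows_of(s)].mean(axis=0)
        return subs, out

    def target(self, column: str = "fsiq") -> np.ndarray:
        """Per-subject phenotype values aligned to :attr:`subjects`."""
        if column not in self.phenotypes.columns:
            raise KeyError(f"unknown phenotype column {column!r}")
        return self.phenotypes.loc[self.subjects, column].to_numpy()

    def select_subjects(self, keep: Sequence) -> "ConnectomeDataset":
        keep_set = set(keep)
        mask = np.fromiter((s in keep_set for s in self.subject_id),
                           dtype=bool, count=self.subject_id.size)
        if not mask.any():
            raise ValueError("no rows left after subject selection")
        kept = [s for s in self.subjects if s in keep_set]
        return ConnectomeDataset(
            fc=self.fc[mask],
            subject_id=self.subject_id[mask],
            run_id=self.run_id[mask],
            phenotypes=self.phenotypes.loc[kept],
            n_roi=self.n_roi,
        )

    def first_run_only(self) -> "ConnectomeDataset":
        """Keep one run per subject (the first in row order)."""
        seen: set = set()
        mask = np.zeros(self.subject_id.size, dtype=bool)
        for k, s in enumerate(self.subject_id):
            if s not in seen:
                seen.add(s)
                mask[k] = True
        return ConnectomeDataset(
            fc=self.fc[mask], subject_id=self.subject_id[mask],
            run_id=self.run_id[mask], phenotypes=self.phenotypes,
            n_roi=self.n_roi)


@dataclass
class UnifiedModel:
    """Cross-fold consensus linear predictor on the edge vector.

    ``weights`` are per-edge coefficients in original FC (Fisher-z)
    units, averaged over all fold models with zeros for unselected
    edges; ``selection_frequency`` is the fraction of fold models in
    which each edge carried a nonzero weight.
    """

    n_roi: int
    weights: np.ndarray
    intercept: float
    selection_frequency: np.ndarray
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        self.selection_frequency = np.asarray(self.selection_frequency, dtype=float)
        m = n_edges_for(self.n_roi)
        if self.weights.shape != (m,) or self.selection_frequency.shape != (m,):
            raise ValueError("weights/selection_frequency length must equal n_edges")
        if ((self.selection_frequency < 0) | (self.selection_frequency > 1)).any():
            raise ValueError("selection_frequency must lie in [0, 1]")

    @property
    def n_edges(self) -> int:
        return self.weights.size

    def to_json(self, path) -> None:
        payload = {
            "n_roi": self.n_roi,
            "weights": self.weights.tolist(),
            "intercept": float(self.intercept),
            "selection_frequency": self.selection_frequency.tolist(),
            "provenance": self.provenance,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path) -> "UnifiedModel":
        d = json.loads(Path(path).read_text())
        return cls(
            n_roi=int(d["n_roi"]),
            weights=np.asarray(d["weights"], dtype=float),
            intercept=float(d["intercept"]),
            selection_frequency=np.asarray(d["selection_frequency"], dtype=float),
            provenance=d.get("provenance", {}),
        )


# ---------------------------------------------------------------------------
# Tabular I/O
# ---------------------------------------------------------------------------

def _edge_columns(n_edges: int) -> list[str]:
    width = max(4, len(str(n_edges - 1)))
    return [f"e{j:0{width}d}" for j in range(n_edges)]


def _sep_for(path) -> str:
    return "\t" if str(path).endswith(".tsv") else ","


def save_dataset(dataset: ConnectomeDataset, out_dir,
                 network_map: NetworkMap | None = None) -> dict[str, Path]:
    """Write fc.tsv / phenotypes.csv (/ networks.tsv) under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}

    fc_df = pd.DataFrame(dataset.fc, columns=_edge_columns(dataset.n_edges))
    fc_df.insert(0, "run_id", dataset.run_id)
    fc_df.insert(0, "subject_id", dataset.subject_id)
    paths["fc"] = out / "fc.tsv"
    fc_df.to_csv(paths["fc"], sep="\t", index=False)

    ph = dataset.phenotypes.reset_index()
    if "subject_id" not in ph.columns:
        ph = ph.rename(columns={ph.columns[0]: "subject_id"})
    paths["phenotypes"] = out / "phenotypes.csv"
    ph[list(PHENOTYPE_COLUMNS)].to_csv(paths["phenotypes"], index=False)

    if network_map is not None:
        nm = pd.DataFrame({"roi_index": np.arange(network_map.n_roi),
                           "network": network_map.labels})
        paths["networks"] = out / "networks.tsv"
        nm.to_csv(paths["networks"], sep="\t", index=False)
    return paths


def load_network_map(path) -> NetworkMap:
    df = pd.read_csv(path, sep=_sep_for(path))
    if not {"roi_index", "network"} <= set(df.columns):
        raise ValueError("network map needs columns roi_index, network")
    df = df.sort_values("roi_index")
    if not np.array_equal(df["roi_index"].to_numpy(), np.arange(len(df))):
        raise ValueError("roi_index must cover 0..n_roi-1 exactly once")
    return NetworkMap(labels=df["network"].to_numpy(dtype=object))


def load_dataset(fc_path, phenotype_path, network_path=None,
                 ) -> tuple[ConnectomeDataset, NetworkMap | None]:
    """Read the three tabular artifacts and validate them jointly.

    Subjects with a missing FSIQ are excluded (their FC rows dropped);
    the exclusion count is logged.
    """
    fc_df = pd.read_csv(fc_path, sep=_sep_for(fc_path),
                        float_precision="round_trip")
    if fc_df.columns[0] != "subject_id" or fc_df.columns[1] != "run_id":
        raise ValueError("FC table must start with subject_id, run_id columns")
    edge_cols = list(fc_df.columns[2:])
    n_edges = len(edge_cols)

    network_map = load_network_map(network_path) if network_path else None
    if network_map is not None:
        expected = n_edges_for(network_map.n_roi)
        if n_edges != expected:
            raise ValueError(
                f"FC table has {n_edges} edge columns; n_roi="
                f"{network_map.n_roi} implies {expected}")
        n_roi = network_map.n_roi
    else:
        # infer n_roi from the edge count
        n_roi = int(round((1 + np.sqrt(1 + 8 * n_edges)) / 2))
        if n_edges_for(n_roi) != n_edges:
            raise ValueError(f"{n_edges} edge columns is not a valid "
                             "upper-triangle count")

    ph = pd.read_csv(phenotype_path, float_precision="round_trip")
    missing_cols = set(PHENOTYPE_COLUMNS) - set(ph.columns)
    if missing_cols:
        raise ValueError(f"phenotype table missing columns {sorted(missing_cols)}")
    ph = ph.set_index("subject_id")

    fc_subjects = fc_df["subject_id"].astype(str)
    ph.index = ph.index.astype(str)
    absent = set(fc_subjects) - set(ph.index)
    if absent:
        raise ValueError(f"FC subjects absent from phenotypes: {sorted(absent)[:5]}")

    excluded = ph.index[ph["fsiq"].isna()]
    if len(excluded):
        logger.info("excluding %d subject(s) with missing FSIQ: %s",
                    len(excluded), list(excluded[:5]))
        keep = ~fc_subjects.isin(set(excluded))
        fc_df = fc_df.loc[keep]
        fc_subjects = fc_subjects.loc[keep]
        ph = ph.drop(index=excluded)

    dataset = ConnectomeDataset(
        fc=fc_df[edge_cols].to_numpy(dtype=float),
        subject_id=fc_subjects.to_numpy(dtype=object),
        run_id=fc_df["run_id"].astype(str).to_numpy(dtype=object),
        phenotypes=ph,
        n_roi=n_roi,
    )
    return dataset, network_map
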