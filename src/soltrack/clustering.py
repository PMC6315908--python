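"""Inlet clustering and inter-cluster flux accounting.

Entry and exit inlets are pooled and clustered in 3-D with a density-based
algorithm (DBSCAN); points in no dense region are flagged as outliers,
which mark incidental, less-travelled pathways.  Clusters are renamed
``C1, C2, …`` by descending size so labels are invariant to input order.

The flux table counts paths by (entry label, exit label) over the labels
``{C1…, OUTLIER, N}``, where ``N`` stands for a path terminus detected
inside the protein.  Two percentage views are derived: the share of inlets
per cluster (N excluded — an N terminus is not a surface inlet) and the
share of paths per (entry → exit) pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN

from .tracking import Inlet, N_TERMINUS, RawPath

__all__ = ["OUTLIER", "InletClusterSet", "FluxTable", "cluster_inlets",
           "flux_table", "outlier_paths"]

OUTLIER = "OUTLIER"


@dataclass
class InletClusterSet:
    """Cluster labels for a list of inlets, plus per-cluster statistics."""

    inlets: list[Inlet]
    labels: list[str]                       # per inlet: "C1", …, or OUTLIER
    centroids: dict[str, np.ndarray] = field(default_factory=dict)
    sizes: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.inlets) != len(self.labels):
            raise ValueError("one label per inlet required")

    @property
    def cluster_names(self) -> list[str]:
        return sorted(self.sizes, key=lambda c: int(c[1:]))

    @property
    def n_outliers(self) -> int:
        return sum(1 for lab in self.labels if lab == OUTLIER)

    def label_of(self, path_id: int, direction: str) -> str | None:
        for inlet, lab in zip(self.inlets, self.labels):
            if inlet.path_id == path_id and inlet.direction == direction:
                return lab
        return None

    def to_frame(self) -> pd.DataFrame:
        rows = [{"x": i.position[0], "y": i.position[1], "z": i.position[2],
                 "frame": i.frame, "direction": i.direction,
                 "path": i.path_id, "cluster": lab}
                for i, lab in zip(self.inlets, self.labels)]
        return pd.DataFrame(rows, columns=["x", "y", "z", "frame",
                                           "direction", "path", "cluster"])


def cluster_inlets(inlets: Sequence[Inlet], eps: float = 2.5,
                   min_samples: int = 3) -> InletClusterSet:
    """Density-based clustering of inlet positions.

    ``eps`` (Å) and ``min_samples`` are the DBSCAN density parameters.
    Deterministic for fixed inputs; cluster ids are assigned by descending
    cluster size (ties broken by centroid coordinates) so the labelling is
    canonical under permutations of the input.
    """
    inlets = list(inlets)
    if not inlets:
        return InletClusterSet([], [])
    pos = np.array([i.position for i in inlets], dtype=float)
    raw = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(pos)

    stats = []
    for lab in sorted(set(raw) - {-1}):
        members = raw == lab
        stats.append((int(members.sum()), tuple(pos[members].mean(axis=0)), lab))
    # big clusters first; centroid lexicographic order breaks size ties
    stats.sort(key=lambda t: (-t[0], t[1]))
    rename = {lab: f"C{rank + 1}" for rank, (_, _, lab) in enumerate(stats)}

    labels = [rename.get(lab, OUTLIER) for lab in raw]
    centroids = {rename[lab]: np.array(c) for _, c, lab in stats}
    sizes = {rename[lab]: n for n, _, lab in stats}
    return InletClusterSet(inlets, labels, centroids, sizes)


@dataclass
class FluxTable:
    """Path counts keyed by (entry label, exit label)."""

    counts: pd.DataFrame          # square, index=entry labels, columns=exit
    empty: bool = False

    @property
    def total_paths(self) -> int:
        return int(self.counts.to_numpy().sum())

    def path_shares(self) -> pd.DataFrame:
        """Percentage of paths per (entry → exit) pair (sums to 100)."""
        if self.empty or self.total_paths == 0:
            return self.counts.astype(float) * 0.0
        return self.counts / self.total_paths * 100.0

    def inlet_counts(self) -> pd.Series:
        """Number of surface inlets per label (entries + exits, N excluded)."""
        per_label = self.counts.sum(axis=1) + self.counts.sum(axis=0)
        return per_label.drop(N_TERMINUS, errors="ignore")

    def inlet_shares(self) -> pd.Series:
        """Percentage of inlets per cluster/outlier label (sums to 100)."""
        counts = self.inlet_counts()
        total = counts.sum()
        if self.empty or total == 0:
            return counts.astype(float) * 0.0
        return counts / total * 100.0


def flux_table(paths: Sequence[RawPath], clusters: InletClusterSet) -> FluxTable:
    """Count each path once at (entry label, exit label).

    Every crossing terminus must carry a cluster or OUTLIER label from
    ``clusters``; N termini use the label ``N``.  An unlabeled crossing
    terminus is a consistency error.
    """
    lookup: dict[tuple[int, str], str] = {
        (inlet.path_id, inlet.direction): lab
        for inlet, lab in zip(clusters.inlets, clusters.labels)}

    order = clusters.cluster_names + [OUTLIER, N_TERMINUS]
    counts = pd.DataFrame(0, index=order, columns=order, dtype=np.int64)
    for p in paths:
        entry = (N_TERMINUS if p.entry_terminus == N_TERMINUS
                 else lookup.get((p.path_id, "entry")))
        exit_ = (N_TERMINUS if p.exit_terminus == N_TERMINUS
                 else lookup.get((p.path_id, "exit")))
        if entry is None or exit_ is None:
            raise ValueError(
                f"path {p.path_id} has a crossing terminus without a cluster label")
        counts.loc[entry, exit_] += 1
    return FluxTable(counts, empty=len(paths) == 0)


def outlier_paths(paths: Sequence[RawPath],
                  clusters: InletClusterSet) -> pd.DataFrame:
    """Paths with at least one OUTLIER terminus, with their end coordinates.

    These identify incidental but permeable pathways distinct from the
    main tunnel mouths.
    """
    lookup = {(i.path_id, i.direction): (lab, i.position)
              for i, lab in zip(clusters.inlets, clusters.labels)}
    rows = []
    for p in paths:
        entry = lookup.get((p.path_id, "entry"), (N_TERMINUS, None))
        exit_ = lookup.get((p.path_id, "exit"), (N_TERMINUS, None))
        if OUTLIER not in (entry[0], exit_[0]):
            continue
        rows.append({
            "path": p.path_id, "molecule": p.molecule_id,
            "entry_label": entry[0], "exit_label": exit_[0],
            "entry_x": entry[1][0] if entry[1] else np.nan,
            "entry_y": entry[1][1] if entry[1] else np.nan,
            "entry_z": entry[1][2] if entry[1] else np.nan,
            "exit_x": exit_[1][0] if exit_[1] else np.nan,
            "exit_y": exit_[1][1] if exit_[1] else np.nan,
            "exit_z": exit_[1][2] if exit_[1] else np.nan,
        })
    cols = ["path", "molecule", "entry_label", "exit_label",
            "entry_x", "entry_y", "entry_z", "exit_x", "exit_y", "exit_z"]
    return pd.DataFrame(rows, columns=cols)
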