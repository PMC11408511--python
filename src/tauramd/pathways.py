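"""Dissociation-pathway mapping by interaction-fingerprint clustering.

Frames from dissociating trajectories (the window from shortly before the
"by residue first" event to trajectory termination) are converted to
binary contact fingerprints over the PP-RE pairs, compared with the
Jaccard distance, and grouped with k-means. Clusters are renumbered so
the mean ligand COM displacement (dCOM) increases with the label: low
labels are bound-like states, high labels are nearly dissociated ones.
Transitions between consecutive frames of a trajectory define a directed
flow graph whose heavy edges trace the dominant unbinding routes, and
average-linkage hierarchical clustering of the sparsest fingerprints
(fewer than three contacts) identifies the last interactions to break.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.cluster import KMeans
from sklearn.metrics import silhouette_score

from .contacts import ContactParams
from .errors import ConfigurationError, EmptySelectionError
from .residence import DissociationEvent


@dataclass
class ClusterConfig:
    pre_window_frames: int = 200  # frames before the event (2 ns at 10 ps)
    k: object = 8  # cluster count, or "auto" for a silhouette scan
    auto_k_range: tuple = (2, 12)
    seed: int = 0
    n_restarts: int = 10
    last_contact_max: int = 3  # strict <: frames with fewer contacts
    dendrogram_cut: float = 0.5
    feature_mode: str = "distance_rows"  # or "fingerprints"
    order_by: str = "delta_com"  # or "com_com"

    def __post_init__(self):
        if self.pre_window_frames < 0:
            raise ConfigurationError("pre_window_frames must be >= 0")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 2):
            raise ConfigurationError("k must be an integer >= 2 or 'auto'")
        if self.feature_mode not in ("distance_rows", "fingerprints"):
            raise ConfigurationError(
                f"unknown feature_mode {self.feature_mode!r}")
        if self.order_by not in ("delta_com", "com_com"):
            raise ConfigurationError(f"unknown order_by {self.order_by!r}")


@dataclass
class FrameSelection:
    """Provenance of the frames entering the clustering."""

    trajectory_ids: np.ndarray  # (n_rows,) per selected frame
    frame_indices: np.ndarray
    times: np.ndarray
    matrices: dict  # trajectory_id -> PairDistanceMatrix

    @property
    def n_rows(self) -> int:
        return len(self.frame_indices)


def select_cluster_frames(matrices: dict, events: dict,
                          config: ClusterConfig = None) -> FrameSelection:
    """Pick the analysis window of every dissociating trajectory.

    ``matrices`` maps trajectory id -> PairDistanceMatrix, ``events`` maps
    trajectory id -> its "by residue first" DissociationEvent. The window
    is [event frame - pre_window_frames, last frame], clamped at 0;
    censored (never-dissociating) trajectories are excluded.
    """
    config = config or ClusterConfig()
    tids, fids, times = [], [], []
    for tid in sorted(matrices):
        if tid not in events:
            continue
        ev = events[tid]
        if ev.censored:
            continue
        mat = matrices[tid]
        interval = mat.times[1] - mat.times[0] if len(mat.times) > 1 else 1.0
        ev_frame = int(round(ev.time / interval))
        start = max(0, ev_frame - config.pre_window_frames)
        for f in range(start, mat.n_frames):
            tids.append(tid)
            fids.append(f)
            times.append(mat.times[f])
    if not tids:
        raise EmptySelectionError(
            "no dissociating trajectory: nothing to cluster")
    return FrameSelection(np.asarray(tids), np.asarray(fids),
                          np.asarray(times), matrices)


@dataclass
class BinaryIFPMatrix:
    """Binary contact fingerprints of the selected frames."""

    matrix: np.ndarray  # (n_rows, n_pairs) bool
    pairs: list  # PP-RE pairs of the retained (not all-zero) columns
    trajectory_ids: np.ndarray
    frame_indices: np.ndarray
    times: np.ndarray
    delta_com: np.ndarray
    com_com: np.ndarray
    rmsd: np.ndarray

    @property
    def n_rows(self) -> int:
        return self.matrix.shape[0]


def build_binary_matrix(selection: FrameSelection,
                        params: ContactParams = None,
                        drop_empty_columns: bool = True) -> BinaryIFPMatrix:
    """Binarize the representative distances: 1 iff distance < d_rr.

    All trajectories must share the PP-RE pair list (they do when computed
    from the same topology/first frame). Columns that are never in contact
    are dropped; they cannot affect Jaccard distances.
    """
    params = params or ContactParams()
    first = selection.matrices[selection.trajectory_ids[0]]
    pairs = first.pairs
    rows, dcom, ccom, rmsd = [], [], [], []
    for tid, f in zip(selection.trajectory_ids, selection.frame_indices):
        mat = selection.matrices[tid]
        rows.append(mat.distances[f] < params.d_rr)
        dcom.append(mat.delta_com[f])
        ccom.append(mat.com_com[f])
        rmsd.append(mat.rmsd[f])
    M = np.asarray(rows, dtype=bool)
    keep = np.arange(M.shape[1])
    if drop_empty_columns:
        keep = np.flatnonzero(M.any(axis=0))
        M = M[:, keep]
    return BinaryIFPMatrix(
        matrix=M,
        pairs=[pairs[i] for i in keep],
        trajectory_ids=selection.trajectory_ids.copy(),
        frame_indices=selection.frame_indices.copy(),
        times=selection.times.copy(),
        delta_com=np.asarray(dcom),
        com_com=np.asarray(ccom),
        rmsd=np.asarray(rmsd),
    )


def jaccard_matrix(binary: BinaryIFPMatrix) -> np.ndarray:
    """Pairwise Jaccard distances between frame fingerprints.

    d_J = 1 - |intersection| / |union| of the contact sets; 0 when both
    sets are empty. Symmetric with zero diagonal.
    """
    M = np.asarray(binary.matrix if isinstance(binary, BinaryIFPMatrix)
                   else binary, dtype=bool)
    if M.shape[0] < 2:
        raise ConfigurationError("jaccard_matrix needs at least 2 rows")
    return squareform(pdist(M, metric="jaccard"))


@dataclass
class ClusterModel:
    labels: np.ndarray  # (n_rows,) in 1..k, ordered by mean dCOM
    k: int
    sizes: np.ndarray  # (k,)
    mean_delta_com: np.ndarray  # (k,)
    mean_com_com: np.ndarray
    mean_rmsd: np.ndarray
    occupancy: np.ndarray  # (k, n_pairs) column means of the binary matrix
    pairs: list
    silhouette_by_k: dict = field(default_factory=dict)


def cluster_frames(distance_matrix: np.ndarray, binary: BinaryIFPMatrix,
                   config: ClusterConfig = None) -> ClusterModel:
    """K-means clustering of dissociation fingerprints.

    In the default ``distance_rows`` mode the rows of the Jaccard distance
    matrix are the feature vectors handed to k-means; the alternative
    ``fingerprints`` mode clusters the binary fingerprints directly. With
    ``k="auto"`` the scan range is evaluated with the mean silhouette
    score (ties break to the smaller k). Labels are renumbered so the
    cluster-mean dCOM (or COM-COM distance) is non-decreasing in the
    label.
    """
    config = config or ClusterConfig()
    X = (np.asarray(distance_matrix, dtype=float)
         if config.feature_mode == "distance_rows"
         else binary.matrix.astype(float))
    n = X.shape[0]

    def fit(k):
        return KMeans(n_clusters=k, n_init=config.n_restarts,
                      random_state=config.seed).fit(X)

    silhouettes = {}
    if config.k == "auto":
        lo, hi = config.auto_k_range
        hi = min(hi, n - 1)
        if lo > hi:
            raise ConfigurationError("too few rows for the auto-k scan")
        best_k, best_score = None, -np.inf
        for k in range(lo, hi + 1):
            km = fit(k)
            if len(np.unique(km.labels_)) < 2:
                continue
            score = silhouette_score(X, km.labels_)
            silhouettes[k] = float(score)
            if score > best_score + 1e-12:
                best_k, best_score = k, score
        if best_k is None:
            raise ConfigurationError("silhouette scan found no valid k")
        k = best_k
    else:
        k = config.k
        if n < k:
            raise ConfigurationError(
                f"{n} rows cannot form {k} clusters")
    km = fit(k)
    raw = km.labels_

    order_key = (binary.delta_com if config.order_by == "delta_com"
                 else binary.com_com)
    means = np.asarray([order_key[raw == c].mean() for c in range(k)])
    order = np.argsort(means, kind="stable")
    relabel = np.empty(k, dtype=int)
    relabel[order] = np.arange(1, k + 1)
    labels = relabel[raw]

    sizes = np.asarray([(labels == c).sum() for c in range(1, k + 1)])
    mdc = np.asarray([binary.delta_com[labels == c].mean()
                      for c in range(1, k + 1)])
    mcc = np.asarray([binary.com_com[labels == c].mean()
                      for c in range(1, k + 1)])
    mrm = np.asarray([binary.rmsd[labels == c].mean()
                      for c in range(1, k + 1)])
    occ = np.vstack([binary.matrix[labels == c].mean(axis=0)
                     for c in range(1, k + 1)])
    return ClusterModel(labels=labels, k=k, sizes=sizes, mean_delta_com=mdc,
                        mean_com_com=mcc, mean_rmsd=mrm, occupancy=occ,
                        pairs=list(binary.pairs),
                        silhouette_by_k=silhouettes)


@dataclass
class FlowEdge:
    source: int
    target: int
    frame_count: int  # source -> target frame transitions
    trajectory_count: int  # distinct trajectories with this transition
    net_flow: int  # frame_count(i->j) - frame_count(j->i)


@dataclass
class FlowGraph:
    edges: list  # FlowEdge, ordered by descending trajectory count

    def to_networkx(self):
        import networkx as nx

        g = nx.DiGraph()
        for e in self.edges:
            g.add_edge(e.source, e.target, frame_count=e.frame_count,
                       trajectory_count=e.trajectory_count,
                       net_flow=e.net_flow)
        return g

    def to_dict(self) -> dict:
        return {"edges": [vars(e) for e in self.edges]}


def flow_graph(model: ClusterModel, selection: FrameSelection) -> FlowGraph:
    """Inter-cluster transitions between consecutive frames per trajectory."""
    labels = model.labels
    tids = selection.trajectory_ids
    counts: dict = {}
    trajs: dict = {}
    for i in range(len(labels) - 1):
        if tids[i] != tids[i + 1]:
            continue
        a, b = int(labels[i]), int(labels[i + 1])
        if a == b:
            continue
        counts[(a, b)] = counts.get((a, b), 0) + 1
        trajs.setdefault((a, b), set()).add(tids[i])
    edges = [
        FlowEdge(a, b, counts[(a, b)], len(trajs[(a, b)]),
                 counts[(a, b)] - counts.get((b, a), 0))
        for (a, b) in counts
    ]
    edges.sort(key=lambda e: (-e.trajectory_count, -e.frame_count,
                              e.source, e.target))
    return FlowGraph(edges)


@dataclass
class LastContactGroup:
    pattern: list  # PP-RE pairs present in over half the group's frames
    n_frames: int
    n_trajectories: int
    trajectory_ids: list


@dataclass
class LastContactReport:
    groups: list  # LastContactGroup, largest trajectory coverage first
    n_frames_considered: int


def last_contact_clusters(binary: BinaryIFPMatrix, events: dict = None,
                          config: ClusterConfig = None) -> LastContactReport:
    """Group the sparsest pre-dissociation fingerprints to find the last
    interactions to break.

    Frames with at least one but strictly fewer than ``last_contact_max``
    contacts qualify; when ``events`` is given, only frames at or before
    each trajectory's event time are considered. Average-linkage
    hierarchical clustering on Jaccard distances, dendrogram cut at
    ``dendrogram_cut``.
    """
    config = config or ClusterConfig()
    counts = binary.matrix.sum(axis=1)
    qual = (counts >= 1) & (counts < config.last_contact_max)
    if events is not None:
        in_time = np.asarray([
            binary.times[i] <= events[tid].time if tid in events else False
            for i, tid in enumerate(binary.trajectory_ids)
        ])
        qual &= in_time
    idx = np.flatnonzero(qual)
    if idx.size == 0:
        warnings.warn("no pre-dissociation frame with fewer than "
                      f"{config.last_contact_max} contacts", stacklevel=2)
        return LastContactReport([], 0)
    M = binary.matrix[idx]
    if idx.size == 1:
        assignments = np.asarray([1])
    else:
        cond = pdist(M, metric="jaccard")
        Z = linkage(cond, method="average")
        assignments = fcluster(Z, t=config.dendrogram_cut,
                               criterion="distance")
    groups = []
    for g in np.unique(assignments):
        rows = idx[assignments == g]
        sub = binary.matrix[rows]
        pattern = [binary.pairs[j]
                   for j in np.flatnonzero(sub.mean(axis=0) > 0.5)]
        tids = sorted(set(binary.trajectory_ids[rows]))
        groups.append(LastContactGroup(pattern, len(rows), len(tids), tids))
    groups.sort(key=lambda g: (-g.n_trajectories, -g.n_frames))
    return LastContactReport(groups, int(idx.size))
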