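"""Waveform clustering: UMAP graph + Louvain communities, validation.

Communities are detected on the UMAP fuzzy neighbour graph, never on the
2-D projection; the embedding is kept for display only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import confusion_matrix
from sklearn.model_selection import StratifiedKFold, cross_val_predict

N_NEIGHBORS = 20
MIN_DIST = 0.2
RESOLUTION = 1.0


@dataclass(frozen=True)
class WaveMapParams:
    n_neighbors: int = N_NEIGHBORS
    min_dist: float = MIN_DIST
    resolution: float = RESOLUTION
    seed: int = 0


@dataclass
class ClusterAssignment:
    embedding_2d: np.ndarray  # (n_units x 2)
    labels: np.ndarray  # (n_units,) integer communities
    params: WaveMapParams
    modularity: float

    @property
    def n_clusters(self) -> int:
        return int(np.unique(self.labels).size)


def _umap_graph(waveforms: np.ndarray, params: WaveMapParams):
    import umap  # deferred: numba JIT import cost

    if waveforms.shape[0] < 2 * params.n_neighbors:
        raise ValueError(
            f"need >= {2 * params.n_neighbors} waveforms for n_neighbors={params.n_neighbors}"
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mapper = umap.UMAP(
            n_neighbors=params.n_neighbors,
            min_dist=params.min_dist,
            n_components=2,
            random_state=params.seed,
        ).fit(np.asarray(waveforms, float))
    return mapper.graph_, mapper.embedding_


def _louvain(graph, resolution: float, seed: int) -> np.ndarray:
    g = nx.from_scipy_sparse_array(graph)
    comms = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    # canonical order: by size descending, then smallest member
    comms = sorted(comms, key=lambda c: (-len(c), min(c)))
    labels = np.empty(graph.shape[0], dtype=int)
    for i, c in enumerate(comms):
        labels[list(c)] = i
    return labels


def build_wavemap(
    waveforms: np.ndarray, params: WaveMapParams = WaveMapParams()
) -> ClusterAssignment:
    """UMAP the waveforms, Louvain-cluster the neighbour graph.

    Deterministic for a fixed seed.  Labels are renumbered by descending
    community size.
    """
    graph, embedding = _umap_graph(waveforms, params)
    labels = _louvain(graph, params.resolution, params.seed)
    g = nx.from_scipy_sparse_array(graph)
    q = nx.community.modularity(
        g,
        [set(np.flatnonzero(labels == l)) for l in np.unique(labels)],
        weight="weight",
    )
    return ClusterAssignment(embedding, labels, params, float(q))


def canonicalize_labels(
    labels: np.ndarray, ttp_width_ms: np.ndarray
) -> tuple[np.ndarray, dict]:
    """Rename clusters by ascending median trough-to-peak width.

    Gives stable NS-like (narrow first) ordering on synthetic data.
    Returns the renamed labels and the old->new mapping.
    """
    labels = np.asarray(labels)
    widths = {
        l: float(np.median(np.asarray(ttp_width_ms)[labels == l]))
        for l in np.unique(labels)
    }
    order = sorted(widths, key=lambda l: widths[l])
    mapping = {old: new for new, old in enumerate(order)}
    return np.array([mapping[l] for l in labels]), mapping


@dataclass
class ResolutionSweepResult:
    resolutions: np.ndarray
    modularity_mean: np.ndarray
    modularity_sd: np.ndarray
    n_clusters_mean: np.ndarray
    chosen_resolution: float


def resolution_sweep(
    waveforms: np.ndarray,
    *,
    resolutions: Optional[np.ndarray] = None,
    n_runs: int = 25,
    subsample_frac: float = 0.8,
    params: WaveMapParams = WaveMapParams(),
) -> ResolutionSweepResult:
    """Mean +/- SD modularity and cluster count over subsampled reruns.

    Each run refits UMAP on a random ``subsample_frac`` of the data with
    its own seed, then sweeps the Louvain resolution grid on that graph.
    The chosen resolution maximises mean modularity (ties -> smallest).
    """
    if resolutions is None:
        resolutions = np.arange(0.0, 10.5, 0.5)
    resolutions = np.asarray(resolutions, float)
    if resolutions.size == 0:
        raise ValueError("empty resolution grid")
    x = np.asarray(waveforms, float)
    n_sub = int(round(subsample_frac * x.shape[0]))
    if n_sub < 2 * params.n_neighbors:
        raise ValueError("subsample too small for n_neighbors")

    q = np.empty((n_runs, resolutions.size))
    k = np.empty((n_runs, resolutions.size))
    root = np.random.default_rng(params.seed)
    for r in range(n_runs):
        run_seed = int(root.integers(2**31))
        rng = np.random.default_rng(run_seed)
        idx = rng.choice(x.shape[0], n_sub, replace=False)
        run_params = WaveMapParams(
            params.n_neighbors, params.min_dist, params.resolution, run_seed
        )
        graph, _ = _umap_graph(x[idx], run_params)
        g = nx.from_scipy_sparse_array(graph)
        for c, res in enumerate(resolutions):
            labels = _louvain(graph, res, run_seed)
            comms = [set(np.flatnonzero(labels == l)) for l in np.unique(labels)]
            q[r, c] = nx.community.modularity(g, comms, weight="weight")
            k[r, c] = len(comms)

    q_mean = q.mean(axis=0)
    chosen = float(resolutions[int(np.argmax(q_mean))])  # argmax -> smallest on ties
    return ResolutionSweepResult(
        resolutions, q_mean, q.std(axis=0, ddof=1) if n_runs > 1 else np.zeros_like(q_mean),
        k.mean(axis=0), chosen
    )


@dataclass
class SeparabilityReport:
    confusion: np.ndarray  # row-normalised percentages
    mean_accuracy: float
    classes: np.ndarray


def separability_cv(
    waveforms: np.ndarray,
    labels: Sequence[int],
    *,
    folds: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> SeparabilityReport:
    """Gradient-boosted-tree separability check with k-fold CV.

    Returns the out-of-fold confusion matrix (rows = true cluster,
    normalised to percent) and the mean of its diagonal.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError("every class needs at least `folds` members")
    clf = GradientBoostingClassifier(n_estimators=n_estimators, random_state=seed)
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    pred = cross_val_predict(clf, np.asarray(waveforms, float), y, cv=cv)
    cm = confusion_matrix(y, pred, labels=classes).astype(float)
    cm = cm / cm.sum(axis=1, keepdims=True) * 100.0
    return SeparabilityReport(cm, float(np.mean(np.diag(cm))), classes)


@dataclass
class MergeMapReport:
    mapping: dict  # low-res label -> sorted list of absorbed high-res labels
    retained_fraction: dict  # low-res label -> fraction of its units in mapping
    coarsening: bool


def merge_map(
    labels_low: np.ndarray, labels_high: np.ndarray, *, threshold: float = 0.9
) -> MergeMapReport:
    """How a low-resolution partition absorbs a high-resolution one.

    A high-res cluster is assigned to the low-res cluster holding its
    majority; the partition pair is a coarsening when every high-res
    cluster sits >= ``threshold`` inside one low-res cluster.
    """
    lo = np.asarray(labels_low)
    hi = np.asarray(labels_high)
    if lo.shape != hi.shape:
        raise ValueError("assignments must cover the same units")
    mapping: dict = {l: [] for l in np.unique(lo)}
    coarsening = True
    for h in np.unique(hi):
        members = lo[hi == h]
        owners, counts = np.unique(members, return_counts=True)
        best = owners[int(np.argmax(counts))]
        mapping[best].append(int(h))
        if counts.max() / counts.sum() < threshold:
            coarsening = False
    retained = {}
    for l, absorbed in mapping.items():
        in_l = lo == l
        retained[l] = float(np.isin(hi[in_l], absorbed).mean()) if in_l.any() else 0.0
    return MergeMapReport({k: sorted(v) for k, v in mapping.items()}, retained, coarsening)
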