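"""Inter-spike-interval profiles, ISI-PCA, bursting index, shuffle tests."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.decomposition import PCA

ISI_BIN_MS = 0.4
ISI_MAX_MS = 100.0
N_SHUFFLES = 500


@dataclass
class ISIProfile:
    bin_ms: float
    max_isi_ms: float
    hist: np.ndarray  # max-normalised
    peak_isi_ms: float

    @property
    def bin_centers_ms(self) -> np.ndarray:
        return np.arange(self.hist.size) * self.bin_ms + self.bin_ms / 2.0


def isi_histogram(
    spike_times_s: np.ndarray,
    *,
    bin_ms: float = ISI_BIN_MS,
    max_isi_ms: float = ISI_MAX_MS,
) -> ISIProfile:
    """Successive-interval histogram, normalised so the peak bin is 1.

    Intervals are the differences of consecutive spike times over the
    whole session, binned at ``bin_ms`` up to ``max_isi_ms``.
    """
    t = np.asarray(spike_times_s, float)
    if t.size < 2:
        raise ValueError("need at least 2 spikes for an ISI histogram")
    isi_ms = np.diff(t) * 1e3
    edges = np.arange(0.0, max_isi_ms + bin_ms, bin_ms)
    counts, _ = np.histogram(isi_ms, edges)
    peak = counts.max()
    hist = counts / peak if peak > 0 else counts.astype(float)
    peak_isi = float(edges[int(np.argmax(counts))] + bin_ms / 2.0)
    return ISIProfile(bin_ms, max_isi_ms, hist.astype(float), peak_isi)


@dataclass
class ISIPCAModel:
    components: np.ndarray  # (n_components x n_bins), orthonormal rows
    loadings: np.ndarray  # (n_units x n_components)
    explained_variance: np.ndarray
    mean: np.ndarray
    sign_convention: dict = field(default_factory=dict)
    degenerate: bool = False


def isi_pca(
    hist_matrix: np.ndarray,
    *,
    n_components: int = 3,
    bin_ms: float = ISI_BIN_MS,
    short_isi_ms: float = 10.0,
) -> ISIPCAModel:
    """PCA of mean-centred ISI histograms with fixed sign conventions.

    PC1 is oriented so its mean over the first ``short_isi_ms`` of ISI
    bins is positive (short-interval mass loads positively); PC3 so the
    same short-ISI mean is negative (a dip at short intervals).  PCA
    signs are otherwise arbitrary and the bursting index l1 - l3 would
    flip without this convention; orienting PC1 by its overall mean
    instead is unstable because that mean vanishes whenever histogram
    mass is balanced across units.
    """
    x = np.asarray(hist_matrix, float)
    if x.ndim != 2 or x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError("need at least 3 units and 3 bins")
    if np.allclose(x, x[0]):
        n = min(n_components, x.shape[1])
        return ISIPCAModel(
            components=np.zeros((n, x.shape[1])),
            loadings=np.zeros((x.shape[0], n)),
            explained_variance=np.zeros(n),
            mean=x.mean(axis=0),
            degenerate=True,
        )
    n = min(n_components, x.shape[0] - 1, x.shape[1])
    pca = PCA(n_components=n, svd_solver="full")
    loadings = pca.fit_transform(x)
    comps = pca.components_.copy()

    convention: dict = {}
    flips = np.ones(n)
    k = int(short_isi_ms / bin_ms)
    if comps[0][:k].mean() < 0:
        flips[0] = -1.0
    convention["pc1"] = f"mean over first {short_isi_ms} ms positive"
    if n >= 3:
        if comps[2][:k].mean() > 0:
            flips[2] = -1.0
        convention["pc3"] = f"mean over first {short_isi_ms} ms negative"
    if n >= 2 and comps[1].mean() < 0:
        flips[1] = -1.0
    convention["pc2"] = "mean positive"
    comps *= flips[:, None]
    loadings *= flips[None, :]
    convention["flips"] = flips.tolist()

    return ISIPCAModel(
        components=comps,
        loadings=loadings,
        explained_variance=pca.explained_variance_.copy(),
        mean=pca.mean_.copy(),
        sign_convention=convention,
    )


def bursting_index(l1: float | np.ndarray, l3: float | np.ndarray):
    """Difference of the first and third PC loadings."""
    return np.asarray(l1, float) - np.asarray(l3, float)


@dataclass
class ShuffleTestResult:
    observed_stat: dict  # cluster -> median
    lo_2_5: dict
    hi_97_5: dict
    n_shuffles: int
    significant: dict  # cluster -> bool


def shuffle_test(
    values: np.ndarray,
    cluster_labels: Sequence,
    *,
    n_shuffles: int = N_SHUFFLES,
    seed: int = 0,
) -> ShuffleTestResult:
    """Label-permutation test of per-cluster medians.

    For each shuffle, labels are permuted across units (cluster sizes
    preserved) and per-cluster medians recomputed; a cluster is
    significant when its observed median falls outside the [2.5, 97.5]
    percentile band of its shuffled medians.
    """
    v = np.asarray(values, float)
    labels = np.asarray(cluster_labels)
    uniq = np.unique(labels)
    if uniq.size < 2:
        raise ValueError("need at least 2 clusters")
    for c in uniq:
        if (labels == c).sum() == 0:
            raise ValueError(f"cluster {c} has no members")
    rng = np.random.default_rng(seed)
    observed = {c: float(np.median(v[labels == c])) for c in uniq}
    sh = {c: np.empty(n_shuffles) for c in uniq}
    for s in range(n_shuffles):
        perm = rng.permutation(labels)
        for c in uniq:
            sh[c][s] = np.median(v[perm == c])
    lo = {c: float(np.percentile(sh[c], 2.5)) for c in uniq}
    hi = {c: float(np.percentile(sh[c], 97.5)) for c in uniq}
    sig = {c: bool(observed[c] < lo[c] or observed[c] > hi[c]) for c in uniq}
    return ShuffleTestResult(observed, lo, hi, n_shuffles, sig)
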