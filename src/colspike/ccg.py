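"""Trial-based cross-correlograms, jitter correction and pair classification.

The raw CCG for an ordered pair (reference j, target k) is

    CCG_{j<-k}(tau) = sum_i sum_t x_j,i(t) x_k,i(t+tau)
                      / (M * theta(tau) * lambda_j * lambda_k)

over binary trial rasters, where M is the trial count, theta(tau) =
N - |tau| corrects the overlapping-bin count and lambda is the mean
spike count per bin over the analysis bins.  Independent stationary
trains give an expectation of 1 at every lag.

Jitter correction subtracts the analytic expectation of an ensemble in
which spikes are uniformly redistributed within non-overlapping windows
(default 25 ms) anchored at the analysis-window start.  The correction
is symmetrised over which train is jittered so the mirror identity
corrected_{k<-j}(tau) = corrected_{j<-k}(-tau) holds exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.fft import irfft, rfft
from scipy.stats import wilcoxon

CCG_WINDOW_S = (0.4, 1.0)
CCG_BIN_MS = 1.0
CCG_MAX_LAG_MS = 100.0
JITTER_MS = 25.0
NOISE_BAND_MS = (50.0, 100.0)
PEAK_WINDOW_MS = 10.0
EXC_Z = 7.0
INH_Z = 5.0
CA_WINDOW_MS = 10.0


@dataclass(frozen=True)
class CCGParams:
    window_s: tuple[float, float] = CCG_WINDOW_S
    bin_ms: float = CCG_BIN_MS
    max_lag_ms: float = CCG_MAX_LAG_MS
    jitter_ms: float = JITTER_MS

    @property
    def n_bins(self) -> int:
        return int(round((self.window_s[1] - self.window_s[0]) * 1e3 / self.bin_ms))

    @property
    def n_lags(self) -> int:
        return int(round(self.max_lag_ms / self.bin_ms))

    @property
    def lags_ms(self) -> np.ndarray:
        return np.arange(-self.n_lags, self.n_lags + 1) * self.bin_ms


@dataclass
class CCGResult:
    pair: tuple[int, int]  # (reference j, target k)
    lags_ms: np.ndarray
    raw: np.ndarray
    corrected: Optional[np.ndarray]
    M: int
    lambda_j: float  # mean spikes per bin
    lambda_k: float
    params: CCGParams = field(default_factory=CCGParams)

    @property
    def theta(self) -> np.ndarray:
        n = self.params.n_bins
        return n - np.abs(self.lags_ms / self.params.bin_ms)

    def mirrored(self) -> "CCGResult":
        """The CCG of the reversed pair: raw_{k<-j}(tau) = raw_{j<-k}(-tau)."""
        return CCGResult(
            pair=(self.pair[1], self.pair[0]),
            lags_ms=self.lags_ms.copy(),
            raw=self.raw[::-1].copy(),
            corrected=None if self.corrected is None else self.corrected[::-1].copy(),
            M=self.M,
            lambda_j=self.lambda_k,
            lambda_k=self.lambda_j,
            params=self.params,
        )


def bin_trials(
    spike_times_s: np.ndarray,
    onsets_s: np.ndarray,
    params: CCGParams = CCGParams(),
) -> np.ndarray:
    """Binary (M x N) raster of spikes in the analysis window of each trial."""
    t0, t1 = params.window_s
    n = params.n_bins
    bw = params.bin_ms / 1e3
    sp = np.asarray(spike_times_s, float)
    x = np.zeros((len(onsets_s), n), dtype=np.float32)
    for i, on in enumerate(np.asarray(onsets_s, float)):
        rel = sp[np.searchsorted(sp, on + t0) : np.searchsorted(sp, on + t1)] - (on + t0)
        idx = np.minimum((rel / bw).astype(int), n - 1)
        x[i, idx] = 1.0
    return x


def _window_means(x: np.ndarray, jitter_bins: int) -> np.ndarray:
    """Replace each raster bin by its within-trial jitter-window mean."""
    m, n = x.shape
    n_win = int(np.ceil(n / jitter_bins))
    pad = n_win * jitter_bins - n
    xp = np.pad(x, ((0, 0), (0, pad)))
    means = xp.reshape(m, n_win, jitter_bins).mean(axis=2)
    # edge window may be short: recompute its mean over real bins only
    if pad:
        means[:, -1] = x[:, (n_win - 1) * jitter_bins :].mean(axis=1)
    return np.repeat(means, jitter_bins, axis=1)[:, :n]


def _trialwise_correlate(a: np.ndarray, b: np.ndarray, n_lags: int) -> np.ndarray:
    """sum_i sum_t a_i(t) b_i(t+tau) for tau in [-n_lags, n_lags]."""
    m, n = a.shape
    nfft = 1
    while nfft < 2 * n:
        nfft *= 2
    fa = rfft(a, nfft, axis=1)
    fb = rfft(b, nfft, axis=1)
    conv = irfft((fa.conj() * fb).sum(axis=0), nfft)
    # conv[d] = sum_t a(t) b(t+d) with negative d wrapped to nfft+d
    out = np.empty(2 * n_lags + 1)
    out[n_lags:] = conv[: n_lags + 1]
    out[:n_lags] = conv[nfft - n_lags :]
    return out


def compute_ccg(
    x_j: np.ndarray,
    x_k: np.ndarray,
    params: CCGParams = CCGParams(),
    *,
    jitter_correct_flag: bool = True,
) -> CCGResult:
    """Normalised CCG of two binary rasters, optionally jitter-corrected.

    ``x_j``/``x_k`` are (M x N) rasters from :func:`bin_trials`.  Raises
    when either unit has no spikes in the window (pair undefined).
    """
    x_j = np.asarray(x_j, np.float64)
    x_k = np.asarray(x_k, np.float64)
    if x_j.shape != x_k.shape or x_j.ndim != 2:
        raise ValueError("rasters must share the same (M x N) shape")
    m, n = x_j.shape
    if m < 2:
        raise ValueError("need at least 2 trials")
    lam_j = x_j.mean()
    lam_k = x_k.mean()
    if lam_j == 0 or lam_k == 0:
        raise ValueError("a unit has zero spikes in the analysis window")

    n_lags = params.n_lags
    theta = n - np.abs(np.arange(-n_lags, n_lags + 1))
    denom = m * theta * lam_j * lam_k
    raw = _trialwise_correlate(x_j, x_k, n_lags) / denom

    corrected = None
    if jitter_correct_flag:
        jb = int(round(params.jitter_ms / params.bin_ms))
        if jb < 1:
            raise ValueError("jitter window smaller than the CCG bin")
        xbar_j = _window_means(x_j, jb)
        xbar_k = _window_means(x_k, jb)
        jitt = 0.5 * (
            _trialwise_correlate(x_j, xbar_k, n_lags)
            + _trialwise_correlate(xbar_j, x_k, n_lags)
        ) / denom
        corrected = raw - jitt

    return CCGResult(
        pair=(-1, -1),
        lags_ms=params.lags_ms,
        raw=raw,
        corrected=corrected,
        M=m,
        lambda_j=float(lam_j),
        lambda_k=float(lam_k),
        params=params,
    )


def ccg_from_spikes(
    spikes_j: np.ndarray,
    spikes_k: np.ndarray,
    onsets_s: np.ndarray,
    params: CCGParams = CCGParams(),
    **kw,
) -> CCGResult:
    return compute_ccg(
        bin_trials(spikes_j, onsets_s, params),
        bin_trials(spikes_k, onsets_s, params),
        params,
        **kw,
    )


@dataclass
class PairClassification:
    kind: str  # 'excitatory' | 'inhibitory' | 'ns'
    extremum_lag_ms: float
    extremum_z: float
    noise_mean: float
    noise_sd: float
    degenerate: bool = False


def classify_pair(
    ccg: CCGResult,
    *,
    exc_z: float = EXC_Z,
    inh_z: float = INH_Z,
    peak_window_ms: float = PEAK_WINDOW_MS,
    noise_band_ms: tuple[float, float] = NOISE_BAND_MS,
) -> PairClassification:
    """7 SD / 5 SD significance rules against the 50-100 ms noise band.

    Noise statistics pool both lag signs of the corrected CCG.  The pair
    is excitatory when the peak within +/-10 ms exceeds noise mean +
    7 SD, inhibitory when the trough falls below noise mean - 5 SD.
    """
    y = ccg.corrected if ccg.corrected is not None else ccg.raw
    lags = ccg.lags_ms
    band = (np.abs(lags) >= noise_band_ms[0]) & (np.abs(lags) <= noise_band_ms[1])
    if not band.any():
        raise ValueError("CCG lags do not cover the noise band")
    mu = float(y[band].mean())
    sd = float(y[band].std(ddof=1))
    if sd == 0:
        return PairClassification("ns", np.nan, np.nan, mu, sd, degenerate=True)
    center = np.abs(lags) <= peak_window_ms
    yc = y[center]
    lc = lags[center]
    i_max = int(np.argmax(yc))
    i_min = int(np.argmin(yc))
    z_max = (yc[i_max] - mu) / sd
    z_min = (yc[i_min] - mu) / sd
    if z_max > exc_z:
        return PairClassification("excitatory", float(lc[i_max]), float(z_max), mu, sd)
    if z_min < -inh_z:
        return PairClassification("inhibitory", float(lc[i_min]), float(z_min), mu, sd)
    z_ext = z_max if abs(z_max) >= abs(z_min) else z_min
    lag_ext = lc[i_max] if abs(z_max) >= abs(z_min) else lc[i_min]
    return PairClassification("ns", float(lag_ext), float(z_ext), mu, sd)


def lead_lag_index(ccg: CCGResult, *, ca_window_ms: float = CA_WINDOW_MS) -> float:
    """Correlogram asymmetry: (right - left) / (right + left).

    Sums rectified corrected CCG values over 0 < tau <= window (right,
    reference leading) and the mirror interval (left).  +1 means the
    reference fully leads the target.
    """
    y = ccg.corrected if ccg.corrected is not None else ccg.raw
    lags = ccg.lags_ms
    r = np.clip(y[(lags > 0) & (lags <= ca_window_ms)], 0.0, None).sum()
    l = np.clip(y[(lags < 0) & (lags >= -ca_window_ms)], 0.0, None).sum()
    if r + l == 0:
        raise ValueError("CA undefined: no positive CCG mass in the window")
    return float((r - l) / (r + l))


@dataclass
class ClusterPairSummary:
    clusters: list
    median_CA: pd.DataFrame  # ref cluster x target cluster
    signed_rank_p: pd.DataFrame
    n_pairs: pd.DataFrame
    directed_edges: list  # dicts: source, target, median_CA, p, weight_class


def cluster_pair_graph(
    pair_rows: pd.DataFrame,
    *,
    alpha_thin: float = 0.01,
    alpha_bold: float = 0.001,
) -> ClusterPairSummary:
    """Cluster-pair lead-lag summary over significant excitatory pairs.

    ``pair_rows`` needs columns ref_cluster, target_cluster, CA, kind.
    Median CA and a two-sided Wilcoxon signed-rank test against 0 are
    computed per unordered cluster pair (both orderings are filled in
    antisymmetrically); a directed edge is emitted from the leading side
    when p < alpha_thin, weight class 'bold' when p < alpha_bold.
    """
    exc = pair_rows[pair_rows["kind"] == "excitatory"]
    clusters = sorted(
        set(pair_rows["ref_cluster"]).union(pair_rows["target_cluster"])
    )
    median = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    pval = pd.DataFrame(np.nan, index=clusters, columns=clusters)
    npairs = pd.DataFrame(0, index=clusters, columns=clusters)
    edges = []
    for ia, a in enumerate(clusters):
        for b in clusters[ia:]:
            # canonical orientation a -> b; pool both recorded orderings
            fwd = exc[(exc["ref_cluster"] == a) & (exc["target_cluster"] == b)]["CA"]
            rev = exc[(exc["ref_cluster"] == b) & (exc["target_cluster"] == a)]["CA"]
            cas = np.concatenate([fwd.to_numpy(float), -rev.to_numpy(float)])
            if a == b:
                cas = fwd.to_numpy(float)
            if cas.size == 0:
                continue
            med = float(np.median(cas))
            if np.allclose(cas, 0.0):
                p = 1.0
            else:
                p = float(wilcoxon(cas, alternative="two-sided").pvalue)
            median.loc[a, b] = med
            pval.loc[a, b] = p
            npairs.loc[a, b] = cas.size
            if a != b:
                median.loc[b, a] = -med
                pval.loc[b, a] = p
                npairs.loc[b, a] = cas.size
                if p < alpha_thin and med != 0:
                    src, dst = (a, b) if med > 0 else (b, a)
                    edges.append(
                        dict(
                            source=src,
                            target=dst,
                            median_CA=abs(med),
                            p=p,
                            n=int(cas.size),
                            weight_class="bold" if p < alpha_bold else "thin",
                        )
                    )
    return ClusterPairSummary(clusters, median, pval, npairs, edges)
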