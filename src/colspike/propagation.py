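"""Multichannel waveform landmarks, propagation velocities, asymmetry index.

Only the linear column of channels containing the soma site is analysed;
channel offsets are signed, positive toward the pia.  "Velocity" below is
an inverse velocity (slope of trough time against distance, ms/mm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .core import WaveformTemplate

N_BOOTSTRAP = 500
SQRT2 = float(np.sqrt(2.0))


@dataclass
class Landmarks:
    channel_offsets_um: np.ndarray  # signed, positive toward pia
    trough_times_ms: np.ndarray  # relative to soma trough; NaN where undefined
    peak_times_ms: np.ndarray
    soma_channel: int


def extract_landmarks(template: WaveformTemplate, *, flat_tol: float = 1e-12) -> Landmarks:
    """Per-channel trough and (post-trough) peak times.

    Times are referenced to the soma-channel trough, so the soma trough
    time is 0 by definition.  Channels with no defined trough (flat
    signal) get NaN landmarks.
    """
    v = template.voltages
    dt_ms = 1e3 / template.sampling_rate_hz
    soma = template.soma_channel
    trough = np.full(template.n_channels, np.nan)
    peak = np.full(template.n_channels, np.nan)
    for c in range(template.n_channels):
        w = v[:, c]
        if np.ptp(w) <= flat_tol:
            continue
        i_tr = int(np.argmin(w))
        trough[c] = i_tr * dt_ms
        after = w[i_tr:]
        if after.size > 1:
            peak[c] = (i_tr + int(np.argmax(after))) * dt_ms
    t0 = trough[soma]
    return Landmarks(template.channel_offsets_um(), trough - t0, peak - t0, soma)


def trim_outlier_troughs(
    trough_matrix: np.ndarray, *, central_fraction: float = 0.95
) -> np.ndarray:
    """Mask (as NaN) trough times outside the central 95% per channel.

    ``trough_matrix`` is (units x channels) within one cluster; the trim
    runs across units independently at each channel, excluding outlier
    channels from downstream regressions.
    """
    x = np.array(trough_matrix, float)
    tail = (1.0 - central_fraction) / 2.0 * 100.0
    for c in range(x.shape[1]):
        col = x[:, c]
        ok = ~np.isnan(col)
        if ok.sum() < 3:
            continue
        lo, hi = np.percentile(col[ok], [tail, 100.0 - tail])
        col[(col < lo) | (col > hi)] = np.nan
    return x


@dataclass
class PropagationProfile:
    v_inv_above: Optional[float]  # ms/mm, offsets toward pia
    v_inv_below: Optional[float]
    si_signed: Optional[float]
    si_unsigned: Optional[float]


def _ols_slope(x: np.ndarray, y: np.ndarray) -> float:
    """Closed-form OLS slope (covariance over variance)."""
    xm, ym = x.mean(), y.mean()
    return float(((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum())


def propagation_velocity(
    trough_times_ms: np.ndarray, channel_offsets_um: np.ndarray
) -> tuple[Optional[float], Optional[float]]:
    """Separate OLS slopes of trough time vs offset above and below the soma.

    Offsets are converted to mm.  A side with fewer than 2 usable
    channels yields None for that slope.
    """
    t = np.asarray(trough_times_ms, float)
    o = np.asarray(channel_offsets_um, float) / 1000.0
    ok = ~np.isnan(t)
    slopes = []
    for side in (o > 0, o < 0):
        m = side & ok
        if m.sum() < 2 or np.ptp(o[m]) == 0:
            slopes.append(None)
        else:
            slopes.append(_ols_slope(o[m], t[m]))
    return slopes[0], slopes[1]


def asymmetry_index(v_inv_below: float, v_inv_above: float) -> tuple[float, float]:
    """Signed and unsigned orthogonal distance from the y = -x diagonal.

    si_signed = (x0 + y0) / sqrt(2) with (x0, y0) = (below, above);
    zero for perfectly symmetric bidirectional propagation.
    """
    si = (v_inv_below + v_inv_above) / SQRT2
    return float(si), float(abs(si))


def unit_propagation(template: WaveformTemplate) -> PropagationProfile:
    lm = extract_landmarks(template)
    above, below = propagation_velocity(lm.trough_times_ms, lm.channel_offsets_um)
    if above is None or below is None:
        return PropagationProfile(above, below, None, None)
    si_s, si_u = asymmetry_index(below, above)
    return PropagationProfile(above, below, si_s, si_u)


@dataclass
class BootstrapComparison:
    clusters: list
    mean: dict  # cluster -> mean slope
    sd: dict  # cluster -> bootstrap SD of the cluster mean
    pairwise_significant: np.ndarray  # symmetric 0/1, 99% CI
    below_slope_nonzero: dict  # cluster -> 0/1, 95% CI
    n_resamples: int
    seed: int


def bootstrap_compare(
    slopes_by_cluster: dict,
    *,
    n_resamples: int = N_BOOTSTRAP,
    seed: int = 0,
    pairwise_ci: float = 99.0,
    zero_ci: float = 95.0,
) -> BootstrapComparison:
    """Bootstrap comparison of per-cluster mean slopes.

    Units are resampled with replacement within each cluster; pairwise
    differences are significant when the ``pairwise_ci``% CI of the
    difference of resampled means excludes 0, and a cluster's slope is
    non-zero when its ``zero_ci``% CI excludes 0.
    """
    clusters = sorted(slopes_by_cluster)
    rng = np.random.default_rng(seed)
    boots = {}
    for c in clusters:
        v = np.asarray(slopes_by_cluster[c], float)
        v = v[~np.isnan(v)]
        if v.size < 3:
            raise ValueError(f"cluster {c} has fewer than 3 units")
        idx = rng.integers(0, v.size, size=(n_resamples, v.size))
        boots[c] = v[idx].mean(axis=1)
    mean = {c: float(np.asarray(slopes_by_cluster[c], float).mean()) for c in clusters}
    sd = {c: float(boots[c].std(ddof=1)) for c in clusters}

    k = len(clusters)
    pair = np.zeros((k, k), dtype=int)
    tail = (100.0 - pairwise_ci) / 2.0
    for i in range(k):
        for j in range(i + 1, k):
            diff = boots[clusters[i]] - boots[clusters[j]]
            lo, hi = np.percentile(diff, [tail, 100.0 - tail])
            if lo > 0 or hi < 0:
                pair[i, j] = pair[j, i] = 1
    ztail = (100.0 - zero_ci) / 2.0
    nonzero = {}
    for c in clusters:
        lo, hi = np.percentile(boots[c], [ztail, 100.0 - ztail])
        nonzero[c] = int(lo > 0 or hi < 0)
    return BootstrapComparison(clusters, mean, sd, pair, nonzero, n_resamples, seed)
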