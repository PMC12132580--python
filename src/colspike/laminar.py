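"""Laminar structure: CSD boundary estimation, depth scaling, layer tests."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.stats import chi2 as chi2_dist

from .core import LAYER_NAMES, LayerBoundaries

CSD_SMOOTH_SIGMA_UM = 120.0

# standard five-point second-difference stencil, truncated at the edges
_STENCIL = np.array([-1.0, 16.0, -30.0, 16.0, -1.0]) / 12.0


@dataclass
class CSDResult:
    csd: np.ndarray  # (interior channels x time)
    channel_depths_um: np.ndarray  # depths of the interior channels
    sigma_um: float
    reversal_depth_um: float
    sink_extremum_depth_um: float


def compute_csd(
    lfp: np.ndarray,
    channel_depths_um: np.ndarray,
    *,
    sigma_um: float = CSD_SMOOTH_SIGMA_UM,
    response_window: slice | None = None,
) -> CSDResult:
    """Five-point CSD along the probe with Gaussian spatial smoothing.

    ``lfp`` is (channels x time), assumed to be a stimulus-triggered
    average; channels must be uniformly spaced in depth.  The CSD is
    ``-d2V/dz2`` evaluated with the (-1, 16, -30, 16, -1)/12h^2 stencil
    (outermost two channels dropped), then smoothed across space with a
    Gaussian of ``sigma_um``.  The sink/source reversal is the lower
    (deeper) zero crossing of the dominant sink, located by linear
    interpolation on the time-averaged CSD profile.
    """
    lfp = np.asarray(lfp, float)
    z = np.asarray(channel_depths_um, float)
    if lfp.ndim != 2 or lfp.shape[0] != z.size:
        raise ValueError("lfp must be (channels x time) matching channel depths")
    if z.size < 5:
        raise ValueError("five-point formula needs at least 5 channels")
    dz = np.diff(z)
    h = float(dz.mean())
    if not np.allclose(dz, h, rtol=1e-6):
        raise ValueError("channels must be uniformly spaced")

    n_int = z.size - 4
    csd = np.zeros((n_int, lfp.shape[1]))
    for k, c in enumerate(_STENCIL):
        csd += c * lfp[k : k + n_int]
    csd = -csd / h**2
    csd = gaussian_filter1d(csd, sigma=sigma_um / abs(h), axis=0, mode="nearest")
    z_int = z[2:-2]

    profile = csd[:, response_window].mean(axis=1) if response_window else csd.mean(axis=1)
    reversal, extremum = _sink_reversal(profile, z_int)
    return CSDResult(csd, z_int, sigma_um, reversal, extremum)


def _sink_reversal(profile: np.ndarray, depths: np.ndarray) -> tuple[float, float]:
    """Lower edge of the dominant (largest-|integral|) negative region."""
    neg = profile < 0
    if not neg.any():
        return float("nan"), float("nan")
    # connected negative runs
    edges_idx = np.flatnonzero(np.diff(neg.astype(int)))
    starts = [0] if neg[0] else []
    starts += [i + 1 for i in edges_idx if neg[i + 1]]
    stops = [i + 1 for i in edges_idx if neg[i]]
    if neg[-1]:
        stops.append(len(profile))
    best = max(zip(starts, stops), key=lambda ab: -profile[ab[0] : ab[1]].sum())
    a, b = best
    i_ext = a + int(np.argmin(profile[a:b]))
    # zero crossing below the extremum
    for i in range(i_ext, len(profile) - 1):
        if profile[i] < 0 <= profile[i + 1]:
            frac = -profile[i] / (profile[i + 1] - profile[i])
            return float(depths[i] + frac * (depths[i + 1] - depths[i])), float(depths[i_ext])
    return float(depths[b - 1]), float(depths[i_ext])


def scale_depths(
    depths_um: np.ndarray,
    session_boundaries: LayerBoundaries,
    reference_boundaries: LayerBoundaries,
) -> tuple[np.ndarray, list[str]]:
    """Map session depths piecewise-linearly onto reference boundaries.

    Each session layer interval is sent onto the corresponding reference
    interval; inverted (calcarine) sessions are flipped first.  Returns
    scaled depths and reference layer labels.
    """
    d = np.asarray(depths_um, float)
    sess = session_boundaries
    if sess.inverted:
        d = -d
        sess = sess.upright()
    ref = reference_boundaries.upright()
    se = np.asarray(sess.edges_um, float)
    re = np.asarray(ref.edges_um, float)
    lo, hi = sess.span_um
    if np.any(d < lo - 1e-9) or np.any(d > hi + 1e-9):
        raise ValueError("depth outside session span")
    scaled = np.interp(d, se, re)
    layers = [ref.layer_of(s) for s in scaled]
    return scaled, layers


@dataclass(frozen=True)
class LayerTestResult:
    observed_counts: tuple[float, ...]
    expected_counts: tuple[float, ...]
    chi2: float
    df: int
    p: float


def layer_chi_square(observed_counts: Sequence[float]) -> LayerTestResult:
    """Pearson goodness-of-fit of layer-group counts against uniformity."""
    obs = np.asarray(observed_counts, float)
    if obs.size < 2:
        raise ValueError("need at least 2 groups")
    total = obs.sum()
    if total <= 0:
        raise ValueError("total count must be > 0")
    expected = np.full(obs.size, total / obs.size)
    if np.any(expected == 0):
        raise ValueError("zero expected count")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(chi2_dist.sf(stat, df))
    return LayerTestResult(tuple(obs), tuple(expected), stat, df, p)


def layer_group_counts(layers: Sequence[str]) -> dict:
    """Counts in the three cortical groupings used for the layer test."""
    groups = {"4A/B+4C": 0, "2/3": 0, "5/6": 0}
    for l in layers:
        if l in ("4A/B", "4C"):
            groups["4A/B+4C"] += 1
        elif l in groups:
            groups[l] += 1
    return groups
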