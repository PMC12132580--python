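"""Unit curation and single-channel waveform features.

Polarity splitting, extremum alignment/normalisation, classical
trough-to-peak features and SNR-based curation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.signal import argrelextrema

from .core import DEFAULT_SCALE_TO_UV, UnitRecord

SNR_LO = 0.0
SNR_HI = 3.7
TRIPHASIC_THRESHOLD = 0.3


@dataclass(frozen=True)
class WaveformFeatures:
    ttp_width_ms: float
    repolarization_ms: float
    amplitude_uV: float


def classify_polarity(
    soma_waveform: np.ndarray, *, triphasic_threshold: float = TRIPHASIC_THRESHOLD
) -> tuple[str, bool]:
    """Split units by spike polarity and flag tri-phasic shapes.

    A unit is positive-spiking when its global maximum precedes the
    global minimum.  It is tri-phasic when local maxima on both sides of
    the trough each reach ``triphasic_threshold`` times the trough
    magnitude; tri-phasic units are labelled negative.
    """
    w = np.asarray(soma_waveform, float)
    if w.size < 3 or np.allclose(w, w[0]):
        raise ValueError("polarity undefined for a constant waveform")
    i_min = int(np.argmin(w))
    i_max = int(np.argmax(w))
    trough_mag = abs(w[i_min])

    peaks = argrelextrema(w, np.greater_equal, order=2)[0]
    peaks = peaks[(w[peaks] > 0) & (peaks != i_min)]
    before = peaks[peaks < i_min]
    after = peaks[peaks > i_min]
    triphasic = (
        trough_mag > 0
        and before.size > 0
        and after.size > 0
        and w[before].max() >= triphasic_threshold * trough_mag
        and w[after].max() >= triphasic_threshold * trough_mag
    )
    if triphasic:
        return "negative", True
    return ("positive", False) if i_max < i_min else ("negative", False)


def align_normalize(
    soma_waveform: np.ndarray, polarity: str, triphasic: bool = False
) -> np.ndarray:
    """Shift the defining extremum to the window centre and scale to +/-1.

    Negative (and tri-phasic) units align to the trough, positive units
    to the peak.  The shift repeats edge samples rather than wrapping, so
    no spurious discontinuities enter the normalised shape.  Idempotent
    and invariant to positive rescaling of the input.
    """
    w = np.asarray(soma_waveform, float)
    peak = float(np.abs(w).max())
    if peak == 0:
        raise ValueError("cannot normalise an all-zero waveform")
    idx = int(np.argmin(w)) if (polarity == "negative" or triphasic) else int(np.argmax(w))
    shift = w.size // 2 - idx
    out = np.empty_like(w)
    if shift > 0:
        out[shift:] = w[:-shift]
        out[:shift] = w[0]
    elif shift < 0:
        out[:shift] = w[-shift:]
        out[shift:] = w[-1]
    else:
        out[:] = w
    return out / peak


def classical_features(
    soma_waveform: np.ndarray,
    sampling_rate_hz: float,
    *,
    polarity: str = "negative",
    scale_to_uV: float = DEFAULT_SCALE_TO_UV,
) -> WaveformFeatures:
    """Trough-to-peak width, repolarization time and amplitude.

    Width is the time from the trough to the subsequent peak;
    repolarization is the time from that peak to the first crossing of
    half the peak value (linear interpolation between samples);
    amplitude is the trough-to-peak voltage difference scaled to
    microvolts.  Positive units are mirrored before measurement.
    """
    w = np.asarray(soma_waveform, float)
    if polarity == "positive":
        w = -w  # the peak-to-trough course becomes trough-to-peak
    i_tr = int(np.argmin(w))
    after = w[i_tr:]
    if after.size < 2:
        raise ValueError("no samples after trough")
    i_pk = i_tr + int(np.argmax(after))
    if i_pk == i_tr:
        raise ValueError("no peak after trough within window")
    dt_ms = 1e3 / sampling_rate_hz
    ttp_ms = (i_pk - i_tr) * dt_ms

    peak_val = w[i_pk]
    half = peak_val / 2.0
    repol_ms = np.nan
    for i in range(i_pk + 1, w.size):
        if w[i] <= half:
            frac = (w[i - 1] - half) / (w[i - 1] - w[i]) if w[i - 1] != w[i] else 0.0
            repol_ms = (i - 1 + frac - i_pk) * dt_ms
            break

    amplitude = float((peak_val - w[i_tr]) * scale_to_uV)
    return WaveformFeatures(float(ttp_ms), float(repol_ms), amplitude)


def compute_snr(template_amplitude: float, residual_sd: float) -> float:
    """Template trough-to-peak amplitude over spike-to-spike residual SD."""
    if residual_sd <= 0:
        raise ValueError("residual_sd must be > 0")
    return float(template_amplitude / residual_sd)


def snr_filter(
    units: Sequence[UnitRecord], lo: float = SNR_LO, hi: float = SNR_HI
) -> list[UnitRecord]:
    """Retain units with lo < SNR <= hi, preserving order."""
    return [u for u in units if lo < u.snr <= hi]


def curate_units(
    units: Iterable[UnitRecord],
    *,
    snr_lo: float = SNR_LO,
    snr_hi: float = SNR_HI,
    triphasic_threshold: float = TRIPHASIC_THRESHOLD,
) -> tuple[list[UnitRecord], pd.DataFrame]:
    """Rule-based curation: SNR filter, polarity split, classical features.

    Returns the retained units (annotated in place) and a features table.
    """
    kept = snr_filter(list(units), snr_lo, snr_hi)
    rows = []
    for u in kept:
        pol, tri = classify_polarity(u.template.soma_waveform)
        u.polarity, u.triphasic = pol, tri
        feats = classical_features(
            u.template.soma_waveform,
            u.template.sampling_rate_hz,
            polarity=pol,
            scale_to_uV=u.template.scale_to_uV,
        )
        rows.append(
            dict(
                unit_id=u.unit_id,
                ttp_width_ms=feats.ttp_width_ms,
                repolarization_ms=feats.repolarization_ms,
                amplitude_uV=feats.amplitude_uV,
                snr=u.snr,
                polarity=pol,
                triphasic=tri,
            )
        )
    return kept, pd.DataFrame(rows)
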