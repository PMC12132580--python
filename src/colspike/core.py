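"""Shared domain types for the columnar spike-analysis pipeline.

Conventions used throughout the package:

* depths are in micrometres and increase from the pia downward;
* channel offsets are signed distances from the soma channel, positive
  toward the pia (i.e. toward shallower depths);
* spike times are seconds; waveform landmarks are milliseconds;
* template voltages are in acquisition units and converted to microvolts
  with ``scale_to_uV`` (default 2.3).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

LAYER_NAMES: tuple[str, ...] = ("2/3", "4A/B", "4C", "5/6", "WM")

#: index of the 4C-5/6 border in a boundary edge array
ANCHOR_EDGE_INDEX = 3

DEFAULT_SCALE_TO_UV = 2.3


@dataclass(frozen=True)
class StimulusSchedule:
    """Drifting-grating stimulus protocol.

    Directions cover the circle in degrees; each trial shows one
    (direction, spatial frequency, eye) condition for ``stimulus_s``
    seconds followed by ``interstim_s`` of blank screen.  The monitor
    lags the nominal onset by ``screen_delay_ms``.
    """

    directions_deg: tuple[float, ...] = tuple(float(d) for d in range(0, 360, 10))
    spatial_frequencies_cpd: tuple[float, ...] = (0.5, 1.0, 2.0, 4.0)
    eyes: tuple[str, ...] = ("both",)
    stimulus_s: float = 1.0
    interstim_s: float = 0.25
    repeats: int = 10
    screen_delay_ms: float = 67.0
    temporal_frequency_hz: float = 4.0

    def __post_init__(self) -> None:
        dirs = np.asarray(self.directions_deg, float)
        if dirs.size == 0 or np.any(dirs < 0) or np.any(dirs >= 360):
            raise ValueError("directions must lie in [0, 360)")
        if len(set(dirs.tolist())) != dirs.size:
            raise ValueError("duplicate stimulus directions")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")

    @property
    def trial_period_s(self) -> float:
        return self.stimulus_s + self.interstim_s

    @property
    def n_conditions(self) -> int:
        return (
            len(self.directions_deg)
            * len(self.spatial_frequencies_cpd)
            * len(self.eyes)
        )

    def trial_table(self, seed: Optional[int] = None) -> pd.DataFrame:
        """Build the trial table (one row per presentation).

        Condition order is shuffled within each repeat block when a seed
        is given; otherwise trials run in a fixed raster order.  Onsets
        are laid out back to back starting at ``interstim_s``.
        """
        conds = [
            (d, sf, eye)
            for eye in self.eyes
            for sf in self.spatial_frequencies_cpd
            for d in self.directions_deg
        ]
        rows = []
        rng = np.random.default_rng(seed) if seed is not None else None
        for rep in range(self.repeats):
            order = np.arange(len(conds))
            if rng is not None:
                rng.shuffle(order)
            for j in order:
                d, sf, eye = conds[j]
                rows.append((d, sf, eye, rep))
        df = pd.DataFrame(rows, columns=["direction_deg", "sf_cpd", "eye", "repeat"])
        df.insert(0, "trial", np.arange(len(df)))
        df["onset_s"] = self.interstim_s + df["trial"].to_numpy() * self.trial_period_s
        return df


@dataclass
class WaveformTemplate:
    """Multichannel mean extracellular waveform of one unit.

    ``voltages`` has shape (n_samples, n_channels) in template units.
    ``channel_positions_um`` has shape (n_channels, 2) as (x, depth).
    """

    voltages: np.ndarray
    sampling_rate_hz: float
    channel_positions_um: np.ndarray
    scale_to_uV: float = DEFAULT_SCALE_TO_UV

    def __post_init__(self) -> None:
        self.voltages = np.asarray(self.voltages, float)
        self.channel_positions_um = np.asarray(self.channel_positions_um, float)
        if self.voltages.ndim != 2:
            raise ValueError("voltages must be (n_samples, n_channels)")
        if self.channel_positions_um.shape != (self.voltages.shape[1], 2):
            raise ValueError("channel_positions_um must be (n_channels, 2)")

    @property
    def n_samples(self) -> int:
        return self.voltages.shape[0]

    @property
    def n_channels(self) -> int:
        return self.voltages.shape[1]

    @property
    def soma_channel(self) -> int:
        """Channel with the largest trough-to-peak amplitude."""
        return int(np.argmax(np.ptp(self.voltages, axis=0)))

    @property
    def soma_waveform(self) -> np.ndarray:
        return self.voltages[:, self.soma_channel]

    @property
    def time_ms(self) -> np.ndarray:
        return np.arange(self.n_samples) / self.sampling_rate_hz * 1e3

    def channel_offsets_um(self) -> np.ndarray:
        """Signed channel offsets from the soma channel, positive toward pia."""
        depths = self.channel_positions_um[:, 1]
        return depths[self.soma_channel] - depths


@dataclass
class TrialSpikeTable:
    """Spike times aligned to stimulus onsets, one array per trial.

    ``trials`` carries trial, direction_deg, sf_cpd, eye, onset_s;
    ``spikes`` holds spike times in seconds relative to the nominal
    onset, restricted to ``window`` (default [-0.25, 1.25] s).
    """

    trials: pd.DataFrame
    spikes: list[np.ndarray]
    window: tuple[float, float] = (-0.25, 1.25)

    def __post_init__(self) -> None:
        if len(self.spikes) != len(self.trials):
            raise ValueError("one spike array per trial required")
        lo, hi = self.window
        for arr in self.spikes:
            a = np.asarray(arr, float)
            if a.size and (a.min() < lo - 1e-9 or a.max() > hi + 1e-9):
                raise ValueError("spike outside alignment window")

    def select(self, **conditions) -> "TrialSpikeTable":
        """Sub-table for trials matching all given column==value filters."""
        mask = np.ones(len(self.trials), bool)
        for col, val in conditions.items():
            mask &= self.trials[col].to_numpy() == val
        idx = np.flatnonzero(mask)
        return TrialSpikeTable(
            self.trials.iloc[idx].reset_index(drop=True),
            [self.spikes[i] for i in idx],
            self.window,
        )

    def __len__(self) -> int:
        return len(self.trials)


@dataclass
class UnitRecord:
    """One curated sorted unit."""

    unit_id: int
    template: WaveformTemplate
    spike_times_s: np.ndarray
    snr: float = np.nan
    depth_um: float = np.nan
    scaled_depth_um: float = np.nan
    layer: Optional[str] = None
    polarity: Optional[str] = None
    triphasic: bool = False
    cluster_label: Optional[int] = None
    group: Optional[str] = None
    session_id: str = "synthetic"

    def __post_init__(self) -> None:
        self.spike_times_s = np.asarray(self.spike_times_s, float)
        if self.spike_times_s.size > 1 and np.any(np.diff(self.spike_times_s) <= 0):
            raise ValueError(f"unit {self.unit_id}: spike times not strictly increasing")


@dataclass(frozen=True)
class LayerBoundaries:
    """Laminar compartment borders along the probe.

    ``edges_um`` are the 6 border depths delimiting the 5 compartments
    2/3 | 4A/B | 4C | 5/6 | WM, ordered from the 2/3 top to the WM
    bottom.  For inverted (calcarine) penetrations the edges decrease
    with index instead; ``inverted`` flags this.
    """

    edges_um: tuple[float, ...]
    inverted: bool = False

    def __post_init__(self) -> None:
        e = np.asarray(self.edges_um, float)
        if e.size != len(LAYER_NAMES) + 1:
            raise ValueError(f"expected {len(LAYER_NAMES) + 1} edges, got {e.size}")
        d = np.diff(e)
        if self.inverted:
            if not np.all(d < 0):
                raise ValueError("inverted boundaries must strictly decrease")
        elif not np.all(d > 0):
            raise ValueError("boundaries must strictly increase")

    @property
    def anchor_um(self) -> float:
        """Depth of the 4C-5/6 border."""
        return float(self.edges_um[ANCHOR_EDGE_INDEX])

    @property
    def span_um(self) -> tuple[float, float]:
        e = np.asarray(self.edges_um, float)
        return float(e.min()), float(e.max())

    def upright(self) -> "LayerBoundaries":
        """Return an equivalent non-inverted boundary set (depths negated)."""
        if not self.inverted:
            return self
        return LayerBoundaries(tuple(-e for e in self.edges_um), inverted=False)

    def layer_of(self, depth_um: float) -> str:
        """Compartment containing ``depth_um`` (upright boundaries only)."""
        if self.inverted:
            raise ValueError("call upright() before layer lookup")
        e = np.asarray(self.edges_um, float)
        if depth_um < e[0] or depth_um > e[-1]:
            raise ValueError(f"depth {depth_um} outside span {self.span_um}")
        idx = int(np.clip(np.searchsorted(e, depth_um, side="right") - 1, 0, len(LAYER_NAMES) - 1))
        return LAYER_NAMES[idx]


def mean_boundaries(sessions: Sequence[LayerBoundaries]) -> LayerBoundaries:
    """Reference boundaries: arithmetic mean of upright session borders."""
    if not sessions:
        raise ValueError("no sessions")
    stacked = np.stack([np.asarray(b.upright().edges_um, float) for b in sessions])
    return LayerBoundaries(tuple(stacked.mean(axis=0)))


DEFAULT_BOUNDARIES = LayerBoundaries((0.0, 500.0, 800.0, 1400.0, 1900.0, 2400.0))
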