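"""Kilosort-style directory reader/writer and ground-truth sidecar."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .core import StimulusSchedule, UnitRecord, WaveformTemplate
from .synthetic import GroundTruthCohort


def write_kilosort(out_dir: str | Path, cohort: GroundTruthCohort) -> Path:
    """Emit spike_times/spike_clusters/templates/channel_positions arrays,
    a trials CSV and a ground-truth JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fs = cohort.config.sampling_rate_hz

    all_times, all_clusters = [], []
    for u in cohort.units:
        samples = np.round(u.spike_times_s * fs).astype(np.int64)
        all_times.append(samples)
        all_clusters.append(np.full(samples.size, u.unit_id, dtype=np.int32))
    times = np.concatenate(all_times) if all_times else np.empty(0, np.int64)
    clusters = np.concatenate(all_clusters) if all_clusters else np.empty(0, np.int32)
    order = np.argsort(times, kind="stable")
    np.save(out / "spike_times.npy", times[order])
    np.save(out / "spike_clusters.npy", clusters[order])

    templates = np.stack([u.template.voltages for u in cohort.units])
    np.save(out / "templates.npy", templates)
    np.save(out / "channel_positions.npy", cohort.units[0].template.channel_positions_um)
    # per-unit channel geometry differs (templates are soma-centred), so keep all
    np.save(
        out / "template_channel_positions.npy",
        np.stack([u.template.channel_positions_um for u in cohort.units]),
    )

    cohort.trials.to_csv(out / "trials.csv", index=False)

    gt = {
        "seed": cohort.seed,
        "sampling_rate_hz": fs,
        "boundaries_um": list(cohort.boundaries.edges_um),
        "schedule": {
            "stimulus_s": cohort.schedule.stimulus_s,
            "interstim_s": cohort.schedule.interstim_s,
            "repeats": cohort.schedule.repeats,
            "screen_delay_ms": cohort.schedule.screen_delay_ms,
            "temporal_frequency_hz": cohort.schedule.temporal_frequency_hz,
        },
        "units": [
            {
                "unit_id": u.unit_id,
                "archetype": cohort.archetype_of[u.unit_id].name,
                "layer": u.layer,
                "depth_um": u.depth_um,
                "snr": u.snr,
            }
            for u in cohort.units
        ],
        "edges": [
            {
                "source_unit": e.source_unit,
                "target_unit": e.target_unit,
                "lag_ms": e.lag_ms,
                "efficacy": e.efficacy,
                "sign": e.sign,
            }
            for e in cohort.edges
        ],
    }
    (out / "ground_truth.json").write_text(json.dumps(gt, indent=1))
    return out


def read_kilosort(in_dir: str | Path) -> tuple[list[UnitRecord], pd.DataFrame, dict]:
    """Load units, the trials table and the ground-truth sidecar (if any)."""
    src = Path(in_dir)
    times = np.load(src / "spike_times.npy")
    clusters = np.load(src / "spike_clusters.npy")
    templates = np.load(src / "templates.npy")
    positions = np.load(src / "template_channel_positions.npy")
    gt = {}
    gt_path = src / "ground_truth.json"
    if gt_path.exists():
        gt = json.loads(gt_path.read_text())
    fs = float(gt.get("sampling_rate_hz", 30000.0))

    units = []
    meta = {u["unit_id"]: u for u in gt.get("units", [])}
    for i, uid in enumerate(np.unique(clusters)):
        spk = np.sort(times[clusters == uid]).astype(float) / fs
        spk = np.unique(spk)
        tmpl = WaveformTemplate(templates[i], fs, positions[i])
        info = meta.get(int(uid), {})
        units.append(
            UnitRecord(
                unit_id=int(uid),
                template=tmpl,
                spike_times_s=spk,
                snr=float(info.get("snr", np.nan)),
                depth_um=float(info.get("depth_um", np.nan)),
                layer=info.get("layer"),
            )
        )
    trials = pd.read_csv(src / "trials.csv")
    return units, trials, gt
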