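"""Configuration-driven orchestration of all analysis stages."""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import ccg as ccg_mod
from . import io as io_mod
from .clustering import WaveMapParams, build_wavemap, canonicalize_labels, separability_cv
from .core import DEFAULT_BOUNDARIES, LayerBoundaries, StimulusSchedule
from .isi import isi_histogram, isi_pca, bursting_index, shuffle_test
from .laminar import layer_chi_square, layer_group_counts, scale_depths
from .propagation import bootstrap_compare, unit_propagation
from .synthetic import default_cohort_config, make_cohort, synth_spikes
from .tuning import tuning_summary, tuning_table
from .waveform import align_normalize, curate_units

log = logging.getLogger("colspike")

STAGES = ("curate", "cluster", "laminar", "tuning", "isi", "propagation", "ccg")


@dataclass
class PipelineConfig:
    """All pipeline tunables; defaults follow the published analysis values
    (WaveMAP 20/0.2/1.0, 0.4 ms ISI bins, 13 ms PSTH kernel, 67 ms screen
    delay, 25 ms jitter, 7/5 SD CCG rules, 500 shuffles/resamples, 120 um
    CSD smoothing, amplitude scale 2.3)."""

    seed: int = 0
    out_dir: str = "colspike_run"
    input_dir: Optional[str] = None  # Kilosort-style directory; None -> synthetic
    stages: tuple[str, ...] = STAGES
    # synthetic cohort
    n_per_class: int = 10
    repeats: int = 5
    include_positive: bool = True
    # curation
    snr_lo: float = 0.0
    snr_hi: float = 3.7
    # clustering
    n_neighbors: int = 20
    min_dist: float = 0.2
    resolution: float = 1.0
    # isi
    n_shuffles: int = 500
    # propagation
    n_resamples: int = 500
    # ccg
    ccg_max_units: int = 40
    ccg_max_pairs: int = 1000

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        bad = set(data) - known
        if bad:
            raise ValueError(f"unknown config keys: {sorted(bad)}")
        if "stages" in data:
            data["stages"] = tuple(data["stages"])
        return cls(**data)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(asdict(self), sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


@dataclass
class AnalysisReport:
    config: PipelineConfig
    tables: dict = field(default_factory=dict)
    summary: dict = field(default_factory=dict)

    def write(self, out_dir: Path) -> None:
        out_dir.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables.items():
            df.to_csv(out_dir / f"{name}.csv", index=False, float_format="%.10g")
        (out_dir / "summary.json").write_text(json.dumps(self.summary, indent=1, default=str))


def _validate(config: PipelineConfig) -> None:
    order = {s: i for i, s in enumerate(STAGES)}
    requested = [s for s in config.stages if s in order]
    unknown = [s for s in config.stages if s not in order]
    if unknown:
        raise ValueError(f"unknown stages: {unknown}")
    if config.input_dir is None and config.n_per_class < 1:
        raise ValueError("synthetic runs need n_per_class >= 1")
    needs_spikes = {"tuning", "isi", "ccg"}
    if needs_spikes & set(requested) and config.input_dir is not None:
        src = Path(config.input_dir)
        if not (src / "spike_times.npy").exists():
            raise ValueError(
                f"stage(s) {sorted(needs_spikes & set(requested))} require spike input; "
                f"missing {src / 'spike_times.npy'}"
            )


def run_pipeline(config: PipelineConfig) -> AnalysisReport:
    """Execute the requested stages in dependency order.

    Fixed seed implies byte-identical result tables.  Stage errors
    surface with the stage name attached.
    """
    _validate(config)
    logging.basicConfig(stream=sys.stderr, format="[%(name)s] %(message)s")
    report = AnalysisReport(config)
    report.summary["provenance"] = {
        "seed": config.seed,
        "config_sha": config.digest(),
        "stages": list(config.stages),
    }

    rng_root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0]) for name, s in
             zip(("cohort", "spikes", "cluster", "isi", "prop", "ccg"), rng_root.spawn(6))}

    if config.input_dir is not None:
        units, trials, gt = io_mod.read_kilosort(config.input_dir)
        schedule = StimulusSchedule(
            repeats=int(gt.get("schedule", {}).get("repeats", config.repeats))
        )
        boundaries = (
            LayerBoundaries(tuple(gt["boundaries_um"]))
            if "boundaries_um" in gt
            else DEFAULT_BOUNDARIES
        )
        # per-trial alignment rebuilt from the session trains + trials table
        from .core import TrialSpikeTable

        onsets = trials["onset_s"].to_numpy()
        lo, hi = -schedule.interstim_s, schedule.trial_period_s
        tables = {}
        for u in units:
            per_trial = []
            for on in onsets:
                a = np.searchsorted(u.spike_times_s, on + lo)
                b = np.searchsorted(u.spike_times_s, on + hi)
                per_trial.append(u.spike_times_s[a:b] - on)
            tables[u.unit_id] = TrialSpikeTable(trials.copy(), per_trial, window=(lo, hi))
    else:
        cohort_cfg = default_cohort_config(
            config.n_per_class,
            include_positive=config.include_positive,
            repeats=config.repeats,
        )
        cohort = make_cohort(cohort_cfg, seeds["cohort"])
        tables_by_unit, _counts = synth_spikes(cohort, seeds["spikes"])
        units = cohort.units
        trials = cohort.trials
        schedule = cohort.schedule
        boundaries = cohort.boundaries
        tables = tables_by_unit
        report.summary["cohort"] = {
            "n_units": len(units),
            "archetypes": sorted({a.name for a in cohort.archetype_of.values()}),
        }

    features = None
    if "curate" in config.stages:
        log.warning("curate: %d units in", len(units))
        units, features = curate_units(units, snr_lo=config.snr_lo, snr_hi=config.snr_hi)
        report.tables["features"] = features
        report.summary["curate"] = {
            "n_retained": len(units),
            "n_positive": int(sum(u.polarity == "positive" for u in units)),
        }

    labels_by_unit: dict[int, int] = {}
    if "cluster" in config.stages:
        if features is None:
            raise ValueError("stage 'cluster' requires stage 'curate'")
        neg = [u for u in units if u.polarity != "positive"]
        wf = np.stack(
            [align_normalize(u.template.soma_waveform, u.polarity, u.triphasic) for u in neg]
        )
        params = WaveMapParams(
            config.n_neighbors, config.min_dist, config.resolution, seeds["cluster"]
        )
        assignment = build_wavemap(wf, params)
        ttp = features.set_index("unit_id").loc[[u.unit_id for u in neg], "ttp_width_ms"]
        labels, _ = canonicalize_labels(assignment.labels, ttp.to_numpy())
        for u, l in zip(neg, labels):
            u.cluster_label = int(l)
            labels_by_unit[u.unit_id] = int(l)
        report.tables["clusters"] = pd.DataFrame(
            dict(
                unit_id=[u.unit_id for u in neg],
                label=labels,
                u1=assignment.embedding_2d[:, 0],
                u2=assignment.embedding_2d[:, 1],
            )
        )
        report.summary["cluster"] = {
            "n_clusters": int(np.unique(labels).size),
            "modularity": assignment.modularity,
        }

    if "laminar" in config.stages:
        scaled, layers = scale_depths(
            np.array([u.depth_um + boundaries.upright().anchor_um for u in units]),
            boundaries,
            boundaries,
        )
        for u, s, l in zip(units, scaled, layers):
            u.scaled_depth_um, u.layer = float(s), l
        narrow = [
            u.layer
            for u in units
            if u.cluster_label is not None and u.polarity == "negative"
        ] or [u.layer for u in units]
        counts = layer_group_counts(narrow)
        test = layer_chi_square(list(counts.values())) if sum(counts.values()) else None
        report.tables["depths"] = pd.DataFrame(
            dict(
                unit_id=[u.unit_id for u in units],
                scaled_depth_um=scaled,
                layer=layers,
            )
        )
        report.summary["laminar"] = {
            "group_counts": counts,
            "chi2": None if test is None else test.chi2,
            "p": None if test is None else test.p,
        }

    tuning_results = None
    if "tuning" in config.stages:
        if tables is None:
            raise ValueError("stage 'tuning' requires per-trial spikes (synthetic input)")
        tuning_results = [
            tuning_summary(u.unit_id, tables[u.unit_id], schedule)
            for u in units
            if u.spike_times_s.size > 1
        ]
        report.tables["tuning"] = tuning_table(tuning_results)
        report.summary["tuning"] = {
            "n_responsive": int(sum(r.responsive for r in tuning_results))
        }

    if "isi" in config.stages:
        with_spikes = [u for u in units if u.spike_times_s.size >= 2]
        hists = np.stack([isi_histogram(u.spike_times_s).hist for u in with_spikes])
        model = isi_pca(hists)
        bi = bursting_index(model.loadings[:, 0], model.loadings[:, 2])
        isi_df = pd.DataFrame(
            dict(
                unit_id=[u.unit_id for u in with_spikes],
                l1=model.loadings[:, 0],
                l2=model.loadings[:, 1],
                l3=model.loadings[:, 2],
                bursting_index=bi,
            )
        )
        report.tables["bursting"] = isi_df
        clustered = [u.unit_id in labels_by_unit for u in with_spikes]
        if sum(clustered) >= 4:
            vals = bi[np.asarray(clustered)]
            labs = [labels_by_unit[u.unit_id] for u, c in zip(with_spikes, clustered) if c]
            if np.unique(labs).size >= 2:
                st = shuffle_test(
                    vals, labs, n_shuffles=config.n_shuffles, seed=seeds["isi"]
                )
                report.summary["isi_shuffle"] = {
                    "significant": {str(k): v for k, v in st.significant.items()}
                }

    if "propagation" in config.stages:
        rows = []
        for u in units:
            p = unit_propagation(u.template)
            rows.append(
                dict(
                    unit_id=u.unit_id,
                    v_inv_above=p.v_inv_above,
                    v_inv_below=p.v_inv_below,
                    si_signed=p.si_signed,
                    si_unsigned=p.si_unsigned,
                )
            )
        prop_df = pd.DataFrame(rows)
        report.tables["propagation"] = prop_df
        by_cluster = {}
        for u, row in zip(units, rows):
            if u.cluster_label is not None and row["v_inv_below"] is not None:
                by_cluster.setdefault(u.cluster_label, []).append(row["v_inv_below"])
        by_cluster = {k: v for k, v in by_cluster.items() if len(v) >= 3}
        if len(by_cluster) >= 2:
            bc = bootstrap_compare(
                by_cluster, n_resamples=config.n_resamples, seed=seeds["prop"]
            )
            report.summary["propagation"] = {
                "below_slope_nonzero": {str(k): v for k, v in bc.below_slope_nonzero.items()}
            }

    if "ccg" in config.stages:
        if tables is None and not units:
            raise ValueError("stage 'ccg' requires spike input")
        cand = [u for u in units if u.spike_times_s.size > 10][: config.ccg_max_units]
        params = ccg_mod.CCGParams()
        onsets = trials["onset_s"].to_numpy()
        rasters = {
            u.unit_id: ccg_mod.bin_trials(u.spike_times_s, onsets, params) for u in cand
        }
        rows = []
        n_done = 0
        for i, uj in enumerate(cand):
            for uk in cand[i + 1 :]:
                if n_done >= config.ccg_max_pairs:
                    break
                try:
                    res = ccg_mod.compute_ccg(
                        rasters[uj.unit_id], rasters[uk.unit_id], params
                    )
                except ValueError:
                    log.warning("ccg: skipping pair (%s, %s)", uj.unit_id, uk.unit_id)
                    continue
                n_done += 1
                for ref, tgt, r in (
                    (uj, uk, res),
                    (uk, uj, res.mirrored()),
                ):
                    cls = ccg_mod.classify_pair(r)
                    try:
                        ca = ccg_mod.lead_lag_index(r)
                    except ValueError:
                        ca = np.nan
                    rows.append(
                        dict(
                            ref=ref.unit_id,
                            target=tgt.unit_id,
                            ref_cluster=ref.cluster_label if ref.cluster_label is not None else -1,
                            target_cluster=tgt.cluster_label if tgt.cluster_label is not None else -1,
                            kind=cls.kind,
                            extremum_lag_ms=cls.extremum_lag_ms,
                            extremum_z=cls.extremum_z,
                            CA=ca,
                        )
                    )
        pair_df = pd.DataFrame(rows)
        report.tables["ccg_pairs"] = pair_df
        if len(pair_df):
            summary = ccg_mod.cluster_pair_graph(pair_df)
            report.summary["ccg"] = {
                "n_pairs": int(n_done),
                "n_excitatory": int((pair_df["kind"] == "excitatory").sum()) // 2,
                "edges": summary.directed_edges,
            }

    out = Path(config.out_dir)
    report.write(out)
    log.warning("wrote report to %s", out)
    return report
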