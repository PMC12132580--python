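# colspike

Structure–function analysis of columnar laminar (Neuropixels-style)
recordings: waveform-shape clustering into candidate cell classes and the
downstream laminar, tuning, bursting, multichannel-propagation and
cross-correlation analyses — exercised end to end on synthetic cohorts with
known ground truth.

## What is in the box

| module | role |
| --- | --- |
| `colspike.synthetic` | seeded ground-truth cohorts: parametric multichannel templates (9 negative archetypes + positive variant), laminar depth sampling, von Mises direction tuning with target DI/OI, Poisson/bursty spike trains, lagged pairwise coupling, current-sink LFP fixture |
| `colspike.waveform` | SNR curation (0 < SNR ≤ 3.7), polarity/tri-phasic splitting, trough alignment and ±1 normalisation, classical features (trough-to-peak width, repolarization time, amplitude × 2.3 µV scale) |
| `colspike.clustering` | UMAP fuzzy-graph + Louvain communities (n_neighbors 20, min_dist 0.2, resolution 1.0 defaults), resolution sweep with modularity maximisation, gradient-boosted 5-fold separability, partition merge maps |
| `colspike.laminar` | five-point CSD with 120 µm spatial smoothing and sink-reversal boundary anchor, piecewise-linear depth scaling onto reference boundaries, layer-distribution χ² test |
| `colspike.tuning` | PSTH (67 ms screen delay, 13 ms kernel), responsiveness, latency, DI/OI, F1/F0 modulation ratio and simple/complex split |
| `colspike.isi` | 0.4 ms ISI histograms (max-normalised), ISI-PCA with fixed sign conventions, bursting index (l1 − l3), 500-shuffle label-permutation tests |
| `colspike.propagation` | per-channel trough/peak landmarks over soma ±5 channels, 95% trough-time trimming, above/below-soma inverse velocities (OLS), asymmetry index vs the y = −x diagonal, 500-resample bootstrap comparisons |
| `colspike.ccg` | trial-based normalised CCGs (0.4–1 s window, 1 ms bins, ±100 ms lags), analytic 25 ms interval-jitter correction, 7 SD / 5 SD excitatory/inhibitory classification against the 50–100 ms noise band, lead-lag (CA) index, signed-rank cluster-pair graph |
| `colspike.pipeline` / `colspike.cli` | configuration-driven orchestration with per-stage subcommands |

## CLI

```bash
# full synthetic run (all stages), results under ./colspike_run
colspike run --seed 1

# from a YAML config (any PipelineConfig field)
colspike run --config my.yaml --out out_dir

# write a Kilosort-style directory + trials.csv + ground-truth sidecar
colspike simulate --seed 0 --out ks_dir --n-per-class 10 --repeats 5

# individual stages (prerequisites run automatically)
colspike curate --seed 1 --out out_dir
colspike ccg --seed 1 --out out_dir

# print the consolidated summary of a finished run
colspike report --out out_dir
```

Outputs are CSV tables (`features`, `clusters`, `depths`, `tuning`,
`bursting`, `propagation`, `ccg_pairs`) plus `summary.json` with provenance
(seed, config hash) and stage summaries.

## Conventions

Depths are µm increasing from the pia downward; channel offsets are signed,
positive toward the pia; inverse velocities are ms/mm; spike times are
seconds; CCGs are normalised so independent stationary trains sit at 1
(raw) / 0 (jitter-corrected). All generators and analyses are deterministic
for a fixed seed.
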