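# spikephen

Spike-train phenotyping of developing cerebellar neurons: rule-based
classification of detected events into simple spikes, complex spikes, and
doublets; six per-cell simple-spike firing statistics (including an
autocorrelogram-based rhythmicity index); and population-level analysis
(z-scored clusterogram, tSNE "pseudotimeline", group-mean PCA + hierarchical
linkage, one-way ANOVA + Tukey-Kramer). A synthetic-data module generates
fully reproducible spike trains with ground-truth event labels so every
stage is testable without real recordings.

## Layout

| module | contents |
|---|---|
| `spikephen.core` | domain types (`SpikeEventSeries`, `ISISequence`), validation, ISI computation, event/metadata/feature-table I/O |
| `spikephen.classify` | event classification (simple / complex / doublet), complex-spike-train detection, class frequencies |
| `spikephen.features` | frequency, frequency mode (2.5 Hz bins), CV, CV2, pause percent, autocorrelogram (5 ms bins, 1 s max lag) and rhythmicity index |
| `spikephen.population` | population matrix + z-scoring, cell clusterogram, tSNE embedding, group-mean PCA + linkage, ANOVA/Tukey-Kramer |
| `spikephen.synthetic` | regular / Poisson / gamma-renewal, burst-pause, and oscillatory generators; complex-spike/doublet injection; cohort presets |
| `spikephen.pipeline` / `spikephen.cli` | end-to-end driver, YAML config, provenance, `spikephen` console script |

## CLI

```bash
# simulate labeled cohorts (event/metadata/ground-truth text files)
spikephen simulate --preset young_control --preset old_control \
    --n-cells 15 --duration-s 120 --seed 1 --out data/

# per-cell event classification summary
spikephen classify --input-dir data/ --out classes.tsv

# per-cell feature table (optionally per-cell autocorrelograms)
spikephen features --input-dir data/ --out features.tsv --acg-dir acgs/

# clusterogram + tSNE + group linkage from a feature table
spikephen population --feature-table features.tsv --out-dir pop/ --seed 1

# everything end to end from a YAML config
spikephen pipeline --config config.yaml --out-dir run/ --seed 1
```

Classifier thresholds (`--doublet-window-ms 20`, `--doublet-ratio 0.9`,
`--cs-min-spikelets 3`, `--cs-train-max-gap-ms 100`) are exposed on the
relevant subcommands; every run writes a `provenance.json` with all
parameters, seeds, and input checksums.

## File formats

- **Event table** (`*.events.tsv`): UTF-8, tab- or comma-delimited
  (auto-detected), header `time_s  amplitude  spikelet_count`, one event per
  row, times in seconds.
- **Metadata** (`*.meta.yaml`): `cell_id`, `recording_duration_s`,
  `group_label`, `genotype`.
- **Feature table**: TSV with columns `cell_id, group_label, frequency_hz,
  frequency_mode_hz, cv, cv2, pause_percent, rhythmicity_index,
  cs_frequency_hz, doublet_frequency_hz, combined_cs_frequency_hz,
  heterogeneous_cs`.
- Dendrograms are written as Newick; embeddings and statistics as TSV.

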