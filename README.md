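# switchkin

Production-state analysis of a bistable genetic switch (the mutually
repressing CI/Cro pair of the λ switch), built as a tested, fully
synthetic-data-driven pipeline:

- **`switchkin.synthetic`** — generators for everything the pipeline
  consumes: calibrated hidden-Markov production-state paths, dual-channel
  per-frame production-count traces over dividing cell lineages
  (truncated-normal cell cycles, 71 ± 22 min), steady-state snapshot
  populations, an exact Gillespie simulator of promoter–operator occupancy
  (adiabatic vs non-adiabatic regimes), and rendered fluorescence spot
  frames with ground truth.
- **`switchkin.spot_quant`** — spot detection (local maxima + 2D Gaussian
  refinement), normalized axial centroid distance *d*, pole/mid channel
  classification at the d = 0.6 threshold, single-molecule intensity
  calibration, and intensity → molecule-count conversion (spot-wise and
  cloud subtraction).
- **`switchkin.traces`** — lineage-trace assembly (one lineage per colony),
  young-cell filtering with chain-break bookkeeping, steady-state ratio
  classification r = CI/(CI+Cro), population percentages, and mRNA
  co-expression summaries.
- **`switchkin.landscape`** — 2D production histograms, potential
  U = −ln P, node-preserving bicubic interpolation, basin/saddle detection
  with persistence and mass filters, and exact minimax-path barrier
  matrices (plus direct-path barriers).
- **`switchkin.hmm` / `switchkin.kinetics`** — K-state HMM with independent
  Poisson (optionally negative-binomial) count emissions per channel:
  scaled forward/backward, multi-trace Baum–Welch with restarts, BIC and
  histogram-match model selection, Viterbi decoding with censoring-aware
  segments, dwell-time statistics, and transition time constants τ_ij
  (decoded-path and transition-matrix estimators).
- **`switchkin.cli`** — `simulate` / `fit` / `landscape` / `report`
  subcommands with JSON run manifests.

## CLI

```bash
switchkin simulate --seed 1 --out runs/sim                 # 94 traces, TSV
switchkin fit --traces runs/sim --k-range 1:6 --criterion bic \
    --seed 1 --out runs/fit                                # model + kinetics
switchkin landscape --traces runs/sim --out runs/land      # U grid + basins
switchkin report runs/sim runs/fit                         # consolidated report
```

Trace files are TSV with columns `lineage_id, frame, time_min, cell_id,
cell_age, division_flag, cro_count, ci_count[, segment_id, true_state]`.
Models are flat key-value text files; images are single-plane TIFF with
TSV truth tables.

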