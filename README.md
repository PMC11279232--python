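# spotscreen

Analysis pipeline for high-throughput colony-array screening experiments:
time-lapse spot growth on 384-array agar plates, pairwise co-culture
("interaction") plates built by stacking a main source plate (MSP) on
replicate source plates (RSPs), and spot-on-lawn antifungal assays scored
as presence/absence inhibition halos.

The pipeline:

1. **plate_io** — parses IRIS-style tab-separated colony quantification
   tables (one file per plate and timepoint), halo score CSVs and layout
   bundles; models the 96→384 condensation (MSP), the four-quadrant
   replication (RSP), and the position-wise pairing of interaction plates.
2. **growth_fitting** — log2(size × opacity) biomass, QC (≥5 timepoints,
   first 20 used), least-squares fits of the three-parameter Gompertz
   curve `y(t) = A·exp(−exp(−k·(t − t_i)))`, per-parameter Wald screening
   (all three p < 0.05) and an automated residual screen.
3. **fitness** — integrated fitness (IF): area under the fitted curve over
   0–72 h; robust per-plate centering (Huber M-location, c = 1.345); MSD,
   the median across isolates of the replicate-IF standard deviation
   (border spots excluded).
4. **interaction_scoring** — ecological classes per pair instance
   (cooperation / competition / neutral via the ±2·MSD rule, comparing the
   pair with the individuals at the same position of the MSP and RSP),
   functional classes per target yeast (induction / suppression /
   neutral from halo flags), behavior profiles, antifungal spectrum
   classes, and cross-media stability matrices.
5. **stats_report** — G-test of independence, Fisher's exact test,
   half-up-rounded proportion summaries, Venn region counts and the
   summary tables of a screening campaign.
6. **synthetic_data** — a seeded generator for complete ground-truth
   experiments (layouts, per-timepoint quantification tables, halo scores)
   so the entire pipeline is testable offline.
7. **cli** — orchestration with a provenance manifest and attrition
   accounting.

## Command line

```sh
# generate a synthetic experiment bundle
spotscreen simulate --seed 1 --out bundle/

# run the full pipeline (io -> fit -> fitness -> scoring -> report)
spotscreen run --bundle bundle/ --out results/

# or both in one step, optionally overriding analysis settings
spotscreen run-all --seed 1 --out results/ --alpha 0.05 --t-max 72
```

`simulate` accepts a YAML config overriding any
`spotscreen.synthetic_data.SimulationConfig` field (isolate count, media,
imaging grid, noise, injected interaction structure, halo prevalence,
suppression/induction probabilities, dropout).  `run` writes `fits.csv`,
`fitness.csv`, `msd.json`, `interactions.csv`, `profiles.csv`,
`spectrum.csv`, a `report/` directory of summary tables and a
`manifest.json` recording versions, configuration and per-stage record
counts.  Exit codes: 0 ok, 2 validation error, 3 stage failure.

## Library use

```python
from spotscreen.synthetic_data import SimulationConfig, simulate_experiment
from spotscreen.cli import RunConfig, run_pipeline

experiment = simulate_experiment(SimulationConfig(seed=1, n_isolates=384))
bundle = experiment.write_bundle("bundle")
run_pipeline(RunConfig(bundle_dir=bundle, out_dir="results"))
```
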