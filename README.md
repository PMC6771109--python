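# atlas-smooth

Bayesian spatial smoothing of small-area cancer burden, packaged end to end:

- **Incidence**: Poisson model for observed vs expected counts (indirect age
  standardisation) with a Leroux conditional-autoregressive prior on the
  spatial field; the key output is the standardised incidence ratio (SIR).
- **Relative survival**: period-method excess-hazard model (Poisson cell
  deaths with an other-cause-mortality offset) with the same Leroux prior;
  the key output is the excess hazard ratio (EHR).
- **Uncertainty**: posterior medians, equal-tailed 60%/80% credible
  intervals, the difference in posterior probabilities
  (DPP = 2 |PP_high − 0.5|), and Geweke convergence flags at p < 0.01.
- **Evidence grading**: Tango's maximised excess events test run three
  times, graded strong / moderate / weak / none from the most conservative
  p-value.
- **Visual encodings**: log-linear diverging colour scale anchored at 1.5
  and its inverse (≈ 0.67), a DPP-driven transparency mask, V-plot and wave
  plot data, and regional distribution summaries.

The real registry inputs are restricted, so a first-class synthetic-data
module generates every input with known ground truth: a lattice geography
with islands, age-structured populations, Poisson counts from a known
Leroux field, and a period-method survival cohort with known excess
hazards. All samplers are Metropolis-within-Gibbs with exact conjugate or
Gibbs updates where available, vectorised over graph colour classes, with
burn-in-only step adaptation.

## Command line

Everything is reachable through one entry point:

```bash
atlas-smooth simulate --out runs/demo --rows 10 --cols 10 --islands 1 --seed 1
atlas-smooth build-graph --areas runs/demo/areas.csv --edges runs/demo/edges.csv --out runs/demo/adj.csv
atlas-smooth standardise --cases runs/demo/cases.csv --population runs/demo/population.csv --out runs/demo/inc.csv
atlas-smooth fit-incidence --data runs/demo/inc.csv --areas runs/demo/areas.csv \
    --edges runs/demo/edges.csv --out runs/demo/draws.csv \
    --burn-in 5000 --iterations 10000 --thin 10 --seed 1
atlas-smooth summarise --draws runs/demo/draws.csv --out runs/demo/estimates.csv
atlas-smooth cluster-test --estimates runs/demo/estimates.csv --expected runs/demo/inc.csv \
    --areas runs/demo/areas.csv --mc 999 --seeds 1,2,3 --out runs/demo/evidence.json
atlas-smooth encode --estimates runs/demo/estimates.csv --out-dir runs/demo/figures
```

or as a single pipeline with a YAML config (see `RunConfig`):

```bash
atlas-smooth run-all --out runs/full          # synthetic end-to-end run
atlas-smooth run-all --config my_run.yaml     # custom schedule/priors
```

`run-all` writes a `manifest.json` recording versions, seeds, per-stage
outputs and timings, acceptance rates, Geweke flag counts and the evidence
category. Reruns with the same seeds are byte-identical.

The default MCMC schedule is the production one (50,000 burn-in, 100,000
iterations, thin 10 → 10,000 retained draws). The survival
variance-hyperprior is a sensitivity hook: half-Normal on the variance
(default, scale 5), half-Normal on the standard deviation, or
inverse-gamma — see `VariancePrior` and the `--prior-family` option.

## Layout

```
src/atlas_smooth/
  synthetic_data.py      # lattice geography, Leroux fields, cohorts, fixtures
  spatial_structure.py   # adjacency (rook), island repair, exclusions
  standardisation.py     # expected counts, strata, period person-time
  mcmc.py                # schedule config, draws container, adaptation
  incidence_model.py     # Poisson-Leroux sampler, SIR draws
  survival_model.py      # excess-hazard sampler, EHR draws
  posterior_summaries.py # medians, CrIs, DPP, Geweke flags
  clustering_evidence.py # Tango's MEET, evidence categories
  visual_encoding.py     # colour scale, opacity, V/wave plots, summaries
  pipeline_cli.py        # stage orchestration + click CLI
```
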