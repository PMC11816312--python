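# bufferguts

Event-based toxicokinetic-toxicodynamic (TKTD) survival modelling for
above-ground terrestrial invertebrates.

Exposure of terrestrial arthropods is event-driven — topical application,
feeding windows, replenished food sources — rather than a constant ambient
concentration. This package provides:

* **Exposure handling** (`bufferguts.exposure`): discretization of exposure
  events into piecewise-constant profiles with a smallest time unit
  (default 1 h), the legacy bee-specific preprocessing mode (fixed
  first-order decline rates per route), two-parameter log-logistic
  dose-response fitting, and toxic-unit (TU) normalization `c -> c / LC50`.
* **Model variants** (`bufferguts.tktd`): the reduced survival models
  `RED_SD` / `RED_IT` (external concentration drives a scaled damage; death
  by stochastic hazard or individual tolerance) and the buffered variants
  `BUFFER_SD` / `BUFFER_IT`, which insert a buffer compartment — residue on
  the exoskeleton or in the gut — that fills instantly with the external
  concentration and drains first-order with the same dominant rate constant
  `kd` that drives damage accrual. Solved with fixed-step forward Euler
  (1/1000 of the exposure time, capped so short pulses stay on the grid).
* **Bayesian calibration** (`bufferguts.calibration`): multinomial
  death-interval likelihood, two-stage prior protocol (broad log-uniform
  preliminary fit on [1e-10, 1e3], widened into weakly informative
  log-normal priors), adaptive Metropolis sampling in log-parameter space
  with R-hat/ESS diagnostics, and posterior-predictive survivor-count
  intervals.
* **Performance metrics** (`bufferguts.metrics`): PPC, NRMSE and SPPE as
  used in EFSA-style model evaluation.
* **Synthetic studies** (`bufferguts.synthetic`): study designs emulating
  standard bee test layouts and survival datasets simulated from known
  parameters, for testing and parameter-recovery checks.

## CLI

```sh
# events -> piecewise-constant profile (1-h smallest time unit)
bufferguts discretize events.csv profile.csv

# simulate a synthetic study (5 levels x 3 replicates x 10 individuals)
bufferguts simulate --route acute_contact --params 0.5,0.02,0.2,2.0 \
    --model BUFFER_SD --seed 1 --out-prefix demo

# full pipeline: discretize -> TU scale -> calibrate -> predict -> score
bufferguts fit demo_survival.csv demo_events.csv --out-prefix fit \
    --preset test --unit-mode raw --seed 1

# re-predict from a saved fit, and score a predictions table
bufferguts predict fit_result data.csv events.csv --out pred.csv
bufferguts score fit_predictions.csv
```

File formats are plain delimited text; see `bufferguts/io.py`. Exit codes:
0 success, 2 validation error, 3 numerical failure or flagged calibration
diagnostics. The `--preset paper` MCMC settings (8 chains, 5000 tune/draw)
are the default; `--preset test` (4 chains, 1000/1000) is for quick runs.

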