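# einet

Probabilistic excitatory–inhibitory (E–I) balance in feedforward inhibitory
circuits: a leaky integrate-and-fire (LIF) simulator with alpha synapses,
plus analytic predictors for firing rates, firing probabilities and
gain-modulation regimes.

The central quantity is the survival probability of excitation,
`pnet = pE * (1 - pI)`: an excitatory input both occurs (with probability
`pE`) and escapes cancellation by coincident feedforward inhibition
(`1 - pI`). The effective inhibitory probability is a product of ratio
constants, `pI = pI_hat * kn * kq * kr * kEI`, folding the relative number,
strength, activity and synaptic reliability of the inhibitory population
into one factor. The package provides:

- **`einet.ei_core`** — the probability algebra: `pnet`, the effective-`pI`
  product (with eager validation that it stays a probability), mean
  steady-state synaptic currents, scaling modes (fixed `pI`, `pI` linear in
  `pE`, feedforward recruitment), and a divisive conductance correction.
- **`einet.lif_sim`** — an event-level simulator: forward-Euler LIF
  (dt = 0.01 ms), alpha-function unitary PSCs/PSGs (current or conductance
  mode), homogeneous/inhomogeneous Poisson barrages, interneuron pool
  recruitment with subsampled inhibitory barrages, trial loops and PSTHs.
  Units are ms / mV / pA / nS / pF / MΩ throughout.
- **`einet.rate_theory`** — analytic input–output theory for sustained
  stimuli: rheobase, the deterministic LIF f–I relation (oscillatory
  regime), a Poisson threshold-count rate for the fluctuation-dominated
  regime, and full I–O curve prediction (the combined rate is the larger of
  the two), including conductance-loaded membranes.
- **`einet.transient`** — the brief-stimulus regime: Gaussian arrival-time
  histograms, compound-PSP probability traces, rectified net drive, exact
  Binomial threshold-crossing probabilities, and first-spike/total firing
  probability via a hazard construction, next to a full Monte-Carlo
  simulator with explicit interneurons for validation.
- **`einet.experiments`** — protocol runners (sustained trials, I–O sweeps,
  Gaussian-tuned gain modulation, ramp–plateau–ramp temporal profiles with
  E/I lags), temporal-regime classification, deterministic fixtures, and
  CSV/JSON output plumbing.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the headline checks (effective-`pI`
product, ~250 µV unitary PSP, 0.0557 pC unitary charge, ~60 Hz sustained
control rate, and the property suite: binomial cancellation oracle,
fixed-`pI` slope, non-monotonicity boundary, transient predictor vs
Monte-Carlo, temporal-regime classification, threshold-aligned curve
collapse, conductance-correction accuracy). The full suite takes a few
minutes; the heavy items are Monte-Carlo comparisons.

## CLI

```sh
einet simulate-sustained --config cfg.yaml --trials 100 --seed 1 --out out/
einet io-curve   --config cfg.yaml --trials 50  --seed 1 --out out/
einet tuning     --config cfg.yaml --mode 2     --seed 1 --out out/
einet temporal   --config cfg.yaml --trials 500 --seed 1 --out out/
einet transient  --config cfg.yaml --trials 5000 --seed 1 --out out/
einet fixtures   --seed 1 --out fixtures/
```

Configs are YAML or JSON with optional `network`, `lif`, `scaling` and
`stimulus` sections; keys mirror the parameter symbols (`nE`, `nI`, `pE`,
`pE_to_R`, `rE`, `aE`, ...). Example:

```yaml
network: {nE: 250, nI: 50, pE: 0.5, pE_to_I: 0.8}
scaling: {mode: fixed_pI, pi_fixed: 0.3}
duration_ms: 500
```

Every run writes result CSVs plus a JSON sidecar holding the complete
parameter set and seed, so any run can be reproduced exactly. `--plot`
renders quick-look PNGs.

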