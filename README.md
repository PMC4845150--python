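# copulagc

Copula-based joint modeling and directional Granger causality for mixed
spike/LFP neural time series: a Gaussian-copula regression of one continuous
channel (LFP) and one binary channel (spikes binned at the LFP rate), with
likelihood fitting, AIC model-order selection, time-resolved directional
Granger causality (GC) with permutation tests and trial-bootstrap SEMs,
baseline normalization, condition contrasts, spike-artifact removal, and a
full generative simulator.

## Model

With order-`p` histories of the LFP `y` and the spike train `x`:

- continuous margin: `y_t ~ Normal(mu_t, sigma^2)`,
  `mu_t = c_y + Σ a_i y_{t-i} + Σ b_i x_{t-i}`
- binary margin (probit): `P(x_t = 1) = Phi(eta_t)`,
  `eta_t = c_x + Σ d_i x_{t-i} + Σ e_i y_{t-i}`
- same-bin dependence via a Gaussian copula with correlation `rho`
  (latent-threshold construction), giving the closed-form conditional
  `P(x_t = 1 | y_t) = Phi((eta_t + rho·z_t) / sqrt(1 - rho^2))` with
  `z_t = (y_t - mu_t)/sigma`.

This is one concrete, self-consistent instantiation of a copula regression
for mixed discrete/continuous neural data; published variants may differ in
detail (e.g. how contemporaneous dependence enters), and all quantitative
behavior documented here refers to this form. Directional GC is the
per-observation deviance between the full fit and a nested fit with the
tested direction's cross-history block removed (`b` for spike→LFP, `e` for
LFP→spike):

```
gc = 2 (loglik_full − loglik_reduced) / n_obs ≥ 0
```

Significance uses per-trial circular-shift permutations of the source
channel; SEMs use a seeded bootstrap over trials.

**Despiking.** The artifact-removal module is a deterministic least-squares
template regression (a deconvolved spike-triggered average, exact under
linear superposition). It deliberately **substitutes** for Bayesian
spike-removal algorithms from the literature, whose details are outside this
package's scope: the contamination control only requires that artifact
energy locked to spike times be removed. Note the caveat that any genuine
spike→LFP coupling acting at lags inside the removal window is removed with
the artifact — keep the window no longer than the physical spike waveform.

## CLI

```bash
copulagc simulate --config sim.json --out trials.tsv
copulagc preprocess --raw raw.txt --cutoff 250 --fs-out 1000 \
    --onsets onsets.txt --spikes spikes.tsv --pre -300 --post 800 --out trials.tsv
copulagc despike --trialset trials.tsv --window 2 --out clean.tsv
copulagc fit --trialset clean.tsv --order 4 --restriction full --out fit.txt
copulagc select-order --trialset clean.tsv --orders 1:8
copulagc gc --trialset clean.tsv --order 4 --direction spike_to_lfp \
    --window 100 --step 10 --nboot 200 --baseline=-300:0 --seed 1 --out gc.tsv
copulagc compare --a gc_weak.norm.tsv --b gc_strong.norm.tsv --eval 0:500
```

All stages write a `<out>.manifest.json` (arguments, seed, version, input
hashes) so a run is exactly reproducible. Trial data use a plain-text
delimited format (or `.npz`; MAT-files readable for legacy data) — see
`copulagc.io_preprocess` for the format definition. A simulator config is a
JSON/TOML file with `model` (keys `p, c_y, a, b, sigma, c_x, d, e, rho`),
`n_trials`, `n_bins`, and optional `fs`, `onset_bin`, `post_onset_model`,
`contamination {template, gain}`, `seed`, `condition`.

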