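# twostep

Simulation and analysis pipeline for a two-step sequential decision task
with stakes, deterministic state transitions, and four outcome framings
(protection, reward, direct reward, punishment). The package covers the
full loop needed to study hybrid model-based / model-free control
offline, with no data download:

- **`twostep.task`** — the task environment: stakes draws (x1 / x5),
  two first-stage states with complementary deterministic transitions to
  two second-stage creatures, payoff random walks (sigma = 2, mirror-fold
  reflection at 0 and 9), final-result arithmetic (e.g. 2 shields on a
  high-stakes 9-flame trial leave 45 − 10 = 35 flames), and exact-count
  25% / 25% disjoint probe schedules. Study presets: `study1`
  (120 trials / 20 practice), `study2` and `study3` (225 / 25).
- **`twostep.agent`** — the generative hybrid learner: SARSA(lambda)
  model-free values over the four first-stage stimuli, model-based
  planning through the transition map, omega-weighted mixture, sticky
  softmax policy (response-key perseveration), valence-aligned internal
  reward, and full-session simulation.
- **`twostep.likelihood`** — numba-compiled trial-wise choice
  log-likelihood (practice trials update the learner but are never
  scored; missed trials score zero and freeze state), profile surfaces,
  and the pointwise matrix needed for WAIC.
- **`twostep.hbayes`** — hierarchical Bayesian fitting of models
  M1–M4 (omega/alpha tied, split by stakes, by variant, or by both;
  lambda/pi/beta always shared), non-centered parameterization
  theta = mu + sigma·eps with standard-normal priors, sigmoid transforms
  (×20 for beta), an adaptive Metropolis-within-Gibbs sampler with
  interweaving moves, split-R-hat diagnostics, posterior means, and the
  per-subject omega-difference score.
- **`twostep.waic`** — WAIC (log-sum-exp lppd, sample-variance p_waic)
  and model ranking with delta tables.
- **`twostep.behavior`** — stay-probability coding (stay defined on
  creatures), the logistic mixed model whose outcome main effect indexes
  model-based control and whose outcome × same-state interaction indexes
  model-free control, corrected reward rate (earned / available), and
  the >20%-missed exclusion rule.
- **`twostep.bias`** — metacognitive (certainty) and predictive
  (outcome-estimate) bias slopes via linear mixed models with random
  slopes (per-subject OLS fallback), and bias-vs-parameter regressions.
- **`twostep.cohort`** — synthetic study generation: latent-scale
  moment matching so cohorts are exactly the population the hierarchical
  model assumes, presets calibrated to the three studies' reported group
  moments, counterbalanced variant order, and a configurable synthetic
  rating generator.
- **`twostep.cli` / `twostep.io`** — CSV dataset dialect, scenario
  files, run manifests, and the command-line surface.

## CLI

```sh
twostep simulate --scenario study1 --n-subjects 20 --seed 1 --out runs/cohort
twostep fit      --data runs/cohort --model M1 --model M3 --preset desk \
                 --seed 1 --out runs/fits
twostep analyze  --data runs/cohort --out runs/analysis
twostep recover  --scenario study1 --n-subjects 10 --model M3 \
                 --preset desk --seed 1 --out runs/recovery
```

`--preset paper` uses the full MCMC contract (4 chains × 4000 samples,
half warmup); `--preset desk` is the scaled-down configuration used in
tests (2 × 1000). Exit codes: 0 ok, 1 user error, 2 internal.

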