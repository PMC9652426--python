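# healthgym

Synthetic mixed-type clinical time series — generation and auditing.

Longitudinal intensive-care and HIV-therapy cohorts are hard to share:
they carry disclosure risk, and access agreements keep them out of most
methods work. `healthgym` implements a complete pipeline for producing and
vetting *synthetic* versions of such cohorts:

1. **Generation** — a sequence Wasserstein GAN whose recurrent generator
   maps latent Gaussian sequences to mixed-type patient trajectories
   (numeric labs, imbalanced categoricals, sparse binary measurement
   flags), trained with a gradient penalty and a correlation-alignment
   loss.
2. **Realisticness validation** — per-variable density comparisons, a
   hierarchical statistical battery (Kolmogorov–Smirnov, then t / F /
   ANOVA-style and three-sigma fallbacks), and static plus trend/cycle
   Kendall correlation structure.
3. **Disclosure audit** — copy-leakage distances and the
   synthetic-to-real attack risk over quasi-identifier equivalence
   classes, against a 9 % release threshold.
4. **Utility verification** — offline reinforcement-learning agents
   (PLS observation reduction, K-means states, batch-constrained
   Q-learning) trained on real vs synthetic data, compared through their
   action-frequency heatmaps.

Because the real sources are restricted, the package ships a
Gaussian-copula cohort **simulator** with known statistical structure
(analytic Kendall-tau oracles, tunable skew, class imbalance, AR(1)
persistence) plus three bundled schemas — acute hypotension (20 variables,
48 hourly steps), sepsis (44 variables, 20 four-hour windows) and HIV
therapy (13 variables, 60 monthly steps) — whose marginals follow the
published descriptive statistics.

## The model

The critic `D` and generator `G` minimise

```
L_D = E[D(G(z))] − E[D(x_real)] + λ_GP · E[(‖∇_x̂ D(x̂)‖₂ − 1)²]
L_G = −E[D(G(z))] + λ_corr · Σ_{i>j} | r_syn(i,j) − r_real(i,j) |
```

with `r` the Pearson correlation matrices over the encoded channels of the
synthetic and real batches. `λ_corr = 0` recovers the vanilla Wasserstein
generator loss exactly; the alignment term pushes the generator to mirror
the real cross-variable correlation structure. Gradients (including the
second-order gradients the penalty needs) come from the package's own
reverse-mode tensor engine, so there is no deep-learning framework
dependency.

Attack risk over quasi-identifier equivalence classes is

```
risk = (1/S) · Σ_s (1/F_s) · I_s
```

averaging, over the `S` synthetic patients, the reciprocal size `F_s` of
the real equivalence class matching patient `s`'s key (`I_s` indicates a
match exists).

## Worked example

```python
from healthgym import (HealthGymGAN, TrainingConfig, default_config,
                       hierarchical_validate, simulate_cohort,
                       synthetic_to_real_risk)
from healthgym.benchmark import scaled_cohort

real = scaled_cohort(seed=1)           # 200 patients x 8 steps x 6 variables
model = HealthGymGAN(real)
results = model.fit(TrainingConfig(total_steps=500, lambda_corr=10.0,
                                   critic_steps_per_generator_step=2,
                                   seed=1))
print(results.summary())
syn = results.sample(200, seed=7)
```

The summary printed by the run above:

```
Health Gym sequence GAN
  schema:            scaled (6 variables, 8 timesteps)
  encoded channels:  9
  training patients: 200
  generator steps:   500
  lambda_GP:         10.0
  lambda_corr:       10.0
  alignment term, first decile of steps: 30.0408
  alignment term, last decile of steps:  22.0500
  final Wasserstein estimate:            3.3867
```

The alignment term (the weighted L1 gap between synthetic and real
correlation matrices) falls as training proceeds; the Frobenius gap
between synthetic and real Kendall-tau matrices for this run is 0.25,
against 1.08 for the same study with the alignment loss ablated
(`lambda_corr=0`). Auditing the sample:

```python
report = hierarchical_validate(real, syn)      # KS-first test hierarchy
audit = synthetic_to_real_risk(real, syn)      # distances (no QIs here)
```

A command-line interface covers the same flow for CSV files:

```bash
healthgym simulate --schema hypotension --patients 500 --seed 1 --out real.csv
healthgym train --real real.csv --schema hypotension --steps 500 --out model/
healthgym generate --model model/ --real real.csv --schema hypotension \
    --patients 500 --seed 2 --out syn.csv
healthgym validate-syn --real real.csv --syn syn.csv --schema hypotension --out report/
healthgym audit --real real.csv --syn syn.csv --schema hypotension
healthgym utility --real real.csv --syn syn.csv --schema hypotension
```

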