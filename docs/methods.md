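# Methods

This note documents the models and procedures implemented in `healthgym`,
the study conditions of its simulator, and the numerical choices made where
the design was genuinely open. It states no empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

A cohort is a fixed-geometry panel: `n_patients × timesteps × variables`,
with one CSV row per (patient, timestep). Variables are numeric, binary or
categorical; binary "(M)" variables are measurement indicators flagging
whether a companion value was actually observed at that timestep
(informative missingness — cells themselves are always populated upstream).
Three bundled schemas mirror published synthetic-cohort layouts:

| schema      | clinical variables        | steps | interval      | quasi-identifiers |
|-------------|---------------------------|-------|---------------|-------------------|
| hypotension | 20 (9 num, 4 cat, 7 bin)  | 48    | 1 hour        | —                 |
| sepsis      | 44 (35 num, 6 cat, 3 bin) | 20    | 4-hour window | Age, Gender       |
| hiv         | 13 (3 num, 5 cat*, 5 bin) | 60    | 1 month       | Gender, Ethnicity |

(*counting Ethnicity and four regimen variables.) Each bundled variable
carries its published descriptive statistics (quartiles or class shares);
the container enforces fixed per-patient length, 0-based consecutive
timesteps, class-vocabulary membership and finite numerics at
construction. Variable-length ingestion is out of scope by design: the
released synthetic cohorts are fixed-length, and the fixed geometry keeps
every downstream reshape trivially safe.

Decile-coded variables (the five extremely skewed sepsis labs) use classes
`C1..C10` with half-open `[lo, hi)` intervals, last interval closed; a
value equal to a cut joins the class whose interval starts there. The
interval-bounds metadata is stored for the variables whose published
bounds are unambiguous (SpO2, Temp, PTT, PT).

## Cohort simulator (the study conditions)

Real sources are restricted, so all training and auditing runs on
simulated cohorts with *known* structure:

- Latent layer: per patient, a stationary Gaussian AR(1) vector process,
  one channel per clinical variable. With per-channel coefficients `a_i`
  the innovation covariance is `R_ij (1 − a_i a_j)`, so the stationary
  cross-channel correlation equals the configured matrix `R` exactly.
- Numerics are monotone transforms of their channel (`exp(μ + σx)` for
  right-skewed labs, affine otherwise). Monotone maps preserve ranks, so
  numeric pairs obey the Gaussian-copula identity
  `τ = (2/π) arcsin(ρ)` — `expected_static_tau` exposes this as an
  analytic oracle, and the validation module is tested against it.
- Categoricals/binaries interval-code their channel at quantile cutpoints,
  reproducing arbitrary class imbalance. Measurement indicators are
  independent Bernoulli draws by default (sufficient to emulate the sparse
  published "(M)" shares); a value-linked mode tilts the probability by the
  target's latent value.
- Quasi-identifiers are held constant within a patient (first-timestep
  latent reused) so equivalence classes are well defined.

Default configurations derive lognormal `μ, σ` from the published
medians/quartiles (`μ = log median`, `σ = log(Q3/Q1) / 2z₀.₇₅`) and
cutpoints from the published class shares (floored at 0.05 % so cuts stay
strictly increasing). Cross-channel correlation defaults to a
`0.4^|i−j|` decay and AR coefficient 0.7 — moderate, always positive
definite, chosen once as plausible for hourly clinical data. What the
simulator does *not* emulate: physiological algebra between variables
(e.g. MAP/SBP/DBP consistency), value-dependent treatment policies, and
variable-length stays. Passing tests therefore demonstrate that the
pipeline recovers known statistical structure, not clinical realism.

## Encoding

Numerics: optional `log1p` (selected when sample skewness > 2.0 and the
support allows it), then min-max scaling to [0, 1] with bounds learned
from the real data; out-of-bound values at generation time are clipped and
counted. Constant columns are rejected (the disclosure audit, which may
see legitimately constant ages in tiny cohorts, substitutes a unit-width
scaling). Categoricals/binaries: K probability channels, one-hot for data,
soft (softmax) for generator output. Decoding resolves blocks by argmax
with ties to the lowest class index. Whether to min-max or standardise was
an open choice; [0, 1] scaling pairs naturally with the generator's
sigmoid heads and makes the encode/decode round-trip exactly invertible
within the fitted bounds (≤1e−6 numerics, exact classes).

## The sequence GAN

Generator: one biLSTM over the latent sequence (i.i.d. standard normal,
default `latent_dim` 16), then three dense layers applied per timestep;
sigmoid heads for numeric channels, softmax per categorical block, so
generator output satisfies the encoded-batch invariants by construction.
Critic: soft embeddings per categorical block (probability-weighted
average of class embedding rows — an ordinary lookup for one-hot input),
two dense layers, a biLSTM, then a dense layer to one score per timestep,
mean-pooled over time (configurable to last-step; the choice is not
determined by the architecture description, and mean pooling makes every
timestep contribute gradient).

Losses:

- Critic: `E[D(G(z))] − E[D(x_real)] + λ_GP E[(‖∇_x̂D(x̂)‖₂ − 1)²]`.
  The penalty point `x̂` defaults to a per-sequence uniform interpolation
  between paired real and synthetic sequences (the standard
  gradient-penalty construction for Wasserstein critics);
  `gp_mode="at_synthetic"` differentiates at the synthetic batch instead,
  for users who want that exact variant.
- Generator: `−E[D(G(z))] + λ_corr Σ_{i>j} |r_syn(i,j) − r_real(i,j)|`,
  with Pearson `r` computed over encoded channels pooled across batch and
  time. Correlation "between variables" is not defined for a categorical
  variable as such; channel-level correlation (each class a channel) is
  the encoding-consistent reading and is what the loss uses. The loss-side
  correlation carries a 1e−8 variance epsilon so near-constant channels do
  not explode gradients; the reporting-side `pearson_matrix` instead
  applies the exact convention r = 0 for constant channels (flagged),
  diagonal 1. At `λ_corr = 0` the alignment term is skipped entirely, so
  the vanilla loss identity holds bitwise. `|·|` uses the subgradient 0 at
  its kink, making the alignment gradient exactly zero at equality.

Training alternates `critic_steps_per_generator_step` critic updates
(default 5) with one generator update, Adam (lr 1e−3, β = 0.5/0.9 — the
conventional setting for gradient-penalty critics), batch 64. `r_real` is
computed per real minibatch by default so the alignment target carries
sampling noise symmetrically; a global-`r` mode computes it once.
Hidden sizes, λ values (λ_GP = 10, λ_corr = 10) and learning rates are
declared defaults, not tuned reproductions. All randomness flows from one
seed; identical seed and configuration give identical training logs and
identical sampled CSV bytes. Non-finite losses abort with the step index
and last finite values.

Gradients come from the package's reverse-mode tensor engine
(`_autodiff.py`): every backward rule is itself expressed in
differentiable operations, which is what makes the penalty term —
a gradient norm that must be differentiated again with respect to critic
parameters — exact rather than approximated. First- and second-order
correctness is verified against finite differences in the test suite.

## Realisticness validation

Stage one renders KDE overlays (numerics) and class-share bars. Stage two
runs, per variable, a two-sample KS test first (categoricals on their
declared ordered class codes; coma scores and decile codes are genuinely
ordinal, for nominal variables the statistic is order-dependent and
documented as such). On KS failure (p < α, default 0.05, no multiplicity
correction): numerics get the pooled-variance t-test and a variance-ratio
F-test (two-sided via doubled tail); categoricals get an ANOVA-style
class-share test; both get the three-sigma test (fraction of synthetic
values inside real mean ± 3 SD, pass threshold 0.997 — the Gaussian 3σ
mass — configurable). Verdicts: `distribution_matched` (KS pass),
`moment_matched` (all parametric follow-ups pass), `range_plausible`
(only three-sigma passes), else `failed`.

The ANOVA construction for categorical failures is deliberately isolated
behind one function: for each class the group holds synthetic membership
indicators centred by the real class share, so group means are per-class
share differences and the one-way F statistic is exactly zero at identical
shares and grows with displaced class mass.

Stage three computes Kendall τ-b matrices: static (pooled across patients
and timesteps) and dynamic — each patient's series is decomposed into an
OLS line (trend) plus residual (cycle), τ is computed per patient per pair
and averaged. Two fitted lines have τ equal to the sign of their slope
product, which is used directly. Patients with constant trend or cycle
sequences have undefined τ and are excluded from that pair's mean (counts
recorded); zero-filling them would bias averages toward zero. "Linearly
decomposed" admits other linear filters; OLS is the simplest exact
reconstruction (`trend + cycle = series`, idempotent on lines).

## Disclosure audit

Copy leakage: exact minimum Euclidean distance between all real ×
synthetic records on the encoded scale (rows by default; whole flattened
patient series as an option), blocked computation with block-independent
results. Distances on the encoded scale are comparable across variable
types but are *not* comparable to raw-unit distances reported for
original-scale data; a `raw_units` mode exists for users who hold such
data. Attack risk: patients sharing a quasi-identifier key (numeric keys
floored to the whole unit, e.g. age in years) form equivalence classes;
risk = `(1/S) Σ_s I_s / F_s` over synthetic patients, with unmatched keys
contributing zero (their real class size is undefined). Patient-level
granularity is used because quasi-identifiers are patient-constant;
row-level matching would count each patient 20–60 times. Key equality is
exact (no tolerance band on rounded age). Threshold 0.09 by default (the
regulatory release level for clinical-trial data), 0.05 selectable.

## Utility verification

Observations (all variables outside the action set) are encoded and
reduced by cross decomposition — PLS regression against the one-hot action
matrix, 5 components by default, with a warning and rank truncation on
rank-deficient inputs. The action-paired view follows the established
protocol for this reduction; the reducer interface isolates that choice.
K-means (default 100 clusters, fixed seed, `n_init` 10) defines states;
the reducer and centroids fitted on the real cohort are reused for the
synthetic one, so both agents act over one shared state space — required
for tile-wise comparability of the resulting policies. Actions are indexed
mixed-radix over the action variables' class lists (4 × 4 = 16 for the ICU
cohorts, 6 × 4 = 24 for HIV); numeric action variables are quantile-binned
to 4 levels on the real data first.

Batch-constrained Q-learning is tabular: 100 full sweeps over the
transition batch in fixed order, learning rate 0.01 ("iterations" read as
sweeps; the update is the standard per-transition rule with the bootstrap
maximum restricted to actions empirically observed in the next state at
frequency ≥ `bcq_threshold`). Discount defaults to 0.99. Greedy ties break
to the lowest action index; states never visited have undefined policy and
are excluded from heatmaps with a reported count. With γ = 0 and a
state-action pair seeing several distinct rewards, the sweep map converges
to a fixed point within O(learning rate) of the mean immediate reward —
the exact closed form is asserted in the tests. Reward functions are
pluggable stand-ins (restore mean arterial pressure ≥ 65 mmHg; reduce a
lactate-based acuity proxy; suppress viral load below 1000 copies/mL),
clearly labelled: the published reward definitions live in other works'
supplements and are not reproduced here.

Policies are compared through action-frequency heatmaps (greedy action
tabulated over every real-cohort row, tiles in percent summing to 100)
and their total-variation distance, plus a ranked list of the
largest-gap actions.

## Scaled training study

Full-size GAN replication needs GPU-scale resources; the package's
standard end-to-end study (`healthgym.benchmark`) is a 200-patient,
8-timestep, 6-variable cohort (4 right-skewed numerics, one imbalanced
3-class categorical, one sparse indicator; `0.5^|i−j|` channel
correlation, AR 0.5), trained for 500 generator steps with 2 critic steps
per generator step, batch 64, and compact networks (hidden 12, dense 24).
Two critic steps per generator step keep a full study under a few CPU
minutes while leaving the alternating dynamics intact; the library default
remains 5. The study checks two qualitative claims: the logged alignment
term falls between the first and last deciles of training, and ablating
the alignment loss (`λ_corr = 0`) leaves a larger Frobenius gap between
synthetic and real static Kendall-τ matrices (median over three seeds in
the tests; `scripts/acceptance.py` reports one seed of each arm).

## Known limitations

- The simulator's copula structure means all dependence is monotone; the
  GAN is never tested here against non-monotone real-world dependence.
- Desk-scale networks and step counts demonstrate mechanism, not
  publication-scale sample quality; KS pass rates on the bundled schemas
  at these scales are not comparable to results obtained from restricted
  clinical sources at full training scale.
- KS on nominal categoricals depends on the declared class order.
- Encoded-scale minimum distances are not comparable across transform
  specifications.
- The tensor engine is plain numpy: correct and exact, but not a
  performance substitute for a deep-learning framework at larger scales.
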