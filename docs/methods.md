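# Methods

## Model and inference

The package implements the interpersonal Gaussian mixture (Inter-GM): two
agents share a latent sign s_n per object, and each agent owns a
sign-to-category table Θ (L rows, Dirichlet(α) prior), per-category Gaussian
parameters Φ = {(μ_k, Λ_k)} (normal–Wishart prior), a categorization
c_n ~ Cat(θ_{s_n}), and an observation x_n ~ N(μ_{c_n}, Λ_{c_n}⁻¹). All
conditionals are conjugate; inference is plain Gibbs sampling with the fixed
scan order c → Θ → Φ (any order is a valid sampler; one is fixed for
reproducibility). Signs are never resampled by the sweep — they change only
through the game's propose/accept exchange, which is exactly the
Metropolis–Hastings kernel for the shared sign.

Densities are computed in log space with Cholesky factorizations;
category posteriors are normalized after max-subtraction, and an all-zero
posterior raises rather than silently renormalizing. Every sampled Θ row is
stochastic and every sampled Λ symmetric positive definite by construction
(Wishart draws are symmetrized against accumulation of floating-point
asymmetry).

Label identifiability is deliberately not resolved (no relabeling step):
the game itself aligns labels between agents, and evaluation uses
label-invariant metrics (adjusted Rand index, sign agreement rate).

## Parameters

| parameter | default | units / range | rationale |
|---|---|---|---|
| K, L | 5, 5 | categories / signs | five labels A–E |
| α | (0.1, …, 0.1) | Dirichlet concentration | sparse sign-category coupling |
| β | 1.0 | prior pseudo-observations for μ | weak mean prior |
| m | (50, 0, 0) | L\*u\*v\* | mid-lightness, neutral hue |
| W⁻¹ | diag(200, 200, 200) | (L\*u\*v\*)² | broad category covariances |
| ν | 4 | Wishart dof | smallest integer = dim + 1 with a finite prior mean precision; not pinned down elsewhere, so results can depend weakly on it (exposed in config) |
| π | (1/5, …, 1/5) | sign prior | uniform |
| n_items | 15 | objects per dataset | session size |
| n_passes | 3 | per role | 15 × 3 = 45 listener decisions per participant per dataset |
| n_null | 1000 | randomization replicates | empirical-CDF resolution 10⁻³ |
| n_model_reps | 100 | precision replicates per model | U-test sample size |
| α-level | 0.001 | U-test significance | strict pairwise criterion |

Stimulus sets: three 3-D Gaussians sharing one covariance. "hard": means
(60, −10, 20), (60, −20, −10), (60, 20, 10), Σ = diag(5², 9², 9²); "easy":
(60, 30, 30), (60, 30, −30), (60, −30, −30), Σ = diag(5², 10², 10²). The
generating component of each item is drawn uniformly from the three
Gaussians by default; a balanced 5/5/5 option exists but is not the default.
Stimuli stay as raw L\*u\*v\* vectors — the analysis never needs displayable
colors, so no gamut clipping or sRGB rendering is done.

## Game protocol choices

- Roles swap after each full pass over all items, not per item: only
  per-pass alternation makes a session of 3 passes per role produce exactly
  45 listener decisions per participant per dataset.
- Item order is reshuffled every pass from the game's named `order` stream.
- The speaker proposal distribution is P(s | Θ, c) ∝ π_s θ_{s,c}; with
  uniform π this is likelihood-proportional sampling.
- Initialization stands in for a participant's manual first categorization:
  parameters from the prior, provisional signs from Cat(π), one perception
  sweep, then each item's sign is set to argmax_l π_l θ_{l, c_n} (ties to
  the lowest index).
- The listener's categorization is updated in the per-pass perception step,
  not within the accept/reject exchange.

## Behavioral analysis choices

- Θ^Li for a logged trial is estimated by the Dirichlet **posterior mean**
  (α_k + n_lk)/(Σα + n_l) over the listener's (category, sign) assignments
  — deterministic given the log and less noisy than a single Gibbs draw. A
  sampled-Θ mode (averaging r^MH over posterior draws) is provided, as is a
  final-state batch mode; the default re-estimates **online** from the
  assignments current at each trial, because listeners relabel during a
  session. Under the Inter-GM factorization Θ's conditional depends only on
  the (c, s) counts, so the color vectors never enter r^MH inference when
  categorizations are observed.
- The bounded MLE of Bern(z | a·r^MH + b) maximizes a concave
  log-likelihood over the polytope {b ≥ 0, a + b ≤ 1, a ≥ −0.01}. The small
  negative slope floor admits the near-zero-but-negative boundary estimates
  that always-accept streams produce while keeping predicted rates within
  clipping distance of [0, 1]; likelihood terms are clipped at 10⁻¹².
  The optimizer is a deterministic adaptive grid: a dense shared feasible
  grid (spacing 0.01) followed by per-stream compass search (move to a
  strictly better neighbor, halve the step when none improves, stop below
  10⁻⁵). Concavity guarantees convergence to the constrained global
  optimum; the search is vectorized across replicate decision streams by
  collapsing trials onto unique r^MH values (the likelihood depends on the
  data only through accept/reject counts per distinct r^MH, and r^MH
  streams are heavily tied), which is what makes the 1,000-replicate null
  cheap. Plateau ties (e.g. all-accept streams) are broken toward small
  a² + (b − ½)², resolving the all-accept case to (a, b) = (0, 1). The fit
  is cross-checked against an independent SLSQP optimizer in the tests.
- The randomization test redraws decisions from Bern(b̄) with r^MH fixed,
  refits the slope per replicate, and reports the inclusive one-sided
  empirical tail P(â_null ≥ â_obs). An observed slope above every null
  sample reports p = 0 (interpretable as < 1/n_null). P′_b is computed and
  reported alongside but drives no decision.
- Model precision draws pseudo-decisions trial-wise from each model's
  probability; the constant model's rate is the observed acceptance rate of
  the scope being tested (participant or pooled). Pairwise comparisons use
  the one-sided Mann–Whitney U-test with the tie-corrected normal
  approximation; an all-tied degenerate pair gets p = 0.5 and is flagged.
  Per-participant tests pool a participant's trials across datasets (90
  where both datasets were played); the per-dataset scope is also available.

## What the synthetic participants do and do not emulate

Pseudo-participants replace the listener's accept rule with one of five
response models (constant b̄; a·r^MH + b; the numerator likelihood; the
rescaled likelihood difference; a 0.1/0.9 threshold at r^MH = 0.5) while
keeping the full game mechanics, so sign state evolves realistically under
the altered decisions. A `resample_decisions_only` mode instead freezes an
existing log's state stream and redraws only decisions — that is the
pseudo-experiment used by the model-comparison test, and the only mode in
which two models share an identical proposal stream. The generator emulates
the statistical structure the analysis assumes (categorical relabeling via
Gibbs perception, per-trial Bernoulli decisions); it does not emulate human
idiosyncrasies — fatigue, order effects, social deference, inconsistent
relabeling — so passing tests show the pipeline's correctness and power
under the model, not that human behavior satisfies it.

## Problem sizes

The test suite and acceptance script run cohorts of 10 pairs (20
participants, 900–1,800 pooled decisions), 1,000-replicate randomization
nulls, a 200-run type-I calibration study, and 100-replicate precision
samples — the cohort sizes and replicate counts of the study design.
Gibbs-oracle checks use 2,000–5,000 draws; recovery checks use up to 10,000
observations.

## Known limitations

- Exactly two agents; the recursive N-agent generalization is out of scope.
- Only Gaussian emissions (the Inter-GM instance); no Dirichlet-mixture or
  other emission families, and no variational or collapsed samplers.
- The bounded MLE cannot reproduce estimates that violate its own bounds
  (e.g. a + b slightly above 1), which unconstrained-tolerance optimizers
  occasionally emit.
- The randomization null conditions on the inferred r^MH stream; it does
  not propagate uncertainty in Θ^Li into the null distribution.
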