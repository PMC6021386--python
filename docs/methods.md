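# Methods

## Model

`bsds` fits a switching linear dynamical system to multivariate time series
`y_t ∈ R^D` (typically ROI-averaged fMRI signals sampled every TR seconds).
A discrete latent brain state `z_t ∈ {1..K}` follows a first-order Markov
chain with initial probabilities `π` and row-stochastic transitions `A`,
`A[j,k] = P(z_t = k | z_{t-1} = j)`. Conditional on `z_t = k`, the
observation is produced by a probabilistic factor analyzer driven by an
autoregressive latent trajectory `x_t ∈ R^P`:

    y_t = U_k x_t + μ_k + e_t,        e_t ~ N(0, Ψ_k)        (Ψ_k diagonal)
    x_t = V_k ⊙ x_{t-1} + ε_t,        ε_t ~ N(m_k, Σ_k)      (Σ_k diagonal)

with a D×P loading matrix `U_k`, observation offset `μ_k`, per-dimension
AR(1) coefficients `V_k` (|v| < 1 for stationarity) and innovation mean and
variance `m_k`, `Σ_k`. Each state is therefore a regime with its own
second-order structure; the stationary observed covariance of state `k` is

    C_k = U_k Γ_k U_kᵀ + Ψ_k,     Γ_k = diag(Σ_k,pp / (1 − v_k,p²)),

which is what all connectivity reporting uses. `U_k` itself is only
identified up to rotation of the latent space (exactly so when `Γ_k ∝ I`),
so loadings are never interpreted directly.

Model assumptions worth keeping in mind: diagonal `Ψ_k` routes all shared
variance through the latents (classical factor analysis); diagonal AR
coefficients mean each latent dimension mixes on its own timescale; and a
single trajectory `x_t` is shared across states, with the state selecting
which dynamics and loadings apply at each frame.

## Variational inference

The posterior is approximated by structured mean field
`q(z) q(x) ∏ q(θ)`:

* **q(z)** — exact HMM smoothing (forward–backward in scaled/log space)
  under per-frame *expected* log-densities
  `E_{q(x)q(θ)}[log p(y_t, x_t | z_t = k, x_{t-1})]`.
* **q(x)** — a Gaussian chain. Collapsing the states with the
  responsibilities γ makes the log-density quadratic in `x` with
  block-tridiagonal precision; marginal means, covariances and lag-one
  cross-covariances come from one forward block-elimination plus a backward
  Takahashi recursion. When γ is one-hot this is the ordinary
  linear-Gaussian smoother.
* **q(θ)** — conjugate factors: Dirichlet for `π` and each row of `A`
  (sticky prior: concentration `1 + κ` on the diagonal, `κ = 10` by
  default), Gaussian rows for `[U_k | μ_k]` with automatic relevance
  determination (ARD) precisions `ν_kp ~ Gamma(10⁻³, 10⁻³)` on loading
  columns and unit prior precision on `μ`, Gaussian pairs for
  `(v_kp, m_kp)` with unit prior precision, and Gamma(10⁻³, 10⁻³) for the
  diagonal precisions of `Ψ_k` and `Σ_k`. The first latent frame has a
  fixed broad prior `x_1 ~ N(0, 10·I)`.

Every update is an exact coordinate-ascent step on one evidence lower
bound, computed as `Σ_s log Z_s` (the forward-pass normalizer, which
absorbs all state-coupled expected-likelihood terms) plus the entropy of
`q(x)` and the `x_1` prior term, minus the parameter KL terms. The ELBO is
therefore monotone non-decreasing by construction, which the test suite
asserts on every dataset it fits (tolerance `10⁻⁸·|ELBO|`). The z↔x
coupling is handled by alternating the two E-steps (2 sweeps per
iteration).

**Initialization.** Restart 0 clusters sliding-window covariance features
(window 15 frames, stride 1, vectorized upper triangle) with k-means
(`n_init=10`) and softens the labels (0.9 mass on the assigned state);
remaining restarts draw responsibilities from a flat Dirichlet. Latent
means start at unit-variance PCA scores. The best restart by final ELBO
wins. All randomness is derived from one seed, and repeated runs with the
same seed are bitwise identical.

**Model complexity.** The model is deliberately over-provisioned
(`K_max` states, `P_max = D − 1` latent dimensions by default) and relies
on two shrinkage mechanisms: redundant states lose responsibility mass
during the VB iterations (their parameters revert to the prior and the
digamma penalty on rarely-used transition rows starves them), and ARD
precisions grow on unused loading columns. After convergence, states with
fractional occupancy below `max(10⁻³, 2/ΣT)` are removed, the
responsibilities renormalized and the model re-smoothed; the surviving
count is reported as `K_effective`. Latent dimensions whose posterior mean
precision exceeds 10³× the state median are reported as pruned
(`effective_P`). Occupancy pruning alone keeps any state above the
threshold, including coordinate-ascent artifacts such as a state
specialized on a handful of regime-switch frames. A final **ELBO
cross-check** therefore performs backward elimination: every surviving
state below 5% occupancy is tentatively removed (responsibilities
renormalized, model refit) and the reduced model is accepted only when
its bound is higher. Genuinely supported small regimes — for which the
bound degrades on removal — are retained.

**Subject-level refits.** `fit_subject` re-runs the same coordinate ascent
on one subject with the *group posterior as the prior* (natural-parameter
carry-over for every factor; ARD is frozen at the group level). State
identities are preserved — no pruning or relabeling — so subject-level
state-specific covariances are directly comparable across subjects.

**AR order.** The simulator supports general R (lagged recursion); the
inference engine implements R = 1, which is the order used for every
analysis here.

## Decoding and state dynamics

Viterbi decoding and plug-in posterior time courses use the stationary
per-state emission density `N(y; μ_k + U_k m*_k, C_k)` with posterior-mean
parameters — a deliberate plug-in approximation that makes decoded
sequences a deterministic function of the fitted parameters. Conventions:
transitions are counted from frame `t` to `t+1`; ties in the Viterbi
recursion break toward the lower state index; runs truncated by a
condition-mask boundary still count in lifetime statistics (excluding them
would bias against long-lived dominant states; configurable). Transition
matrices can alternatively be computed from the VB pairwise marginals ξ;
the decoded-sequence version is the default and the one reported.
Cross-fit state matching computes both models' posterior time courses on
the same data and solves the exclusive assignment maximizing total Pearson
correlation (Hungarian algorithm). The onset-locked occupancy window
defaults to 5 s.

## Downstream statistics

Condition prediction uses a linear multiclass (one-vs-rest logistic)
classifier on per-frame state posteriors with leave-one-subject-out folds;
significance comes from permuting condition labels within subject,
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`. Link-wise connectivity contrasts
are paired two-tailed t-tests across subjects on Fisher-z correlations per
link, Benjamini–Hochberg corrected (paired because every subject
contributes both states). Graph metrics binarize the top proportion of
edge weights (default 40%, deterministic tie-break toward lower indices)
and report row-sum degree and *unnormalized* betweenness centrality.
Behavior regression is ordinary least squares with leave-one-out folds and
the Pearson correlation between pooled out-of-fold predictions and
observed scores; note that this correlation is negatively biased under the
null (out-of-fold predictions anti-correlate with the held-out response),
so its null distribution is centered below zero — the test suite freezes
its expectations from null simulations rather than from the naive
sampling law of r. The sliding-window + k-means baseline chooses k by
silhouette (first k wins ties) and applies Ledoit–Wolf shrinkage when
windows are shorter than the channel count.

## Synthetic data

The generator emulates the block-design validation paradigms as
regime-switching Gaussian series drawn exactly from the model above:

* `tvb` — five 60 s OFF/ON cycles (40 s OFF, 20 s ON) at TR 0.7 s,
  mirroring a three-node neural-mass stimulation paradigm;
* `nengo` — twenty trials of 40 s OFF / 20 s ON alternating between two ON
  regimes, 1200 s total at TR 0.7 s, mirroring a seven-node
  basal-ganglia-circuit paradigm;
* `hcp_wm` — eight 27.5 s n-back task blocks (alternating 0-back/2-back)
  and four 15 s fixation blocks at TR 0.72 s.

Preset generating parameters (`default_state_parameters`) give each state
an orthonormalized random loading subspace scaled to variance 2.25 per
direction against diagonal noise 0.2, unit stationary latent variance,
AR coefficient 0.5, equal means across states — so regimes are
distinguishable by covariance structure only, which is the property the
model is supposed to exploit — and a sticky chain (0.95 self-transition)
for chain-driven runs. Two states' P-dimensional subspaces can only be
disjoint when `K·P ≤ D`; fixtures are chosen accordingly.

At every state *entry* the latent trajectory is redrawn from the entering
state's stationary law (`latent_reinit="switch"`, the default), so each
regime expresses its stationary covariance from its first frame and
design-driven ground truth has exactly the design's segment structure.
With `latent_reinit="start"` latents instead evolve continuously across
switches, which produces brief (1–2 frame) cross-regime transients; fitted
models can resolve these into a real low-occupancy transition state.

Subject variability is emulated by independent noise streams per subject
(spawned from one seed) and optionally a per-subject constant channel
offset (`subject_offset_sd`, default 0). An optional canonical
double-gamma HRF convolution (peak 6 s, undershoot 16 s, ratio 1/6) is OFF
by default since the model's intended inputs are already BOLD-like.

What the generator does *not* emulate: scanner noise physics, slow drifts,
motion artifacts, hemodynamic variability across regions, inter-subject
parameter heterogeneity beyond mean offsets, or mis-specified emission
families. Passing recovery tests therefore demonstrates correctness of the
inference machinery under the model's own assumptions — not robustness to
the full messiness of real fMRI.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale versions of the validation
paradigms: 3 subjects × 428 frames (tvb), 1 × 1714 frames (nengo), and a
parameter-recovery study at K=3, D=8, P=3, 10 subjects × 2000 frames with
`P_max = 4`. Bounding the latent dimensionality in fits is standard
practice for switching models of this kind and is reported alongside the
results. Convergence is declared at relative ELBO change < 10⁻⁶ (max 500
iterations). Covariances failing a Cholesky get jitter `10⁻⁸·mean(diag)`
once before erroring. Degenerate inputs are rejected with named locations:
constant channels, non-finite cells, series shorter than R + 2.

## Known limitations

* Decoding uses stationary plug-in emissions rather than re-running the
  latent smoother per candidate sequence; sequences at regime boundaries
  can differ from the full-posterior argmax by a frame or two.
* Occupancy-based pruning cannot distinguish a reproducible small regime
  from redundant structure the optimizer failed to merge; `K_effective`
  can exceed the generating count when a stable micro-regime forms.
* The ELBO is a lower bound: comparisons across K are heuristic.
* No missing-data support; series must be complete.
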