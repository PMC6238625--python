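# Methods

This document describes the model, the numerical methods, and the design
decisions behind `clockloops`, in enough detail to reproduce or audit every
computation.

## 1. Model

### 1.1 Network

The mammalian core clock is condensed to five representative transcripts:
the transcriptional activators **Bmal1** and **Dbp** and the inhibitors
**Per2**, **Cry1** and **Rev-erb-α** (written `RevErbA` in code). They are
wired by 17 regulations acting through three classes of promoter elements:

| source  | targets                      | mode       | element |
|---------|------------------------------|------------|---------|
| Bmal1   | Dbp, Per2, Cry1, RevErbA     | activation | E-box   |
| Dbp     | Per2, Cry1, RevErbA          | activation | D-box   |
| Per2    | Dbp, Per2, Cry1, RevErbA     | inhibition | E-box   |
| Cry1    | Dbp, Per2, Cry1, RevErbA     | inhibition | E-box   |
| RevErbA | Bmal1, Cry1                  | inhibition | RRE     |

That is 7 activations and 10 inhibitions. Protein production,
modification and nuclear transport are not modelled explicitly; instead
each regulator gene acts on all of its targets after one explicit delay
τ_source (hours). This "delay per regulator" choice keeps the parameter
count at 34 (see below) and reflects that the lag is dominated by the
production and maturation of the regulator itself.

### 1.2 Equations

Each transcript level x_g(t) (mean-normalized, dimensionless) obeys a
delay differential equation

    dx_g/dt = Π_e F_e( x_src(e)( t − τ_src(e) ) ) − d_g · x_g(t)

where the product runs over the regulations e targeting gene g, and

  - activating edge:  F(y) = (1 + a (y/K)^n) / (1 + (y/K)^n) ∈ [1, a]
  - inhibiting edge:  F(y) = 1 / (1 + (r y)^n)               ∈ (0, 1]

with Hill exponent n = 3 by default (configurable per regulation; it
plays the role of a binding-site count). An empty product equals 1, the
basal production rate. Because the activation factor has a floor at 1
and the inhibition factor a ceiling at 1, "no regulation" is the neutral
element of the product — clamping an edge at factor 1 removes it exactly.

### 1.3 Parameters, units and bounds

34 free parameters, flattened in a stable order (activation folds `a`,
activation thresholds `K`, inhibition strengths `r`, degradation rates
`d`, delays `τ`):

| block | count | bounds        | unit | meaning                              |
|-------|-------|---------------|------|--------------------------------------|
| a     | 7     | [1, 50]       | –    | maximal activation fold              |
| K     | 7     | [0.05, 5]     | –    | activation threshold (level units)   |
| r     | 10    | [0.1, 20]     | –    | inhibition strength (1/level)        |
| d     | 5     | [0.05, 1.0]   | 1/h  | degradation rate (half-life 0.7–14 h)|
| τ     | 5     | [0, 12]*      | h    | regulator delay                      |

*The Bmal1 delay is searched on [0, 6] h. With expression data the Bmal1
delay is weakly identified (its targets peak roughly half a cycle after
Bmal1, compatible with τ near 6 h or near 18 ≡ −6 h); restricting the
range removes the aliased solution.

## 2. Numerical integration

SciPy offers no delay-differential solver, and the delayed lookups are
the inner loop of everything downstream, so the integrator is built in
the package and compiled with numba:

- **Method of steps with fixed-step RK4** (default step 0.05 h; steps
  above 0.1 h are rejected). A fixed grid makes every delayed lookup a
  constant-time interpolation and the whole pipeline bit-reproducible.
- **History**: constant at the normalized mean (1.0) unless given; kept
  on the same grid extended to negative times.
- **Delayed lookups** use cubic Lagrange interpolation on the grid.
  Lookups that fall inside the step currently being computed (τ smaller
  than the step) use the current RK4 stage state, which is exact in the
  τ → 0 limit.
- **Non-negativity** is enforced by clipping; a non-finite state aborts
  integration with an error that the scoring layer converts into the
  non-rhythmic penalty.

Verification (all in the test suite): exact exponential decay under total
clamping at factor 0 (≤1e-8 absolute error), the algebraic fixed point
under total clamping at arbitrary constants, fourth-order step-halving
convergence, and independence from the history when all delays are zero.

Defaults: 720 h simulated, the first 480 h discarded as transient.
`RunConfig.test_budget()` (240 h at 0.1 h, 144 h transient, used by the
heavier tests) retains four scored cycles; `RunConfig.battery_budget()`
additionally shrinks the swarm for many-fit statistical comparisons.
These problem sizes are package choices for desk-scale runtimes; the
science does not depend on them.

## 3. Data features and scoring

Expression tables are 5 genes × 24 samples (every 2 h over 48 h),
mean-normalized per gene. Data features come from a **two-harmonic
cosinor fit** (least squares with a 24 h fundamental plus second
harmonic): the phase is the fitted curve's global peak time relative to
the Bmal1 peak, the fold change is max/min of the fitted curve, and the
period is fixed at 24 h (entrained sampling).

Simulated features come from the limit cycle directly: the period is the
mean peak-to-peak interval of Bmal1 after the transient (peaks by local
maximum detection with quadratic refinement), phases are peak times
relative to the last Bmal1 peak, and fold changes are max/min over the
last cycle.

The score is a sum of ten squared, tolerance-normalized deviations —
1 period term (σ_T = 0.5 h), 4 relative-phase terms (σ_φ = 1 h, shortest
arc on the 24 h circle), and 5 fold-change terms (σ_FC = 0.5 log2 units):

    S = ((T_sim − T_dat)/σ_T)² + Σ_g (Δφ_g/σ_φ)² + Σ_g (Δlog2FC_g/σ_FC)²

Non-rhythmic or failed simulations receive a flat penalty of 1000. A fit
is **good** iff S < 10 strictly, i.e. the root-mean-square deviation is
below one tolerance unit.

Note that the two feature estimators differ by construction (cosinor on
24 discrete samples vs peak detection on the dense simulation). On
strongly non-sinusoidal waveforms the cosinor peak can shift by up to
about an hour relative to the true peak, so even a parameter set scored
against its own sampled output typically lands at S ≈ 2–5, not 0 — still
far below the threshold.

## 4. Vector-field (gradient-matching) initialization

Instead of integrating, VFO matches the model's right-hand side to time
derivatives estimated from the data:

1. the two measured days are averaged sample-wise into one 12-point
   24 h cycle, interpolated by a periodic cubic spline;
2. derivatives are estimated by periodic central differences,
   (x(t+2h) − x(t−2h)) / 4h;
3. the objective Σ_{g,k} (ẋ_g(t_k) − RHS_g(t_k; θ))² is minimized by
   L-BFGS-B from multiple uniform random starts within the bounds, with
   delayed levels read from the periodic interpolant.

The path is purely algebraic — a test asserts via a global simulation
counter that it never integrates the DDE system. The result seeds the
swarm: particle 0 is placed exactly at the VFO optimum and a fraction
ρ = 0.25 of particles get their kinetic parameters (not delays)
re-sampled within ±25% of the range around it.

Because the folded cycle constrains each target equation through its
regulators, antiphase relationships pin the delays: on a profile where
all four Bmal1 targets peak 12 h after Bmal1, gradient matching drives
the Bmal1 delay to the top of its [0, 6] h range.

## 5. Particle swarm optimization

Box-constrained PSO with: Latin hypercube initialization (one sample per
equal-width bin per dimension), linearly decaying inertia 0.9 → 0.4,
cognitive = social = 1.494, ring neighborhood of 5 (local best), velocity
clamped to 20% of each parameter's range, positions clipped to the box
with the velocity zeroed in clipped dimensions, and non-finite objective
values treated as +∞. A fit is fully determined by (profile, config,
seed): all random streams are derived from the single seed.

## 6. Clamping analysis

Clamping is the in-silico analogue of constitutive expression:

- **edge clamp**: a regulation's factor is frozen at its time average
  over one period of the unperturbed limit cycle (computed by trapezoidal
  quadrature, with the delayed regulator level read from the base
  trajectory);
- **gene clamp**: a gene is frozen at its cycle-mean level.

A **negative feedback loop is essential** when clamping any single one of
its edges abolishes rhythms. A set of loops is a **rhythm-generating
(minimal) oscillator** when rhythms persist with every regulation outside
the set clamped, and no proper subset suffices. For oscillators of two or
more loops, the relationship is classified as *independent* (at least two
loops suffice alone), *dependent* (no proper subset suffices) or *mixed*.

The loop catalog contains the four families most discussed for the
mammalian clock: the Per2 and Cry1 auto-inhibition loops (each with its
extension through Dbp), the Bmal1/Rev-erb-α two-gene loop, and the
three-inhibitor chain Per2 ⊣ Rev-erb-α ⊣ Cry1 ⊣ Per2 (a repressilator).
All simple cycles of the network are enumerated exactly (via
`networkx.simple_cycles`) and checked against a brute-force oracle in the
tests.

### Rhythmicity criterion

A trajectory is rhythmic when, in the post-transient window, some judged
gene keeps a relative amplitude (max − min)/mean above 0.01 **and** the
amplitude of its last cycle is at least 0.95 of the previous one (this
excludes slowly damped spirals). By default **any** gene may carry the
rhythm. Judging only the reference gene (Bmal1) is available via
configuration but is not the default, deliberately: when the oscillator
driving the system does not include Bmal1, Bmal1 is rhythmic only through
a readout edge, and clamping that edge would flatten Bmal1 while the true
oscillator keeps cycling — the readout edge would then masquerade as
essential, and no subset lacking it could be judged sufficient. Judging
all genes makes essentiality and sufficiency statements about the
oscillator itself rather than about one reporter.

## 7. Synthetic data

Two generators:

- **Harmonic tissue profiles**: x_g(t) = [1 + A_g cos(2π(t − φ_g)/24)] ·
  exp(η), η ~ N(0, σ²) i.i.d. per sample, with A_g = (FC_g − 1)/(FC_g + 1)
  so the preset's fold change is exact at zero noise. Ten tissue presets
  encode the qualitative contrasts of published atlases — the SCN's small
  amplitudes and early Cry1 peak, the large Rev-erb-α amplitudes and late
  Cry1 of liver, adrenal gland and kidney. **The numeric preset values
  are fixture choices, not measurements.**
- **Model-sampled profiles**: a known parameter set is simulated, and its
  limit cycle is sampled every 2 h for 48 h starting at a Bmal1 peak,
  optionally with the same multiplicative noise. Three **ground-truth
  fixtures** are shipped (repressilator, Bmal1/Rev-erb-α loop, Per2
  self-inhibition); each is verified at construction (period within 2 h
  of 24 h, every edge of the target loop individually essential). Each
  fixture adds weak zero-gain "readout" edges outside the loop so that
  all five genes oscillate coherently; without them near-flat genes make
  the data phase ill-conditioned.

## 8. Ensemble statistics

Aggregations over many independent fits: frequency tables of essential
families per tissue (over good fits only), Venn-style counts of
minimal-oscillator family compositions, PCA of the standardized
34-dimensional parameter vectors (plain SVD), and LDA via the generalized
eigenproblem S_b w = λ (S_w + εI) w with ridge ε = 10⁻⁶ (fits per tissue
are typically fewer than 34). The Wilcoxon rank-sum test is exact (full
enumeration, ties included) when the smaller sample has ≤ 8 observations
and a tie-corrected normal approximation otherwise. Circular statistics
(mean phase, resultant length) handle the 24 h wrap-around; repressor
phases can be shifted by half a cycle for activator/repressor
comparisons. Where scikit-learn or SciPy equivalents exist they are used
as test oracles only, never at runtime.

## 9. Limitations

- Transcript-only model: no explicit proteins, complexes or
  post-translational regulation; delays absorb all of it.
- The period is fixed at 24 h on the data side (entrained sampling);
  free-running data would need a period-fitting cosinor.
- Clamp constants are derived from the unperturbed cycle; a clamped
  system that drifts far from that cycle is still compared against the
  original constants (this matches the constitutive-expression analogy
  but is a modelling choice).
- The minimal-oscillator search is restricted to the four-family catalog
  (up to 6 member cycles), not all 28 simple cycles of the network.
- Fits at the reduced budgets are exploratory; full-scale fitting (40
  particles × 500 iterations on 720 h simulations) is the intended
  production setting.
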