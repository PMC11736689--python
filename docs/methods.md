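# Methods

This note documents the models, conventions and numerical choices behind
`abfekit`, in the spirit of the methods documentation of packages such as
statsmodels or msprime: what is computed, under which assumptions, and what
the synthetic test bed does and does not establish.

## The double-decoupling cycle

The binding free energy is assembled as

    ΔG_b = ΔG_alch^com − ΔG_restr^com − ΔG_alch^lig + ΔG_restr^lig + ΔG_conf^prot

where ΔG_alch^lig is the free energy of decoupling the ligand from solvent,
ΔG_restr^lig that of imposing Boresch restraints on the decoupled ligand
(analytic, below), ΔG_alch^com that of coupling the ligand in the binding
site, ΔG_restr^com that of releasing the restraints there, and
ΔG_conf^prot an empirical term absorbing apo/holo conformational and
related systematic errors.  The sign convention is pinned by unit tests
and echoed in every report (`meta.convention`).  Component standard errors
combine in quadrature, treating legs as independent.  By default the
coupling and restraint-release steps of the complex leg are combined into
one 15-window transformation (the separate 12-window restraint leg is
supported through the `restraints12` schedule); the combined route is
substantially cheaper with near-identical results.

## Equilibrium estimator

TI computes ΔG = ∫₀¹ ⟨∂H/∂λ⟩ dλ.  The angular brackets denote **ensemble
averaging over replicas** — independent simulations differing in initial
velocities — not a single-trajectory time average.  Built-in λ-schedules:

* `coupling13` = {0, 0.01, 0.05, 0.1, 0.2, …, 0.9, 1.0} for ligand
  (de)coupling;
* `combined15` = `coupling13` ∪ {0.95, 0.99} for simultaneous coupling and
  restraint release (restraint strength 1−λ);
* `restraints12` = {0, 0.01, 0.025, 0.05, 0.075, 0.1, 0.15, 0.2, 0.3, 0.5,
  0.75, 1.0} for separate restraint removal.

Windows crowd near λ = 0 where the energy gradient is steepest.  Van der
Waals interactions scale linearly with λ; electrostatics stay off until
λ = 0.45 and then grow linearly (`coupling_weights`).

**Uncertainty.**  At each window the per-replica gradient samples are
bootstrapped and then ensemble-averaged; the per-window standard error is
the SD of the bootstrap means.  When all replicas carry equal sample
counts (the normal case) one resampling index matrix is shared across
replicas — statistically equivalent to independent per-replica resampling
for the variance of the ensemble mean, and it makes the estimate exactly
invariant under replica relabelling (replica means are also sorted before
averaging so floating-point summation order is canonical).  Unequal counts
fall back to per-replica streams consumed in sorted-id order.  No block
bootstrap is applied: samples are recorded sparsely (every 2 ps in the
protocols this package targets) and treated as given.

**Quadrature.**  The profile is integrated by the composite trapezoid rule
(windows are unevenly spaced; higher-order rules buy nothing at 13–15
points), and window uncertainties propagate through the trapezoid weights
w₁ = (λ₂−λ₁)/2, w_K = (λ_K−λ_{K−1})/2, w_k = (λ_{k+1}−λ_{k−1})/2, assuming
independent windows: stderr = √(Σ w_k² σ_k²).

Defaults: `n_boot = 1000`, seed mandatory in the estimator API (CLI
default 2024).  The bootstrap stream is split per λ-window with
`SeedSequence.spawn`, so results are reproducible bit for bit.

## Nonequilibrium estimator

Work values are accumulated by integrating ∂H/∂λ along fast 0→1
("forward") and 1→0 ("reverse") transitions.  **Sign convention:** stored
work is the work done on the system along the transition's own direction;
the Crooks pairing therefore compares forward works against *negated*
reverse works.  With this convention, relabelling forward↔reverse
estimates the reverse process and flips the sign of the estimate exactly.

The bidirectional estimate solves the Bennett/Crooks maximum-likelihood
self-consistency equation

    Σ_i [1 + (n_f/n_r)·exp((W_f,i − ΔG)/kT)]⁻¹
        = Σ_j [1 + (n_r/n_f)·exp((W_r,j + ΔG)/kT)]⁻¹

by bracketed root finding (Brent, tolerance 1e-8 kcal/mol, bracket
±10⁴ kcal/mol).  The objective is monotone in ΔG; if it does not change
sign strictly across the bracket, or if every sample's likelihood weight
underflows at the root (totally separated distributions produce an exact
zero plateau), a convergence error advises checking overlap.

**Uncertainty** is reported two ways.  `bar_mle` attaches the asymptotic
maximum-likelihood standard error (Bennett's variance evaluated at the
solution over the combined sample).  `neq_free_energy` reports the
between-replica standard error: the pooled estimate plus SD/√R of the R
per-replica estimates, replica r using only works tagged r in *both*
directions (bidirectional pairing by equal replica index; whether
per-replica subestimates should instead be unidirectional is ambiguous in
the field, and the chosen pairing is recorded in report metadata).

**Extreme-work filter.**  Fast coupling transitions in a crowded binding
site occasionally produce astronomically large forward works.  Records
with work > 1000 kcal/mol are removed before estimation (idempotent;
counts logged).  The maximum-likelihood estimator assigns such samples
essentially zero weight, so filtering mainly protects the sample-size
ratio and any moment-based diagnostics.

The unidirectional Jarzynski estimate −kT·ln⟨exp(−W/kT)⟩ uses log-sum-exp
stabilisation; it is biased at finite n and bounded above by the mean work.
No decorrelation of works is attempted: transitions start from equidistant
end-state conformations and are treated as independent.

## Diagnostics

* **Overlap coefficient** — forward and negated-reverse works are
  histogrammed on shared bins spanning the pooled range
  (Freedman–Diaconis width, minimum 10 bins), normalised to unit area;
  the coefficient is Σ min(p_f, p_r)·Δ, in [0, 1].  A histogram (rather
  than a KDE) makes the [0, 1] bounds and exact-zero overlap reproducible;
  the bin rule is recorded in the report.  A degenerate pooled range
  returns 1 with a flag.
* **Distance** — min(forward) − max(negated reverse): positive values
  measure the gap between non-overlapping distributions, negative values
  mean the ranges interleave (outliers can yield negative distance at zero
  histogram overlap).
* **Moments** — population (biased) skewness m₃/m₂^{3/2} and excess
  kurtosis m₄/m₂²−3; the sample-adjusted variants are available via
  `bias=False`.
* **Reliability flags** — precision passes when stderr ≤ 0.5 kcal/mol,
  overlap (NEQ only) when distance ≤ 0; both thresholds are configurable
  and boundary-inclusive (documented choice; equality passes).

## Restraints and adjustment

The Boresch term uses the stiff-spring closed form

    ΔG_restr^lig = −kT·ln[ 8π²V₀·√(K_r KθA KθB KφA KφB KφC)
                           / (r₀² sinθA₀ sinθB₀ (2πkT)³) ]

with V₀ = 1660 Å³.  It is validated in the test suite against an
independent quadrature oracle of the restrained configurational integral
(the 6-D integral factorises over coordinates), agreeing to < 0.05
kcal/mol in the stiff-spring regime; the stiff-spring form ignores the
Jacobian's variation across the restraint well, so it degrades for very
soft restraints (K ≲ 1 kcal/mol/rad²).

ΔG_conf^prot is estimated per system as the mean signed error of raw
predictions against reference values over that system's complexes;
adjusted predictions subtract it, which zeroes the per-system mean signed
error by construction.  This requires reference data (≥ 2 complexes per
system by default; smaller systems are left unadjusted and flagged) and is
an empirical, not a simulated, quantity.

Benchmark metrics (MUE, RMSE, Pearson r, Spearman ρ) carry standard errors
from a nonparametric bootstrap over complexes (default 1000 resamples);
propagation of the per-complex prediction error bars into the metric
uncertainties is deliberately not mixed in.

## Protocol cost model and escalation

An EQ leg costs n_λ × ensemble × replica-length; an NEQ leg costs two
end-state equilibrium ensembles plus (transitions per replica × ensemble)
× (forward + reverse transition length).  With the combined complex leg an
EQ protocol carries no separate restraint-leg cost; an NEQ protocol's
restraint leg is costed equal to its complex leg.  Recommended parameters:

| parameter | standard EQ | standard NEQ | minimum EQ | minimum NEQ |
|---|---|---|---|---|
| ensemble (complex / ligand) | 10 / 5 | 10 / 5 | 5 / 5 | 5 / 5 |
| replica length (ns) | 10 | 10 | 5 | 5 |
| transitions per replica | – | 50 | – | 25 |
| transition length fwd/rev (ps, complex) | – | 800 / 400 | – | 800 / 400 |
| λ-windows (complex / ligand) | 15 / 13 | – | 15 / 13 | – |

Escalation raises one complex-leg parameter at a time until both
reliability criteria pass: transitions per replica 50→75→100, then forward
transition length 800 ps→1 ns→2 ns (reverse at half, floored at 400 ps),
then ensemble size +5 to 100, then replica length ×2 to 100 ns; EQ skips
the first two.  Only the ordering and the caps (100 transitions, 2 ns) are
externally prescribed; the intermediate step values, the complex-leg-only
scope (the ligand-leg ensemble of 5 is already sufficient) and the 100 ns
replica cap (the longest duration studied) are package choices,
overridable through the escalation config.  Transition re-runs are costed
from scratch (no reuse of discarded transitions); exhausting all caps is
reported explicitly, since some systems genuinely need to breach them.

## Synthetic test bed

The ground-truth system is a 1-D harmonic oscillator with interpolated
stiffness k(λ) = (1−λ)k₀ + λk₁, for which ∂H/∂λ = ½(k₁−k₀)x²,
⟨∂H/∂λ⟩ = ½(k₁−k₀)·kT/k(λ) and ΔG = (kT/2)·ln(k₁/k₀) exactly.  Defaults in
tests use k₀ = 1, k₁ = 4 kcal/mol/Å² at 300 K (ΔG ≈ 0.4132 kcal/mol) with
the standard ensemble size 10 and 200 samples per window — a desk-scale
stand-in for the 10 ns/2 ps-sampling production protocol.

* `gaussian_work_set` draws W_f ~ N(ΔG + σ²/2kT, σ²) and
  W_r ~ N(−ΔG + σ²/2kT, σ²), which satisfies the Crooks relation exactly in
  distribution — a calibration target for the maximum-likelihood estimator
  at any dissipation σ²/2kT.
* `ou_switching_work` produces genuinely dissipative works: each
  transition starts from the exact initial-state Boltzmann distribution
  and propagates by exact overdamped Ornstein–Uhlenbeck updates in the
  instantaneous potential while λ switches linearly; work accumulates as
  Σ[H(λ_{i+1},x_i) − H(λ_i,x_i)].  Mean dissipation decreases
  monotonically with total switching time; the single-step limit
  reproduces the free-energy-perturbation identity.  Note that forward
  works of this system are χ²-shaped with support touching zero, so the
  forward and negated-reverse supports always interleave: the
  gap-shrinkage trend seen in real data as positive distances falling
  toward zero appears here as |distance| → 0 from the negative side, which
  is how the trend tests assert it.
* `inject_extremes` appends forward works ≥ 1001 kcal/mol to emulate the
  extreme-value pathology; `skewed_dg_ensemble` draws skew-normal ΔG
  ensembles with closed-form skewness for the moment diagnostics.

Every generator splits replica streams with `SeedSequence.spawn` and is
bit-reproducible for a fixed seed.

**What passing these tests shows — and does not.**  The synthetic bed
validates estimator mathematics, uncertainty calibration, convention
consistency and diagnostic monotonicity.  It does not emulate slow protein
conformational change, multiple binding modes, water-occupancy effects or
force-field error: agreement on the toy system is necessary, not
sufficient, for accuracy on real complexes — which is precisely why the
ΔG_conf^prot adjustment and the reliability thresholds exist.

## Numerical choices and degenerate inputs

* λ values in files must match schedule windows within 1e-9 (text
  round-trip safety); energies are uniformly kcal/mol, times ps, replica
  ids 1-based; k_B = 0.0019872041 kcal/mol/K (kT ≈ 0.59616 at 300 K).
* Root finding: Brent on ±10⁴ kcal/mol, |Δ| < 1e-8 kcal/mol.
* Single-sample replicas, empty directions after filtering, zero-variance
  moment inputs and non-rectangular (λ, replica) grids raise typed
  validation errors rather than returning NaN; non-finite numbers are
  rejected at report-writing time.
* Bootstrap SDs use the population form (ddof 0); the between-replica
  standard error uses ddof 1 over R replica estimates.
* The acceptance script's problem sizes (50 seeds × ensemble 10 × 200
  samples for TI; 10⁴ works per side for BAR; 10⁵ for Jarzynski; 5×10⁴ per
  side for the overlap check) are chosen so each closed form is resolved
  well inside its tolerance at interactive runtimes.

## Known limitations

* The TI variance treats λ-windows as independent; correlations between
  windows (shared starting structures) are not modelled.
* The analytic BAR standard error is asymptotic; at very small n or poor
  overlap the between-replica error is the more honest choice.
* The escalation model is a planning aid: it tracks parameter state and
  cumulative cost but does not launch simulations.
* Histogram overlap depends (mildly) on the bin rule; the rule is fixed
  and recorded so values are comparable across runs.
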