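# Methods

## The model and its assumptions

`gliokin` integrates four ordinary differential equations coupling an
intracellular insulin-signalling module to a scalar tumor-size law,
plus one algebraic conservation relation for the ligand pool. The
biological content, and the assumptions it encodes:

* **IGFI** is not given its own ODE. The total pool is conserved and
  partitioned between free ligand and the IGFI–IGFBP2 complex; the
  complex acts as a reservoir, and degradation of the complex
  implicitly returns ligand to the free pool. Receptor binding
  (IGFIR), ILK/integrin signalling and the VHL/PHD degradation
  machinery are not modelled explicitly — their kinetics are lumped
  into the fitted rate constants.
* **IGFBP2** is produced in a ligand-dependent, logistic fashion
  (capacity 1/k₂ ≈ 2500 nM), consumed and released by complex
  formation/dissociation, degraded at rate k_d, and promoted by HIF1α
  (the k₅ arm, standing in for an ILK-mediated path).
* **HIF1α** is degraded in proportion to the oxygen level (the
  lumped PHD/VHL route), produced basally through an
  oxygen-independent Hill term k₈H/(k₁₂ + k₉H), and driven by both
  free IGFI (k₆) and IGFBP2 (k₁₀). The k₁₀ arm is the scientific
  hypothesis the model exists to interrogate.
* **Growth** is a two-channel diameter law, dGD/dt = v₁ + k₁₁H: basal
  glucose-dependent growth plus a HIF1α-proportional channel. Volume
  follows from the sphere formula. There is no spatial resolution; O₂
  is a scalar held constant for the duration of a run.

Two unit conventions matter and are deliberate:

* Species carry heterogeneous units (nM for the IGF species, μM for
  HIF1α, μm for diameter) and the equations operate on the bare
  numeric values with **no conversion factors** — the fitted constants
  absorb all unit bridging. This is the only convention under which
  the bundled constants reproduce sensible trajectories.
* **O₂ enters as the percent number** (2–21), not a fraction. With
  O₂ = 21 and k₇ = 0.1176 the degradation term (≈2.47 hr⁻¹) dominates
  every HIF1α source, reproducing the absence of detectable HIF1α
  under normoxia.

One internal inconsistency in the source equations had to be resolved:
the complex balance as printed uses the *binding* constant k₃ for the
dissociation flux, while the IGFBP2 balance credits that same flux
with k₄ (and k₄ is named the dissociation rate). Mass balance between
the two pools requires equal-magnitude opposite fluxes, so the package
uses k₄ by default and offers `strict_printed_dissociation=True` for
the literal reading.

## Parameters and defaults

The bundled U87 and LN229 profiles share all signalling constants
(k₁ = 0.0452, k₂ = 0.0004, k₃ = 0.0002, k₄ = 0.0007, k₅ = 9.5495,
k₆ = 0.0001, k₇ = 0.1176, k₈ = 0.01057, k₉ = 0.0241, k₁₀ = 0.0002,
k₁₂ = 21, k_d = 3.92702) and initial concentrations (free IGFI
92.5 nM, IGFBP2 3.68 nM, complex 2.6 nM, HIF1α 1 μM); they differ only
in the growth channel — U87: v₁ = 2.601 μm/hr, k₁₁ = 21.6 μm/hr,
GD₀ = 170 μm; LN229: v₁ = 0.5779, k₁₁ = 179.55, GD₀ = 3200 μm. The
printed units of k₅ (hr⁻¹) and k₆ (nM⁻¹) do not dimension-check
against their terms' outputs; they are applied under the
numeric-value convention above without further interpretation.

Simulation spans follow the calibration experiments: "40 days" means a
960-hour horizon on an hourly grid; in-vitro runs use the day marks
24, 96, 120, 144 hr.

## Numerical choices

* Integration: LSODA (stiffness-switching), rtol 1e-8 / atol 1e-10,
  explicit output grids. The t = 0 row is pinned to the exact initial
  state. Negative excursions smaller than 1e-9 are clipped to zero;
  anything larger raises. Accuracy is cross-checked in the test suite
  against a fixed-step RK4 oracle (0.01 hr steps, 1e-4 relative over
  96 hr) and by tolerance-halving.
* The Hill term evaluates 0/0 (k₈H = 0 with k₁₂ = k₉ = 0) as 0 — the
  term is absent — and raises only for a genuinely singular
  denominator with nonzero numerator.
* Steady state is declared per species when
  |dX/dt|·t_final/max(|X|, 1e-12) < 1e-4 throughout the trailing 10%
  of the grid. The diameter grows without bound whenever v₁ > 0 and is
  reported but never flagged converged. Hypoxia fold-changes are
  computed against the steady state at the 21% control by default
  (`baseline="initial"` is available), on a 2000-hour horizon — the
  species settle within ~50 hours, so this is conservative.
* Fitting searches log₁₀-parameter space (the constants span five
  decades). GA defaults: population 50, 200 generations, binary
  tournament, SBX crossover (η = 15, p = 0.9), polynomial mutation
  (η = 20, per-gene rate 1/n), elitism 1, mandatory seed. Nelder–Mead
  refinement (fatol 1e-10, ≤5000 evaluations) is kept only if it does
  not worsen the objective. The objective is the weighted sum over
  series of SSE normalized by each series' total sum of squares about
  its mean, which makes μm, μm³, nM and relative-expression series
  commensurable; relative observables are matched through a
  per-evaluation least-squares scale factor. Solver failures map to a
  large finite penalty (1e12).
* Local sensitivity: SI = |GD_n − GD_o|/(C·T·Δk) with T the horizon in
  hours and Δk the multiplying factor. C ("maximum diameter at the
  final time point") is read as the maximum final diameter across the
  sweep being summarized, control included — the only reading that
  yields one shared normalizer per analysis; `normalizer="control"`
  gives the alternative. The canonical sweep covers 13 constants; k₁₂
  is excluded because it only re-parameterizes the same basal Hill
  term as k₉.
* Global sensitivity: Latin-Hypercube designs (scipy's sampler;
  the Latin property — exactly one sample per equal-probability
  stratum per dimension — is asserted in tests), log-uniform over
  0.1×–10× by default. Partial correlations are computed values-based
  by default with a rank-based (PRCC) option, via two independent
  routes (residual regression and the inverse joint correlation
  matrix) that must agree to 1e-8; the test suite additionally checks
  against an external statistics package. PCA standardizes the
  log-scaled parameter columns with the response appended.
* Knockouts zero a single constant. k₇, k₈, k₉ and k₁₂ are excluded:
  they parameterize the basal production and oxygen-dependent
  degradation of HIF1α, which is ubiquitous in normal cells and not a
  tumor-specific target. The k₁₀-vs-k₆ contrast is reported both as a
  diameter-growth ratio and a volume-growth ratio (growth = final −
  initial, so the shared initial size cancels); the diameter-growth
  reading is the headline number.

## Synthetic data: what it emulates and what it does not

The generators reproduce the *structure* of the calibration
experiments — hanging-drop spheroid diameters on days 1/4/5/6 averaged
over ~20 droplets; xenograft volumes on a daily 40-day grid averaged
over 10 animals; IGFBP2 time courses after a 0 or 100 nM ligand bolus
(0–48 hr, 6-hr sampling); and a steady-state HIF1α-vs-O₂ curve
normalized to its maximum. They do not reproduce the original
measurements' numbers: the underlying datasets exist only as plotted
points, and real error magnitudes are unrecoverable, so noise defaults
to multiplicative lognormal with 5% relative sd — an explicit
placeholder chosen for positivity and scale invariance. Passing
recovery tests therefore demonstrate that the pipeline is correct and
the constants are identifiable under the stated designs, not that the
bundled constants are the true optima of the original data.

Each generated series embeds its generating environment (O₂, ligand
pool, bolus) in its metadata/overrides so that a fit replays exactly
the conditions that produced the data.

Identifiability drives the choice of dataset per constant in the
recovery harness: v₁ and k₁₁ are growth constants and are recovered
from growth series; k_d from the IGFBP2 time courses; k₅ from an
IGFBP2 time course generated at 2% O₂, because at normoxia HIF1α sits
near 0.004 μM and the HIF1α→IGFBP2 arm carries essentially no signal;
and k₇ from the HIF1α-vs-O₂ curve *paired with* growth data, because
the relative curve fixes only the shape in O₂ — its free scale factor
absorbs an overall 1/k₇ — while growth pins the absolute HIF1α scale.

## Known limitations and reference-value caveats

* The sensitivity index is mathematically bounded: since both final
  diameters are ≤ C, SI ≤ 1/(T·Δk) = 1.04e-4 for T = 960 hr, Δk = 10.
  Published index values for this model family quote a top value of
  2.50e-3, which exceeds that bound and equals exactly 1/(40·10) —
  attainable only with T counted in days *and* a perturbed run that
  dwarfs every other diameter. Under the equations as implemented
  (and under every O₂/unit convention we analyzed), a 10× increase of
  k₈ shifts the HIF1α balance by well under 1% and cannot produce such
  a run. The package therefore reports k₈ among the *least* influential
  constants, while reproducing the remainder of the published ranking
  (k₁ ≈ k₁₁ > k₁₀ > k₆ > v₁ > … with k₄/k₉ last).
* Likewise, the hypoxic steady-state fold-changes computed here
  (HIF1α ≈ 10.7×, IGFBP2 ≈ 1.03× at 2% vs 21% O₂; the ratio is
  essentially k₇·21/k₇·2 weakly modified by feedback) differ from the
  reference values of 7× and 1.25×, and the U87 knockouts are not
  growth-neutral (final-volume changes of 27% / 7.6% for the k₁₀/k₆
  knockouts) because U87 shares all signalling constants with LN229
  and HIF1α still contributes ~11% of its growth rate. These
  quantities are computed and reported as-is; no parameter or
  tolerance was adjusted toward the reference numbers.
* The model has no spatial oxygen or nutrient gradients, no explicit
  receptor kinetics, and an unbounded linear growth law; it is a
  minimal hypothesis-testing scaffold, not a predictive tumor-growth
  simulator.
* Partial inhibition (dose–response) is not a first-class experiment;
  knockouts are all-or-nothing, though intermediate values can be
  explored through user-edited profiles.
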