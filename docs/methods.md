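# Methods

`fitscape` models and analyses a genetically homogeneous yeast population
carrying a bistable positive-feedback circuit in which an ATc-inducible
transactivator (rtTA) drives its own expression and that of a bifunctional
reporter/resistance fusion protein (yEGFP::ZeoR).  Fluorescence F is the
per-cell proxy for resistance-protein level.  Two environmental axes matter:
the inducer ATc (C, ng/ml), which both populates the high-expression state
and poisons cells through active rtTA, and the DNA-damaging antibiotic
Zeocin (Z, mg/ml), against which ZeoR protects by irreversible binding.

The pipeline runs: single-cell event tables → gated, smoothed fluorescence
distributions → marginal fitness functions → cellular-current memory
estimates → two-state switching dynamics → fitness landscapes over (C, Z).

## Cytometry processing

Events are gated on (log SSC, log FSC) with a two-dimensional Gaussian fit;
events whose fitted density is at least 90% of the maximum are kept.  For
Gaussian scatter this retains 10% of events (density ≥ q·max is equivalent
to Mahalanobis² ≤ −2 ln q, a χ²₂ statement), i.e. it is a deliberately
small gate centred on the modal cell size and granularity.

Fluorescence is binned into 256 log-spaced half-open bins over [1, 10⁴]
a.u. (the moving average runs over log-axis bins, the usual flow-cytometry
convention) and smoothed with a centred 32-bin moving average whose window
shrinks at the histogram edges.  Per-bin raw counts are close to Poisson,
so each smoothed count is treated as normal with variance equal to its
expectation divided by the window length.  Bimodality is declared when some
interior minimum of the smoothed histogram lies more than four standard
deviations below both flanking maxima under that variance model, with
z = (μ_max − μ_min)/√((μ_max + μ_min)/32); among accepted valleys the
classification threshold θ maximises the product of the two z-scores, ties
breaking toward lower fluorescence.  Unimodal samples fall back to the
constant reference threshold of 50 a.u.  Cells with F ≥ θ are "high"
(the boundary is assigned to the high state).  The summary CV uses the
population-SD convention (ddof = 0, configurable).

## Growth and fitness

Fitness is the exponential growth rate of cell counts.  Two estimators are
provided: per-interval rates ln(N_{k+1}/N_k)/Δt averaged with a standard
error, and the OLS slope of ln N versus t.  Drug-exposure curves use the
slope over the last six of seven 12-hourly samples to skip the transient
after drug addition.  Model quality is scored with R² about the observed
mean; negative values are reported as-is because a misspecified model can
underperform the mean.

## Instantaneous fitness functions

Zeocin toxicity (γ₁).  Extracellular Zeocin exchanges freely across the
membrane at rate h_Z = 0.5, binds unbound ZeoR irreversibly at rate s, and
bound complexes turn over at the ZeoR dilution rate d = 0.25.  At steady
state, with the total pool constrained by fluorescence (F = R_u + B), the
free intracellular Zeocin Z_i solves h_Z(Z − Z_i) = s·Z_i·R_u with
R_u = F/(1 + s·Z_i/d) — a quadratic in Z_i whose admissible root is
evaluated in a cancellation-free form (the residual check in the tests
holds to ~1e-16).  Damage accrues with Z_i and is repaired at a constant
rate, giving γ₁ = 1/(1 + χ·Z_i^φ).  Defaults: φ = 1.182, χ = 0.5028×10⁻⁷,
s = 1.2732×10⁶.

rtTA toxicity (γ₂).  ATc binds rtTA saturably with scale β = 5.8 ng/ml;
the cost of active rtTA is proportional to expression:
γ₂ = 1/(1 + α·(F/F_ref)·C/(β + C)), with α = 936.

Joint stress uses Bliss independence, γ = γ₁·γ₂, reflecting the unrelated
mechanisms of DNA damage and transcription-factor squelching.  The
combination rule is isolated behind `gamma_joint` so alternative
interaction models can be swapped in.

Unit calibration.  The mass-action model is written in molecule-like
concentration units while the data arrive in mg/ml and fluorescence a.u.;
no published unit convention connects them, so the package fixes two
explicit calibration constants, `zeocin_scale = 5×10⁶` per mg/ml and
`fluorescence_scale = 1×10⁵` per a.u., chosen once so that the default
(φ, χ, s, h_Z, d) produce a full protective/toxic dynamic range over the
experimental grid: uninduced cells at 2 mg/ml Zeocin retain ~10% of
maximal fitness while high-mode cells (~500 a.u.) are fully protected.
Similarly γ₂ normalises fluorescence by `f_ref = 3×10⁵` a.u. so that the
default α imposes ≈50% instantaneous cost on high-mode cells at 10 ng/ml —
consistent with a moderate, not catastrophic, population-fitness decline
under full induction.  Normalising instead by the histogram maximum
(10⁴ a.u.) would make rtTA toxicity so strong at the default α that high
expressors would grow more slowly than antibiotic-poisoned low expressors
at every inducer level, abolishing the rescue effect the model exists to
describe.  All three constants are ordinary dataclass fields.

Maximal fitness defaults to g₀ = 0.35 h⁻¹ (a two-hour doubling time,
typical of budding yeast in rich conditions).

Parameter fitting minimises squared error between fast-switching
predictions and measured marginal fitness values with Nelder-Mead in
log-parameters from five spread starting points; h_Z and d stay fixed.
From a single marginal Zeocin curve the triple (φ, χ, s) is
ridge-identifiable: the prediction curve is reproduced essentially exactly
while s individually is pinned only to a few percent.  The tests therefore
check the prediction curve tightly and the parameters at ridge-appropriate
tolerances.

## Cellular currents and memory

Within a stationary distribution, cells drift down in fluorescence as
growth dilutes the stable reporter and are pushed back up by expression
noise.  The downward current through θ is the dilution flux

    I_H→L = θ · g₀γ₂(θ, C) · ∂N/∂F |_{θ⁺},

with the density taken from the first smoothed bin above θ.  The dilution
rate uses γ₂ only because stationary distributions are measured without
antibiotic.  When instantaneous fitness varies with F, stationarity forces
a compensating net upward flux equal to the surplus cell production below
the threshold, net = N·∫_{F<θ}(g(F) − g_T)p(F)dF (trapezoidal quadrature;
g_T is the same-quadrature weighted mean so the full-range flux vanishes
identically); then I_L→H = I_H→L + net.  Memories follow as
τ_H = N_H/I_H→L and τ_L = N_L/I_L→H.  Empty bins near θ are filled by the
moving-average smoothing (or a 2-bin Gaussian kernel when no smoothing is
present), which can only raise the valley density, so τ_H is flagged as a
conservative lower bound whenever the raw bin above θ was empty.

Validation uses an independent single-cell oracle: a two-state promoter
with deterministic production–dilution dynamics within each state, where
threshold crossings and sojourn times are measured directly.  The estimator
reproduces counted crossings within ~15% and measured residence times
within ~20–25% on well-resolved inputs (10⁵ events, 256 bins); the residual
bias comes from evaluating the transport speed as θ·g rather than
(θ − F_floor)·g and from smoothing across the valley.

## Two-state population dynamics

(N_L, N_H) evolve linearly with rising rate r = I_L→H/N_L, falling rate
f = I_H→L/N_H and state division rates g_L, g_H.  The dominant eigenvalue
a₁ of [[g_L − r, f], [r, g_H − f]] is the asymptotic population fitness;
the closed-form spectral solution also gives R(t) = N_L/N_H for arbitrary
initial compositions.

Switching rates are fitted to cell-sorting relaxation experiments: the
log-ratios of high- and low-sorted arms, normalised pointwise by the
unsorted control and rescaled by its mean, are jointly least-squares fitted
in (log r, log f) with Nelder-Mead from nine starting points; each arm's
initial composition comes from its measured t = 0 ratio; g_L and g_H are
supplied from the fitness model evaluated at the subpopulation mean
fluorescences.  Confidence intervals use a parametric bootstrap: all three
arms are regenerated from the fitted model with multiplicative log-normal
noise at the residual-estimated level and refitted.  A resampling bootstrap
over time points was rejected because the dominant uncertainty enters
through quantities shared across the whole series — the measured t = 0
composition and the unsorted-arm normalisation — which resampling cannot
vary, producing intervals several-fold too narrow.

Lineage statistics ignore fitness: dp_H/dt = r(1 − p_H) − f·p_H, whose
window average has a closed form.  Populations and lineages disagree
whenever g_L ≠ g_H; with fitter low expressors, snapshots under-represent
the high state relative to lineage time-averages.

Fluctuating environments are integrated piecewise (one spectral propagator
per episode) in log-population coordinates, so arbitrarily long horizons
cannot overflow; random schedules draw exponential episode durations and
average the realised log-growth over replicates.

## Landscapes

The fast-switching predictor weights γ(F, C, Z) by the antibiotic-free
distribution p(F) at each inducer level.  The memory-aware predictor builds,
per inducer level, a two-state system with r = 1/τ_L(C), f = 1/τ_H(C) and
division rates g₀γ evaluated at the smoothed-histogram mean fluorescences
of the low and high subpopulations, and reports a₁.  Memory at inducer
levels missing from the table is log-linearly interpolated with a warning.
The Zeocin-free distributions parameterise the expression structure at all
Z; selection enters only through the division rates.  The sweet spot is the
argmax of a₁ along C at fixed Z, with sharpness the negative discrete
second difference at the peak.

Because the fitness-corrected currents make each measured distribution a
fixed point of its two-state system, the memory-aware and fast-switching
predictions coincide (to a few tenths of a percent) at Z = 0 and diverge
under antibiotic, where slow switching protects the high-expressor lineage
from re-equilibration.

## The synthetic study system

No single-cell or growth data are shipped; every input is generated with
known ground truth.  The stationary fluorescence model is a two-component
log₁₀-normal mixture — low mode 3 a.u. (σ = 0.25 decades), high mode
500 a.u. (σ = 0.20 decades) — with the high fraction following a Hill
curve f_H(C) = 0.8·C²/(60 + C²): unimodal without inducer, first bimodal
near 1–2 ng/ml, balanced at 10 ng/ml, saturating near 80%.  Scatter
channels are correlated log-normal.  Growth curves are exponentials with
unit-mean multiplicative log-normal count noise (default CV 5%, a
hemocytometer-scale error) sampled every 12 h, matching the resuspension
schedule that keeps cultures in log phase.  Sorting experiments follow the
closed-form two-state solution from sorted initial compositions (default
purity 0.99; a perfect sort is capped at 1 − 10⁻¹² to keep ratios finite).

The birth–switch population simulator is an exact event-driven (Gillespie)
realisation of the four reactions (two divisions, two switches); population
sizes of ≤10⁵ make exact simulation affordable.  When a cap is set, the
culture is binomially thinned back to its target size at record times and
the removed factor accumulates so the undiluted log-count remains
available — the in-silico analogue of resuspension.  Expected trajectories
match the two-state ODEs (verified at 3-SE tolerance); lineage holding
times are exponential with means 1/r and 1/f.

What the generators do not emulate: instrument artefacts (autofluorescence,
spectral spillover, doublets), cell-cycle and size structure beyond the
scatter gate, intracellular expression kinetics (promoter states, mRNA
bursts — the two-state birth–switch process stands in for them), death as
distinct from growth arrest, and lag or stationary growth phases.  Passing
tests therefore certify the estimators and the model machinery on data
satisfying the model's own assumptions, not the wet-lab performance of the
assay.

## Benchmark problem sizes and numerical choices

The landscape benchmark uses 11 inducer levels (0–20 ng/ml in steps of 2)
at 2 mg/ml Zeocin, 10⁵ events per distribution, and birth–switch
simulations started from 10⁴ cells at the stationary antibiotic-free
composition, run for 72 h with dilution above 2×10⁴ cells and fitness read
from the last six samples.  At these sizes the memory-aware eigenvalue
predictions explain ≳99% of the simulated fitness variance while the
fast-switching predictor, blind to selection between states, scores far
below zero.  Recovery studies use 20 noisy replicates (count-noise CV 2%
for dose–response fitting, ratio-noise CV 5% for sorting fits); the
bootstrap coverage study is scaled to 15 replicates × 80 draws.

Degenerate inputs are handled explicitly: defective (repeated-eigenvalue)
rate matrices fall back to the matrix exponential; zero currents yield
infinite memory flags rather than exceptions; r = f = 0 lineages are
returned degenerate with a warning; unimodal distributions route to the
constant threshold; thresholds at the histogram edge and singular scatter
covariances raise errors.

## Known limitations

The γ₁/γ₂ functional forms are semi-phenomenological reconstructions
(saturable binding, proportional toxicity, constant-rate repair); their
unit calibrations are package choices, so absolute memory values depend on
bin width and smoothing and should be read comparatively, not as hours-true
estimates — the τ_H of sparse high tails in particular is a lower bound.
The reciprocal-memory identification r = 1/τ_L, f = 1/τ_H treats threshold
residence as a two-state sojourn, which is exact only when within-state
relaxation is fast compared with switching.  Joint identifiability of the
Zeocin triple from one marginal curve is not guaranteed (only the curve
itself is).  The two-state reduction ignores within-state fluorescence
dynamics under drug, so its predictions degrade when selection reshapes a
distribution faster than switching re-equilibrates it.
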