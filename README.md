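# fitscape

Environmental fitness landscapes of a bistable drug-resistance gene
circuit: from single-cell fluorescence distributions and growth curves to
switching rates, nongenetic memory, and memory-aware predictions of
population fitness across inducer × antibiotic conditions.

## The problem

A positive-feedback circuit in budding yeast couples an ATc-inducible
transactivator (rtTA) to a fluorescent resistance fusion protein
(yEGFP::ZeoR).  Above a low inducer threshold the population splits into
coexisting low- and high-expressing states: the high state is protected
from the DNA-damaging antibiotic Zeocin but pays an rtTA-toxicity cost.
Predicting how well such a population grows at an arbitrary combination of
inducer C and antibiotic Z requires more than the expression distribution —
it requires knowing how long individual cells *remember* their state.

`fitscape` is aimed at quantitative/systems biologists studying stochastic
phenotype switching, bet hedging and nongenetic drug tolerance.  It
implements:

- **Cytometry processing** — elliptical scatter gating, log-binned
  histograms, 32-point moving-average smoothing, a z-test bimodality
  criterion (valley > 4 SD below both peaks under a Poisson/window variance
  model) and threshold selection by maximal z-score product.
- **Marginal fitness functions** — γ₁(F, Z) from a steady-state
  intracellular-Zeocin binding model and γ₂(F, C) for saturable
  rtTA toxicity, combined by Bliss independence, γ = γ₁γ₂.
- **The fast-switching predictor** — g_T = g₀ Σ_F γ(F, C, Z) p(F), which
  assumes the distribution p(F) survives selection unchanged.
- **Cellular currents** — within a stationary distribution the downward
  flux through a threshold θ is the dilution flux
  I_H→L = θ·g(θ)·∂N/∂F|θ⁺; fitness differences force a compensating net
  upward flux.  Memories follow as τ_H = N_H/I_H→L, τ_L = N_L/I_L→H.
- **Two-state population dynamics** — d/dt (N_L, N_H) =
  [[g_L − r, f], [r, g_H − f]] (N_L, N_H), solved in closed form; the
  dominant eigenvalue a₁ is the overall population fitness.  Switching
  rates (r, f) are fitted to cell-sorting relaxation time courses with
  parametric-bootstrap confidence intervals.
- **Landscapes** — memory-aware fitness surfaces over (C, Z), the
  drug-resistance "sweet spot", model comparison by R², selection
  reshaping of the subpopulation split, and fluctuating-environment
  simulation.
- **Synthetic data generators** — event tables, growth curves, sorting
  experiments and exact (Gillespie) birth–switch populations/lineages
  with known ground truth, so the whole pipeline is testable end to end.

See `docs/methods.md` for the model details, calibrations and limitations.

## Worked example

```python
import fitscape as fs

# 1. stationary events at 10 ng/ml inducer, no antibiotic
events = fs.generate_stationary_events(fs.mixture_for_atc(10.0, n_events=100_000), seed=1)
dist = fs.smooth_histogram(fs.build_histogram(events))
res = fs.bimodality_test(dist)
print(f"bimodal: {res.is_bimodal}, threshold = {res.selected_threshold:.1f} a.u.")
print(f"N_L/N_H = {fs.classify_subpopulations(events, res.selected_threshold).ratio:.3f}")

# 2. cellular memory from the fitness-corrected currents
row = fs.memory_dose_response({10.0: dist}).iloc[0]
print(f"tau_L = {row.tau_low:.1f} h, tau_H = {row.tau_high:.0f} h")

# 3. switching rates from a sorting-relaxation experiment
g_low = fs.DEFAULT_G0 * float(fs.gamma2(3.2, 10.0))
g_high = fs.DEFAULT_G0 * float(fs.gamma2(500.0, 10.0))
truth = fs.TwoStateParams(r=28.5e-3, f=0.7e-3, g_low=g_low, g_high=g_high)
data = fs.generate_sorting_experiment(truth, purity=0.99,
    config=fs.SimConfig(seed=2, duration_h=120.0, noise_cv=0.05))
fit = fs.fit_switching_rates(data, g_low, g_high, n_boot=200, seed=0)
print(f"r = {fit.params.r*1e3:.1f}e-3 1/h, f = {fit.params.f*1e3:.2f}e-3 1/h")

# 4. lineage statistics at the fitted rates
p = fs.TwoStateParams(r=fit.params.r, f=fit.params.f, g_low=0.3, g_high=0.3)
print(f"asymptotic lineage occupancy: {100*fs.lineage_occupancy(p):.1f}%")
print(f"30-h window from p0=0.45:     {100*fs.lineage_occupancy(p, 0.45, 30.0):.1f}%")
```

prints

```
bimodal: True, threshold = 47.8 a.u.
N_L/N_H = 1.004
tau_L = 11.6 h, tau_H = 23283 h
r = 28.1e-3 1/h, f = 0.47e-3 1/h
asymptotic lineage occupancy: 98.3%
30-h window from p0=0.45:     62.5%
```

Reading: at balanced induction the two subpopulations are equal (ratio ≈ 1)
with the classification threshold falling in the inter-mode valley near
50 a.u.  The high state is orders of magnitude stickier than the low state
(τ_H ≫ τ_L), which the sorting fit confirms independently (r ≫ f).  A
single-cell lineage therefore spends almost all of the long run high — even
though population snapshots stay balanced, because low expressors divide
faster and replenish their half.

A command-line interface mirrors the library
(`fitscape simulate|cytometry|fitness|memory|two-state|landscape`, see
`fitscape --help`).

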