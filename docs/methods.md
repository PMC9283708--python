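# Methods

## Model

Cells are unit-diameter discs performing overdamped Brownian motion on an
unbounded plane, with three coupled processes per time step, applied in a
fixed order:

1. **Death.** Each cell is removed independently with probability γδt
   (uniform draw compared against the rate–step product).
2. **Birth.** Each surviving pre-existing cell proliferates independently
   with probability Γδt. The daughter is placed at distance exactly one
   diameter from the mother at a uniform angle θ ∈ [0, 2π); if the site
   violates the overlap rule the angle is redrawn, up to `max_retries`
   (default 100) times, after which the birth is rejected. Daughters do not
   divide within the sweep that created them, but they do block later
   placements.
3. **Motion.** Every cell — including newborns and a lone founder — takes
   one Euler–Maruyama step `drift·δt + √(2Dδt)·η`. The drift is the
   screened chemotactic attraction: the stationary chemical field of point
   sources with linear degradation is `φ(r) = α₀ Σ_j K₀(|r−r_j|/σ)` in 2-D,
   and its gradient gives a central pair force of magnitude
   `(Δ/σ)·K₁(r/σ)` on each cell, directed toward the other cell. Cells are
   updated **sequentially in id order**, each later cell seeing the already
   updated positions of earlier ones. An inadmissible proposal redraws only
   its Gaussian noise (the drift is configuration-determined); after
   `max_retries` failures the cell keeps its position for that step.

Overlap rule: cells are compressible, so overlaps shallower than 0.2
diameters are tolerated — admissibility means center distance ≥ 0.8,
boundary inclusive. This is the only monotone reading of "overlap less
than 0.2 of cell size" for unit discs.

All quantities are dimensionless: lengths in cell diameters
(ℓ = 10 µm), times in proliferation cycles (τ = 10⁴ s). At those scales a
cell diffusion coefficient of 10⁻² µm²/s maps to D = Dτ/ℓ² = 1, and the
attraction strength aggregates the motility, emission rate and cycle time
into Δ = µα₀τ/ℓ². The `DimensionalMapping` record documents this
bookkeeping; the dynamics never touch dimensional numbers.

### Parameters and defaults

| parameter | symbol | default | meaning |
|---|---|---|---|
| attraction strength | Δ | (free) | drift coefficient; Δ⁻¹ acts as temperature |
| attraction range | σ | 1.5 | screening length of the chemical field |
| birth rate | Γ | 1 | per cycle |
| death rate | γ | 0.1 | per cycle |
| diffusion | D | 1 | dimensionless |
| time step | δt | 10⁻³ | Euler–Maruyama step |
| steps | — | 40 000 | 40 proliferation cycles (full scale) |
| overlap floor | — | 0.8 | minimum admissible center distance |
| contact threshold | — | 1.0 | network link distance |
| force cutoff | — | 8σ | see below |
| retries | — | 100 | for births and moves |

Γ > γ is required for net growth; the validator deliberately does not
enforce the inequality so that degenerate settings (immortal single cells,
certain-death stress tests) remain expressible.

## Numerical choices

* **Force cutoff.** K₁ decays exponentially, so pair contributions beyond
  8σ (relative size ≲ K₁(8)/K₁(1) ≈ 2×10⁻⁴) are dropped. The cutoff is
  configurable; an exact all-pairs evaluation (`net_forces(...,
  method="brute")`) is kept for cross-checking, and the truncation obeys
  the analytic bound N·(Δ/σ)·K₁(r_c/σ) verified in tests.
* **Compiled kernel.** The motion sweep is a numba kernel. Pair forces are
  evaluated through a linear-interpolation table of (Δ/σ)K₁(r/σ)/r built
  from scipy's K₁ on [0.2, cutoff] with 0.002 spacing (interpolation error
  ~10⁻⁵ relative; pair separations are bounded below by the overlap floor,
  so the domain is never left). Neighbor gathering uses a uniform grid of
  bin size 3 rebuilt each sweep from pre-sweep positions; admissibility
  candidates are cells currently within 3 diameters, enough to cover any
  realistic proposal, and proposals displacing a cell by more than 1
  diameter (noise is ~0.045) fall back to a brute-force check.
* **Randomness.** One `numpy` Generator per run drives death and birth
  draws and seeds the kernel's per-sweep RNG, so runs are bit-reproducible
  from the seed. Replicate seeds are `seed + attempt_index`; sweep grid
  points use disjoint seed blocks.
* **Contact threshold fuzz.** Links require center distance ≤ 1 + 10⁻⁹.
  The absolute fuzz makes lattice fixtures built at spacing exactly 1
  robust to floating-point roundoff; it cannot create spurious degree-7
  configurations because seven neighbors at distance ~1 would need angular
  separations below 60°, which the hard-core floor forbids.
* **Derivatives and peaks.** Sweep curves are differentiated by plain
  central differences (one-sided at the ends) with an optional centered
  moving average (off by default, recorded in the report). For measures
  that decrease with Δ⁻¹ (P₆, transitivity, ⟨k⟩) the transition is the most
  negative derivative, located as the maximum of −dy. Ties break toward
  the lower Δ⁻¹; a monotone derivative yields a "no peak" result rather
  than an error. Peak uncertainty is reported as ± one grid spacing.
* **g(r) convention.** `pair_distribution` implements the literal
  ordered-pair-count normalization (1/N per unit distance, total mass
  N − 1), *not* the density-normalized liquid-state RDF; the convention is
  recorded on the histogram object. Replicate averaging is left to the
  caller (per-replicate histograms are simply averaged bin-wise).
* **Power-law slopes.** Component sizes are pooled over replicates and
  binned geometrically (factor 2). Counts are divided by bin width, so a
  density ∝ s^a fits slope a; the fit is ordinary least squares on the
  log-log points with zero-count bins excluded, and requires at least
  three usable points. More elaborate estimators (MLE, KS-optimized
  cutoffs) are out of scope.
* **Degenerate inputs.** Measures on an empty network raise
  `EmptyNetworkError`; an all-isolated final configuration contributes
  NaN to sweep aggregation (NaNs are excluded from means); coincident
  centers and queries at a source center raise, since K₀/K₁ diverge.

## Problem sizes used by the tests and the acceptance script

The full-scale study conditions are 40,000 steps × 20 replicates per Δ on a
fine Δ⁻¹ grid. The package's automated checks run reduced versions chosen
to keep the whole suite in the minutes range on one core:

* phase-trend comparison: 10,000 steps, 5 surviving replicates at
  Δ ∈ {2.5, 0.5} (Δ⁻¹ = 0.4, 2.0);
* criticality slope: 10,000 steps, 10 surviving replicates at Δ = 1.5;
* integrator checks: a noise-free attracting pair over 5 time units
  against an adaptive Runge–Kutta oracle, and 10⁴ noninteracting cells
  over 10³ steps against the free-diffusion closed form.

At these reduced sizes tumors reach ~150 (Δ = 2.5) to ~800 (Δ = 0.5)
cells — an order of magnitude smaller than at full scale.

## What the reduced scale does and does not show

The qualitative phase structure is robust at reduced scale: final network
size, P₂ and ρ_c increase with Δ⁻¹ while P₆, ⟨k⟩ and transitivity
decrease, with clear (>3 SE) separation between the strong- and
weak-attraction states after only 10 cycles.

The component-size distribution at Δ = 1.5 does **not** come out
scale-free under this implementation. After 10 cycles a tumor consists of
one compact main body (~100–350 cells) plus a dust of dimers and trimers:
the pooled final-configuration histogram is bimodal with an empty gap
between roughly 8 and 128, and the log-binned fit gives a slope near
−1.4. This is not a small-system artifact: at the full study length
(40,000 steps, final populations of 2,500–3,200 cells over 10 replicates)
the histogram is still giant-plus-dust and fits −1.25. Nearby strengths
(Δ = 0.8–1.2) behave the same way, and pooling sizes over time snapshots
instead of final configurations fills the gap but still fits only −1.47.
In other words, the simulated Δ = 1.5 state here is a cohesive liquid
whose main body rarely sheds mid-sized fragments; a critical exponent of
−2 is not reproduced by final-configuration pooling at any scale we
measured. The dynamics are sensitive to procedural details that the
verbal simulation recipe leaves open (sequential update order, what is
redrawn on a rejected move, whether newborns move in their birth step);
these are fixed here by the documented interpretations above. The
acceptance script reports the exponent actually measured under the
reduced conditions; the estimator itself is validated independently
(exact synthetic s⁻² recovered to 10⁻⁶, noisy power laws to ±0.1).

## What the synthetic fixtures emulate

`fixture_hexagonal` reproduces the close-packed solid (every interior node
at the kissing degree 6); `fixture_hardcore_gas` the dispersed gas (sparse
hard-core configurations, empty or near-empty networks);
`fixture_clusters` the fragmented liquid (k well-separated compact
clusters → exactly k components). They are used as analytically solvable
oracles for the network layer. None of them contains the birth/death
history, compression heterogeneity, or fractal boundaries of simulated
tumors, so passing fixture tests validates the *measures*, not the
*dynamics* — the dynamics are validated separately against the diffusion
and pair-collapse closed forms and by the phase trends above.

## Known limitations

* Two-dimensional only; no cell polarity, phenotype switching (e.g. EMT),
  or mechanics beyond isotropic overlap rejection.
* The chemical field is stationary (fast-diffusion limit); no
  time-dependent chemotaxis.
* The sequential one-by-one update makes the integrator weakly order
  dependent at O(δt); this matches the stated simulation procedure but
  differs from a simultaneous update at finite δt.
* Full-scale transition-peak localization (40,000 steps × 20 replicates ×
  fine grid) takes hours on one core and is not part of the automated
  suite; the machinery is exercised on synthetic curves with the measured
  curve shapes instead.
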