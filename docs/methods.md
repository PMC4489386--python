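# Methods

This note records the models the package implements, the conventions and
numerical choices behind them, what the synthetic generator does and does not
emulate, and where the design was genuinely open.

## Movement model

A two-fix Brownian bridge describes space use between consecutive GPS fixes.
For fixes **a** at time 0 and **b** at time *T* the utilization distribution
(UD) is

UD(z) = (1/T) ∫₀ᵀ N(z; **a** + α(**b** − **a**), σ²(t)·I) dt,
σ²(t) = T·α(1−α)·σ₁² + ((1−α)² + α²)·σ₂², α = t/T.

Conventions that matter:

- **Time unit is hours.** σ₁ is in m·h^−1/2, so its numeric value depends on
  this choice; the same physical movement expressed with *T* in seconds
  makes σ₁ sixty times smaller (√3600). The adehabitat-style estimates of
  ~5 that circulate in the bear literature use seconds; in hour units the
  equivalent magnitude is ~300. Both scales appear in our tests: strict
  parameter-recovery experiments run at σ₁ = 5 (any scale is equally valid
  for a self-consistency check), while the synthetic campaign uses
  σ₁ = 300 m·h^−1/2 so that bridges have realistic, landscape-scale extent.
- σ₂ is the GPS location-error SD, default 5 m, applied at both endpoints
  (the (1−α)² + α² term). Fixes are pre-filtered at PDOP < 10 (strict).
- The time integral is a midpoint rule with 100 nodes by default. Against
  adaptive quadrature the default grid is accurate to ~10⁻³ relative at
  interior points; the integrand develops a boundary layer only exactly at
  the fixes themselves. Tests pin both facts.
- Per-cell mass is density at the cell centre × cell area, **never
  renormalized**. The automatically sized grid (margin = 6 × max positional
  SD) keeps edge truncation below 10⁻³; an explicitly undersized grid raises
  a truncation error rather than silently rescaling. Cell-centre quadrature
  can overshoot a total of 1 by ~10⁻⁸ on narrow UDs; that slack is
  discretization error, not created mass.
- Grid resolution defaults to 10 m, matching nominal GPS precision; the
  window-scan stages use 20–25 m cells and 40–50 time nodes, which changes
  habitat compositions by less than the landscape's stand size.

**σ₁ estimation** uses the alternate-fix likelihood: every odd-indexed
interior fix is an observation of the bridge between its two neighbours, and
the summed log transition density is maximized over a search interval by a
400-point geometric scan refined with bounded scalar minimization
(deterministic, resolution ≪ 0.01 map units). A maximum at an interval
boundary is flagged, not raised — a straight-line constant-speed track
legitimately drives σ₁ to the lower bound. Steps across flagged schedule
gaps (Δt > 1.5 × the nominal 2-h interval) contribute no triples, and no
bridge is ever built across them: the two-hour bridge model is not
calibrated for six-hour steps.

**Isopleths.** "The 75% ellipse" is the smallest set of cells, taken in
decreasing mass order, whose cumulative mass reaches 0.75 — the home-range
convention — not cells whose individual value exceeds 0.75 (which would
essentially always be empty). Cell sets are dissolved into polygons along
exact cell boundaries; optional one-pass simplification at one cell width is
off by default because bit-reproducibility beats cosmetics. On a fine grid
the 75% region of an isotropic Gaussian matches the closed form
−2πσ²ln(0.25) within 5%.

## Backward windows and the transit scan

A scat site's **departure point** is the earliest fix within 20 m of the
site (≈ two GPS precision radii); if none is inside the buffer the nearest
fix is used with a distance warning. Behind the departure point, a step
qualifies for window (h_from, h_to) when its **end lag** — departure time
minus step end — lies in [h_from, h_to] and the step starts within a 24-h
lookback (the twelve previously recorded 2-h fixes). This convention
reproduces the protocol's counts: window (10, 16) yields the four bridges
ending 10, 12, 14 and 16 h back; window (0, 24) yields twelve.

Qualifying bridges' 75% regions are **dissolved into one region** (geometric
union) and a single habitat composition is computed, rather than averaging
per-bridge compositions: the quantity of interest is the region plausibly
used, and overlap between consecutive bridges should not be double-counted.
The union convention makes composition invariant to bridge order and
monotone in window width; both are tested.

The **transit window** is selected by scanning candidate windows and keeping
the one maximizing the diet variance explained by the first two CCA axes of
the habitat constraint. The library default candidate family is every
contiguous window on the 2-h lattice with width ≥ 4 h inside [0, 24]; the
analysis scripts and validation runs scan the ten width-6 windows
(0,6) … (18,24), a one-parameter screening design under which "one 2-h
shift" is unambiguous. Ties prefer the narrower window, then the earlier
start. Note a structural ±2 h ambiguity: a step *ending* at lag h covers
movement back to lag h + 2, so a true ingestion support of [10, 16] h is
almost equally well covered by the (8, 14) and (10, 16) windows; recovery
experiments accept one 2-h shift accordingly.

## Scat macroscopy model

Per scat: raw_j = Σ_s w_s·v_{s,j} over the 1-mm and 0.5-mm sieves
(w₁ + w₀.₅ = 1; the 0.1-mm sieve captures small identification-only
fragments and carries zero mass), renormalized to 100 over identified items
with the unidentified share reported. Digestibility correction multiplies by
per-item factors and renormalizes — invariant to a common factor rescaling.
Corrected profiles are averaged per site (unweighted), matching the decision
to analyze feces separately when deposit times are unknown. The order is
fixed: correct per scat, then average; the operations do not commute unless
all scats share a composition, and a test pins the non-commutativity.

Correction factors are study inputs, not constants of the package: published
values live in the black/grizzly bear feeding-trial literature and are read
from a CSV; the synthetic generator ships its own plausible table (berries
≈ 1, highly digestible animal matter > 2, foliage < 1).

Rare items (present in fewer than 3 *scats*, counted before site averaging)
are dropped without renormalizing the site matrix — correspondence analysis
works on relative frequencies internally, and leaving the rows unscaled
preserves the audit trail. Season bounds are closed: spring May 15–Jun 14,
summer Jun 15–Jul 31, fall Aug 1–Sep 14; population summaries are mean ± SD
(sample SD, ddof = 1) over site profiles. Cub scats carry a flag and are
excluded from inference.

## Ordination and inference

CCA is implemented from first principles: P = Y/total, row/column masses r,
c, standardized residuals Q = (P − rcᵀ)/√(rcᵀ); the row-weighted projection
of Q onto the (weighted, centred) constraint columns is SVD-decomposed; the
squared singular values of the fitted and residual parts are the constrained
and unconstrained eigenvalues, and total inertia ΣQ² equals the table's
chi-square statistic over its grand total. Scores use principal scaling of
linear-combination site scores (u·√λ/√r). The implementation is verified
against a brute-force dense eigensolve of the defining matrices and against
an independent reference implementation in the test suite.

**Restricted permutations.** The individual bear is the exchangeability
unit throughout:

- *Axis tests*: sequential by axis; axis k's pseudo-F (its eigenvalue over
  residual unconstrained inertia) is compared to a null built by permuting
  the rows of Y within strata, with the previous axes' site scores
  partialled out of both the response and the constraints.
  p = (1 + exceedances)/(1 + n_perm).
- *envfit*: each variable is fitted by least squares onto score axes 1–2;
  r² is the fraction of its variance explained and the direction is the
  unit coefficient vector. Site-level variables permute within strata. A
  variable constant within every stratum — any individual trait — cannot
  move under that scheme and would always give p = 1; for those, whole
  strata are exchanged (the trait values permute across individuals and are
  broadcast back to their sites). Either way the individual, not the site,
  is the permutation unit, which is the point of the restriction.

The axis-1 test's type-I error under a within-strata exchangeable null is
calibrated to [0.03, 0.07] at α = 0.05 over 1000 simulations in the
acceptance suite.

**Constraint pruning** drops one member of every pair with |Pearson r| > 0.6
(the member with the larger mean absolute correlation to the remaining
columns; ties drop the later column), then removes max-VIF columns until all
VIF < 10, returning a full audit trail.

**Diet groups** come from the significant categorical trait vectors: with
reproductive status significant, the three field groups (females with cubs,
females with yearlings, lone bears of both sexes — pooled even when sex is
also significant); with only sex significant, two groups; with nothing, one
group plus a warning. A config override can impose any site→group map.

## Synthetic generator

`bearlink.synthetic` emulates the study design with known truth:

- **Landscape**: square stands (default 500 m) drawn i.i.d. from a category
  mixture over the seven habitat classes, plus random straight road/river
  segments laid until each layer reaches its target density (default
  secondary 1.0 + closed 0.8 km/km² ≈ the study area's 1.8, rivers 0.3).
- **Bears**: 6 males, 6 females with cubs, 6 with yearlings, 2 lone females,
  with ages, weights and body condition drawn around group-typical values.
- **Movement**: a habitat-biased correlated random walk — per 2-h step,
  candidate displacements with Rayleigh(σ₁√Δt) lengths and correlated
  headings are weighted by the group's preference for the habitat at the
  candidate endpoint. A bridge cannot generate a free path (it conditions on
  both endpoints), so the walk is deliberately a different model; strict σ₁
  recovery uses the pure-bridge sampler `simulate_bridge_track`, in which
  every odd fix is drawn exactly from the bridge transition law. Fixes get
  Gaussian error (σ₂ = 5 m), gamma-distributed PDOP (a few percent above
  10), and independent 12.6% loss (87.4% fix rate).
- **Foraging and scats**: a feeding event occurs at every true 2-h position
  with the group × habitat kernel's item mixture; a scat excreted at a
  retained, PDOP-clean fix contains the renormalized sum of kernel rows over
  events with lag in [10, 16] h (configurable). Scat counts: sites per bear
  ~ Poisson(3.55), extra scats per site ~ Poisson(0.8) (≈ 1.8 scats/site).
  True mixtures are inverted through the macroscopy model — divide by the
  correction factors, split across sieves by per-item affinities — with
  optional multiplicative lognormal observation noise (default 5%; recovery
  tests that require exact inversion pass 0).

What the generator does **not** emulate: seasonal phenology of the diet
kernels (item mixtures are time-constant, so synthetic seasonal summaries
show no spring/fall contrast), attraction to linear features, home-range
fidelity, cub scats, den entry/exit, and any energetics. Passing tests
therefore demonstrate that the pipeline recovers the structures the
generator encodes (lag window, group diet differences, habitat-diet links,
movement variance) — not that field data would show them.

## Problem sizes and defaults

Validation runs use deliberately scaled designs, chosen once: the transit-
window recovery experiment runs ten replicate 20-bear, 20-day campaigns
scanned at 20-m cells with 50 time nodes; permutation calibration uses 1000
null datasets of 15 sites in 5 strata at n_perm = 199; σ₁ recovery uses 20
replicates of 500 triples. The analysis scripts run a single 20-bear, 40-day
campaign. All randomness flows from a single seed through named per-stage
substreams (SHA-256 of the stage name into the seed sequence), so any stage
is independently reproducible and a rerun is checksum-identical.

## Known limitations

- The raster pathway for habitat composition is centre-point sampling over
  the vector map (one-cell boundary error); there is no true raster map
  ingestion.
- Bridges assume planar projected coordinates in metres; geographic input is
  rejected, not reprojected.
- The sequential axis test conditions on the observed first-axis scores when
  testing later axes; with very few strata its null is conservative.
- The transit-window scan pools all individuals (no strata inside the scan
  CCA), mirroring the screening use of the statistic.
- `estimate_sig1` assumes the alternate-fix observation scheme; with heavy
  fix loss the usable triple count shrinks quickly.
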