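# Methods

This note records the models, conventions and numerical choices behind
`tmdassoc`, and what the synthetic-data tests do and do not demonstrate
about real simulation data.

## Reaction coordinate and units

The reaction coordinate r is the distance between the mass-weighted centers
of mass of the membrane-embedded Cα ranges of the two helices (for the
integrin αIIbβ3 numbering, residues 996–1015 of the α chain and 718–747 of
the β chain).  All energies are in kcal/mol, distances in Å, temperatures
in K.  The gas constant R = 1.9872041×10⁻³ kcal mol⁻¹ K⁻¹ is used for both
R and k_B (per-mole convention), so k_B·T = 0.59616 kcal/mol at 300 K
everywhere in the package.

## Synthetic umbrella sampling

`simulate_umbrella_series` is a Metropolis random walk on a 1-D analytic
landscape w(r) plus a harmonic bias U_i(r) = (k/2)(r − r0)².  Only the
stationary distribution matters for WHAM correctness, so a random walk is
preferred over Langevin integration: it is exact (no time-step bias), and
its serial correlation is a feature, exercising the statistical-
inefficiency machinery the way correlated MD frames would.  Parameters:

- temperature 300 K (default);
- proposal σ = 0.3 Å, giving 50–70% acceptance for the default landscapes;
- burn-in 10% of the requested steps when not set explicitly (the
  appropriate burn-in is problem-dependent and not prescribed by the
  workflow this package implements; 10% is a free choice, generous for a
  1-D walk that decorrelates in tens of steps);
- one RNG child stream per window (`seed + window_index`), so windows are
  independent and removing one never perturbs the others.

The default window layout mirrors the published umbrella protocol for
integrin TMDs: centers 8 → 11 Å in 0.5 Å steps and 11 → 24 Å in 1 Å steps
(20 windows), springs k = 4 kcal mol⁻¹ Å⁻² with k = 20 for the steep
tightly-bound region (centers ≤ 10 Å), where a soft spring yields skewed,
poorly overlapping histograms.  The bias convention carries a
`half_factor` flag so imported data restrained as U = k(r−r0)² (no ½, the
AMBER NMR-restraint convention) can declare it; WHAM then uses the same
energies the sampler did.

Landscape presets: `flat`; `double_well` (bound well at 9 Å ≈ −6.5
kcal/mol, metastable well at 12.5 Å, ~3 kcal/mol association barrier at
15.5 Å) used for parameter-recovery tests; `integrin_like` (three minima
near 9, 12.5 and 15 Å, ~1.5 kcal/mol barrier) echoing the measured
helix-dimer profile shape.  All are anchored to w(20 Å) = 0.

What the generator does *not* emulate: helix tilting/rotation degrees of
freedom orthogonal to r, lipid relaxation, or any slow orthogonal mode —
so a passing recovery test certifies the estimator chain, not the adequacy
of r as a reaction coordinate for a given real system.

## WHAM

Histogram WHAM with bin width 0.1 Å.  The bin grid is aligned so that bin
*centers* lie on integer multiples of the width (rounded to 9 decimals so
lattice points like 20.0 are exact floats); with the default width the
conventional 20 Å anchor coincides with a bin center, which makes
"w(20) = 0 exactly" and "zero bootstrap spread at the anchor bin" hold
simultaneously.  The default range is [min center − 2σ, max center + 2σ]
(σ the per-window harmonic width), widened to cover every sample; empty
bins are excluded from the output rather than reported as +∞.

The self-consistent iteration runs in linear space with the bias Boltzmann
factors exp(−U_i(r_j)/k_BT) precomputed (they underflow harmlessly far
from each window's center); convergence is max|Δf_i| < 10⁻⁷ kcal/mol,
capped at 10⁵ iterations with a hard error when `strict`.  Neighbouring
windows must share at least one populated bin, otherwise a gap error names
the offending pair — the estimator is meaningless across a sampling gap.

Bootstrap errors resample, per window, N_eff = n/g decorrelated values
with replacement (g from the statistics module), re-solve with a warm
start from the full-data shifts, re-anchor identically, and report the
per-bin SD over 200 trials (default).  Resampling raw frames instead
would understate the error by roughly √g.

Known limitation: within ~2σ beyond the outermost window centers the
profile is an extrapolation supported only by one window's Gaussian tail;
there the small-sample bias of −ln(counts) (order k_BT/2N per bin) is not
covered by the bootstrap SD.  Recovery guarantees are therefore stated for
the windowed range.

## Association thermodynamics

K_a integrates r·e^{−w/k_BT} by trapezoid on the PMF grid up to the dimer
cutoff D (default 12 Å, with the value at D interpolated in as the final
node).  The integral nominally starts at 0, but no PMF exists below the
smallest sampled bin; integration starts there, and a warning is issued
when the profile at its inner edge is less than 2 kcal/mol above the
minimum (i.e. when the truncated region could actually contribute).
K_x = K_a·N_L/A with defaults N_L = 85 lipids per leaflet and A = 5950 Å²
(85 × 70 Å², the textbook DOPC area per lipid); both are plain inputs,
never hard-coded into results.  ΔG = −RT ln K_x.

||Ω|| is the product of the sampled ranges of the two helix-packing angles
θ_a, θ_b (each the angle at one helix COM between the other helix COM and
a three-residue reference COM), evaluated over dimer-state frames (r ≤ D
when a mask is not given) and capped at (2π)².

Minima are prominence-filtered (≥ 0.5 kcal/mol by default) local minima of
a 5-bin moving-average smoothing, refined on the raw profile — prominence
filtering rejects the shallow wiggles a converged but noisy profile shows
on its dissociated plateau.  The association barrier ΔG‡ is the maximum of
w between the global minimum and the dissociated plateau (mean of the
outermost 2 Å), relative to that plateau and clipped at 0; it is gauge
(anchor) invariant.  The TST bound k = k‡·e^{−ΔG‡/RT} treats k‡ as a
collision frequency (10⁵–10⁶ s⁻¹ for a TM protein) and is an upper bound,
not a kinetic prediction.

## Reweighting

Each biased configuration t receives the standard multi-window unbiased
weight w^t ∝ [Σ_i n_i e^{(f_i − U_i(r_t))/k_BT}]⁻¹ with the WHAM shifts
f_i, normalised to Σ w^t = 1.  Weights are computed over the entire
ensemble and renormalised within a window subset by default (a
subset-local normalisation mode is exposed; the two differ only by a
common factor, so relative weights agree).

Weighted means use a per-window error model: within each source window the
weighted variance is divided by an effective sample size equal to the Kish
size (Σw)²/Σw² of the weighted sample divided by the series' statistical
inefficiency g, and the per-window errors are propagated with the windows'
total weights.  This holds the WHAM shifts fixed; their uncertainty is a
real additional variance component, available through
`bootstrap_reweighted_mean` (resample windows → re-solve WHAM → recompute
the weighted mean), whose spread is a full standard error.  Analytic
MBAR-style covariance matrices are deliberately out of scope.

`minima_windows` maps PMF minima to the umbrella windows sampling them
using the asymmetric interval [m, m + 1 Å]: with the 20-center layout and
minima near 9, 12 and 15 Å this reproduces the window groupings used for
minima-resolved clasp statistics (windows 3–5, 8–9, 11–12 in 1-based
numbering).  A symmetric ±1 Å rule would drag in the sub-minimum windows
(8.0, 8.5 Å) that the published groupings exclude; both half-widths are
exposed.

## Structural observables

- Cutoff comparisons are inclusive (≤) throughout; the boundary case is
  pinned by a dedicated test.
- Ring centroids are unweighted means of the 6 (Phe) / 9 (Trp) ring heavy
  atoms; toy structures carry a single pre-placed `RC` pseudo-atom instead.
  d_IMC is the frame-wise minimum of the F992- and F993-ring centroid
  distances to the W715 ring centroid.
- Hydrogen bonds: donor–acceptor distance ≤ 3.5 Å *and* donor–H–acceptor
  angle ≥ 120°; with heavy-atom-only models (no hydrogens) the criterion
  degrades to distance-only with a logged warning.
- Salt bridges: minimal inter-group heavy-atom distance ≤ 4 Å.
- Contacts: a residue pair (default granularity) is in contact when any
  atom pair is within 7 Å; atom-pair granularity (cpptraj-style totals) is
  available because published absolute contact counts depend on that
  convention.  Native = present in the reference frame (frame 0), non-native
  = formed later.
- RMSD/RMSF use mass-weighted Kabsch superposition onto frame 0; fit and
  report selections default to the same set.  RMSF is per-residue over Cα.
- PC-overlap convergence superposes both trajectories on the first frame,
  runs PCA on the pooled coordinates, and reports the histogram
  intersection (sum of bin-wise minima, 50 bins over the pooled range) of
  the two projection histograms per component on growing prefixes.

Multi-model PDB I/O goes through biotite; masses come from the element
column with a first-letter-of-atom-name fallback and a carbon-mass default
(with warning) for unknown elements.  Fixed-width PDB coordinates limit
round-trip fidelity to 10⁻³ Å.

## Statistics

The statistical inefficiency is g = 1 + 2Σ_τ (1 − τ/n)·C(τ) with the
normalised autocorrelation C computed by FFT and the sum truncated at its
first non-positive value (initial-positive-sequence style) — oracle-tested
against the analytic AR(1) value (1+ρ)/(1−ρ) and against block-duplicated
series.  Equilibration start t₀ maximises N_eff = (n − t₀)/g of the
remaining suffix over 50 candidate offsets in the first 90% of the series.
SEM = SD/√N_eff; replicate runs combine by √(ΣSEMᵢ²) or, for occupancy-type
quantities, as SD(replicate means)/√n.

Two-sample tests are two-sided Welch t-tests with N_eff in place of the
raw sample sizes and Welch–Satterthwaite degrees of freedom on N_eff (the
classic equal-variance pooling can be emulated by the triplicate mode with
equal group sizes).  Significance labels follow the convention *: p<0.05,
**: p<0.001, ***: p<0.0001 — note the non-standard ** threshold, kept as a
faithful house style of the analyses this package reproduces.  On
synthetic equal-mean AR(1) pairs the corrected test holds the nominal 5%
type-I error; without the correction the rate exceeds 60%, which is the
entire point of the machinery.

## Problem sizes in the shipped checks

The acceptance script and test suite use 20 windows × 5×10⁴ samples for
landscape recovery (with 200 bootstrap trials), 10⁶ points for the AR(1)
inefficiency check, 1000 replicates of n = 4000 series pairs for the
type-I calibration, and ≤ 500-atom toys for the exact brute-force
structural oracles — sizes at which every stated tolerance is comfortably
resolved by the corresponding Monte-Carlo error.
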