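# tmdassoc

Association thermodynamics of transmembrane (TM) helix dimers from
umbrella-sampling data.

Integrin adhesion receptors are held in their resting state partly by the
association of the two single-pass TM helices of their α and β subunits,
clasped together at an outer (GXXXG-motif) and an inner (GFFKR-motif)
interface.  How strongly a given α/β pair associates — and therefore how
easily the receptor activates — can be quantified by the potential of mean
force (PMF) w(r) along the inter-helix center-of-mass distance r, estimated
from umbrella-sampling simulations.  `tmdassoc` implements the complete
analysis chain downstream of the (expensive, external) sampling step, for
computational biophysicists who have window time series in hand or want to
validate the machinery on synthetic data:

1. **WHAM** — merge the biased window histograms into one PMF by iterating

       p_j = ( Σ_i n_ij ) / ( Σ_i N_i e^{(f_i − U_i(r_j))/k_B T} ),
       f_i = −k_B T ln Σ_j e^{−U_i(r_j)/k_B T} p_j

   to self-consistency, with w(r_j) = −k_B T ln p_j anchored to 0 at the
   dissociated distance (20 Å) and per-bin Monte-Carlo bootstrap errors
   over decorrelated samples.

2. **Association free energy** — integrate the PMF into an area-scale
   dimerization constant and convert to the mole-fraction standard state:

       K_a = ||Ω||/(2π)² ∫₀^D r e^{−w(r)/k_B T} dr,
       K_x = K_a N_L / A,
       ΔG  = −RT ln K_x

   where D is the largest separation still counted as dimer, N_L/A the
   lipid surface density, and ||Ω|| = Δθ_a · Δθ_b the configurational
   restriction of the two helices in the dimer relative to the (2π)²
   available to free monomers.  The association barrier read off the PMF
   also gives a transition-state-theory rate bound k = k‡ e^{−ΔG‡/RT}.

3. **Structural observables** — outer/inner clasp distances (d_OMC, d_IMC),
   COM distances, hydrogen-bond (3.5 Å / 120°) and salt-bridge (4 Å)
   occupancies, lysine snorkeling, native/non-native contacts (7 Å),
   RMSD/RMSF after mass-weighted Kabsch superposition, helix-packing
   θ angles, and principal-component histogram-overlap convergence, all on
   multi-model PDB ensembles.

4. **Reweighting** — WHAM-consistent per-configuration weights turn biased
   umbrella configurations into unbiased averages, e.g. clasp distances
   evaluated "inside" each PMF minimum.

5. **Statistics** — statistical inefficiency g, equilibration detection,
   effective sample sizes N_eff = (T − t₀ + 1)/g, SEM propagation, and
   N_eff-corrected Welch t-tests with the *, **, *** significance
   convention.

A synthetic-data layer generates every input the pipeline consumes: biased
Boltzmann sampling of known 1-D landscapes under harmonic umbrellas (so
estimates can be compared with exact ground truth), AR(1) series with known
autocorrelation, and toy two-helix PDB ensembles carrying the integrin
residue labels (G972/G976, F992/F993, R995/R997, W715, K716, D723/E726)
plus a pseudo-lipid head-group oxygen plane.

## Worked example

Twenty umbrella windows (centers 8→11 Å in 0.5 Å steps, 11→24 Å in 1 Å
steps; springs 4 kcal mol⁻¹ Å⁻², stiffened to 20 below 10 Å) are sampled on
the built-in three-minimum landscape and pushed through the full chain:

```python
from tmdassoc import (SamplerConfig, default_bias_specs, make_landscape,
                      simulate_umbrella_series, solve_wham)

land = make_landscape("integrin_like")
cfg = SamplerConfig(temperature=300.0, n_steps=20000, seed=1)
windows = simulate_umbrella_series(land, default_bias_specs(), cfg)
pmf = solve_wham(windows, anchor_at=20.0).bootstrap(n_trials=200, seed=1)
print(pmf.summary())
print(pmf.association(omega=0.07, dimer_cutoff=12.0).summary())
```

prints

```
Umbrella-sampling PMF (WHAM)
============================================
windows:        20
temperature:    300 K
bins (pop.):    178 [7.70, 25.50] Å
iterations:     3090 (converged)
anchor:         w(20 Å) = 0
min w(r):       -6.040 kcal/mol at r = 9.00 Å
median boot SD: 0.1037 kcal/mol

TM helix association thermodynamics
============================================
||Ω||:          0.07 rad²  (0.177% of (2π)²)
K_a:            217.4 Å²   (D = 12 Å)
K_x:            3.106      (N_L/A = 85/5950 Å⁻²)
ΔG:             -0.68 kcal/mol at 300 K
PMF minima at:  9.0, 12.5, 15.1 Å
ΔG‡:            1.54 kcal/mol
TST rate ≤      7.53e+03 s⁻¹ (k‡ = 1e+05 s⁻¹)
```

Reading: the bound dimer sits at r ≈ 9 Å, 6.0 kcal/mol below the
dissociated plateau, with two metastable part-dissociated states (12.5 and
15.1 Å — the outer clasp lets go before the inner one).  With the helices'
angular sampling restricted to ||Ω|| = 0.07 rad² and a lipid density of
85 lipids per 5950 Å² leaflet, the mole-fraction constant K_x ≈ 3.1 makes
association mildly favourable (ΔG ≈ −0.7 kcal/mol), and the 1.5 kcal/mol
association barrier bounds the association rate at ~8×10³ s⁻¹ for a
10⁵ s⁻¹ collision frequency.  `minima_windows` then maps those minima onto
the umbrella windows that sample them (here windows 3–5, 9 and 12 in
1-based numbering) for reweighted clasp-distance averages.

The same chain is available from a shell:

```
tmdassoc synth pmf --preset integrin_like --seed 1 --out-dir run/
tmdassoc wham --metadata run/windows.meta --zero 20 --bootstrap 200 --out run/pmf.csv
tmdassoc assoc --pmf run/pmf.csv --omega 0.07 --out run/assoc.json
tmdassoc synth helix --separations 9,12,16 --out dimer.pdb
tmdassoc observe --pdb dimer.pdb --metric d_omc
```

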