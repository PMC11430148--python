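# Methods

## Decay model and fitting

Each resonance of a pulsed-field-gradient diffusion experiment attenuates
as `I(g) = I₀ exp(−D·b(g))` with the Stejskal–Tanner factor
`b(g) = γ² g² δ² (Δ − δ/3)`. The default acquisition parameters mirror a
bipolar stimulated-echo (ledbpgp2s-type) experiment: diffusion time
Δ = 90 ms and total gradient pulse length δ = 1.9 ms, with the proton
gyromagnetic ratio γ = 2.675×10⁸ rad s⁻¹ T⁻¹. Published attenuation
factors for bipolar sequences differ in small sequence-specific timing
terms (τ/2 corrections); `GradientScheme.timing_correction` adds such a
term to the effective diffusion time (default 0), so the factor can be
adapted to any specific sequence without code changes. Gradients are
stored in T/m; readers accept `G/cm` via an explicit `gradient_unit`
field (1 G/cm = 0.01 T/m) and never guess units.

The primary estimator is weighted linear least squares on
`ln I = ln I₀ − D·b` with weights ∝ I², i.e. the propagation of a
constant absolute intensity noise into log space. The true noise
statistics of processed DOSY amplitudes are generally unknown (covariance
processing changes them), so the reported `sigma_d` is the
leverage-corrected (HC3) sandwich covariance of the slope rather than the
naive weighted-least-squares covariance: the sandwich form stays
approximately calibrated whether the noise is constant-absolute or
multiplicative. Measured on 200 replicates of 2% multiplicative noise at
8 gradients, the ±1σ interval covers the truth 66.5% of the time
(nominal 68.3%); the naive covariance under-covers at 56.5%.

Decays containing non-positive intensities (noise-dominated tails) fall
back to a nonlinear exponential fit; an optional nonlinear refinement of
the log-linear estimate is available and agrees within 2σ on
well-conditioned data. A residual bootstrap of `sigma_d` is available
behind an explicit seed. A fitted total attenuation below 10⁻⁹ across the
whole gradient ramp is indistinguishable from zero diffusion-driven decay
and is reported as `d = 0` with a `no_attenuation` flag; such peaks are
excluded from pairing.

## Pairing, clustering and significance

Peaks are matched across the two conditions of a comparison by greedy
globally-nearest chemical shift within a tolerance (default 0.02 ppm —
binding-induced shift perturbations are not simulated and real ones are
expected to be small for weak binders). The tie-break key
(|Δppm|, smaller shift, larger shift, smaller id, larger id) is
role-agnostic, which makes matching exactly symmetric under swapping the
lists. Unmatched peaks are reported, never imputed.

Matched pairs become points `(log10 D_ref, log10 D_test)`. Clusters are
the connected components of the graph joining points within Euclidean
distance `eps_log` (default 0.05 log₁₀ units), computed by single-linkage
hierarchical clustering cut at that distance — deterministic, and
identical to a brute-force ε-graph construction (which the test suite
verifies on random instances). The default radius is roughly twice the
per-point log-D scatter of a 2% noise fit, and deliberately wider than
the log-D separation of small molecules of similar mass: compounds within
~40% in mass merge into one cluster unless binding moves one of them.
One compound may legitimately produce several clusters; compound-level
aggregation happens only at annotation time, statistics stay at cluster
level.

Each cluster is scored by the mean member log-ratio
`r = mean(log10 D_ref − log10 D_test)` with standard error propagated
from the per-peak fit uncertainties,
`se_r = sqrt(Σ_i var_i)/n`, `var_i = (σ_ref/(D_ref ln10))² +
(σ_test/(D_test ln10))²`, and `z = r/se_r`. Two-sided p-values use the
standard-normal reference on z; Benjamini–Hochberg adjustment runs across
all clusters of one comparison and clusters with `q ≤ alpha`
(default 0.05) are labelled `slower_in_test` or `slower_in_ref` by the
sign of r. A seeded sign-permutation test is available as an alternative
reference (`significance_method="permutation"`); the normal reference is
the default because it is deterministic and the propagated uncertainties
are explicitly calibrated (above). With `se_r = 0` and `r ≠ 0` the
cluster is flagged and treated as infinitely significant; `r = 0` exactly
is never significant.

## Screen modes

The mode fixes the (reference, test) assignment so a hit is always "test
diffuses slower than reference": binding = (L, LP), competitive =
(LPK, LP), cooperative = (LP, LPK). Competitive and cooperative screens
of the same list pair are exact mirror images (identical clusters, r
negated, hit sets exchanged with the opposite-direction set); both
directions are always reported, the mode only selects which one is called
"hits". Intensity changes between conditions (e.g. partial precipitation
of a ligand) do not move D under fast exchange with ligand in excess, so
the pipeline deliberately ignores amplitude discrepancies.

## Binding-equilibrium simulator

The generator solves mass action for species P, PL_i, PK and the ternary
complexes PL_iK with

```
[PL_i] = [P][L_i]/K_i,  [PK] = [P][K]/K_K,  [PL_iK] = α_i [P][L_i][K]/(K_i K_K)
```

The coupling factor α_i multiplies the probe's association to the
protein when the known-ligand site is occupied: α = 0 is same-site
competition, α = 1 independence, α > 1 cooperativity. This thermodynamic
coupling subsumes mechanistically different cooperative routes (direct
ligand–ligand contacts in a ternary complex, or oligomerization-shift
effects) in a single phenomenological parameter; explicit protein
dimerization equilibria are out of scope. At α = 1 the two sites
factorize and each ligand's bound fraction equals its value with no known
ligand present — the test suite uses this identity, the single-site
quadratic closed form, and an independent log-space least-squares solver
as oracles.

Free concentrations come from scalar root-finding (Brent) on the protein
conservation equation with an inner fixed point for the free ligand and
known-ligand concentrations; solutions are verified against every
conservation equation to a relative residual of 10⁻¹² (measured: ~10⁻¹⁵)
and the solver raises rather than returning a partial answer.

Free diffusion coefficients follow Stokes–Einstein with the radius of a
sphere of the molecular volume, `r = (3m/(4πρN_A))^(1/3)`,
`D = k_BT/(6πηr)`, with densities 1.0 g/cm³ (small molecules) and
1.35 g/cm³ (proteins), T = 298 K and η = 8.9×10⁻⁴ Pa·s by default. All
protein complexes diffuse at the protein's coefficient. Observed
coefficients are fast-exchange population averages; noise is
multiplicative Gaussian on intensities (default σ = 2%), with one integer
seed per study from which per-condition generator seeds are spawned
deterministically.

## Shipped scenarios

Both named scenarios are synthetic constructions that mirror the
*structure* of real screens (their parameters are simulation choices, not
literature values), sized so that the binding-induced diffusion changes
are detectable at 2% intensity noise with a 16-step gradient ramp
(0.05–0.5 T/m) — real studies often run leaner in protein and rely on
more gradient steps or signal averaging:

* **tyrosinase-like** (competitive): two non-binders of 121 and 150 Da —
  deliberately within one clustering radius of each other, reproducing
  the near-isobaric indistinguishability caveat — a 138 Da same-site
  probe (K_D = 10 μM, α = 0, four aromatic resonances), a known ligand
  (K_D = 20 μM, 2 mM) and a 120 kDa protein at 200 μM. The probe's bound
  fraction drops from 0.48 (LP) to 0.13 (LPK), a 0.18 log₁₀-unit
  diffusion change.
* **lysozyme-like** (cooperative): tris-like (121 Da) and imidazole-like
  (68 Da) probes with weak intrinsic binding (K_D = 2 mM) strongly
  coupled to a GlcNAc-like known ligand (α = 20, K_K = 100 μM, 2 mM), a
  non-binder, and a 14.3 kDa protein at 1 mM (the concentration regime of
  real lysozyme mixtures). Probe bound fractions rise from 0.22 to 0.45
  on adding the known ligand.

What passing tests on these scenarios show: the statistics recover known
ground truth under the stated noise and concentration regimes. What they
do not show: performance on real spectra, where peak overlap, baseline
distortions, temperature/viscosity drifts between samples, chemical-shift
perturbations on binding, and non-Gaussian noise all add failure modes
that the generator intentionally omits (an optional per-list global D
rescaling against designated reference peaks is provided for viscosity
matching, off by default; shift perturbations and lineshape effects are
out of scope).

## Numerical and design notes

* Log-linear fitting needs ≥ 4 gradient points and strictly increasing
  gradients; the first intensity must be positive.
* Greedy matching, single-linkage clustering and BH adjustment are all
  deterministic; the only randomness in the package is simulation noise
  and the optional permutation/bootstrap procedures, each behind an
  explicit seed.
* Cluster reports serialize to TSV/JSON and round-trip exactly; every
  CLI output directory carries `provenance.json` with the parameters and
  seeds needed to reproduce it.
* Problem sizes in the test-suite and acceptance script (20-point fit
  grids, 10×10 equilibrium grids, 100 random clustering instances,
  25 noisy replicates per screen) were chosen to exercise every code path
  while keeping a full run in the seconds range on one CPU.
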