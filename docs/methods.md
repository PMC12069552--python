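# Methods

## Model overview

The package models the partitioning of three transcription factors — WOX5,
BRAVO and PLT3 — into heterodimers and one trimer in the four cell types of
the Arabidopsis root stem cell niche. All reactions follow mass action:

```
B + W ⇌ BW            (a_BW, d_BW)
W + P ⇌ WP            (a_WP, d_WP)
B + P ⇌ BP            (a_BP, d_BP)
WP + B ⇌ T            (a_T1, d_T1)   trimer path 1
BP + W ⇌ T            (a_T2, d_T2)   trimer path 2
```

Free PLT3 exchanges with the trimer T = WOX5-PLT3-BRAVO only through the
dimers; there is no direct three-body association step. The dynamics
conserve each protein's total (free + complexed), which expresses the model
assumption that measured per-cell protein levels are constant on the
timescale of complex formation and are merely repartitioned.

## Rate calibration from binding affinities

A FRET-FLIM binding percentage b·100 is interpreted as the fraction of
donor molecules in complex at steady state. For each reaction, the
reversible dimerisation (the first three equations restricted to one pair)
is started from equal donor and acceptor pools and every grid pair
(a, d) ∈ {0, 0.0002, …, 0.5}² whose steady-state bound fraction matches b
within 10⁻⁵ is accepted. The trimer-path affinities come from
split-fluorophore (BiFC) donors — the reconstituted WOX5-PLT3 or BRAVO-PLT3
dimer — so each trimer path is calibrated as the same two-body problem with
the dimer as a unit donor species.

Numerical and design choices:

- **Initial pools D₀ = A₀ = 1 a.u., DA₀ = 0.** Units are arbitrary, so the
  unit pool is the canonical choice; with it the steady state has the
  closed form "smaller root of a·(1−x)² = d·x", giving the accepted-set
  line d = a·(1−b)²/b. One caveat is worth recording: with unit pools every
  measured affinity (0.117–0.363) calibrates to a < d, whereas the
  crossover a = d sits at b = (3−√5)/2 ≈ 0.382. Referencing the same
  binding values to half-unit pools would place the crossover at b ≈ 0.27,
  i.e. high-affinity pairs at a > d and low-affinity pairs at a < d. The
  choice rescales all equilibrium constants by a common factor and does not
  affect the calibrated binding closure or the relative comparisons made
  here; it matters only for the verbal reading "association faster than
  dissociation".
- **Scan implementation.** Integrating all 2501² grid points is wasteful:
  the sensitivity |∂x/∂d| is at least ≈ 0.34 anywhere on the grid interior,
  so the 10⁻⁵ acceptance window in d is at most ≈ 3·10⁻⁵ — a fraction of
  one grid step. Candidates are therefore pre-filtered to grid points
  within two steps of the closed-form line and each survivor is verified by
  ODE integration; the accepted set is identical to the brute force, which
  `scan_rates_exhaustive` retains for sub-ranges and cross-checking.
- **Steady-state criterion.** max |dX/dt| < 10⁻¹⁰ a.u./time, checked at
  doubling time checkpoints with a hard cap of 10⁶ time units (exceeding
  the cap raises). Integration uses LSODA with rtol 10⁻¹⁰, atol 10⁻¹².
  The irreversible limit d = 0 approaches its fixed point only
  algebraically and is returned analytically (the complex absorbs the
  limiting pool).
- **Degeneracy.** Accepted pairs differ only in formation speed. The
  default policy selects one pair per reaction with a seeded random draw;
  `fastest` (largest a) and `slowest` (smallest positive a) exist for
  robustness checks.

## Niche simulation

Each cell type is integrated independently from the all-free initial
condition (complexes zero) to the same steady-state criterion. All-free is
the minimal assumption about unknown pre-bound fractions; a multi-start
check from random feasible pre-bound partitions confirms the steady state
is independent of the initial partition for the calibrated rates (the test
suite asserts agreement to 10⁻⁸). The steady state is also verified against
an algebraic fixed-point solve (generic nonlinear root-finder) to 10⁻⁶.

One caveat: because the measured affinities violate the detailed-balance
(Wegscheider) condition on the dimer–trimer cycle
(K_WP·K_T1 / (K_BP·K_T2) ≈ 1.74 for the wild-type table), the steady state
is a non-equilibrium state carrying a small cycle flux. Its magnitude
depends weakly on the absolute rate scales, not only on the ratios a/d:
signatures computed with all-`fastest` versus all-`slowest` accepted pairs
agree to within a few percent per entry (largest relative deviations
~4·10⁻², in the mid-sized dimer entries), not exactly. Visually the
signatures are indistinguishable, but exact speed-invariance should not be
assumed when reporting many digits.

Display helpers: `heatmap_matrix` normalises each row (species) by its
maximum across cell types by default (configurable); `radar_data` returns
the four complex rows.

## Default abundances (synthetic data)

The per-cell-type protein levels backing the published signature figures
are not available as a numeric table, so the generator ships defaults that
encode the described qualitative pattern, normalised to BRAVO in the stele
initials (the global anchor, mean 1.0):

| | SI | QC | CSC | CC |
|---|---|---|---|---|
| BRAVO | 1.00 | 0.40 | 0.15 | 0.02 |
| PLT3 | 0.60 | 0.55 | 0.65 | 0.10 |
| WOX5 | 0.30 | 0.60 | 0.45 | 0.01 |

These satisfy: BRAVO strictly decreasing SI→QC→CSC→CC; WOX5 peaking in the
QC and nearly absent in CCs; PLT3 similar across SI/QC/CSC and lower in
CCs; per-cell orderings BRAVO>PLT3>WOX5 (SI), WOX5>PLT3>BRAVO (QC), PLT3
predominant (CSC). Within those constraints the values were fixed so that
the simulated wild-type niche reproduces the described signature pattern
(trimer maximal in SI/QC, WOX5-PLT3 maximal in CSC, free BRAVO in SI, free
WOX5 in QC, free PLT3 fraction highest in CSC/CC, negligible CC complexes);
they are package defaults, not measurements, and are user-overridable
everywhere.

Per-nucleus intensities are drawn as max(0, Normal(mean, sd)) — truncated
at zero because fluorescence cannot be negative — with 1–3 nuclei per root
averaged per root, 28 roots by default. Binding percentages are drawn
untruncated (donor-only and negative controls legitimately scatter below
zero). The generator emulates tabulated measurements only: no images,
no segmentation, no spatial correlation between nuclei, no root-to-root
heteroscedasticity — so passing recovery tests demonstrate estimator
correctness under the stated noise model, not robustness to real
microscopy artifacts.

## Scenarios

- **Wild type:** affinities {BW 0.224, WP 0.306, BP 0.280, T1 0.363,
  T2 0.298}.
- **PrD deletion:** WP → 0.185 and BP → 0.117; trimer-path rates kept at
  wild-type values by default, consistent with the re-measured split-donor
  trimer binding being nearly unchanged (0.315 full length vs 0.289
  deleted); `trimer="remeasured"` recalibrates both paths to 0.289 instead.
  Under the default abundances the simulation reproduces the reported
  direction of every shift: both PLT3 dimers fall in SI/QC/CSC, BRAVO-WOX5
  rises in SI/QC, and free protein rises nearly everywhere (free PLT3 in
  the CSC by ~13%). The trimer, however, falls by ~40–45% in SI and QC:
  at steady state the trimer scales with the dimer equilibrium constants,
  which the deletion reduces to 0.44× (WP path) and 0.28× (BP path), and
  free-pool increases can compensate only partially. A markedly milder
  trimer response is not reachable in this model for any abundance table
  consistent with the described pattern; this is recorded as a known
  limitation of the steady-state reading of that observation.
- **Controls:** C1 a=d=0.1, C2 a=0.1/d=0.05, C3 a=0.05/d=0.1 (uniform
  across all five reactions, measured abundances); C4 calibrated rates with
  equal abundances; C5–C7 the pairwise combinations with equal abundances
  (every pool 0.5 a.u. — mid-scale, configurable). The equal-abundance
  controls (C4–C7) destroy the cell-type pattern and fail the qualitative
  flags. The uniform-rate controls with measured abundances (C1–C3) do
  *not* fail the six binary flags: steady-state signatures depend on the
  reactions' equilibrium constants, and the flag set is dominated by the
  abundance pattern, so flag-level discrimination between uniform-rate
  ratios is not achievable here. Distinguishing them requires full
  quantitative comparison (`compare_signatures` distance), not the binary
  pattern flags.
- `compare_signatures` reports entry-wise differences, both signatures'
  flags, and an L1 distance over per-entry max-normalised values
  (scale-free; zero iff identical). "Marked" changes are operationalised as
  >10% relative in the package's own tests.

## Decay simulation and fitting

TCSPC histograms are modelled as a two-exponential mixture convolved with a
Gaussian instrument response (IRF), wrapped into the 31.25 ns repetition
window (32 MHz), over a uniform background:

- **Amplitude convention.** α_F is the *photon-count* fraction drawn from
  the FRET-quenched exponential. Under equal brightness of quenched and
  unquenched donors this equals the molecule fraction undergoing FRET,
  which is exactly how the fitted amplitude is reported as binding. The
  generator and the fitter share this convention; both are tested against
  it (mixture mean-arrival check, recovery to ±0.02 median error at 10⁵
  photons).
- **Defaults:** τ_D = 3.0 ns (center of the display scale used for such
  donors), σ_IRF = 0.1 ns, 1024 bins. All overridable.
- **Likelihood.** Per-bin Poisson, the natural photon-counting model,
  maximised with bounded quasi-Newton (L-BFGS-B) over shape parameters
  only: the overall scale is profiled out analytically (for Poisson, the
  optimal scale equals the observed total), which keeps all optimised
  parameters O(1) and avoids gradient-scaling pathologies. The
  Gaussian⊗exponential density uses the scaled-complementary-error-function
  form with an asymptotic branch deep in the tail; wrap terms k = −1…4
  cover the window to ≪ single-photon accuracy.
- **IRF handling.** With a known IRF width the full histogram is fitted
  with the analytic convolution; without one, the fit falls back to the
  pure-exponential tail starting 0.5 ns after the histogram peak.
- **Donor-only model selection** between mono- and bi-exponential is by
  BIC (the underlying choice is stated in the source analyses without a
  rule).
- **FRET fits** fix the slow lifetime to the supplied τ_D and constrain the
  FRET lifetime to efficiencies in [10%, 80%]; solutions pinned at a
  constraint are flagged (`at_boundary`), mirroring how no-FRET samples
  accumulate at the constraint values. Fitted amplitudes are non-negative
  by construction; negative *observed* binding values exist only in the
  sampling emulation, since the sign convention that produces them in the
  reference software is not documented.
- Pixel-wise image fitting is out of scope; fits operate on aggregate
  per-nucleus histograms.

## Statistics

Kruskal–Wallis uses the tie-corrected H with the χ² approximation (H = 0,
p = 1 with a warning when all values are identical). Dunn's pairwise
z-tests use the tie-corrected pooled variance and two-sided p-values
(sidedness is not stated in the source; two-sided is the standard default),
adjusted by Benjamini–Hochberg across the k(k−1)/2 comparisons. Compact
letters are assigned with the insert-and-absorb algorithm; two groups share
a letter iff their adjusted p ≥ α. The 2×2 proportion test is Pearson's χ²
with Yates' continuity correction (zero marginals rejected). Under the
null, the Kruskal–Wallis rejection rate is verified at the nominal level
over 2000 simulated three-group replicates in the test suite.

## Problem sizes used in the shipped tests

The test suite and the reproduction script run the full calibration grid
(2501 points per axis via the pre-filter, candidates ODE-verified), 100
random rate pairs for the closed-form cross-check, 34 simulated decays per
amplitude level at 10⁵ photons for recovery, and 2000 null replicates for
the test-level calibration; these sizes give Monte-Carlo errors comfortably
below the asserted tolerances.

## Known limitations

- No intercellular protein movement, gene-regulatory feedback, degradation
  or synthesis: protein totals are fixed inputs per cell type.
- No nuclear-body formation or phase-separation dynamics, although the
  PrD domains that motivate the deletion scenario are implicated in such
  behaviour.
- The abundance defaults are qualitative stand-ins (see above); any
  quantitative conclusion should be re-run with measured tables via the
  config/CSV inputs.
- Steady-state signatures carry a small rate-magnitude dependence through
  the broken-detailed-balance cycle (see Niche simulation) — exact
  speed-invariance holds only for ratio-preserving common rescaling.
- The decay fitter re-implements the published quantities (binding, FRET
  efficiency, amplitude-weighted lifetime) with a documented estimator; it
  does not reproduce any vendor software's proprietary grouping or pattern
  analyses.
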