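# Methods

## Signal model

Single coherent fibre populations are modelled as two axially symmetric
compartments sharing one axis: an intra-axonal *stick* (zero
perpendicular diffusivity) and an extra-axonal *zeppelin* with
perpendicular diffusivity D_e,⊥. Both compartments have parallel
diffusivity d∥ = 1.9 μm²/ms. With b in ms/μm² (b-values in s/mm² are
divided by 1000 at the interface so diffusivities in μm²/ms multiply
directly) and c the cosine between gradient and fibre axis:

    S(b, c) = f exp(−b d∥ c²) + (1−f) exp(−b [D_e,⊥ + (d∥ − D_e,⊥) c²])

Signals are S0-normalised; b = 0 measurements are exactly 1. Rician
noise replaces S by √((S+ε₁)² + ε₂²) with ε ~ N(0, σ²), σ = 1/SNR on
the b = 0 signal. Not modelled: axon diameter, exchange, orientation
dispersion, compartmental T2, gradient nonlinearity.

## Acquisition schemes

The built-in scheme mirrors a Connectom-style acquisition: b = 0 (14
volumes), 500 (30 directions), 1200 (30), 2400 (60), 4000 (60),
6000 (60) s/mm². Directions are generated per shell by antipodally
symmetric electrostatic repulsion (projected gradient descent with
backtracking from a seeded random start; stop at energy decrease
< 1e-9 or 10,000 iterations). The original acquisition staggered
directions across shells; per-shell uniformity is sufficient for every
single-voxel quantity computed here, so cross-shell staggering is
deliberately omitted. Gradient tables read and write in the FSL
bval/bvec dialect; b < 50 s/mm² is pooled as b = 0 and b-values within
±100 s/mm² form one shell.

Sub-scheme selectors: `ss_1200` … `ss_6000` (one shell each) and
`ms_all` (all five weighted shells). The b = 500 shell participates
only in `ms_all`.

## Response function and deconvolution

The single-fibre response kernel is the analytic zonal (m = 0)
spherical-harmonic expansion of the compartment signal about its axis,
computed per shell by 64-point Gauss–Legendre quadrature in cos θ
(exact far beyond l = 8). The kernel is fixed at f = 0.3,
D_e,⊥ = 0.8 μm²/ms, deliberately *mismatched* to most simulated voxels
— the mismatch is the object of study.

The spherical-harmonic basis is real, orthonormal, even-order,
antipodally symmetric, ordered l ascending then m from −l to +l.
CSD forms the forward matrix per selected shell as the direction basis
times the Funk–Hecke factors r_l(b)·√(4π/(2l+1)) and solves iteratively:
initialise unconstrained at l_max = 4; at each iteration, amplitudes on
a 300-point hemisphere grid below τ·(mean initial amplitude), τ = 0.1,
form the active set; a penalty block drives them to zero in a stacked
least-squares solve; convergence when the active set repeats. The
user-facing constraint weight λ = 1 is normalised internally to
λ·n_data·r₀/n_constraint per row, following the convention of the
method's reference implementation — a literal per-row weight of 1
overwhelms the data term and inflates the kernel voxel's AFD by 2–13%
depending on scheme, which would break the identity convention below.
Harmonic order: l_max = 8 for 60-direction shells and multi-shell fits,
6 for 30-direction shells.

AFD is the FOD's integral over the sphere, c₀₀·√(4π), reported
*kernel-relative*: every fit is divided by the AFD the identical
pipeline produces for the kernel's own signal (fibre on +z, cached per
selector/response/options). A voxel whose parameters equal the
kernel's therefore reads exactly 1 at the reference orientation. At
arbitrary orientations the read-out varies by ~1e-3 (up to ~2.6e-3 at
b = 6000): the kernel's l > 8 content aliases through any 60-direction
set; this is a property of discrete sampling, not of the solver (it
persists with the constraint disabled and across direction-set seeds).

`ms_all` uses one anisotropic kernel whose zonal coefficients vary per
shell (single-tissue multi-shell deconvolution). The in-vivo analyses
this emulates used three-tissue multi-shell CSD; simulated voxels
contain no GM/CSF compartment, so the isotropic tissues would be
identically zero, but this substitution is a fidelity caveat for the
multi-shell comparisons.

## Simulation study

The grid crosses f ∈ {0.2, …, 0.8} (7) with D_e,⊥ ∈ {0.2, 0.4, 0.6,
0.8, 1.0, 1.2} μm²/ms (6): 42 geometries, each deconvolved under all
five schemes. Fibre orientation is fixed at +z (the read-out is
orientation-independent at the tolerance above). Noise, when enabled,
adds 100 Rician realizations per cell at SNR ∈ {50, 35, 20} (one
printed source gives 25 for the lowest value; the methods text's 20 is
used, and the grid is configurable).

The scheme comparison is OLS of AFD on the full factorial
`f * D_e,⊥ * scheme` with raw (uncentred) continuous predictors and
treatment-coded scheme, reference ss_6000; the highest-order
coefficient is invariant to centring, so only standardisation would
change it and none is applied. The model is fitted on the noiseless
table by default; a flag fits per-realization noisy AFD instead
(noiseless and SNR-50 coefficients agree within their 95% intervals).
Degeneracy counting uses tolerance 0.05 in AFD, half the visual
resolution of the published figure.

## Synthetic cohort

`generate_cohort` (statistical mode) emulates the reference population:
78 subjects, age uniform on (8, 18) years (mean 13, sd ≈ 2.89 — within
rounding of the reported 12.4 ± 2.9), 45 female, log-normal RMS
displacement (median 0.5 mm, log-sd 0.4). Per tract × scheme cell an
AFD column is planted as √R²·z(age) + √(1−R²)·ε, mapped to mean 1,
sd 0.1 (the statistics used downstream are affine-invariant, so the
scale is a convenience). Sex and motion effects default to zero; flags
add them for robustness checks. The default R² targets are the shipped
38-tract × 4-scheme reference matrix (`src/afdsim/data/table1.tsv`).

Because the fitted multiple R² of a 3-predictor model exceeds the
planted population R² by the chance fit (null expectation
p/(n−1) = 3/77 ≈ 0.039), planting is calibrated analytically:
the generator plants max(0, t − p(1−t)/(n−1)) for target t. A target
of zero plants zero and recovers the null expectation; targets at or
below ~0.04 cannot be recovered more closely than the null floor by
any generator.

`mechanistic_cohort` pushes age-dependent microstructure through the
full simulator and CSD instead of planting correlations:
f = 0.45 + 0.012·(age − 12.4) + N(0, 0.01²) and
D_e,⊥ = 0.8 − 0.02·(age − 12.4) + N(0, 0.15²), clipped to the valid
box with a warning. The noise asymmetry (f_sd ≪ de_sd) encodes the
regime the study design presumes: the developmental signal lives in
the intra-axonal fraction, while extra-axonal diffusivity varies
substantially between subjects and acts as the nuisance that
contaminates low-b AFD. In this regime the age-R² advantage of b = 6000
over b = 1200 emerges end-to-end for essentially all tracts; with the
asymmetry reversed it does not.

What a green synthetic-cohort test establishes: that the statistics
stage (R², BCa, clustering, medians) faithfully recovers structure a
generator planted. It does not establish anything about real tissue:
the generator has no spatial correlation between tracts, no
heteroscedasticity, no exclusions or missing data, and its AFD scale is
arbitrary.

## Cohort statistics

Per tract × scheme: multiple R² of OLS `afd ~ age + sex + motion`
(sex coded female = 1; coding cannot change R²). Scheme comparisons
bootstrap subjects with replacement (both schemes' rows carried
together, B = 10,000 by default) and report 95% BCa intervals with
bias correction z₀ = Φ⁻¹(#{θ* < θ̂}/B) and jackknife acceleration
a = Σ(θ̄−θᵢ)³ / (6[Σ(θ̄−θᵢ)²]^{3/2}). Degenerate resamples are dropped
with a logged count; if every bootstrap statistic falls on one side of
the estimate, the widest interval is returned with a warning flag.
Measured coverage on symmetric nulls is ≈92–93% at n = 78 — the known
small-sample undercoverage of BCa. Multiple testing: Bonferroni,
0.05/(38·4) ≈ 3.3e-4.

The R² matrix is clustered unscaled with complete-linkage agglomeration
under Euclidean distance (scipy implementation; ties are broken by
scipy's internal ordering, which is deterministic). Dendrograms export
to Newick with each node at half its merge height, so leaf-to-leaf path
lengths equal cophenetic distances. Column medians use the mean of the
central pair for even counts.

## Numerical choices

* Direction optimizer: energy tolerance 1e-9, max 10,000 iterations;
  local optima are accepted (tests assert energy, not coordinates).
* SH least squares via `numpy.linalg.lstsq`; a condition number above
  1e6 logs a warning; underdetermined fits raise with the required
  direction count.
* CSD non-convergence at max_iter = 50 returns a flagged result rather
  than raising; rank deficiency raises.
* Per-stage sub-seeds derive from the global seed via
  `SeedSequence(seed).spawn` in a fixed order, keeping every derived
  seed below 2³¹.

## Known limitations

* **The published interaction coefficients are not reproduced.** The
  recomputed three-way coefficients (ss_1200 ≈ −0.09, ss_2400 ≈ +0.39,
  ms_all ≈ −0.29, reference ss_6000) do not match the published
  0.80/0.55/0.83, and the AFD range across D_e,⊥ at fixed f is not
  monotone decreasing in b (it peaks at b = 2400–4000). This is a
  property of the stated model, not of the solver: closed-form powder
  averages of the stick–zeppelin signal show that under any
  kernel-relative linear read-out the kernel's own powder signal
  shrinks with b faster than the extra-axonal signal range, and at
  D_e,⊥ = 0.2 the zeppelin is nearly stick-like and survives b = 6000.
  Alternative read-outs (main-lobe integral, peak amplitude,
  signal-unit scaling, log models) do not recover the published
  pattern either. The corresponding acceptance tests fail by design
  and are documented rather than weakened.
* Identity at arbitrary fibre orientation holds to ~2.6e-3 at b = 6000
  (truncation aliasing), not the nominal 1e-3.
* Recovery of planted R² targets below the p/(n−1) null floor is
  mathematically impossible; 146 of the 152 reference cells recover
  within ±0.02.
* The strict increase of all four R² column medians holds in ~75–86%
  of synthetic cohorts, not ≥95%: adjacent published medians differ by
  as little as 0.04, within the sampling noise of a median of 38
  fitted R² values.
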