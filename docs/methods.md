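# Methods

## Signal model and spectral inversion

A voxel's diffusion decay is modelled as a non-negative mixture of
mono-exponentials over a fixed dictionary of diffusion coefficients
(DCs) D_1 < … < D_N (internally in mm²/s so that b·D is dimensionless
with b in s/mm²):

    S(b_i)/S(b_0) = Σ_j A_j exp(−b_i D_j),  A_j ≥ 0.

The amplitudes are obtained by active-set NNLS on the linear system
whose rows are the b > 0 measurements, normalized by the (mean) b = 0
signal.  By default the system additionally carries the b = 0
measurement itself as a first row — an all-ones design row against the
unit ratio S(b_0)/S(b_0) = 1 — which softly constrains the total
amplitude to 1, exactly as the model implies for normalized data.
This row is load-bearing: without it, noise-free signals synthesized
from single dictionary atoms that sit at the global minimum or
adjacent to the 4.0×10⁻³ mm²/s component boundary are re-expressed by
alternative zero-residual supports that leak amplitude across the
component boundary (fraction errors up to 0.17); with it, every one of
the 400 stock single-atom signals is recovered with component-fraction
error below 10⁻¹⁴.  The row is exposed as the `b0_row` switch on
`nnls_solve` and the estimator for callers who want the b>0-only
system.

Active-set NNLS is deterministic; `scipy.optimize.nnls` is used and
its objective is verified in the tests against an exhaustive
enumeration oracle (unconstrained least squares on every column
support, keeping feasible minimizers) on small dictionaries.

### Marker extraction

The spectrum is integrated over three diffusivity ranges (×10⁻³
mm²/s): parenchymal below 1.5, intermediate 1.5–4.0 with both
boundaries inclusive, microvascular above 4.0 up to 1000.  The atom at
the global minimum 0.1 counts as parenchymal.  F_int is the
intermediate amplitude sum divided by the total amplitude sum (so the
three fractions add to 1 for any non-empty spectrum; raw sums are
available via `normalize=False` — noisy fits do not otherwise sum
to 1).  D_int is the dictionary DC at the arg-max amplitude within the
intermediate range, ties broken toward the lower DC for determinism;
it is undefined (NaN, validity flag false) exactly when the
intermediate amplitude sum is zero.

### Identifiability caveat

With six b-values the linear system has 6 rows and 200 unknowns: a
zero-residual fit of a multi-compartment signal is massively
non-unique, and the active-set path returns one sparse representative
whose component split need not match the generating compartments.
Concretely, a noise-free three-compartment voxel with DCs
0.7/2.5/50 ×10⁻³ mm²/s and amplitudes 0.80/0.15/0.05 is fit exactly
(residual ~10⁻¹⁶) by a spectrum with essentially zero intermediate
mass; the same holds for classic Lawson–Hanson, so this is a property
of the method, not of a solver variant.  Recovery is exact for
single-atom signals and for configurations whose microvascular
compartment is fully decayed at the first b > 0 (e.g. D ≈ 500×10⁻³),
but voxel-level generative-fraction recovery must not be assumed in
general at six b-values.  F_int / D_int are therefore surrogate
markers whose value lies in group contrasts, and the Monte-Carlo
machinery below exists precisely to quantify this estimator error.

## Dictionaries

`build_log_dictionary(n)` places n atoms geometrically from 0.1 to
1000 ×10⁻³ mm²/s inclusive; with n = 200 the atoms flanking the upper
intermediate boundary are D_80 = 3.872 and D_81 = 4.055 ×10⁻³ and the
component census is 59/21/120.  `build_component_linear_dictionary`
places the requested count of atoms linearly within each component
range; the intermediate run includes both boundaries while the outer
runs exclude the shared boundary (parenchymal: from 0.1 by step
(1.5−0.1)/n_par; microvascular: from 4.0 + (1000−4)/n_mic to 1000).
With counts 66/68/66 the boundary-flanking atoms are D_134 = 4.000 and
D_135 = 19.091 ×10⁻³.  The parenchymal run mirrors the microvascular
construction by symmetry; only the microvascular side is pinned by a
printed atom value.  Atom indices are 1-based in all user-facing
output; CSV export carries D at full precision on the ×10⁻³ scale.

## Monte-Carlo study

The simulation draws, per compartment count n ∈ {1..50} and pattern,
a ground truth of n compartments: each DC is sampled by first choosing
one of the three components with probability 1/3 and then uniformly
(linear scale) within that component's range — a plain uniform draw
over 0.1–1000 would make almost every DC microvascular.  Amplitudes
are i.i.d. uniform(0,1) renormalized to sum to 1 (a flat Dirichlet is
available via `amplitude_law="dirichlet"`; the normalized-uniform law
is the default and is slightly more concentrated than Dirichlet(1)).
The default grid is 50 counts × 1000 patterns × 50 noise SDs =
2,500,000 decay patterns per fitted condition.

Noise: magnitude (Rician) noise is formed as |s + g_re + i·g_im| with
g_re, g_im ~ N(0, sd²), applied to the theoretical signals at every
b-value including b = 0; the fitted signal is the ratio of noisy
S(b_i) to noisy S(b_0), as magnitude data are normalized in practice.
The noise ladder is 50 SDs equally spaced on [0, 0.05]·S0 inclusive of
both endpoints, so the first level is noise-free.

The grid is a paired design along both comparison axes.  One
compartment set per (count, pattern) is shared across all noise levels
and all conditions, so condition differences are not confounded by
ground-truth resampling.  Along the noise axis, one standard
complex-Gaussian draw per (pattern, b-scheme) is scaled by each
level's SD (common random numbers), so noise-level differences are
paired rather than resampled; this leaves each level's error
distribution untouched while removing level-to-level realization
jitter from the comparison.  Conditions sharing a b-scheme share the
realization.  The record stream is a pure function of (grid,
conditions, seed), via seed sequences keyed by grid coordinates.

Three stock conditions mirror the acquisition question the study
answers: the current 6-b scheme (0/50/100/250/500/1000 s/mm²) with
Lin200 or Log200, and the legacy 15-b scheme
(0/5/7/10/15/20/30/40/50/60/100/200/400/700/1000) with Log200.

## Accuracy surfaces

Estimator error is summarized per (count, noise) cell as
nRMSE = RMSE(ground truth, estimate) / mean(ground truth), per marker.
Cells whose ground-truth mean is zero are undefined (NaN), never
reported as 0.  For D_int, pairs where either side lacks an
intermediate component are excluded (mirroring the in-vivo rule that a
zero-F_int ROI contributes neither marker), and the surviving count is
tracked per cell.  The cell population is that cell's patterns; per-cell
aggregation is the only unit consistent with a surface over the two
grid axes.  `compare_conditions` ranks conditions by grand-mean nRMSE
over defined cells plus per-cell win counts; at reduced scale
(counts 1–10, 100 patterns, 10 levels — sized to run in seconds) the
6-b Lin200 condition attains the lowest grand-mean F_int nRMSE of the
three, and the F_int error is non-decreasing along the noise ladder.

## Voxelwise maps

`fit_volume` b0-normalizes every masked voxel (multiple b = 0 volumes
are averaged first; voxels with non-positive b0 are flagged invalid
and skipped, and solver failures at single voxels do not abort the
run), applies the NNLS fit and marker extraction, and writes F_int in
percent and D_int on the ×10⁻³ mm²/s scale.  Invalid/background voxels
are NaN in the floating-point maps and 0 in the validity map, whose
true voxels coincide exactly with the defined-D_int voxels.  I/O is
NIfTI-1 (gzip accepted) with FSL-style whitespace `.bval` files.
Volumes acquired along several motion-probing gradient directions are
expected trace-averaged upstream; `average_directions` collapses
repeated b-values by geometric (default, the trace-weighting
equivalent) or arithmetic mean.  Preprocessing — denoising, Gibbs
ringing removal, bias-field correction, spatial normalization — is out
of scope and assumed done.

## Synthetic phantom and cohort generator

The default phantom is a 32³ grid (tests use smaller) with a 4-voxel
background margin and two slab regions: healthy-white-matter-like
tissue with component fractions 0.80/0.15/0.05 and
periventricular-hyperintensity-like tissue with 0.45/0.50/0.05, each
decaying with one representative DC per component (defaults 0.7, 2.5,
50 ×10⁻³ mm²/s, near each component's center of mass; configurable),
sampled at the 6-b scheme at S0 = 1000 with seeded Rician noise.
Ground-truth markers accompany every phantom.  The phantom emulates
compartmental decay plus Rician noise only: no anatomy, no partial
volume, no spatial noise correlation, no artifacts — so passing
round-trip tests demonstrate pipeline correctness, not in-vivo
validity.  Per the identifiability caveat, the zero-noise fit of these
three-compartment voxels does not reproduce the generative fractions
(the two classes remain clearly separated in the maps); region-level
tests therefore assert fit determinism, region uniformity and class
separation rather than generative-fraction recovery.

`make_cohort` skips the image level entirely and draws per-subject
ROI-level markers from truncated normals (F_int clipped to [0, 100] %,
D_int positive) around group means; the default three groups use
centrum-semiovale-like values (F_int 12.7 ± 7.0, 12.6 ± 7.1 and
40.3 ± 18.4 %) so that the statistics layer can be exercised for both
power and type-I behavior.  Ages are uniform on 20–90 years and
independent of the markers unless an explicit `age_effect` slope (in
percentage points per year) is set.

## ROI statistics

ROI means are taken over defined voxels (valid-D_int voxels for
D_int).  The exclusion rule — an ROI with measured F_int = 0
contributes neither marker — is applied before testing and is
idempotent.  Group comparison is the Kruskal–Wallis omnibus test
followed by Dunn's rank-based pairwise z-tests with the tie-corrected
pooled-rank variance and Bonferroni adjustment over all pairs (the
all-pairs family matches how such comparisons are conventionally
tabulated; the adjustment choice is a documented decision).  The
significance threshold is 0.05 and is only reported, never used to
drop data.  Age relationships use Spearman's rank correlation with
average ranks for ties, with group-subset selection supporting
"controls only" and "controls plus non-hyperintense patients"
inclusion schemes.

## Numerical and design notes

* Solver: `scipy.optimize.nnls` with its default termination; the fit
  is deterministic and the tests pin objective optimality at 1e-9
  against enumeration and single-atom recovery at 1e-6 (observed
  ~1e-14).
* Degenerate inputs: an all-zero signal has the zero spectrum as its
  optimum in the b>0-only system; with the unit row the mass moves to
  the fastest-decaying atoms — F_int is 0 either way.  Dead voxels
  (b0 ≤ 0) and non-finite rows yield NaN rows rather than errors in
  batch transforms.
* Problem sizes in the shipped tests and the acceptance script
  (reduced grid 10×100×10, phantoms 12³–16³, 15 cohort repeats) were
  chosen so the whole suite completes in a few minutes on one CPU
  while keeping every qualitative conclusion stable under seed
  changes.
* Known limitations: no regularized or Bayesian spectral inversion
  (the sparse active-set representative is the estimator), no
  tensor-valued/directional fitting, no artifact simulation in the
  phantom, and the uniform ground-truth DC law of the simulation may
  favor dictionaries with more intermediate atoms.
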