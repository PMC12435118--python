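# specdiff

Spectral diffusion analysis (SDA) of multi-b-value diffusion MRI in
Python: non-negative least-squares (NNLS) decomposition of diffusion
signal decay over a dictionary of diffusion coefficients, yielding
surrogate markers of interstitial-fluid volume (**F_int**) and
diffusivity (**D_int**), together with a Monte-Carlo framework for
evaluating b-value schemes and dictionary designs, voxelwise map
computation, a synthetic DWI phantom, and ROI-level nonparametric
statistics.

## The problem and the model

Diffusion-weighted MRI signal in brain tissue decays with the
diffusion weighting *b* as a mixture of compartments.  SDA is a variant
of intravoxel incoherent motion analysis that imposes no fixed
compartment count: the normalized decay is modelled as

    S(b_i) / S(b_0) = Σ_j  A_j · exp(−b_i · D_j),      A_j ≥ 0,

where the candidate diffusion coefficients *D_j* form a fixed
dictionary and the non-negative amplitudes *A_j* are found by NNLS on
the design matrix `A[i, j] = exp(−b_i D_j)` (the linear system also
carries the b = 0 measurement as a unit row, softly constraining
Σ A_j = 1).  The spectrum is integrated over three diffusivity ranges
(in 10⁻³ mm²/s):

| component | range | interpretation |
|---|---|---|
| parenchymal diffusion | 0.1 – 1.5 | hindered tissue water |
| intermediate diffusion | 1.5 – 4.0 (inclusive) | interstitial-fluid-like water |
| microvascular pseudo-diffusion | 4.0 – 1000 | capillary perfusion |

**F_int** is the summed (total-normalized) amplitude in the
intermediate range and **D_int** the dictionary diffusivity at the
maximum amplitude inside it; both serve as surrogate markers of
interstitial-fluid volume and diffusivity, of interest e.g. in
normal-pressure hydrocephalus, where cerebrospinal fluid permeates
periventricular tissue.

Two stock dictionaries are built in: `log200` (200 geometrically
spaced coefficients over 0.1–1000 ×10⁻³ mm²/s; 59/21/120 atoms per
component) and `lin200` (66/68/66 atoms linearly spaced within each
component range), plus generalizations of either scheme.  The package
also ships the Monte-Carlo study used to compare acquisition schemes:
random multi-compartment ground truths (1–50 compartments, components
sampled with equal probability), Rician noise from 0–5 % of S0, and
normalized-RMSE accuracy surfaces per compartment count and noise
level.

## Worked example

The central interface is a scikit-learn style transformer mapping a
matrix of decay signals (one row per voxel, one column per b-value) to
the four spectral features:

```python
import numpy as np
from specdiff import SpectralDiffusionAnalysis, make_default_phantom

dwi, labels, gt = make_default_phantom(noise_sd=0.02, seed=7, shape=(16, 16, 16))
X = np.vstack([dwi.data[labels == 1][0], dwi.data[labels == 2][0]])
sda = SpectralDiffusionAnalysis(dictionary="lin200")  # b-values 0/50/100/250/500/1000
print(sda.fit(X).transform(X))
# [[0.0504 0.004  0.8811 0.0685]
#  [0.0996 0.004  0.7718 0.1286]]
print(sda.get_feature_names_out())
# ['f_int' 'd_int' 'f_parenchymal' 'f_microvascular']
```

Row one is a healthy-white-matter-like voxel (F_int 5 % at this noise
realization), row two a periventricular-hyperintensity-like voxel
(F_int 10 %); `d_int` is in mm²/s and is NaN wherever the intermediate
range carries no amplitude.  Whole volumes go through
`fit_volume` / `extract_roi`:

```python
from specdiff import fit_volume, extract_roi

maps = fit_volume(dwi, dictionary="lin200")          # F_int %, D_int ×10⁻³
print(extract_roi(maps, labels, names={1: "HC-WM", 2: "iNPH-PVH"}).to_string(index=False))
#   region  label  n_voxels  n_f_int     f_int  n_d_int    d_int
#    HC-WM      1       256      256 10.058685      107 3.399149
# iNPH-PVH      2       256      256 45.720618      229 2.941374
```

The two synthetic tissue classes (generative intermediate fractions
0.15 and 0.50) separate clearly in the noisy maps.  Group statistics
(Kruskal–Wallis omnibus, Dunn's pairwise post-hoc with Bonferroni
adjustment, Spearman age correlation, and the zero-F_int exclusion
rule) live in `specdiff.roistats`.

A `specdiff` command-line tool wraps each stage
(`dict`, `simulate`, `evaluate`, `fit`, `phantom`, `roistats`); run
`specdiff --help`.

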