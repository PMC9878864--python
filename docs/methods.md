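# Methods

## The model

A lambda stack records, at every voxel, fluorescence intensity in C narrow
emission bands (here 32 bands covering the visual spectrum roughly every
8 nm). Fluorescent emissions mix linearly, so after flattening the stack to
an n-pixel matrix the observation model is

    F = S A,        F ∈ [0,1]^{C×n},  S ∈ [0,1]^{C×k},  A ∈ [0,1]^{k×n}

where the columns of S are the emission signatures ("fingerprints" or
endmembers) of the k sources — fluorophores, autofluorescence such as
lipofuscin, and a background term — and A holds per-pixel abundances.
Unmixing recovers A (and, when requested, S) from F. The number of sources
k is assumed known (it equals the number of dyes plus the autofluorescence
and background terms) and must not exceed C, or the system is
under-determined.

The only pre-processing is normalization: division by the saturation value
of the source integer type (`dtype_max`), never by a per-image maximum, so
intensities remain comparable across the images of a batch. Flattening is
z-major row-major and exactly invertible; band order is forced ascending in
wavelength on read.

## Endmember extraction (VCA)

Under the linear model all pixel spectra lie in the simplex spanned by the
endmembers; if each source has at least one pure pixel, the vertices of
that simplex are observed spectra. Vertex component analysis finds them by
iteratively projecting the data onto random directions orthogonal to the
span of the vertices already found and taking the extreme pixel. Before the
iteration the data are reduced to k dimensions: at high estimated SNR by a
singular-subspace projection followed by perspective (projective) scaling,
at low SNR by mean removal, (k−1)-dimensional PCA and a constant
coordinate. The SNR estimate compares the energy captured by the
k-dimensional principal subspace with the residual energy; the path
threshold is 15 + 10·log10(k) dB, the value used in the original VCA
publication, and can be overridden to force either path. Zero pixels are
excluded as candidates. All randomness comes from one seeded generator
(`numpy` PCG64); given (data, k, seed) the selected pixel indices are
reproducible exactly.

Two extraction workflows are supported. With *single positives* (one
specimen per fluorophore) VCA runs with k = 2 per stack; the two columns
are the fluorophore and the background signature. They are told apart by
unmixing the stack against both candidates and comparing the mean total
intensity of the pixels each candidate dominates — the fluorophore wins the
bright pixels. One shared background column (the flattest, by lowest
peak-to-mean ratio) is kept for the assembled set. With a *multiplex* stack
VCA runs once with the full k and the columns are labeled by maximum-
correlation assignment against reference curves (exact Hungarian
assignment; ties broken toward agreeing peak wavelengths and flagged). A
column whose best correlation is below 0.5 is labeled `unassigned`. Two
extracted columns that correlate above 0.98 with *each other* are one
simplex vertex found twice — the signature of a missed endmember, which is
exactly what happens when an autofluorescence spectrum nearly coincides
with a dye; the weaker duplicate is demoted and its reference reported
unmatched rather than silently mislabeled.

## Abundance estimation

**FCLSU.** Per pixel, minimize ‖S a − x‖² subject to a ≥ 0 (non-negativity,
ANC) and Σa = 1 (sum-to-one, ASC). This is solved *exactly* by an
active-set method on the equality-constrained KKT system with dual
feasibility checks. Inactive variables are pinned by row substitution so
every pixel solves the same (k+1)-sized system, which lets the whole image
batch move through vectorized `numpy` solves; the result is independent of
pixel order and worker count by construction. Pixels with zero total
intensity receive all-zero abundance columns — forcing them onto the
simplex would manufacture meaningless compositions.

**ELMM.** Spectral variability is modeled as a per-pixel, per-endmember
scalar scaling ψ: minimize ½‖S·diag(ψ)·a − x‖² + (λψ/2)‖ψ − 1‖² with a on
the simplex and ψ ≥ ψ_min. Block-coordinate descent alternates an exact
FCLSU step against the scaled endmembers with closed-form coordinate
updates of ψ (clipped at ψ_min), so the objective never increases. The ASC
is kept deliberately: a carries proportions, ψ carries amplitude.

With λψ = 0 the per-pixel factorization a·ψ is not identifiable for
mixed pixels (only the product is), and the alternating scheme has
non-optimal fixed points where excess simplex mass hides on endmembers with
near-floor scalings. Each iteration therefore also evaluates two cheap
escape candidates per pixel — a product-preserving prune of floor-pinned
components, and a dominant-vertex collapse with exact one-dimensional
rescale — accepting either only when it strictly lowers the objective.
Monotonicity is preserved and pure pixels converge to the exact vertex
solution in finitely many steps.

**GELMM.** The scaling becomes a per-pixel band profile Ψ ∈ R^{C×k}:
minimize ½‖(S∘Ψ)a − x‖² + (λ_s/2)Σ_j‖D₂Ψ[:,j]‖² + (λ_u/2)‖Ψ − 1‖², with D₂
the second-difference operator across bands. Alternation: exact a-step on
the scaled endmembers; per-endmember profile updates solving
(diag(w²) + λ_s·D₂ᵀD₂ + λ_u·I)ψ = rhs, which is symmetric pentadiagonal and
handled by a batched O(C) LDLᵀ solver vectorized over pixels (validated
against dense solves to 1e−13). The ψ ≥ ψ_min bound uses clamp-and-resolve
with the clamped columns' coupling moved to the right-hand side. Ψ is
initialized from the ELMM solution (Ψ[:,j] = ψ_j·1).

Neither ELMM nor GELMM uses spatial regularization: the remote-sensing
formulations they derive from couple neighboring pixels, but puncta in
tissue are spatially sparse and the per-pixel problems stay embarrassingly
parallel.

Defaults: λψ = 0, λ_s = λ_u = 0.01, ψ_min = 1e−3, relative-objective
tolerance 1e−6, max 200 (ELMM) / 100 (GELMM) iterations.

**Channel reconstruction.** Unitless abundances are converted to
ZEN-comparable intensity images by the modeled peak-band contribution:
channel j at a pixel is a_j · (scaling at the peak band) · S[peak_j, j] ·
dtype_max, rounded half-to-even to the source dtype (overflow clamps to
dtype_max and is counted). Raw float abundance maps are also written for
quantitative use. A binary lipofuscin mask (any nonzero reconstructed
lipofuscin intensity) is exported for downstream autofluorescence masking.

## Metrics

RMSE, SSIM and Dice operate on [0,1]-normalized images. SSIM is the
windowed product of luminance, contrast and structure factors with the
standard constants C1 = (0.01L)², C2 = (0.03L)², C3 = C2/2, L = 1, and an
11×11 Gaussian window (σ = 1.5); exponents α, β, γ default to 1, under
which the implementation is algebraically symmetric in its arguments. 3-D
stacks are scored per z-plane and averaged for SSIM; RMSE and Dice use
whole volumes. Dice binarizes at "nonzero after conversion back to the
integer dtype" by default; the threshold is configurable because any Dice
on grayscale unmixed images implies a binarization choice. Both masks empty
is defined as Dice 1 (identical segmentations). Comparisons against
*ground-truth* masks (as opposed to a reference unmixing) instead use a
fixed detection threshold of 0.1 on abundance for both sides: at the
benchmark SNR the solver assigns O(1e−2) noise abundances everywhere, so a
pure nonzero rule would score noise, not separation.

## The synthetic generator

The generator is the test bed standing in for microscope data. Emission
curves are log-normal-shaped lobes, exp(−ln²(λ/λ_peak)/2ρ²) — unit maximum
at the nominal peak with the long red tail real fluorophores have, which is
what makes neighboring dyes bleed. The default panel is DAPI (461 nm, plus
a secondary lobe near 510 nm that produces the documented bleed into the
520 dye), four Opal-like dyes peaking at 520/570/620/690 nm, a broad
flat-ish lipofuscin curve (wide lobe at 550 nm over a 0.35 offset), and a
background signature modeled as a low flat noise floor (2% of peak) plus a
narrow residual excitation spike at the blue edge of the grid. The default
grid is 32 bands, 410–658 nm in 8 nm steps; the 690 nm dye's maximum lies
past the detector range, so its recorded fingerprint rises to the last band
— as it does on a real 32-band detector. An engineered variant replaces
lipofuscin with a near-copy of the 520 dye to reproduce the known failure
mode of multiplex fingerprint extraction.

Scenes place non-overlapping hard-ellipsoid nuclei (DAPI), per-gene 3-D
Gaussian puncta with Poisson-distributed counts (σ ≈ 1.5–2.5 px in-plane),
and lipofuscin as irregular clumps of overlapping blobs that preferentially
hug nuclei. Per-pixel abundances sum to at most 1 and the background map
completes the sum to 1 (floored at 0 against ulp overshoot from rescaling
overlaps). The first object of every class is rendered pure (abundance
exactly 1 at an integer voxel), so the pure-pixel assumption of vertex
extraction holds by construction — the synthetic analogue of the bright
isolated punctum a microscopist would pick by hand. Defaults: ~1 nucleus
per 2500 in-plane pixels, 2 puncta per 1000 px³ per gene, 0.15 lipofuscin
clumps per 1000 px³ (1.0 for lipofuscin single positives, which emulate
negative-control tissue rich in granules).

Rendering is F = S·A exactly (to integer quantization), optionally with
drawn ψ fields (ELMM variability), a step attenuation of one endmember
above a wavelength, or smooth random band curves (GELMM variability), then
Poisson shot noise (off by default) and Gaussian read noise calibrated so
10·log10(P_signal/σ²) hits the requested SNR over signal pixels. Everything
is reproducible bit-exactly per seed.

What the generator does *not* emulate: optics (no PSF, no chromatic
aberration), photobleaching and quenching (the linear model's stated
limitation), detector gain variation across bands, and the textured
nonuniform autofluorescence of real tissue. Passing tests therefore show
the algorithms are implemented correctly and behave as designed under the
linear model with realistic spectral overlap and noise — not that unmixing
of any particular real specimen reaches the same accuracy.

## Validation scenes and sizes

The study-scale experiments (in `specunmix.benchmarks`, asserted by the
acceptance tests and reported by `scripts/acceptance.py`) use: 100 random
C=4, k=3 instances against a dense simplex-grid + SLSQP oracle; 420 VCA
recovery runs (k = 2..8, C ∈ {8,16,32}, 20 draws); six 2×64×64 single
positives at 40 dB and 2×96×96 multiplex stacks; 256×256 spectral-
variability mosaics; and a 256×256×4×32 six-member scene at 30 dB for the
end-to-end benchmark. These sizes keep the full suite in the minutes range
on one CPU while leaving every per-pixel problem identical to the
paper-scale (1024×1024) case — all solvers are strictly per pixel, so
accuracy results do not depend on image area, only runtimes do.

The ELMM recovery mosaic is rendered at abundance 0.8: unit-max spectra
scaled by ψ up to 1.2 would saturate the integer detector range. With the
ASC the solver's scaling on a single-endmember pixel equals
amplitude × ψ, so the benchmark divides by the amplitude before scoring —
the physically identifiable quantity is the product. The GELMM attenuation
scene uses a 410–700 nm grid so that several bands lie above the 650 nm
step edge.

## Known limitations

* Linear mixing only; quenching, photobleaching and other nonlinearities
  are out of scope.
* k > C systems are rejected, not regularized.
* ELMM/GELMM with λψ = λ_u = 0 are non-convex; the escape steps make
  pure-pixel recovery exact but global optimality on arbitrary mixed data
  is not guaranteed (it is not identifiable there in any case).
* CZI input requires an optional reader plug-in that is not bundled;
  OME-TIFF is the supported interchange format.
* SSIM on constant images is dominated by the stabilization constants; the
  reported value is clipped to [0, 1].
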