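# Methods

## Scene model

Scenes are hypercubes `H(x, y, λ)` on a strictly increasing wavelength
grid (nm), stored `(row, col, band)`, origin top-left, 0-based. The linear
mixing model synthesizes `H(n, m, ·) = E · A(n, m) + n` with endmember
matrix `E (Q × L)` and abundance map `A (N × M × L)`. Abundances are
constrained nonnegative only; ground-truth maps additionally keep
per-pixel sums ≤ 1, but no sum-to-one constraint is imposed anywhere
(reference abundance maps in the literature are themselves nonnegative
least-squares products and do not sum to one). Noise is i.i.d. Gaussian
per (pixel, band); negative radiance is clipped at 0 by default
(`clip_negative=False` disables, e.g. for noise-statistics checks).
Radiance units are arbitrary: every merit compares abundances or
normalized reconstructions, so no absolute calibration is assumed.

A consequence of band-level noise worth stating explicitly: two filters
with identical responses integrate the *same* noise realization, so exact
channel duplication never improves unmixing in this model. Redundant
sampling of a spectral feature instead appears as two filters offset by
roughly one bandwidth, which decorrelates their band noise while staying
on the feature. This differs from a per-measurement (sensor shot/read)
noise model, where literal duplication averages noise; the simulator
implements only the band-noise model.

## Channel integration

Channel signals and effective endmember signatures are trapezoidal
quadratures of `F_j(λ) H(n, m, λ)` and `F_j(λ) E_l(λ)` on the native
grid — exact under the piecewise-linear reading of the sampled spectra,
and commuting with the mixing model, so the noiseless un-mosaicked
pipeline recovers abundances to solver precision whenever the effective
design has full column rank. Gaussian filters are peak-normalized
(maximum response 1); bandwidth is FWHM by default or the Gaussian σ
(both conventions appear in published designs). Arbitrary tabulated
response vectors are accepted wherever a Gaussian filter is.

## Demosaicking

**WBI.** Each channel is interpolated with a separable triangular kernel
of half-width equal to the unit-cell pitch per axis, as the
mask-normalized ratio `(Ĩ_j ∗ B) / (p_j ∗ B)`; the normalization removes
boundary attenuation, and boundaries use symmetric reflection (a dark rim
would bias the spatial merit toward patterns that keep channels away from
edges). Measured pixels are re-imposed exactly, which also covers cells
where a channel occupies several sites (RGGB-style double greens).

**Spectral differences.** For target channel j and each donor k ≠ j, the
channel difference at j's sampled pixels is `Δ_kj = Î_k^WBI ⊙ p_j − Ĩ_j`;
it is raised to full resolution by the same mask-normalized interpolation
over `p_j`, and the donor-based estimate is `Î_k^WBI − Δ̂_kj`. The K = J−1
estimates are averaged (without the 1/K the estimate would scale with
channel count) and measured pixels are re-imposed. The published
formulation masks the assembled sum onto `p_j`, which cannot yield a
full-resolution image; the interpretation above is the standard
difference-interpolation scheme consistent with the surrounding
definitions, and the test suite pins it against an independent loop
transcription. Difference fields are smoother than the channels when
channels are correlated, which is exactly when the method beats WBI;
on constant planes it is exact.

**Iterative spectral differences.** The same update repeated; pass t uses
the pass t−1 estimates as donors, and pair (k, j) freezes its contribution
after `G_kj` passes. `G_kj = max(1, round(exp(−3 σ_kj)))` — the clamp
guarantees at least one pass, and for any dissimilarity σ ≥ 0 the count
is exactly 1, so extra passes arise only from a user-supplied σ < 0
(anti-correlated channels). The bundled default statistic is
`σ_kj = 1 − ρ_kj`, the Pearson correlation distance of the full-resolution
channel planes over pixels (constant planes count as perfectly
correlated); the published definition of σ is ambiguous about the
ensemble, so any user σ matrix is accepted and the default should not be
read as canonical. With `G ≡ 1` the iterative path is bit-identical to
single-pass spectral differences (same code path).

## Unmixing

Per-pixel active-set NNLS (`scipy.optimize.nnls`), deterministic, pixels
independent. Rank-deficient designs are solved anyway (NNLS remains
well-posed) with a warning reporting the condition number. A fully
constrained variant (soft sum-to-one via a weighted ones-row, weight 1e4)
exists behind a flag but is never used in the reproduction pipeline.

## Merit functions

All four objectives are RMS forms, zero iff exact agreement. The spectral
and total merits treat the inner square over the L-vector as the squared
Euclidean norm (the only reading that yields a scalar):
`ε = sqrt( Σ_{n,m} ‖A₀ − Â‖² / (N M) )`. The spectral merit unmixes the
*un-mosaicked* channel signals (every filter responsive at every pixel)
and so scores the filter set alone; the total merit unmixes the
demosaicked mosaic signal and is the design's end-to-end unmixing error.
The spatial merit is `sqrt( Σ (I_j − Î_j)² / (N M J) )` against the
un-mosaicked planes. The RGB merit is the RMS over pixels and 3 channels
between sRGB renderings of the scene and of the MSFA reconstruction, on
linear-light values (display gamma would make the objective depend on a
transfer function irrelevant to the physics; gamma is applied only at PNG
export).

## Spectral search

*Gradient (coordinate) descent*: bandwidths start at the midpoint of the
allowed range; centers are drawn without replacement from the scene's
discrete wavelength grid restricted to the search range; the best 5 of
`n_random_starts` (default 50) random draws are refined by cycling ±2 nm
center perturbations then ±2 nm bandwidth perturbations (the center step
is published; the bandwidth step mirrors it and is configurable), keeping
strict improvements, until a full cycle accepts nothing or `max_iters`
cycles. *Simulated annealing*: neighbors perturb every center and
bandwidth uniformly within ±10 nm, clipped to bounds; strictly improving
moves are always accepted with temperature unchanged; worsening (or
equal) moves are accepted with probability `exp(−Δε/T)`, and each such
acceptance cools by `T_step`. This cooling rule — temperature falls *only*
on accepted worsening moves — is implemented literally; it terminates
almost surely because worsening proposals always have positive acceptance
probability, and a `max_steps` cap plus an optional stall guard
(off by default: also cool after a configurable run of consecutive
rejections) protect against pathological schedules. Both searches are
deterministic for fixed seeds, memoize merit evaluations, and log every
candidate to the run trace.

With zero noise and J ≥ L, any full-rank design unmixes exactly and the
spectral landscape is flat at the solver floor; recovery studies therefore
add band noise (σ = 0.05 on order-1 endmember peaks), which makes filter
placement matter through the conditioning of the effective design. The
bundled recovery study fixes the bandwidth (bmin = bmax = 30 nm) so that
the optimum is a pure center-placement problem verifiable by exhaustive
search over all grid-center pairs.

## Spatial search

Every assignment of the J channels to the h × w unit cell (h·w = J) is
scored with the spatial merit and the argmin returned (ties: first in the
deterministic enumeration order). Cyclic-shift deduplication of unit
cells is available but off by default: a shifted cell tiles to a
*translated* sensor pattern, and against a fixed finite scene the
translated sampling grid scores differently (scene alignment and boundary
phase), so deduplication is a lossy reduction, not an equivalence. A
budget guard rejects J! enumerations beyond a configurable size.
Duplicate spectral channels are kept as distinct channels throughout; the
reporting layer flags pairs whose FWHM passbands intersect as
"nearly overlapping" (threshold overridable, e.g. to the emission
linewidth of the features under study).

## Colorimetry

Tristimulus values are trapezoidal quadratures against the CIE 1931
2° observer. The bundled 5 nm CMF table is generated from the
Wyman–Sloan–Shirley multi-lobe Gaussian analytic fit (accurate to ~1 % of
peak; negative lobe excursions clipped at 0; zero outside 360–830 nm) and
linearly interpolated to the scene axis. The sRGB primaries and D65 white
point enter as chromaticity coordinates; the XYZ→RGB matrix is the
primary-chromaticity matrix with columns scaled so the white point maps
to R = G = B = 1 (the published relation maps chromaticities through the
primary matrix and leaves this standard white-point scaling implicit — the
scaling is verified by the white-input anchor test). Out-of-gamut values
are clipped to [0, 1]; all-dark pixels take the white-point chromaticity
by convention. MSFA results are rendered by re-expanding each pixel as
`Σ_j Î_j F_j(λ)` before conversion; images are normalized by the scene's
maximum luminance Y.

## Synthetic scenes

The generator produces two scene families with full ground truth,
deterministic per seed.

*Reflectance* scenes emulate airborne land-cover cubes: 2–4 smooth
low-frequency cosine abundance fields (spatial wavelengths of roughly the
image size, matching the large contiguous regions of real land-cover
maps) normalized to per-pixel sums ≤ 1, and endmembers that are sums of
2–4 broad Gaussian lobes plus a reflectance floor.

*Fluorescence* scenes emulate benchtop dye imaging of a well plate: flat
circular wells (one per dye plus one equal mixture) on a dark background,
blurred by a 1.2 px Gaussian emulating the imaging PSF, with the
illumination endmember present uniformly. Dye emissions are single
Gaussians (FWHM 20–35 nm) whose peaks crowd the lower half of the
detection window, as real NIR dye panels do; the illumination endmember is
the source reflectance of a multi-LED lamp — a comb of LED lines near the
dye bands plus a dye-free reference line in the upper window. These
choices give the scene about as many informative narrow spectral sites as
endmembers, which is the regime in which channel counts above the
endmember count produce redundant (band-re-sampling) channels.

What the generator does **not** emulate: atmospheric effects and sensor
artifacts (only an explicit band-index mask is offered for bad bands),
spatially correlated or signal-dependent noise, endmember variability
within a scene, and per-measurement sensor noise (see above). Passing
tests on these fixtures therefore demonstrates correctness of the
pipeline and the qualitative design phenomenology, not performance on any
particular real sensor.

## Problem sizes and numerics

Bundled studies use 16 × 16 scenes with 151-band axes (2 nm grids) and
8 × 8 scenes for exhaustive grid oracles — small enough that every search
and every literal loop-based oracle runs in seconds to a couple of
minutes on one core, while keeping the NNLS systems and mosaic geometry
identical in structure to full-size problems. Merit memoization keys
round parameters to 1e-9 nm. Exact ties in searches resolve to the
first candidate in deterministic order. ENVI I/O supports BSQ/BIL/BIP
interleaves with little/big endian scalars; HDF5 uses `/cube` and
`/wavelengths` datasets; `.npz` archives add ground-truth abundance and
endmember arrays.

## Known limitations

Filter responses are ideal Gaussians (or user tables): no angular
blue-shift, Fabry–Pérot lineshapes, polarization, or fabrication
tolerancing. The spectral and spatial stages optimize sequentially, so a
design whose advantage only materializes end-to-end (e.g. duplication
purely for demosaicking resolution) is found only insofar as the spectral
objective already prefers it. Exhaustive spatial search is factorial in J
(practical to J = 8–9). NNLS runs per pixel in Python; very large scenes
will be slow.
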