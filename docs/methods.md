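# Methods

## Imaging model and scope

A fluorescence image of an ultrathin section is modelled as
`d = h ⊛ f + noise`: the section is thin enough (70 nm default) that no
out-of-focus light contributes, the PSF `h` is spatially invariant across
the field, intensities from point emitters add linearly, and the detection
noise is Poisson. These are exactly the conditions under which 2D
Richardson–Lucy (RL) deconvolution is the maximum-likelihood restorer, and
they are the package's operating assumptions throughout. Volumes are
treated as ordered stacks of independent 2D sections; nothing is ever
deconvolved across z, because the axial dimension is produced by physical
sectioning, not by optics.

## Point spread functions

**Empirical.** Bead-field images are screened for candidate beads as local
maxima above an automatic level (image median + 5·MAD; plateau ties broken
in row-major order). A candidate is discarded when its window leaves the
image, when the window contains two or more pixels exactly at the detector
saturation level (one saturated pixel is tolerated), or when two candidates
fall closer than the minimum separation (both are dropped — overlapping
tails would bias the average). Each surviving window is background
subtracted by the median of its one-pixel border ring, re-extracted so its
brightest pixel sits at the window center (integer-pixel registration —
sub-pixel interpolation would low-pass filter the kernel and bias the MTF;
the residual ≤0.5 px jitter is accepted), averaged, clipped at zero and
normalized to unit sum.

**Synthetic.** Four models share one contract (non-negative, unit-sum, odd
window, peak at center):

* `airy` — the paraxial incoherent pattern `(2·J₁(v)/v)²` with
  `v = 2π·NA·r/λ`; its first zero falls at `0.61·λ/NA`. Integrated over
  each pixel's area by 5×5 supersampling, modelling the camera pixel as an
  area detector.
* `bead_convolved_airy` — the Airy pattern convolved with a uniform disc of
  the bead diameter: what a real sub-diffraction bead images as, and the
  right reference when comparing against bead-derived empirical PSFs.
* `confocal_product` — pixel-wise product of excitation and emission Airy
  patterns (emission wavelength defaults to the excitation value),
  renormalized; the product of two unimodal patterns is strictly narrower
  than either.
* `gaussian` — isotropic Gaussian of a stated FWHM, *sampled at pixel
  centers* rather than area-integrated. This is a deliberate exception: the
  Gaussian model's contract is its width on the grid (box integration would
  widen it ~2%, breaking the FWHM round-trip), whereas the diffraction
  models' contract is physical.

Widths are measured as the FWHM of the central horizontal cross-section
with linear interpolation between pixels; a single-pixel delta therefore
reports one pixel.

## Richardson–Lucy

The update is the standard multiplicative EM step

    f ← f · [ mirror(h) ⊛ ( d / (h ⊛ f) ) ]

starting from a **uniform estimate carrying the observed total flux**, so
intensity is conserved from iteration zero. Convolutions are computed in
the Fourier domain on a canvas padded by edge replication (pad = PSF
radius by default), which avoids wrap-around artifacts; the pad is cropped
from the returned image. On the padded canvas conservation is exact
(machine precision) every iteration; on the crop it holds to <0.1% whenever
the image content stays a PSF radius away from the edge — content touching
the edge exchanges flux with the replicated border, which no pad-and-crop
scheme avoids. The division is guarded by a floor of 1e-12. Diagnostics
recorded per iteration: total intensity of the cropped estimate, relative
L1 change between successive estimates, and the Poisson negative
log-likelihood of the data under the current model (monotone non-increasing
— the EM property, asserted in tests).

**Iteration counts.** Image restoration defaults to 10 iterations, the
routine depth for section stacks, where the restoration is already strongly
sharpened but not yet spiky. Two-point threshold scans default to 500
iterations: the separation-2 dip for the reference Gaussian PSF (FWHM
3.2 px) only emerges after ~150–200 plain multiplicative updates, so scans
are run comfortably past that onset, effectively at the noiseless
maximum-likelihood limit. (Accelerated RL variants reach the same point in
far fewer nominal iterations; this package implements only the plain
update.) No automatic stopping rule is imposed.

**Blind deconvolution** alternates an image update (PSF fixed) with a PSF
update (image fixed) each iteration; the PSF is then re-projected onto its
fixed initial support window, clipped non-negative, recentered on its
brightest pixel, and renormalized. The initial kernel is a Gaussian
(FWHM 2.5 px unless stated). Blind RL recovers the generating kernel's
shape well on point-source images (Pearson r > 0.9 in tests) but returns
less light to the central pixel than RL with the true PSF.

## Frequency analysis

The MTF of a kernel (or of a restored point-source image) is the magnitude
of its DFT on a 256² zero-padded canvas, normalized by the zero-frequency
value, rotationally averaged into radial bins one DFT sample wide
(`pixel_limit/(pad/2)` cycles/µm); empty bins are dropped, and the DC bin
contains only the DC sample so modulation(0) = 1 exactly. Normalization
precedes averaging. Frequencies are in cycles/µm, matching the cut-off
convention `2·NA/λ` (5.74 cycles/µm at 488 nm, 1.4 NA); the pixel limit is
`1000/(2·pixel_nm)` (5 cycles/µm at 100 nm pixels — note that 100 nm
pixels under-sample the 488 nm diffraction limit, so the band between the
two limits is only non-empty at 50 nm pixels).

The "deconvolved modality's MTF" is defined as the MTF of the RL-restored
image of a point source — the restored PSF — so gains are measured on the
system response, not on object-dependent spectra. `mtf_gain` floors the
reference curve at 1e-12; `band_extension` reports the highest frequency
still above a contrast floor and the fraction of the (cut-off, pixel-limit]
band above it (0 when that band is empty).

## Two-point resolvability

Two copies of the PSF are added at integer pixel centers a stated number of
pixels apart (optionally with unequal intensities). The pair counts as
resolved when the line profile through the centers contains two strict
local maxima with at least one pixel strictly below both between them —
the weakest objective reading of "visibly separate" in a cross-section
plot; the dip depth `1 − min/smaller-peak` is reported so stricter criteria
can be applied afterwards. Maxima below 1e-6 of the profile peak are
ignored as multiplicative FFT roundoff. One-pixel separations can never
resolve (no pixel lies between adjacent centers). The reference PSF for
threshold experiments is the Gaussian of FWHM 3.2 px at 100 nm pixels,
which matches the width regime of empirical wide-field PSFs; a
diffraction-perfect Airy kernel is narrower and already resolves 3 px
without deconvolution.

## Poisson-noise calibration

"x% noise" scales the image so its brightest pixel corresponds to
`(100/x)²` expected photons (at which SD/mean = x/100), replaces every
pixel with a Poisson draw, and scales back. The definition is scale-free,
preserves expected intensity pixel-wise, and is reproducible from one
integer seed. The noise scan renders a point source through the PSF,
injects noise, restores with the true PSF (10 iterations), and averages the
raw and restored MTF curves over replicates (20 by default; single draws
make per-bin comparisons unstable). In-band frequency recovery degrades
monotonically with noise (≈19× mean in-band gain noiseless, ≈6× at 5%,
≈4× at 10% for the bead-convolved Airy reference). Note that the
*ratio* of restored to raw modulation stays above 1 in this protocol at any
noise level: RL sharpens the estimate, and a spikier image's spectral
modulus is pointwise at least that of the blurred noisy image, approaching
it from above as noise grows.

## Segmentation

Foreground voxels are those strictly above `fraction × dynamic-range`
(0.1 × 65535 = 6553.5 counts by default; values exactly at the threshold
are background). Components are labelled under 26-neighborhood adjacency
(face, edge and corner neighbours; sections adjacent in z), ordered by the
scan-order first voxel, and summarized by intensity-weighted centroids
(weights are the original voxel intensities — true centers of mass), voxel
counts and integrated intensities. The sum of integrated intensities over
components equals the foreground intensity sum exactly. Matching between
two puncta sets uses 3D nearest-neighbour distances in lateral-pixel units
with z scaled by `section_nm/pixel_nm`; connectivity itself stays
voxel-topological. Coordinates are 0-based voxel indices. Because RL
concentrates intensity well above the original camera range, restored
volumes should be mapped back onto the detector scale before applying the
absolute threshold.

## Synthetic scenes

Bead fields place delta sources at integer pixels (rejection-sampled to a
minimum separation, a PSF radius plus margin off the edges); filament pairs
are two parallel 1-px-wide unit columns with a stated number of blank
columns between them (straight lines suffice for separability
experiments); puncta volumes place 3D Gaussian blobs (in-plane σ drawn from
0.8–1.5 px, axial σ one section, amplitudes 0.5–1.0). Observed images are
the truth convolved section-wise with the PSF plus calibrated Poisson
noise; manifests record every object's coordinates and parameters, and a
fixed seed renders bitwise-identical scenes. These scenes emulate geometry
and photon noise only — not tissue texture, labeling stochasticity,
aberrations or registration error — so passing tests demonstrate
algorithmic correctness, not performance on real tissue.

## Known limitations

* Restoration is strictly 2D and unregularized; no Tikhonov/TV variants,
  no automatic iteration selection, no acceleration.
* Bead registration is integer-pixel; sub-pixel localization and
  aberration fitting are out of scope.
* The resolvability criterion is intentionally minimal (strict dip); it
  reports no localization precision.
* Flux conservation on the cropped output degrades for content at the
  image edge (see above).
* Segmentation has no watershed splitting; touching puncta merge.
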