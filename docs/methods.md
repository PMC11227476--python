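# Methods

This note records the models, conventions and numerical choices behind
`chromomotion`, and what the synthetic benchmarks do and do not show.

## Trajectory model

The generator produces exact fractional Brownian motion (fBm). Per axis,
positions started at zero have covariance

    Cov(x_t, x_s) = D (t^α + s^α − |t−s|^α),

equivalently stationary increments with `E[(x_{t+Δ} − x_t)²] = 2D·Δ^α`, so
the d-dimensional MSD is `2dD·Δ^α` (6DΔ^α in 3D, 4DΔ^α in 2D). Tracks are
synthesised by Cholesky factorisation of this covariance — exact for any
admissible α ∈ (0, 2], at O(n³) cost that is irrelevant for the ≤ a few
hundred frames used here. Near α = 2 the matrix approaches rank 1; a
relative jitter of 1e-12 on the diagonal (falling back to a clipped
eigendecomposition) keeps the factorisation defined. `D` carries units
µm²/s^α; for α = 1 it is the ordinary diffusion coefficient. Brownian
motion is the α = 1 special case, immobile is D = 0, and directed motion
adds a constant drift to a Brownian track. Defaults mirror the imaging
protocol the pipeline targets: 12 frames at 10 s intervals, 7 z-sections,
voxel 41 × 41 × 125 nm.

Tracks are not reflected at the nuclear boundary. Over 110 s the RMS
excursion at the simulated mobilities (~0.1–0.25 µm) is small against the
nucleus, and a free process keeps the MSD exactly equal to the closed form
that the recovery benchmarks assume.

## Rendering

Foci are anisotropic Gaussians with σ = (51, 51, 150) nm (x, y, z) in the
SIM-like regime and (102, 102, 300) nm in the widefield-like regime —
lateral FWHM ≈ 120 nm vs ≈ 240 nm, the two resolutions being compared.
The nucleus channel is a soft-edged ellipsoid carrying a static granular
texture (Gaussian random field, σ = 0.12 µm, 40% relative amplitude) that
moves rigidly with the cell. The texture stands in for the punctate
appearance of a replication-machinery marker; it matters because non-rigid
registration needs intensity structure inside the nucleus, which is
precisely why such a marker channel is used for registration on real data.
Noise is Poisson on signal + background followed by additive Gaussian read
noise (the standard sCMOS approximation), applied last. The default spot
amplitude (200 counts over a background of 20, read noise σ = 2) gives a
peak SNR of roughly 13; real movies' SNR is not published, so these are
config parameters, not constants.

Global motion composes a per-frame affine with a smooth sinusoidal
displacement field (affine first, matching the estimation order of the
registration stage). Frame 1 is always the identity. Moving stacks are
resampled through the inverse map (two fixed-point iterations for the
deformation inverse, accurate to O(|u||∇u|)).

The fixed-cell DNA scenes invert the quantification problem: focus voxel
intensities are solved so that each focus's share of the summed nuclear
intensity equals a prescribed fraction exactly before noise, giving the
quantification stage a known answer.

## Registration

Estimation runs on maximum-intensity projections and is applied per
z-slice; with only ~1 µm of axial range and poor axial resolution a 3D
deformation model would fit noise. The affine step minimises the mean
squared intensity difference over a 3-level pyramid; the non-rigid step is
a symmetric-forces demons estimator run on images downscaled by
`scale_factor` (default 0.25; the value is a config parameter), with the
field linearly upscaled afterwards — smoothness is therefore guaranteed by
construction, not by a penalty term. Two guards keep the stage safe on
degenerate input: every estimated transform is discarded in favour of the
identity if it fails to reduce the dissimilarity to frame 1, and demons
updates are suppressed where the frame difference is within the image
noise (threshold 1.2× a median-absolute-deviation estimate of the
reference's high-frequency noise). The second guard is what keeps the
displacement field null between frames that differ only by shot noise —
without it the estimator warps noise onto noise and displaces foci by
1–2 px. Intensities are interpolated linearly and out-of-view pixels are
filled with the frame median, so resampling does not fabricate spot-like
ringing.

## Detection and tracking

The spot-enhancing filter response is the sign-flipped
Laplacian-of-Gaussian, with per-axis σ matched to the PSF (z scaled by the
voxel anisotropy). The threshold is `mean(|R|) + k·std(|R|)` with one `k`
for a whole sequence. The shipped default is k = 3, appropriate for frames
that actually contain foci (the signal inflates the response statistics);
for noise-only control volumes the false-positive rate at k = 3 is not
negligible, and `calibrate_k` reproduces the control-based procedure —
raise k until a fixed control yields no detections — which lands near
k ≈ 8–9 on the default scene geometry. Sub-voxel positions come from
per-axis quadratic interpolation of the response around each maximum
(typical accuracy ~0.1 voxel); each detection's volume estimate is its
connected above-threshold region.

Linking cost is the distance between a track's constant-velocity
prediction and a candidate detection, solved per frame pair by the optimal
one-to-one assignment with a hard gate; the velocity state is an equal
blend of the previous velocity and the last observed step. Unmatched
detections seed tracks; a track coasts on its prediction through up to
`max_gap` (default 1) missed frames. The gate radius is a config
parameter; benchmarks use 0.3 µm, about 7× the per-frame RMS step at the
largest simulated mobility, which is wide enough never to truncate real
steps yet narrow enough not to bridge sub-resolution encounters between
neighbouring foci into spurious long jumps. Territories, being large,
slow and well separated, use greedy mutual nearest-neighbour linking with
no gap closing.

## Motion analysis conventions

Per-track MSD is the time average over all ordered pairs at each lag
(gap-aware); the ensemble curve is the unweighted mean of per-track MSDs,
with summed pair counts kept as fit weights. The diffusion fit is a
weighted least-squares slope through the origin (`D = slope/2d`); the
anomalous fit is a weighted linear regression of log MSD on log Δt
(α = slope, Γ = exp(intercept)). Neither fit includes a localisation-noise
offset; consequently α fitted on noise-dominated immobile data is
meaningless, which is exactly what the flat-MSD fixed-control check is
for. Ensemble fits use all 11 lags of a 12-frame movie; per-track fits use
lags up to half the track duration. The per-track estimator carries a
small negative bias that grows with the fit range (the log of a noisy MSD
is biased low at sparsely-sampled long lags; ~−0.05 at α = 1.66 for
100-frame tracks), visible in the subpopulation benchmark, where k-means
centroids sit a few hundredths below the generating means but well within
the ±0.08 acceptance band.

Group comparisons use the two-sided Wilcoxon rank-sum test: exact
enumeration when the smaller group has ≤ 8 values and there are no ties,
otherwise the tie-corrected normal approximation; two identical constant
samples return p = 1.

## Shells, subpopulations, DNA

Shell construction follows the stated geometry literally: the convex hull
of the 2D mask contour (gift wrapping, vectorised inner scan; verified
against an independent hull implementation), scaled about its area
centroid by `sqrt(i/N)` — the unique scaling law that makes ring areas
equal, which they then are to machine precision for any convex polygon.
"Equal volume" is realised as equal projected area; z is ignored. Majority
assignment breaks ties toward the outer shell (deterministic, and
conservative for the border effects under test); points outside the hull
— possible after registration resampling — count as shell 1, being
peripheral by construction.

Subpopulation clustering is 1D k-means, k = 2, k-means++ initialisation,
10 restarts keeping the best objective, labels ordered by centroid so
population 0 is always the constrained one. No additional α-threshold is
applied on top of the cluster assignment.

DNA quantification is ratio-based and therefore invariant to global
intensity rescaling. The triangle threshold runs on a 256-bin histogram of
the 16-bit-rescaled label channel, and the thresholded mask is combined
with the original image by voxelwise minimum. Two robustness rules: objects
under 10 voxels are speckle and dropped, and a segmentation covering more
than 25% of the volume means the histogram had no focus mode (labeled foci
are sparse), so the stage returns empty rather than nonsense. Nucleus
segmentation for the fixed-cell protocol exposes a manual intensity
threshold (defaulting to Otsu) because construction-bright foci can
dominate an automatic histogram split; nuclei below 500 µm³ are rejected.
The histogram summary reports the mode bin (default width 10 kbp) ± 5 bins
and the median.

## Benchmark design and problem sizes

Because no raw movies are available at desk scale, accuracy is
demonstrated by parameter recovery on synthetic data at published values:
α ∈ {0.76, 0.95, 1.06} and nine D values between 2.73 and
13.01 × 10⁻⁵ µm²/s, each from 1000 simulated 12-frame tracks; an
end-to-end imaging run (3 rendered movies × 28 foci) at the SIM-condition
D; a territory run (5 movies × 5 blobs, 2D, DoG + nearest-neighbour); and
the subpopulation mixture (300 tracks of 100 frames per group, exponents
spread with σ = 0.15 around each group mean). These sizes keep every
benchmark in the seconds-to-a-minute range while leaving the statistical
error comfortably inside the stated tolerances — except the territory
benchmark, whose 25 short tracks give the fitted D a ~11% relative spread;
it is unbiased (mean ≈ 3.19 vs 3.18 across seeds) but individual seeds can
approach its ±20% band.

What passing these benchmarks shows is internal consistency: the pipeline
recovers the parameters of data generated under its own assumptions, at
realistic noise, resolution and density. What they do not show is
performance on real microscopy — the generator has no structured
background, no photobleaching, no chromatin polymer coupling between
neighbouring foci, no aberrations or reconstruction artifacts, and
Gaussian PSFs instead of measured ones. Real-data quantities reported for
this kind of experiment (per-focus DNA medians, shell widths in
nanometres, absolute focus counts) depend on those unmodelled factors and
are out of scope; the qualitative behaviours (threefold focus-count ratio
between resolutions on clustered truth, upward shift of per-focus DNA at
broader PSF) are reproduced by construction only.

## Known limitations

* Registration assumes in-plane global motion; genuine axial drift is not
  corrected.
* The per-track α estimator's negative bias (above) is inherent to
  log-fitting noisy time-averaged MSDs of short tracks.
* The tracker handles neither merges/splits nor re-identification after
  gaps longer than `max_gap`.
* k-means with k = 2 is a classification device, not a mixture model; near
  α ≈ 1 the boundary between populations is data-dependent.
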