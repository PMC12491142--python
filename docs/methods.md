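# Methods

`acspect` models the quantitative imaging chain for post-therapy
actinium-225 SPECT, where three energy windows are usable — the 440 keV
photopeak of Bi-213 (emission probability 25.9%), the 218 keV photopeak
of Fr-221 (11.4%), and a wide 78 keV window collecting the 70–90 keV
X-ray emissions of the decay chain — and where counting statistics are
extremely poor (roughly 8 MBq administered, ~180 Bq/ml in kidneys at
48 h). Every stage below is implemented as an explicit, testable
operator; a synthetic phantom and acquisition simulator provide data
with the statistical structure the analysis assumes.

## Digital phantom and acquisition model

The phantom is a water cylinder (25 cm diameter, 8.7 L, height set by
the volume) holding three spheres of 191, 100 and 48 ml at 4.2 kBq/ml
over a 0.5 kBq/ml background. Sphere centres sit on a 6.2 cm circle in
the z = +4 cm plane, 120° apart. That radius is the smallest that keeps
the matched-filter VOIs (sphere radius + 2 cm, see below) disjoint;
placement is validated (containment, non-overlap) at construction.
Voxelisation is by voxel-centre membership. Labels: 0 exterior, 1–3
spheres, 4 background. The attenuation map is uniform water inside the
cylinder, with `mu` = 0.0929, 0.136 and 0.184 cm⁻¹ at 440, 218 and
78 keV respectively.

Acquisitions use 32 projections over 360° (the orbit is not otherwise
constrained; a full circular orbit is the standard body protocol),
128×128 bins of 4.80 mm at clinical scale, 10 s per projection for the
low-count (LC) protocol and 120 s for the high-count (HC) protocol.
Expected counts are the attenuated, resolution-blurred forward
projection of the voxel activities times dwell time, emission
probability and a detector sensitivity of 1e-4 counts/(Bq·s) — a
typical high-energy-collimator planar sensitivity (~100 cps/MBq). Under
these settings the LC 440 keV acquisition collects ~35 kcounts in
total, i.e. a fraction of a count per bin: the extreme low-count regime
the clinical protocol operates in. The 78 keV per-decay yield is taken
as 0.58 (approximate combined X-ray yield of the chain); it scales
count levels only. Poisson noise is sampled from a single seeded
generator per run; the seed is recorded in the projection metadata and
in every report.

## Projector

The forward model is rotation-based: the volume is resampled into a
detector-aligned frame by a per-angle sparse bilinear (optionally
nearest-neighbour) rotation matrix, each constant-depth plane is
weighted by the accumulated attenuation toward the detector
(interleaved convention: half a voxel of self-attenuation plus the full
path beyond), blurred with a distance-dependent Gaussian
`sigma(d) = sigma0 + slope·d` (defaults 0.4 cm + 0.025/cm, a
two-parameter stand-in for a full collimator-detector response that
septal penetration would otherwise complicate), and summed along the
ray. Every step has a closed-form transpose — sparse-matrix transpose,
diagonal weight, symmetric kernel with zero fill, broadcast — so the
back projector is the exact adjoint of the forward projector; the inner
product identity holds to machine precision, which the EM convergence
theory relies on.

The study runner uses per-window response parameters, calibrated so
that the matched-filter analysis of the desk-scale reconstruction
returns the effective PSF sigmas the physical system exhibits: ~1.5 cm
for the 440 and 218 keV photopeaks (sigma0 = 1.1 cm, slope 0.04 —
high-energy collimator response degraded by septal penetration) and
~1.0 cm for the 78 keV window (0.7 cm, 0.03). The module-level default
(0.4 cm + 0.025/cm) is a generic sharp system for unit-level work.

## Reconstruction

MAP-MLEM with the additive forward model `y ~ Poisson(A x + s)`:
multiplicative EM updates, the scatter estimate `s` entering only the
expected-counts denominator (never subtracted from the data, preserving
Poisson statistics). Defaults: 100 iterations, `beta` = 0.01, 30 mm
FWHM Gaussian post-filter.

The penalty is a one-step-late quadratic 6-neighbourhood smoothing
prior, the most common MAP-MLEM choice. Its gradient is normalised by
the local image intensity (floored at 1e-3 of the image mean), making
the OSL term dimensionless — equivalent to penalising log-intensity
differences. Without some such normalisation a fixed `beta` has no
meaning: the raw quadratic gradient carries the intensity scale of the
data, and at clinically realistic scales it dwarfs the sensitivity term
and drives the OSL denominator negative. The OSL multiplier is clamped
to [0.5, 2] per iteration. The exact prior of the scanner-side
algorithm this emulates is not public, so `beta` values are not
transferable; 0.01 here produces a mild smoothing, visibly weaker than
the 30 mm post-filter.

Calibration follows the homogeneous-phantom protocol: the sphere-free
cylinder at 0.5 kBq/ml is imaged with the HC protocol, reconstructed
identically (including the post-filter), and the mean over a central
16 cm spherical VOI maps reconstruction units to Bq/ml. Factors are
window- and scatter-mode-specific and refuse (by tag check) to be
applied across modes.

## Scatter correction

*Energy-window estimators.* DEW for 440 keV: a 10% lower adjacent
window scaled by the width ratio `W_p/W_l` (the multiplier is
configurable; the width ratio is the standard choice). TEW for 218 keV:
20% windows at 178 and 267 keV combined as a trapezoid,
`(C_l/W_l + C_u/W_u)/2 · W_p`. No scatter correction is used for
78 keV, where overlapping X-ray emissions and collimator lead
fluorescence make adjacent-window estimates unreliable. Estimates are
non-negative by construction and bin-local; no smoothing is applied by
default.

*Transmission-dependent scatter correction (TDSC).* Scatter kernels are
tabulated per slab depth (2–40 cm in 2 cm steps) as mono-exponential
radial tails; queries beyond 40 cm clamp to the 40 cm entry (the slopes
change by <3% per extra 2 cm there), queries below 2 cm clamp upward
with a warning. In place of Monte-Carlo slab simulations, the synthetic
tables follow a smooth slope law
`slope(d) = s_inf + (s0 − s_inf)·exp(−d/12 cm)` (per-window parameters,
e.g. 0.35→0.09 cm⁻¹ at 440 keV) with unit-sum kernel normalisation, and
the scatter-to-primary fraction follows the fitted model

    SF(p) = A − B·exp(−p)^gamma − 1,

with `p` the dimensionless mu path length from the voxel to the surface
in the detector direction (A, B, gamma per window; (3.0, 2.0, 0.5) at
440 keV, giving SF = 0 at the surface, rising with depth). Inside the
reconstruction, each detector-aligned slice of the current estimate is
convolved with the kernel for its depth below the surface, each voxel
is scaled by SF at its path length, and the scatter image is summed
along the ray — with no further PSF blur and no attenuation weighting,
since SF already expresses scatter relative to the attenuated
primaries. The scatter projections are recomputed once per full
iteration and are deterministic functionals of the estimate: the noise
advantage over the Poisson-noisy energy-window estimates is the
mechanism behind the CNR gains the phantom study measures.

The acquisition simulator generates scatter with the same kernel
formalism; a `mismatch` multiplier lets the correction be exercised
under a deliberately wrong model. With a matched model and no noise,
reconstructions with the in-loop TDSC estimate and with the simulated
true scatter agree to well under 1% in the sphere means once converged
— the inverse-crime consistency the test suite pins.

## Partial-volume correction

Both methods assume a spatially invariant isotropic Gaussian blur.

*Richardson-Lucy* — anatomy-free multiplicative deconvolution. Flux is
conserved to <0.1% for interior activity; non-negativity is structural.
The default workflow runs RL on the *unfiltered* reconstruction with
the system PSF sigma and filters afterwards, with per-window iteration
counts 7/15/10. The iteration count and the filter ordering are,
however, tuning knobs whose best values depend on the noise level:
deconvolution trades recovery against amplified background noise. The
study runner therefore re-runs the selection on its own images: it
scans a small grid (1/3/7 iterations, filter before or after RL, with
the quadrature-combined sigma when filtering first) and keeps the
setting with the largest total sphere RC whose CNR does not fall below
the uncorrected level for any sphere (falling back to the smallest
worst-sphere CNR loss if none qualifies). The chosen settings are
recorded in the report bundle.

*Iterative Yang* — region-based: each iteration builds a
piecewise-constant template from the current regional means, smooths it
with the PSF, and corrects the observed image by the ratio
template/smoothed-template; 10 iterations. The filter is applied
*before* IY, so its PSF is the quadrature combination of the system
sigma and the filter sigma (30 mm FWHM → 1.27 cm): 1.96 cm at 440/218
keV, 1.62 cm at 78 keV.

The system sigma is estimated by matched filtering: blur the
ground-truth phantom image with candidate sigmas 0.5–2.0 cm in 0.25 cm
steps, compare to the unfiltered reconstruction by RMSE inside
spherical VOIs expanded 2 cm beyond each sphere, and take the sigma
minimising the summed RMSE (ties to the smaller sigma — the less
aggressive correction). The study runner defaults to the per-window
sigmas 1.50/1.50/1.00 cm directly rather than re-estimating them inside
every run, since estimation needs an extra HC reconstruction per window;
the estimator itself is exercised separately.

## Metrics

RC = mean concentration in the CT-style sphere mask / true
concentration × 100 (no spill-over correction). CNR = (VOI mean −
background mean)/background SD, with background statistics averaged
over four rectangular VOIs of 54, 145, 260 and 280 ml placed in the
background compartment at ≥3 cm from every sphere surface. Placement
enumerates the exactly feasible corner positions (a minimum-filter
erosion of the admissible region) and samples among them with the run's
generator, trying progressively flatter box shapes — the sphere-free
axial band of the cylinder is too short for the largest boxes as cubes.

Lesion-style segmentation is an isocontour at a percentage of the
regional maximum, keeping the 26-connected component containing the
hottest voxel; mask volume is non-increasing in the threshold. The
threshold is calibrated on the smallest sphere by matching the
segmented volume to the known 48 ml over a 40–95% grid in 5% steps.

## Dosimetry

Region time-activity curves from two imaging time points (24 and 48 h)
are modelled as a single exponential fitted exactly through the two
samples; non-decaying pairs are rejected as non-physical. The
time-integrated activity is the 0→∞ integral `A0/lambda` — the only
self-consistent choice with one exponential and two samples, and it is
reported explicitly in every dose record. Absorbed dose follows the
MIRD formalism, `D = RBE · TIA · S`, with whole-decay-chain S-values
supplied as configuration (local energy deposition of all daughters
assumed; no transport is computed) and RBE = 5 applied as a single
multiplier. The demo uses 4.5e-11 and 9.4e-11 Gy/(Bq·s) for the
kidney-like (100 ml) and lesion-like (48 ml) regions — self-dose
S-values of order (alpha-chain energy)/(region mass) — and an effective
half-life of 55 h.

## Problem sizes and numerical choices

The study runner defaults to a 64³ grid of 7.2 mm voxels with 50 MLEM
iterations for the LC study and 30 for calibrations; the dosimetry demo
uses 48³/9.6 mm/40 with the 210 s clinical dosimetry protocol. These
desk-scale settings preserve the full
geometry (the 48 ml sphere spans ~6 voxels across) while keeping a
complete three-window, two-scatter-mode study with calibrations in the
ten-minute range; clinical-scale settings (128³, 4.8 mm, 100
iterations) are plain config values. Gaussian blurs use zero-fill
boundaries with truncation at 4 sigma; EM guards division by an
exclusion mask on near-zero sensitivity voxels rather than epsilon
division; kernel tables interpolate slope and amplitude linearly in
depth and are memoised per (depth, voxel size).

## What the synthetic data does and does not show

The simulator shares its projector and scatter formalism with the
reconstruction (an inverse crime, deliberate for convergence and
consistency checks) and omits septal-penetration star artefacts,
downscatter between windows (e.g. Tl-209 into 440 keV), detector
dead-time, and anatomical background heterogeneity. Passing tests
therefore demonstrate the internal correctness and the *relative*
behaviour of the estimators under matched low-count conditions — the
CNR ordering of model-based vs energy-window scatter correction, the
RC/CNR gains from PVC — not absolute clinical accuracy. Quantities tied
to physical measurements (absolute RC levels, patient doses) are
expected to differ from any scanner's.

One behaviour deserves explicit mention: on these synthetic low-count
images the Richardson-Lucy CNR effect is a noise-level quantity. RL
reliably raises RC for every sphere, but its CNR change sits within
roughly ±3% of the uncorrected value and its sign varies with the
sphere and the noise realisation, even after the iteration/ordering
optimisation — deconvolution amplifies background noise at nearly the
same rate it restores contrast here. The region-based Iterative Yang
correction, by contrast, improves both RC and CNR by large, robust
margins. The study reports both; treat small RL CNR differences as
noise.
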