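"""Post-reconstruction partial-volume correction.

Two methods are provided, both assuming the reconstruction suffers a
spatially invariant, isotropic 3-D Gaussian blur:

* Richardson-Lucy (RL) — anatomy-free multiplicative deconvolution. The
  Gaussian post-filter is applied *after* RL, and RL runs on the
  unfiltered reconstruction with the matched-filter sigma.
* Iterative Yang (IY) — region-based: a piecewise-constant template built
  from the current regional means is smoothed with the PSF and the ratio
  template/smoothed-template corrects the observed image; 10 iterations
  by default. The Gaussian filter is applied *before* IY, so the IY PSF
  is the quadrature combination of the matched-filter sigma and the
  filter sigma.

The system PSF sigma is estimated by a matched filter: blur the
ground-truth phantom image with candidate sigmas (0.5-2.0 cm in 0.25 cm
steps), compare to the unfiltered reconstruction inside spherical VOIs
expanded 2 cm beyond each sphere radius, and keep the sigma minimising
the summed RMSE.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .recon import _FWHM_PER_SIGMA, gaussian_postfilter
from .volume import VolumeImage

__all__ = [
    "PsfModel",
    "PvcConfig",
    "rl_deconvolve",
    "iy_correct",
    "estimate_psf_sigma",
    "fwhm_to_sigma",
    "sigma_to_fwhm",
    "combine_sigma_quadrature",
    "apply_pvc_workflow",
]

DEFAULT_SIGMA_GRID_CM = np.arange(0.5, 2.0 + 1e-9, 0.25)


@dataclass(frozen=True)
class PsfModel:
    """Isotropic Gaussian PSF sigma in cm."""

    sigma_cm: float
    origin: str = "config"  # or "matched_filter"

    def __post_init__(self) -> None:
        if self.sigma_cm < 0:
            raise ValueError("sigma must be non-negative")

    def sigma_vox(self, voxel_size_mm: float) -> float:
        return self.sigma_cm * 10.0 / voxel_size_mm


@dataclass(frozen=True)
class PvcConfig:
    method: str = "RL"  # or "IY"
    n_iterations: int = 10
    filter_order: str = "auto"  # after RL, before IY
    postfilter_fwhm_mm: float = 30.0

    def __post_init__(self) -> None:
        if self.method not in ("RL", "IY"):
            raise ValueError("method must be 'RL' or 'IY'")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")


def fwhm_to_sigma(fwhm: float) -> float:
    """FWHM -> sigma of a Gaussian (30 mm -> 12.74 mm, i.e. 1.27 cm)."""
    if fwhm < 0:
        raise ValueError("fwhm must be non-negative")
    return fwhm / _FWHM_PER_SIGMA


def sigma_to_fwhm(sigma: float) -> float:
    return sigma * _FWHM_PER_SIGMA


def combine_sigma_quadrature(s1: float, s2: float) -> float:
    """Quadrature sum of two Gaussian sigmas (cascade of two blurs)."""
    if s1 < 0 or s2 < 0:
        raise ValueError("sigmas must be non-negative")
    return float(np.hypot(s1, s2))


def _blur(data: np.ndarray, sigma_vox: float) -> np.ndarray:
    if sigma_vox <= 0:
        return data
    return gaussian_filter(data, sigma_vox, mode="constant", truncate=4.0)


def rl_deconvolve(image: VolumeImage, psf: PsfModel, n_iter: int = 10) -> VolumeImage:
    """Richardson-Lucy deconvolution with a Gaussian PSF.

    The multiplicative update preserves non-negativity, and — the Gaussian
    being symmetric — conserves total flux for activity away from the
    grid boundary.
    """
    if np.any(image.data < 0):
        raise ValueError("RL requires a non-negative image")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    s = psf.sigma_vox(image.voxel_size_mm)
    y = image.data.astype(float)
    if s <= 0:
        out = image.with_data(y.copy())
        out.meta["pvc"] = "RL"
        return out
    x = y.copy()
    tiny = np.finfo(float).tiny
    for _ in range(n_iter):
        est = _blur(x, s)
        ratio = np.where(est > tiny, y / np.where(est > tiny, est, 1.0), 0.0)
        x = x * _blur(ratio, s)
    out = image.with_data(x)
    out.meta.update(pvc="RL", pvc_iterations=n_iter, pvc_sigma_cm=psf.sigma_cm)
    return out


def iy_correct(
    image: VolumeImage, regions: VolumeImage, psf: PsfModel, n_iter: int = 10
) -> VolumeImage:
    """Iterative Yang region-based correction.

    ``regions`` is an integer label volume covering every voxel (the
    background, and any exterior, are regions too). Each iteration builds
    a piecewise-constant template from the current regional means of the
    corrected image, smooths it with the PSF, and rescales the *observed*
    image by template / smoothed-template.
    """
    if not image.same_grid(regions):
        raise ValueError("image and region labels must share the same grid")
    lab = regions.data.astype(int)
    ids = np.unique(lab)
    for rid in ids:
        if not np.any(lab == rid):  # pragma: no cover - unique guarantees
            raise ValueError(f"region {rid} is empty")
    if ids.size == 0:
        raise ValueError("no regions supplied")
    s = psf.sigma_vox(image.voxel_size_mm)
    y = image.data.astype(float)
    if s <= 0:
        out = image.with_data(y.copy())
        out.meta["pvc"] = "IY"
        return out
    masks = [lab == rid for rid in ids]
    x = y.copy()
    tiny = np.finfo(float).tiny
    for _ in range(n_iter):
        template = np.zeros_like(y)
        for m in masks:
            template[m] = x[m].mean()
        smoothed = _blur(template, s)
        corr = np.where(np.abs(smoothed) > tiny, template / np.where(
            np.abs(smoothed) > tiny, smoothed, 1.0), 1.0)
        x = y * corr
    out = image.with_data(x)
    out.meta.update(pvc="IY", pvc_iterations=n_iter, pvc_sigma_cm=psf.sigma_cm)
    return out


def estimate_psf_sigma(
    ground_truth: VolumeImage,
    recon: VolumeImage,
    sphere_centers_cm,
    sphere_radii_cm,
    sigma_grid_cm=DEFAULT_SIGMA_GRID_CM,
    voi_margin_cm: float = 2.0,
) -> PsfModel:
    """Matched-filter estimate of the effective reconstruction PSF.

    For each candidate sigma the ground truth is blurred and compared to
    the (unfiltered) reconstruction by RMSE inside spherical VOIs whose
    radii exceed the sphere radii by ``voi_margin_cm``; the sigma with the
    smallest summed RMSE wins, ties going to the smaller sigma.
    """
    if not ground_truth.same_grid(recon):
        raise ValueError("ground truth and reconstruction must share the grid")
    sigma_grid_cm = np.atleast_1d(np.asarray(sigma_grid_cm, dtype=float))
    centers = [np.asarray(c, dtype=float) for c in sphere_centers_cm]
    radii = [float(r) + voi_margin_cm for r in sphere_radii_cm]
    for i in range(len(centers)):
        for j in range(i + 1, len(centers)):
            if np.linalg.norm(centers[i] - centers[j]) < radii[i] + radii[j]:
                raise ValueError(
                    "expanded matched-filter VOIs overlap; increase sphere "
                    "separation or reduce the margin"
                )
    X, Y, Z = ground_truth.coords_cm()
    vois = [
        (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
        for c, r in zip(centers, radii)
    ]
    scores = []
    for s_cm in sigma_grid_cm:
        blurred = _blur(ground_truth.data, s_cm * 10.0 / ground_truth.voxel_size_mm)
        rmse_sum = 0.0
        for m in vois:
            diff = blurred[m] - recon.data[m]
            rmse_sum += float(np.sqrt(np.mean(diff**2)))
        scores.append(rmse_sum)
    best = int(np.argmin(scores))  # argmin takes the first (smallest) on ties
    return PsfModel(float(sigma_grid_cm[best]), origin="matched_filter")


def apply_pvc_workflow(
    image: VolumeImage,
    cfg: PvcConfig,
    psf: PsfModel,
    regions: VolumeImage | None = None,
) -> VolumeImage:
    """Full PVC chain with the method-specific filter ordering.

    RL: deconvolve the unfiltered reconstruction with the system PSF,
    then apply the Gaussian post-filter. IY: post-filter first, then IY
    with the quadrature-combined sigma (system PSF + filter).
    """
    audit: list[str] = []
    if cfg.method == "RL":
        out = rl_deconvolve(image, psf, cfg.n_iterations)
        audit.append(f"RL(sigma={psf.sigma_cm} cm, n={cfg.n_iterations})")
        if cfg.postfilter_fwhm_mm > 0:
            out = gaussian_postfilter(out, cfg.postfilter_fwhm_mm)
            audit.append(f"gaussian_filter(fwhm={cfg.postfilter_fwhm_mm} mm)")
    else:
        if regions is None:
            raise ValueError("IY-based PVC requires a region label volume")
        out = image
        if cfg.postfilter_fwhm_mm > 0:
            out = gaussian_postfilter(out, cfg.postfilter_fwhm_mm)
            audit.append(f"gaussian_filter(fwhm={cfg.postfilter_fwhm_mm} mm)")
        combined = combine_sigma_quadrature(
            psf.sigma_cm, fwhm_to_sigma(cfg.postfilter_fwhm_mm) / 10.0
        )
        out = iy_correct(out, regions, PsfModel(combined), cfg.n_iterations)
        audit.append(f"IY(sigma={combined:.4g} cm, n={cfg.n_iterations})")
    out.meta["pvc_audit"] = audit
    return out
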