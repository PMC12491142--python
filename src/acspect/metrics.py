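"""Phantom quantification metrics and isocontour segmentation.

Recovery coefficient (RC) of a VOI, in percent:

    RC = AC_VOI / AC_true x 100

with AC_VOI the mean measured concentration in the VOI (no spill-over
correction). Contrast-to-noise ratio:

    CNR = (mu_VOI - mu_bg) / sigma_bg

where mu_bg and sigma_bg are the averages of the means and of the
standard deviations over four rectangular background VOIs (54, 145, 260
and 280 ml) distributed through the background compartment away from the
spheres.

Lesion-style segmentation uses an isocontour at a percentage of the
regional maximum: the 26-connected component containing the hottest
voxel. The threshold percentage is calibrated on the smallest phantom
sphere by matching the segmented volume to the known 48 ml.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import minimum_filter
from skimage import measure

from .volume import VolumeImage

__all__ = [
    "VoiStats",
    "voi_stats",
    "compute_rc",
    "compute_cnr",
    "place_background_vois",
    "isocontour_segment",
    "calibrate_isocontour_threshold",
    "DEFAULT_BACKGROUND_VOLUMES_ML",
    "DEFAULT_THRESHOLD_GRID_PCT",
]

DEFAULT_BACKGROUND_VOLUMES_ML = (54.0, 145.0, 260.0, 280.0)
DEFAULT_THRESHOLD_GRID_PCT = tuple(range(40, 100, 5))


@dataclass(frozen=True)
class VoiStats:
    mean: float
    sd: float
    volume_ml: float
    label: str = ""

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise ValueError("VOI volume must be positive")
        if self.sd < 0:
            raise ValueError("VOI sd must be non-negative")


def voi_stats(image: VolumeImage, mask: np.ndarray, label: str = "") -> VoiStats:
    if not np.any(mask):
        raise ValueError(f"empty VOI mask {label!r}")
    vals = image.data[mask]
    return VoiStats(
        float(vals.mean()), float(vals.std(ddof=0)),
        float(mask.sum() * image.voxel_volume_ml), label,
    )


def compute_rc(image: VolumeImage, voi_mask: np.ndarray, true_ac: float) -> float:
    """Recovery coefficient in percent; ``true_ac`` in the image's units."""
    if true_ac <= 0:
        raise ValueError("true activity concentration must be positive")
    return 100.0 * voi_stats(image, voi_mask).mean / true_ac


def compute_cnr(image: VolumeImage, voi_mask: np.ndarray, bg_masks) -> float:
    """Contrast-to-noise ratio against a set of background VOIs."""
    if len(bg_masks) == 0:
        raise ValueError("at least one background VOI is required")
    stats = [voi_stats(image, m, f"bg{i}") for i, m in enumerate(bg_masks)]
    mu_bg = float(np.mean([s.mean for s in stats]))
    sd_bg = float(np.mean([s.sd for s in stats]))
    if sd_bg == 0:
        raise ValueError("background standard deviation is zero (noiseless input?)")
    return (voi_stats(image, voi_mask).mean - mu_bg) / sd_bg


def place_background_vois(
    labels: VolumeImage,
    sphere_labels,
    background_label: int,
    volumes_ml=DEFAULT_BACKGROUND_VOLUMES_ML,
    min_distance_cm: float = 3.0,
    rng: np.random.Generator | None = None,
    max_tries: int = 5000,
) -> list[np.ndarray]:
    """Place rectangular (near-cubic) background VOIs by rejection sampling.

    Each box must lie entirely in the background compartment, at least
    ``min_distance_cm`` from every sphere surface, and not intersect a
    previously placed box.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    lab = labels.data
    vx_mm = labels.voxel_size_mm
    bg = lab == background_label
    sphere_mask = np.isin(lab, list(sphere_labels))
    if sphere_mask.any():
        from scipy.ndimage import distance_transform_edt

        dist_vox = distance_transform_edt(~sphere_mask)
        far = dist_vox * vx_mm / 10.0 >= min_distance_cm
    else:
        far = np.ones_like(bg)
    allowed = bg & far

    placed: list[np.ndarray] = []
    occupied = np.zeros_like(bg)
    for vol in volumes_ml:
        n_vox = vol / labels.voxel_volume_ml
        side = n_vox ** (1.0 / 3.0)
        # try several aspect ratios: flattened boxes (smaller z-extent)
        # fit the sphere-free axial band of the cylinder more easily, but
        # need more transaxial room
        shapes = []
        for f in (1.0, 0.8, 0.6, 0.45, 0.3):
            dz = max(int(round(f * side)), 1)
            a = max(int(round(np.sqrt(n_vox / dz))), 1)
            if (a, a, dz) not in shapes:
                shapes.append((a, a, dz))
        done = False
        for dims in shapes:
            # all feasible corner positions at once: a box fits at corner
            # c iff the eroded allowed-and-free mask is True there
            ok = allowed & ~occupied
            fits = minimum_filter(ok, size=dims, mode="constant", cval=False)
            # minimum_filter windows are centred; shift to corner indexing
            off = [d // 2 for d in dims]
            corners = np.argwhere(fits)
            corners = corners - np.array(off)
            inb = np.all(
                (corners >= 0) & (corners + np.array(dims) <= np.array(lab.shape)),
                axis=1,
            )
            corners = corners[inb]
            rng.shuffle(corners)
            for lo in corners[: max(1, max_tries)]:
                sl = tuple(slice(int(a), int(a + d)) for a, d in zip(lo, dims))
                if not allowed[sl].all() or occupied[sl].any():
                    continue
                box = np.zeros_like(bg)
                box[sl] = True
                occupied |= box
                placed.append(box)
                done = True
                break
            if done:
                break
        if not done:
            raise RuntimeError(f"could not place a {vol:.0f} ml background VOI")
    return placed


def isocontour_segment(
    image: VolumeImage, search_mask: np.ndarray, threshold_pct: float
) -> np.ndarray:
    """Isocontour mask at ``threshold_pct`` % of the regional maximum.

    Returns the 26-connected component (within the search region) that
    contains the hottest voxel.
    """
    if not 0 < threshold_pct <= 100:
        raise ValueError("threshold_pct must be in (0, 100]")
    if not np.any(search_mask):
        raise ValueError("empty search region")
    vals = np.where(search_mask, image.data, -np.inf)
    vmax = vals.max()
    thresholded = search_mask & (image.data >= threshold_pct / 100.0 * vmax)
    cc = measure.label(thresholded, connectivity=3)
    seed = np.unravel_index(np.argmax(vals), vals.shape)
    return cc == cc[seed]


def calibrate_isocontour_threshold(
    image: VolumeImage,
    search_mask: np.ndarray,
    true_volume_ml: float = 48.0,
    candidate_pcts=DEFAULT_THRESHOLD_GRID_PCT,
) -> float:
    """Pick the isocontour percentage whose mask volume best matches the
    true volume (the smallest sphere by default)."""
    candidates = list(candidate_pcts)
    if not candidates:
        raise ValueError("candidate threshold list is empty")
    errs = []
    for pct in candidates:
        vol = isocontour_segment(image, search_mask, pct).sum() * image.voxel_volume_ml
        errs.append(abs(vol - true_volume_ml))
    return float(candidates[int(np.argmin(errs))])
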