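"""Scatter estimation: energy-window methods and transmission-dependent
scatter correction (TDSC).

Energy-window scatter correction (EWSC) estimates the scatter in the
photopeak window from counts in adjacent windows:

* DEW — one lower adjacent window; scatter = lower counts scaled by the
  photopeak/lower width ratio.
* TEW — lower and upper windows; the scatter spectrum under the photopeak
  is approximated by a trapezoid:
  ``scatter = (C_l / W_l + C_u / W_u) / 2 * W_p``.

TDSC is model based: every detector-aligned slice of the current image
estimate is convolved with a depth-dependent scatter kernel, each voxel is
scaled by a scatter-to-primary fraction (SF) evaluated at its attenuation
path length, and the resulting scatter image is summed along the ray
direction. The SF model is

    SF(p) = A - B * exp(-p) ** gamma - 1,

with ``p`` the dimensionless mu path length from the voxel to the surface
in the detector direction. The kernel tail slopes are tabulated per slab
depth (mono-exponential fits); queries beyond the deepest tabulated depth
clamp to the deepest entry, because the slopes change by less than 3% per
additional 2 cm of water there.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.signal import fftconvolve

from .projector import Projector
from .volume import ProjectionSet

__all__ = [
    "WindowArithmetic",
    "ScatterKernelTable",
    "ScatterToPrimaryModel",
    "dew_estimate",
    "tew_estimate",
    "fit_tail_monoexp",
    "fit_sf_model",
    "tdsc_scatter_projection",
    "tdsc_scatter_projections",
]


# ---------------------------------------------------------------------------
# energy-window arithmetic
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class WindowArithmetic:
    """Widths (keV) of the photopeak and adjacent scatter windows."""

    peak_width_kev: float
    lower_width_kev: float | None = None
    upper_width_kev: float | None = None

    def __post_init__(self) -> None:
        for w in (self.peak_width_kev, self.lower_width_kev, self.upper_width_kev):
            if w is not None and w <= 0:
                raise ValueError("window widths must be positive")


def dew_estimate(lower: ProjectionSet, wa: WindowArithmetic) -> ProjectionSet:
    """Dual-energy-window scatter estimate: lower counts x W_p / W_l."""
    if wa.lower_width_kev is None:
        raise ValueError("DEW requires the lower scatter-window width")
    if np.any(lower.data < 0):
        raise ValueError("scatter-window counts must be non-negative")
    scale = wa.peak_width_kev / wa.lower_width_kev
    out = ProjectionSet(
        lower.data * scale, lower.angles_deg, lower.bin_size_mm,
        lower.time_per_projection_s, lower.window, dict(lower.meta),
    )
    out.meta["scatter_estimator"] = "DEW"
    return out


def tew_estimate(
    lower: ProjectionSet, upper: ProjectionSet, wa: WindowArithmetic
) -> ProjectionSet:
    """Triple-energy-window (trapezoid) scatter estimate."""
    if wa.lower_width_kev is None or wa.upper_width_kev is None:
        raise ValueError("TEW requires lower and upper scatter-window widths")
    if not lower.same_geometry(upper):
        raise ValueError("lower and upper scatter windows must share geometry")
    est = 0.5 * (
        lower.data / wa.lower_width_kev + upper.data / wa.upper_width_kev
    ) * wa.peak_width_kev
    # non-negative by construction; clip defensively in case the inputs
    # were smoothed upstream
    est = np.clip(est, 0.0, None)
    out = ProjectionSet(
        est, lower.angles_deg, lower.bin_size_mm,
        lower.time_per_projection_s, lower.window, dict(lower.meta),
    )
    out.meta["scatter_estimator"] = "TEW"
    return out


# ---------------------------------------------------------------------------
# kernel table and SF model
# ---------------------------------------------------------------------------

@dataclass
class ScatterKernelTable:
    """Depth-indexed mono-exponential scatter kernels.

    ``slopes[i]`` is the radial decay constant (1/cm) of the kernel for a
    source at depth ``depths_cm[i]``; ``amplitudes[i]`` scales the kernel.
    With ``normalization='unit_sum'`` the radial kernel is normalised to
    unit sum before the amplitude is applied, so the amplitude is the
    total (relative) scatter weight and the slope only shapes it.
    """

    depths_cm: np.ndarray
    slopes: np.ndarray
    amplitudes: np.ndarray
    normalization: str = "unit_sum"

    def __post_init__(self) -> None:
        self.depths_cm = np.asarray(self.depths_cm, dtype=float)
        self.slopes = np.asarray(self.slopes, dtype=float)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (self.depths_cm.size == self.slopes.size == self.amplitudes.size):
            raise ValueError("depths, slopes and amplitudes must have equal length")
        if self.depths_cm.size == 0:
            raise ValueError("kernel table is empty")
        if np.any(np.diff(self.depths_cm) <= 0):
            raise ValueError("depths must be strictly increasing")
        if np.any(self.depths_cm <= 0):
            raise ValueError("depths must be positive")
        if np.any(self.slopes <= 0):
            raise ValueError("slopes must be positive")
        if self.normalization not in ("unit_sum", "raw"):
            raise ValueError("normalization must be 'unit_sum' or 'raw'")

    def params_at(self, depth_cm: float) -> tuple[float, float]:
        """(slope, amplitude) linearly interpolated in depth, clamped at
        both ends of the table. Depths beyond the deepest entry reuse that
        entry; depths below the shallowest raise a warning and use it."""
        if depth_cm < self.depths_cm[0]:
            warnings.warn(
                "depth below tabulated kernel range; using the shallowest entry",
                stacklevel=2,
            )
            return float(self.slopes[0]), float(self.amplitudes[0])
        slope = float(np.interp(depth_cm, self.depths_cm, self.slopes))
        amp = float(np.interp(depth_cm, self.depths_cm, self.amplitudes))
        return slope, amp

    def to_csv(self, path) -> None:
        """Write as ``depth_cm, slope, amplitude`` CSV."""
        import pandas as pd

        pd.DataFrame(
            {"depth_cm": self.depths_cm, "slope": self.slopes,
             "amplitude": self.amplitudes}
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalization: str = "unit_sum") -> "ScatterKernelTable":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(df["depth_cm"].values, df["slope"].values,
                   df["amplitude"].values, normalization)

    def kernel_2d(self, depth_cm: float, voxel_size_cm: float) -> np.ndarray:
        """Isotropic 2-D kernel for a slice at ``depth_cm``.

        The radial profile is ``exp(-slope * r)`` truncated at
        ``r = 5 / slope``, sampled on the voxel lattice. Results are
        memoised — the same few depths recur every reconstruction
        iteration.
        """
        key = (round(depth_cm, 4), round(voxel_size_cm, 6))
        cache = self.__dict__.setdefault("_kernel_cache", {})
        if key in cache:
            return cache[key]
        slope, amp = self.params_at(depth_cm)
        r_max = 5.0 / slope
        half = max(int(np.ceil(r_max / voxel_size_cm)), 1)
        ax = (np.arange(-half, half + 1)) * voxel_size_cm
        rr = np.hypot(ax[:, None], ax[None, :])
        k = np.exp(-slope * rr)
        k[rr > r_max] = 0.0
        if self.normalization == "unit_sum":
            k /= k.sum()
        k = amp * k
        cache[key] = k
        return k


@dataclass
class ScatterToPrimaryModel:
    """SF(p) = A - B * exp(-p)**gamma - 1 with p the mu path length."""

    A: float
    B: float
    gamma: float
    voxel_size_cm: float = 0.48
    fit_report: dict = field(default_factory=dict)

    def __call__(self, path_length) -> np.ndarray:
        p = np.asarray(path_length, dtype=float)
        return self.A - self.B * np.exp(-p) ** self.gamma - 1.0

    def validate_range(self, p_max: float) -> None:
        p = np.linspace(0.0, p_max, 200)
        if np.any(self(p) < -1e-9):
            raise ValueError(
                "SF model is negative inside the admissible path-length range"
            )

    def to_yaml(self, path) -> None:
        import yaml

        payload = {"A": self.A, "B": self.B, "gamma": self.gamma,
                   "voxel_size_cm": self.voxel_size_cm}
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh)

    @classmethod
    def from_yaml(cls, path) -> "ScatterToPrimaryModel":
        import yaml

        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(d["A"], d["B"], d["gamma"], d.get("voxel_size_cm", 0.48))


def fit_tail_monoexp(
    distance: np.ndarray, counts: np.ndarray, tail: slice | np.ndarray | None = None
) -> tuple[float, float, dict]:
    """Least-squares fit of ``a * exp(-b * x)`` to the tail of a profile.

    Returns ``(amplitude, slope, report)``; the report carries the RMS
    residual relative to the tail mean. Requires at least three strictly
    positive tail samples.
    """
    x = np.asarray(distance, dtype=float)
    y = np.asarray(counts, dtype=float)
    if tail is not None:
        x, y = x[tail], y[tail]
    if x.size < 3 or np.any(y <= 0):
        raise ValueError("tail fit needs >= 3 strictly positive samples")
    # log-linear start, then proper nonlinear refinement
    b0, loga0 = np.polyfit(x, np.log(y), 1)
    p0 = (float(np.exp(loga0)), float(max(-b0, 1e-6)))
    try:
        popt, _ = curve_fit(
            lambda t, a, b: a * np.exp(-b * t), x, y, p0=p0, maxfev=10000
        )
    except RuntimeError as exc:  # pragma: no cover - degenerate data
        raise ValueError(f"mono-exponential tail fit did not converge: {exc}")
    a, b = float(popt[0]), float(popt[1])
    if a <= 0 or b <= 0:
        raise ValueError("degenerate tail fit (non-positive amplitude or slope)")
    resid = y - a * np.exp(-b * x)
    report = {"rms_relative": float(np.sqrt(np.mean(resid**2)) / y.mean())}
    return a, b, report


def fit_sf_model(
    path_lengths: np.ndarray, sf_values: np.ndarray, voxel_size_cm: float = 0.48
) -> ScatterToPrimaryModel:
    """Nonlinear least-squares fit of the SF model coefficients (A, B, gamma)."""
    p = np.asarray(path_lengths, dtype=float)
    s = np.asarray(sf_values, dtype=float)
    if p.size < 4:
        raise ValueError("SF fit needs at least 4 samples")
    if np.ptp(p) <= 0:
        raise ValueError("path lengths must span a range")

    def model(x, A, B, g):
        return A - B * np.exp(-x) ** g - 1.0

    p0 = (s.max() + 1.0, s.max() - s.min() + 0.5, 1.0)
    try:
        popt, pcov = curve_fit(
            model, p, s, p0=p0, bounds=([-np.inf, 0.0, 1e-6], np.inf), maxfev=20000
        )
    except RuntimeError as exc:
        resid = "n/a"
        raise ValueError(f"SF model fit did not converge (residuals {resid}): {exc}")
    resid = s - model(p, *popt)
    report = {
        "rms": float(np.sqrt(np.mean(resid**2))),
        "n": int(p.size),
    }
    out = ScatterToPrimaryModel(
        float(popt[0]), float(popt[1]), float(popt[2]), voxel_size_cm, report
    )
    out.validate_range(float(p.max()))
    return out


# ---------------------------------------------------------------------------
# TDSC
# ---------------------------------------------------------------------------

def _surface_index(rmu: np.ndarray, mu_eps: float = 1e-6) -> int:
    """Index of the last (closest-to-detector) y-plane with mu support."""
    support = np.any(rmu > mu_eps, axis=(0, 2))
    if not support.any():
        return -1
    return int(np.max(np.nonzero(support)[0]))


def tdsc_scatter_projection(
    image: np.ndarray,
    rmu_path: np.ndarray,
    rmu: np.ndarray,
    table: ScatterKernelTable,
    sf: ScatterToPrimaryModel,
    voxel_size_cm: float,
) -> np.ndarray:
    """Scatter projection for one angle from detector-aligned arrays.

    ``image``/``rmu``/``rmu_path`` are already rotated into the detector
    frame (detector at the +y face). Per slice y: convolve the (x, z)
    slice with the kernel for that slice's depth below the surface, scale
    each voxel by SF at its mu path length, and sum the slices. No PSF
    blur and no attenuation weighting are applied to the assembled scatter
    image — the SF scaling already expresses scatter relative to the
    attenuated primaries.
    """
    nx, ny, nz = image.shape
    y_surf = _surface_index(rmu)
    out = np.zeros((nx, nz))
    if y_surf < 0:
        return out
    for y in range(y_surf + 1):
        sl = image[:, y, :]
        if not sl.any():
            continue
        depth = (y_surf - y + 0.5) * voxel_size_cm
        kern = table.kernel_2d(depth, voxel_size_cm)
        conv = fftconvolve(sl, kern, mode="same")
        sf_slice = np.clip(sf(rmu_path[:, y, :]), 0.0, None)
        out += conv * sf_slice
    return np.clip(out, 0.0, None)


class tdsc_scatter_projections:
    """All-angle TDSC operator bound to a projector's geometry.

    Precomputes the rotated mu frames and path lengths once; calling the
    instance with an image estimate returns the stack of scatter
    projections (noise-free functionals of the estimate, recomputed once
    per reconstruction iteration).
    """

    def __init__(
        self,
        projector: Projector,
        table: ScatterKernelTable,
        sf: ScatterToPrimaryModel,
    ) -> None:
        self.projector = projector
        self.table = table
        self.sf = sf
        self._paths = projector.path_frames()
        self._rmus = [
            projector._apply_rot(R, projector.mu.data) for R in projector._rot
        ]

    def __call__(self, image: np.ndarray) -> np.ndarray:
        P = self.projector
        out = np.empty((len(P._rot), P.n, P.nz))
        for k, R in enumerate(P._rot):
            rimg = P._apply_rot(R, image)
            out[k] = tdsc_scatter_projection(
                rimg, self._paths[k], self._rmus[k], self.table, self.sf, P.dx_cm
            )
        return out
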