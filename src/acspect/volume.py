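"""In-memory containers for volumetric images and projection data.

All volumes are 3-D scalar grids on an isotropic lattice. Array axes are
``(x, y, z)`` with ``z`` the scanner (axial) axis; the detector rotates in
the transaxial ``(x, y)`` plane. Physical lengths are carried in
millimetres on the containers and converted to centimetres where the
physics wants them (attenuation coefficients are 1/cm).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = ["VolumeImage", "ProjectionSet"]


@dataclass
class VolumeImage:
    """A 3-D scalar field (activity concentration, counts rate, mu, labels).

    Parameters
    ----------
    data:
        3-D array indexed ``[ix, iy, iz]``.
    voxel_size_mm:
        Isotropic voxel edge length in mm.
    origin_mm:
        Physical position of voxel ``(0, 0, 0)``'s corner. Defaults to a
        grid centred on the physical origin.
    meta:
        Free-form provenance tags (energy window, scatter mode, units).
    """

    data: np.ndarray
    voxel_size_mm: float
    origin_mm: tuple[float, float, float] | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError(f"VolumeImage requires a 3-D array, got ndim={self.data.ndim}")
        if self.voxel_size_mm <= 0:
            raise ValueError("voxel_size_mm must be positive")
        if self.origin_mm is None:
            half = tuple(-0.5 * n * self.voxel_size_mm for n in self.data.shape)
            self.origin_mm = half  # type: ignore[assignment]

    # -- geometry -----------------------------------------------------------
    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_size_cm(self) -> float:
        return self.voxel_size_mm / 10.0

    @property
    def voxel_volume_ml(self) -> float:
        """Voxel volume in ml (= cm^3)."""
        return (self.voxel_size_mm / 10.0) ** 3

    def coords_cm(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Voxel-centre coordinates (cm) as a sparse open grid."""
        axes = []
        for n, o in zip(self.data.shape, self.origin_mm):
            axes.append((o + (np.arange(n) + 0.5) * self.voxel_size_mm) / 10.0)
        return tuple(np.meshgrid(*axes, indexing="ij", sparse=True))  # type: ignore[return-value]

    def with_data(self, data: np.ndarray) -> "VolumeImage":
        """New volume on the same grid carrying ``data`` (meta copied)."""
        return VolumeImage(data, self.voxel_size_mm, self.origin_mm, dict(self.meta))

    def same_grid(self, other: "VolumeImage") -> bool:
        return (
            self.shape == other.shape
            and np.isclose(self.voxel_size_mm, other.voxel_size_mm)
            and np.allclose(self.origin_mm, other.origin_mm)
        )

    # -- I/O ----------------------------------------------------------------
    def to_nifti(self, path: str | Path) -> None:
        affine = np.diag([self.voxel_size_mm] * 3 + [1.0]).astype(float)
        affine[:3, 3] = self.origin_mm
        nib.save(nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine), str(path))

    @classmethod
    def from_nifti(cls, path: str | Path) -> "VolumeImage":
        img = nib.load(str(path))
        zooms = img.header.get_zooms()[:3]
        if not np.allclose(zooms, zooms[0]):
            raise ValueError(f"anisotropic voxels not supported: {zooms}")
        origin = tuple(np.asarray(img.affine[:3, 3], dtype=float))
        return cls(np.asarray(img.get_fdata()), float(zooms[0]), origin)


@dataclass
class ProjectionSet:
    """Stack of 2-D projections: ``data[angle, u, v]``.

    ``u`` is the transaxial detector bin, ``v`` the axial bin. The set
    carries the acquisition angles (degrees), bin size (mm), the dwell
    time per projection (s), and an energy-window tag.
    """

    data: np.ndarray
    angles_deg: np.ndarray
    bin_size_mm: float
    time_per_projection_s: float = 1.0
    window: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.angles_deg = np.asarray(self.angles_deg, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("ProjectionSet data must be (n_angles, nu, nv)")
        if self.data.shape[0] != self.angles_deg.size:
            raise ValueError("number of projections does not match number of angles")

    @property
    def n_angles(self) -> int:
        return self.data.shape[0]

    def same_geometry(self, other: "ProjectionSet") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.allclose(self.angles_deg, other.angles_deg)
            and np.isclose(self.bin_size_mm, other.bin_size_mm)
        )

    def save(self, path: str | Path) -> None:
        """Write as NPZ with a JSON sidecar holding the acquisition tags."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), data=self.data)
        sidecar = {
            "angles_deg": self.angles_deg.tolist(),
            "bin_size_mm": self.bin_size_mm,
            "time_per_projection_s": self.time_per_projection_s,
            "window": self.window,
            "meta": self.meta,
        }
        path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "ProjectionSet":
        path = Path(path)
        data = np.load(path.with_suffix(".npz"))["data"]
        sidecar = json.loads(path.with_suffix(".json").read_text())
        return cls(
            data,
            np.asarray(sidecar["angles_deg"]),
            sidecar["bin_size_mm"],
            sidecar["time_per_projection_s"],
            sidecar.get("window", ""),
            sidecar.get("meta", {}),
        )
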