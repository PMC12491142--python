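"""Digital phantom and acquisition simulation.

Synthetic stand-in for the physical measurement: builds the cylindrical
water phantom (8.7 L, 25 cm diameter) with three hot spheres (191, 100
and 48 ml at 4.2 kBq/ml over a 0.5 kBq/ml background), the matching
mu-map and label volume, depth-indexed scatter-kernel tables, and Poisson
projection data for the three Ac-225 energy windows:

* 440 keV (20% width, 25.9% emission probability, Bi-213) with a lower
  adjacent 10% scatter window,
* 218 keV (20%, 11.4%, Fr-221) with 20% scatter windows at 178/267 keV,
* 78 keV (50% width) covering the X-ray emissions.

Acquisitions follow the clinical protocol: 32 projections over 360
degrees, 128x128 bins of 4.80 mm, 10 s per projection (low count, LC) or
120 s (high count, HC). All randomness flows through one seeded
generator.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field

import numpy as np

from .projector import Projector, ProjectorConfig
from .scatter import ScatterKernelTable, ScatterToPrimaryModel, tdsc_scatter_projections
from .volume import ProjectionSet, VolumeImage

__all__ = [
    "PhantomSpec",
    "EnergyWindowSpec",
    "AcquisitionSpec",
    "ScatterSimModel",
    "SimulationResult",
    "MU_WATER_PER_CM",
    "DEFAULT_WINDOWS",
    "BACKGROUND_LABEL_OFFSET",
    "default_phantom_spec",
    "homogeneous_phantom_spec",
    "build_phantom",
    "make_kernel_table",
    "default_kernel_table",
    "simulate_projections",
]

# Narrow-beam linear attenuation of water at the three window energies (1/cm)
MU_WATER_PER_CM = {"440keV": 0.0929, "218keV": 0.136, "78keV": 0.184}

# Detector sensitivity (counts per Bq s at zero depth, collimator included).
# ~100 cps/MBq planar sensitivity, typical of a high-energy collimator;
# with it the LC protocol lands in the extreme low-count regime the
# clinical kidney protocol operates in.
DEFAULT_SENSITIVITY_CPS_PER_BQ = 1.0e-4

BACKGROUND_LABEL_OFFSET = 1  # background label = n_spheres + 1; exterior = 0


@dataclass(frozen=True)
class EnergyWindowSpec:
    """Photopeak window with its adjacent scatter windows.

    ``scatter_windows`` maps a label to ``(center_kev, width_fraction)``.
    """

    label: str
    center_kev: float
    width_fraction: float
    emission_probability: float
    scatter_windows: tuple = ()

    def __post_init__(self) -> None:
        if not 0 < self.width_fraction < 1:
            raise ValueError("width_fraction must be in (0, 1)")
        if not 0 <= self.emission_probability <= 1:
            raise ValueError("emission_probability must be in [0, 1]")

    @property
    def width_kev(self) -> float:
        return self.center_kev * self.width_fraction

    def scatter_width_kev(self, label: str) -> float:
        c, w = dict(self.scatter_windows)[label]
        return c * w


# The X-ray window bundles several 70-90 keV emissions of the decay chain;
# 0.58 is the approximate combined per-decay yield used for the synthetic
# detector model.
DEFAULT_WINDOWS = (
    EnergyWindowSpec(
        "440keV", 440.0, 0.20, 0.259, scatter_windows=(("lower", (374.0, 0.11765)),)
    ),
    EnergyWindowSpec(
        "218keV", 218.0, 0.20, 0.114,
        scatter_windows=(("lower", (178.0, 0.20)), ("upper", (267.0, 0.20))),
    ),
    EnergyWindowSpec("78keV", 78.0, 0.50, 0.58),
)
# note: the 440 keV lower window is specified as "10% width" of the
# photopeak energy (44 keV); expressed as a fraction of its own centre
# (374 keV) that is 44/374 = 0.11765.


@dataclass(frozen=True)
class AcquisitionSpec:
    n_projections: int = 32
    time_per_projection_s: float = 10.0
    matrix: tuple[int, int] = (128, 128)
    bin_size_mm: float = 4.8
    angular_range_deg: float = 360.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_projections < 1:
            raise ValueError("n_projections must be >= 1")
        if self.time_per_projection_s < 0:
            raise ValueError("time_per_projection must be non-negative")

    @property
    def angles_deg(self) -> np.ndarray:
        return np.arange(self.n_projections) * (
            self.angular_range_deg / self.n_projections
        )


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and activity of the cylindrical sphere phantom."""

    cylinder_diameter_cm: float = 25.0
    cylinder_volume_ml: float = 8700.0
    sphere_volumes_ml: tuple = (191.0, 100.0, 48.0)
    sphere_centers_cm: tuple = ()
    sphere_ac_kbq_ml: float = 4.2
    background_ac_kbq_ml: float = 0.5
    mu_water_per_cm: float = MU_WATER_PER_CM["440keV"]
    voxel_size_mm: float = 4.8
    grid_shape: tuple[int, int, int] = (128, 128, 128)

    @property
    def cylinder_height_cm(self) -> float:
        r = self.cylinder_diameter_cm / 2.0
        return self.cylinder_volume_ml / (np.pi * r**2)

    @property
    def sphere_radii_cm(self) -> tuple:
        return tuple((3.0 * v / (4.0 * np.pi)) ** (1.0 / 3.0) for v in self.sphere_volumes_ml)

    def validate(self) -> None:
        if any(v <= 0 for v in self.sphere_volumes_ml):
            raise ValueError("sphere volumes must be positive")
        if self.sphere_ac_kbq_ml < 0 or self.background_ac_kbq_ml < 0:
            raise ValueError("activity concentrations must be non-negative")
        if len(self.sphere_centers_cm) != len(self.sphere_volumes_ml):
            raise ValueError("one centre per sphere is required")
        radii = self.sphere_radii_cm
        r_cyl = self.cylinder_diameter_cm / 2.0
        h = self.cylinder_height_cm / 2.0
        for i, (c, r) in enumerate(zip(self.sphere_centers_cm, radii)):
            cx, cy, cz = c
            if np.hypot(cx, cy) + r > r_cyl or abs(cz) + r > h:
                raise ValueError(
                    f"sphere {i} (r={r:.2f} cm at {c}) extends outside the cylinder"
                )
        for i in range(len(radii)):
            for j in range(i + 1, len(radii)):
                d = np.linalg.norm(
                    np.subtract(self.sphere_centers_cm[i], self.sphere_centers_cm[j])
                )
                if d < radii[i] + radii[j]:
                    raise ValueError(f"spheres {i} and {j} overlap (centres {d:.2f} cm apart)")


def _plain(obj):
    if isinstance(obj, (tuple, list)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    return obj


def spec_to_yaml(spec, path) -> None:
    """Write a PhantomSpec or AcquisitionSpec as YAML."""
    import yaml

    payload = {k: _plain(v) for k, v in asdict(spec).items()}
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh)


def spec_from_yaml(cls, path):
    """Read a PhantomSpec or AcquisitionSpec back from YAML."""
    import yaml

    with open(path) as fh:
        d = yaml.safe_load(fh)
    for key, val in d.items():
        if isinstance(val, list):
            d[key] = tuple(tuple(v) if isinstance(v, list) else v for v in val)
    return cls(**d)


def default_phantom_spec(voxel_size_mm: float = 4.8,
                         grid: int = 128,
                         window: str = "440keV") -> PhantomSpec:
    """The three-sphere measurement phantom.

    Sphere centres sit on a 6.2 cm circle in the z = +4 cm plane, 120
    degrees apart: mutually clear, inside the cylinder, and far enough
    apart that the matched-filter VOIs (sphere radius + 2 cm) do not
    overlap. The sphere-to-background concentration ratio follows the
    stated concentrations (4.2 / 0.5 kBq/ml).
    """
    R = 6.2
    angles = np.deg2rad([90.0, 210.0, 330.0])
    centers = tuple((R * np.cos(a), R * np.sin(a), 4.0) for a in angles)
    return PhantomSpec(
        sphere_centers_cm=centers,
        mu_water_per_cm=MU_WATER_PER_CM[window],
        voxel_size_mm=voxel_size_mm,
        grid_shape=(grid, grid, grid),
    )


def homogeneous_phantom_spec(voxel_size_mm: float = 4.8,
                             grid: int = 128,
                             window: str = "440keV",
                             ac_kbq_ml: float = 0.5) -> PhantomSpec:
    """Calibration phantom: the same cylinder with the spheres removed."""
    return PhantomSpec(
        sphere_volumes_ml=(),
        sphere_centers_cm=(),
        sphere_ac_kbq_ml=0.0,
        background_ac_kbq_ml=ac_kbq_ml,
        mu_water_per_cm=MU_WATER_PER_CM[window],
        voxel_size_mm=voxel_size_mm,
        grid_shape=(grid, grid, grid),
    )


def build_phantom(spec: PhantomSpec) -> tuple[VolumeImage, VolumeImage, VolumeImage]:
    """Voxelise a phantom spec into (activity, mu, labels) volumes.

    A voxel belongs to a sphere when its centre lies inside the analytic
    sphere. Labels: 0 exterior, 1..n the spheres (in spec order), n+1 the
    cylinder background.
    """
    spec.validate()
    act = VolumeImage(np.zeros(spec.grid_shape), spec.voxel_size_mm)
    X, Y, Z = act.coords_cm()
    r_cyl = spec.cylinder_diameter_cm / 2.0
    h = spec.cylinder_height_cm / 2.0
    inside = (X**2 + Y**2 <= r_cyl**2) & (np.abs(Z) <= h)

    labels = np.zeros(spec.grid_shape, dtype=np.int16)
    bg_label = len(spec.sphere_volumes_ml) + BACKGROUND_LABEL_OFFSET
    labels[inside] = bg_label
    activity = np.where(inside, spec.background_ac_kbq_ml, 0.0)
    for i, (c, r) in enumerate(zip(spec.sphere_centers_cm, spec.sphere_radii_cm)):
        m = (X - c[0]) ** 2 + (Y - c[1]) ** 2 + (Z - c[2]) ** 2 <= r**2
        labels[m] = i + 1
        activity[m] = spec.sphere_ac_kbq_ml
    mu = np.where(inside, spec.mu_water_per_cm, 0.0)

    vs, org = spec.voxel_size_mm, act.origin_mm
    return (
        VolumeImage(activity, vs, org, {"units": "kBq_per_ml"}),
        VolumeImage(mu, vs, org, {"units": "per_cm"}),
        VolumeImage(labels, vs, org, {"units": "label"}),
    )


# ---------------------------------------------------------------------------
# scatter-kernel tables (synthetic stand-in for slab Monte-Carlo fits)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SlopeLaw:
    """Smooth depth law for the kernel tail slope and amplitude.

    slope(d) = slope_inf + (slope_0 - slope_inf) * exp(-d / d_scale):
    broad (slowly decaying) kernels at depth, sharper ones near the
    surface, with successive-slope changes below 3% per 2 cm beyond 40 cm.
    """

    slope_0: float = 0.35
    slope_inf: float = 0.09
    d_scale_cm: float = 12.0
    amplitude_0: float = 1.0

    def slope(self, depth_cm) -> np.ndarray:
        d = np.asarray(depth_cm, dtype=float)
        return self.slope_inf + (self.slope_0 - self.slope_inf) * np.exp(-d / self.d_scale_cm)

    def amplitude(self, depth_cm) -> np.ndarray:
        return np.full_like(np.asarray(depth_cm, dtype=float), self.amplitude_0)


def make_kernel_table(
    depths_cm=None,
    slope_law: SlopeLaw | None = None,
    sf_coeffs: tuple[float, float, float] = (3.0, 2.0, 0.5),
    voxel_size_cm: float = 0.48,
) -> tuple[ScatterKernelTable, ScatterToPrimaryModel]:
    """Kernel table for water slabs of 2-40 cm (2 cm steps) plus the SF model."""
    if depths_cm is None:
        depths_cm = np.arange(2.0, 40.0 + 1e-9, 2.0)
    depths_cm = np.asarray(depths_cm, dtype=float)
    if np.any(np.diff(depths_cm) <= 0):
        raise ValueError("depths must be strictly increasing")
    if np.any(depths_cm <= 0):
        raise ValueError("depths must be positive")
    law = slope_law or SlopeLaw()
    table = ScatterKernelTable(
        depths_cm, law.slope(depths_cm), law.amplitude(depths_cm), "unit_sum"
    )
    sf = ScatterToPrimaryModel(*sf_coeffs, voxel_size_cm=voxel_size_cm)
    sf.validate_range(2.0)
    return table, sf


def default_kernel_table(window: str = "440keV", voxel_size_cm: float = 0.48):
    """Per-window kernel tables: lower energies scatter into broader
    kernels with a larger scatter-to-primary fraction."""
    laws = {
        "440keV": SlopeLaw(0.35, 0.09, 12.0),
        "218keV": SlopeLaw(0.30, 0.08, 12.0),
        "78keV": SlopeLaw(0.25, 0.07, 12.0),
    }
    sf_coeffs = {
        "440keV": (3.0, 2.0, 0.5),
        "218keV": (3.4, 2.4, 0.5),
        "78keV": (3.8, 2.8, 0.5),
    }
    return make_kernel_table(
        slope_law=laws[window], sf_coeffs=sf_coeffs[window], voxel_size_cm=voxel_size_cm
    )


# ---------------------------------------------------------------------------
# projection simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ScatterSimModel:
    """Scatter generation for the acquisition simulation.

    Reuses the TDSC kernel formalism to add scatter to the photopeak and
    to populate the adjacent scatter windows. ``mismatch`` scales the
    simulated scatter relative to the TDSC model so the correction can be
    exercised under an imperfect model (1.0 = matched model).
    """

    table: ScatterKernelTable
    sf: ScatterToPrimaryModel
    mismatch: float = 1.0


@dataclass
class SimulationResult:
    photopeak: ProjectionSet
    scatter_windows: dict[str, ProjectionSet] = field(default_factory=dict)
    true_primary: np.ndarray | None = None
    true_scatter: np.ndarray | None = None


def simulate_projections(
    activity: VolumeImage,
    mu: VolumeImage,
    window: EnergyWindowSpec,
    acq: AcquisitionSpec,
    scatter_model: ScatterSimModel | None = None,
    projector_cfg: ProjectorConfig | None = None,
    sensitivity_cps_per_bq: float = DEFAULT_SENSITIVITY_CPS_PER_BQ,
    rng: np.random.Generator | None = None,
    noise: bool = True,
) -> SimulationResult:
    """Noisy projection data for one energy window.

    Expected photopeak counts are the attenuated, resolution-blurred
    forward projection of the voxel activities (Bq) times dwell time,
    emission probability and detector sensitivity, plus (optionally) a
    kernel-model scatter term. Scatter windows receive the true scatter
    scaled by their width fraction of the photopeak window, so the
    width-ratio estimators are unbiased on average. Poisson noise is
    sampled from the supplied/seeded generator.
    """
    if not activity.same_grid(mu):
        raise ValueError("activity and mu must share the same grid")
    if rng is None:
        rng = np.random.default_rng(acq.seed)

    act_bq = activity.data * 1000.0 * activity.voxel_volume_ml  # Bq per voxel
    P = Projector(mu, projector_cfg or ProjectorConfig(), acq.angles_deg)
    scale = (
        acq.time_per_projection_s * window.emission_probability * sensitivity_cps_per_bq
    )
    primary = scale * P.forward(act_bq)

    scatter = np.zeros_like(primary)
    if scatter_model is not None:
        tdsc = tdsc_scatter_projections(P, scatter_model.table, scatter_model.sf)
        scatter = scale * scatter_model.mismatch * tdsc(act_bq)

    expected = primary + scatter
    counts = rng.poisson(expected).astype(float) if noise else expected
    meta = {"seed": acq.seed, "sensitivity_cps_per_bq": sensitivity_cps_per_bq}
    photo = ProjectionSet(
        counts, acq.angles_deg, acq.bin_size_mm, acq.time_per_projection_s,
        window.label, dict(meta),
    )

    sw = {}
    for name, (_c, _w) in window.scatter_windows:
        frac = window.scatter_width_kev(name) / window.width_kev
        exp_sw = scatter * frac
        data = rng.poisson(exp_sw).astype(float) if noise else exp_sw
        sw[name] = ProjectionSet(
            data, acq.angles_deg, acq.bin_size_mm, acq.time_per_projection_s,
            f"{window.label}:{name}", dict(meta),
        )
    return SimulationResult(photo, sw, primary, scatter)
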