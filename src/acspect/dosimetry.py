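"""Region-level RBE-weighted absorbed dose via the MIRD formalism.

With only two post-therapy time points, the time-activity curve (TAC) of
a region is modelled as a single exponential ``A(t) = A0 exp(-lambda t)``
fitted exactly through the two samples. The time-integrated activity is
the 0-to-infinity integral ``TIA = A0 / lambda``, and the absorbed dose

    D = RBE x TIA x S

with S the whole-decay-chain S-value (Gy per Bq s) for the region — a
configuration input (e.g. from OpenDose), assuming local energy
deposition of all Ac-225 daughters — and RBE the relative biological
effectiveness weighting for alpha emitters (5 by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import VolumeImage

__all__ = [
    "TimeActivityFit",
    "DoseRecord",
    "fit_monoexp_tac",
    "time_integrated_activity",
    "absorbed_dose",
    "region_activity",
    "DEFAULT_RBE",
]

DEFAULT_RBE = 5.0
SECONDS_PER_HOUR = 3600.0


@dataclass(frozen=True)
class TimeActivityFit:
    """Mono-exponential TAC through two measured points.

    ``A0`` in Bq at t = 0, ``lam`` in 1/h.
    """

    A0: float
    lam: float
    times_h: tuple[float, float]
    activities_bq: tuple[float, float]

    def __call__(self, t_h) -> np.ndarray:
        return self.A0 * np.exp(-self.lam * np.asarray(t_h, dtype=float))

    @property
    def effective_half_life_h(self) -> float:
        return float(np.log(2.0) / self.lam)


@dataclass(frozen=True)
class DoseRecord:
    region: str
    window: str
    tia_bq_s: float
    s_value_gy_per_bq_s: float
    rbe: float
    dose_gy: float


def fit_monoexp_tac(times_h, activities_bq) -> TimeActivityFit:
    """Exact mono-exponential fit through two (time, activity) samples.

    lambda = ln(a1/a2) / (t2 - t1); A0 = a1 exp(lambda t1). Requires a
    physically decaying curve (a2 < a1 for t2 > t1).
    """
    t = np.asarray(times_h, dtype=float)
    a = np.asarray(activities_bq, dtype=float)
    if t.size != 2 or a.size != 2:
        raise ValueError("exactly two time points are required")
    if t[0] == t[1]:
        raise ValueError("time points must be distinct")
    if np.any(a <= 0):
        raise ValueError("activities must be positive")
    (t1, t2), (a1, a2) = (t, a) if t[0] < t[1] else (t[::-1], a[::-1])
    if a2 >= a1:
        raise ValueError(
            "activity does not decay between the two time points "
            "(non-physical effective half-life)"
        )
    lam = float(np.log(a1 / a2) / (t2 - t1))
    A0 = float(a1 * np.exp(lam * t1))
    return TimeActivityFit(A0, lam, (float(t1), float(t2)), (float(a1), float(a2)))


def time_integrated_activity(fit: TimeActivityFit) -> float:
    """TIA in Bq s: the 0-to-infinity integral A0 / lambda."""
    if fit.lam <= 0:
        raise ValueError("lambda must be positive for a finite integral")
    return fit.A0 / fit.lam * SECONDS_PER_HOUR


def absorbed_dose(
    tia_bq_s: float,
    s_value_gy_per_bq_s: float,
    rbe: float = DEFAULT_RBE,
    region: str = "",
    window: str = "",
) -> DoseRecord:
    """RBE-weighted absorbed dose: D = RBE x TIA x S."""
    if tia_bq_s < 0 or s_value_gy_per_bq_s < 0 or rbe < 0:
        raise ValueError("TIA, S-value and RBE must be non-negative")
    return DoseRecord(
        region, window, tia_bq_s, s_value_gy_per_bq_s, rbe,
        rbe * tia_bq_s * s_value_gy_per_bq_s,
    )


def region_activity(image_bq_ml: VolumeImage, mask: np.ndarray) -> float:
    """Total activity (Bq) in a region of a calibrated (Bq/ml) image."""
    if not np.any(mask):
        raise ValueError("empty region mask")
    return float(image_bq_ml.data[mask].sum() * image_bq_ml.voxel_volume_ml)
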