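"""SUV and ADC quantitation for co-registered PET and diffusion-MRI volumes.

The two maps this module produces are the inputs to every downstream stage:

* the apparent diffusion coefficient (ADC), obtained by inverting the
  mono-exponential decay ``S(b) = S0 * exp(-b * ADC)`` between two
  diffusion weightings (b = 0 and, by default, 800 s/mm^2), reported in
  the clinical convention of 1e-3 mm^2/s;
* the body-weight standardized uptake value (SUV), the PET activity
  concentration normalized by decay-corrected injected activity per gram
  of body weight (tissue density taken as 1 g/mL), which is dimensionless.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Any

import numpy as np

__all__ = [
    "GA68_HALF_LIFE_S",
    "GA68_BRANCHING_FACTOR",
    "GridMismatchError",
    "VoxelGrid",
    "DoseRecord",
    "compute_adc",
    "decay_correct",
    "compute_suv",
    "suv_to_activity",
]

#: Gamma half-life of Ga-68 in seconds, used for decay correction.
GA68_HALF_LIFE_S = 4057.7

#: Positron branching factor of Ga-68. Carried as metadata only: it enters
#: scanner-side reconstruction, which is outside this pipeline.
GA68_BRANCHING_FACTOR = 0.89

#: Unit tags a :class:`VoxelGrid` may carry. NIfTI has no field for these
#: quantities, so the tag travels in a JSON sidecar on disk.
VALID_UNITS = ("signal_au", "suv", "adc_1e-3_mm2_s", "activity_Bq_per_mL")


class GridMismatchError(ValueError):
    """Raised when two volumes do not share a grid (shape and spacing)."""


@dataclass
class VoxelGrid:
    """A 3D scalar field with isotropic-in-plane voxel spacing in mm.

    All modalities of one subject (DWI, ADC, PET activity, SUV) live on a
    single common grid; no resampling happens anywhere in the pipeline,
    so congruence is enforced wherever two grids meet.
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float]
    units: str = "signal_au"
    meta: dict[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {v.shape}")
        if not np.all(np.isfinite(v)):
            raise ValueError("volume contains non-finite values")
        self.values = v
        sp = tuple(float(s) for s in self.spacing_mm)
        if len(sp) != 3 or any(s <= 0 for s in sp):
            raise ValueError(f"spacing must be 3 positive reals, got {sp!r}")
        self.spacing_mm = sp  # type: ignore[assignment]
        if self.units not in VALID_UNITS:
            raise ValueError(f"unknown units {self.units!r}; expected one of {VALID_UNITS}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    def copy(self, **overrides: Any) -> "VoxelGrid":
        kw: dict[str, Any] = dict(
            values=self.values.copy(),
            spacing_mm=self.spacing_mm,
            units=self.units,
            meta=dict(self.meta),
        )
        kw.update(overrides)
        return VoxelGrid(**kw)


def check_congruent(a: VoxelGrid, b: VoxelGrid, tol_mm: float = 1e-3) -> None:
    """Assert two grids share shape and spacing (within ``tol_mm``)."""
    if a.shape != b.shape:
        raise GridMismatchError(f"grid shapes differ: {a.shape} vs {b.shape}")
    if any(abs(x - y) > tol_mm for x, y in zip(a.spacing_mm, b.spacing_mm)):
        raise GridMismatchError(
            f"voxel spacings differ beyond {tol_mm} mm: {a.spacing_mm} vs {b.spacing_mm}"
        )


@dataclass(frozen=True)
class DoseRecord:
    """Injected-dose bookkeeping needed to scale activity into SUV."""

    injected_activity_MBq: float
    body_weight_kg: float
    injection_to_scan_s: float = 0.0
    half_life_s: float = GA68_HALF_LIFE_S
    branching_factor: float = GA68_BRANCHING_FACTOR

    def __post_init__(self) -> None:
        if self.injected_activity_MBq <= 0:
            raise ValueError("injected activity must be positive")
        if self.body_weight_kg <= 0:
            raise ValueError("body weight must be positive")
        if self.injection_to_scan_s < 0:
            raise ValueError("injection-to-scan delay must be nonnegative")
        if self.half_life_s <= 0:
            raise ValueError("half-life must be positive")
        if not (0 < self.branching_factor <= 1):
            raise ValueError("branching factor must lie in (0, 1]")


def compute_adc(
    b0: VoxelGrid, bhigh: VoxelGrid, b_value_s_mm2: float = 800.0
) -> VoxelGrid:
    """Invert the mono-exponential DWI decay into an ADC map.

    Per voxel, ``ADC = ln(S0 / Sb) / b``, reported in 1e-3 mm^2/s. Voxels
    that cannot be inverted (``S0 <= 0``, ``Sb <= 0``, or ``Sb > S0``,
    i.e. apparent signal gain) are clamped to 0; their count is recorded
    in ``meta['n_clamped']`` rather than silently dropped.
    """
    check_congruent(b0, bhigh)
    if b_value_s_mm2 <= 0:
        raise ValueError("b-value must be positive")
    s0 = b0.values
    sb = bhigh.values
    bad = (s0 <= 0) | (sb <= 0) | (sb > s0)
    adc = np.zeros_like(s0)
    ok = ~bad
    # ln(S0/Sb)/b is in mm^2/s; multiply by 1e3 for the 1e-3 mm^2/s convention
    adc[ok] = np.log(s0[ok] / sb[ok]) / b_value_s_mm2 * 1e3
    return VoxelGrid(
        adc,
        b0.spacing_mm,
        units="adc_1e-3_mm2_s",
        meta={"n_clamped": int(bad.sum()), "b_value_s_mm2": float(b_value_s_mm2)},
    )


def decay_correct(dose: DoseRecord) -> float:
    """Activity (MBq) remaining at scan start: ``A0 * 2**(-dt / T_half)``."""
    return dose.injected_activity_MBq * 2.0 ** (-dose.injection_to_scan_s / dose.half_life_s)


def compute_suv(activity: VoxelGrid, dose: DoseRecord) -> VoxelGrid:
    """Convert an activity-concentration volume (Bq/mL) into body-weight SUV.

    ``SUV = C[Bq/mL] * W[g] / A[Bq]`` with the usual 1 g/mL tissue-density
    convention, where ``A`` is the decay-corrected injected activity. The
    exact inverse is :func:`suv_to_activity`.
    """
    if np.any(activity.values < 0):
        raise ValueError("activity concentrations must be nonnegative")
    a_bq = decay_correct(dose) * 1e6
    if a_bq <= 0:
        raise ValueError("decay-corrected activity must be positive")
    weight_g = dose.body_weight_kg * 1000.0
    suv = activity.values * weight_g / a_bq
    return VoxelGrid(suv, activity.spacing_mm, units="suv", meta=dict(activity.meta))


def suv_to_activity(suv: VoxelGrid, dose: DoseRecord) -> VoxelGrid:
    """Exact inverse of :func:`compute_suv` (SUV -> Bq/mL)."""
    a_bq = decay_correct(dose) * 1e6
    weight_g = dose.body_weight_kg * 1000.0
    values = suv.values * a_bq / weight_g
    return VoxelGrid(values, suv.spacing_mm, units="activity_Bq_per_mL", meta=dict(suv.meta))


def activity_per_suv(dose: DoseRecord) -> float:
    """Activity concentration (Bq/mL) corresponding to SUV = 1."""
    return decay_correct(dose) * 1e6 / (dose.body_weight_kg * 1000.0)


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * math.sqrt(2.0 * math.log(2.0)))
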