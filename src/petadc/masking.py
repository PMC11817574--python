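"""Lesion ROI masks and percentage-of-SUVmax threshold series.

A subject starts from one manually delineated lesion ROI (here supplied by
the phantom as ground truth). SUVmax is taken over that ROI on the
reference PET, and thresholded masks keep the voxels whose SUV is at least
``pct/100 * SUVmax``. The inequality is inclusive, so the SUVmax voxel
survives every threshold and no mask can be empty for pct <= 100. Masks
thresholded at increasing percentages are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .quantitation import VoxelGrid

__all__ = [
    "ZONES",
    "DEFAULT_THRESHOLDS",
    "ROIMask",
    "roi_suv_max",
    "threshold_mask",
    "mask_series",
    "extract_values",
]

ZONES = ("PZ", "TZ")

#: Threshold percentages of SUVmax used for the standard mask series.
DEFAULT_THRESHOLDS = (10, 20, 30, 40, 50, 60)


@dataclass
class ROIMask:
    """Boolean lesion mask with zone label and thresholding provenance.

    ``threshold_pct == 0`` means the manual (ground-truth) ROI; any
    positive value means the mask was derived by percentage-of-SUVmax
    thresholding, in which case ``source_suv_max`` records the SUVmax the
    cutoff was computed from.
    """

    mask: np.ndarray
    zone: str
    provenance: str = "manual"
    threshold_pct: int = 0
    source_suv_max: Optional[float] = None

    def __post_init__(self) -> None:
        m = np.asarray(self.mask)
        if m.dtype != np.bool_:
            m = m.astype(bool)
        if m.ndim != 3:
            raise ValueError(f"mask must be 3D, got shape {m.shape}")
        if not m.any():
            raise ValueError("ROI mask is empty")
        self.mask = m
        if self.zone not in ZONES:
            raise ValueError(f"zone must be one of {ZONES}, got {self.zone!r}")
        if self.provenance not in ("manual", "thresholded"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if (self.provenance == "manual") != (self.threshold_pct == 0):
            raise ValueError("threshold_pct 0 if and only if provenance is manual")
        if self.provenance == "thresholded" and self.source_suv_max is None:
            raise ValueError("thresholded masks must record their source SUVmax")

    @property
    def n_voxels(self) -> int:
        return int(self.mask.sum())


def _check_mask_grid(volume: VoxelGrid, roi: ROIMask) -> None:
    if volume.shape != roi.mask.shape:
        raise ValueError(
            f"mask shape {roi.mask.shape} does not match volume shape {volume.shape}"
        )


def roi_suv_max(suv: VoxelGrid, roi: ROIMask) -> float:
    """Maximum SUV over the ROI voxels."""
    _check_mask_grid(suv, roi)
    return float(suv.values[roi.mask].max())


def threshold_mask(suv: VoxelGrid, roi: ROIMask, pct: int) -> ROIMask:
    """Keep the ROI voxels with SUV >= (pct/100) * SUVmax (inclusive)."""
    if not 0 < pct <= 100:
        raise ValueError(f"threshold percentage must lie in (0, 100], got {pct}")
    if roi.provenance == "thresholded" and roi.threshold_pct > pct:
        raise ValueError(
            "source mask was thresholded at a higher percentage; "
            "threshold from the manual ROI or a coarser mask"
        )
    _check_mask_grid(suv, roi)
    smax = roi_suv_max(suv, roi)
    cutoff = pct / 100.0 * smax
    mask = roi.mask & (suv.values >= cutoff)
    # the argmax voxel always satisfies the inclusive inequality
    assert mask.any(), "thresholded mask unexpectedly empty"
    return ROIMask(
        mask,
        zone=roi.zone,
        provenance="thresholded",
        threshold_pct=int(pct),
        source_suv_max=smax,
    )


def mask_series(
    suv: VoxelGrid, roi: ROIMask, pcts: Sequence[int] = DEFAULT_THRESHOLDS
) -> list[ROIMask]:
    """Thresholded masks for a strictly increasing list of percentages.

    All masks are derived from the same parent ROI (hence the same SUVmax),
    so the series is nested: ``mask(p2) ⊆ mask(p1)`` whenever ``p2 > p1``.
    """
    if list(pcts) != sorted(set(pcts)):
        raise ValueError(f"threshold percentages must be strictly increasing, got {list(pcts)}")
    masks = [threshold_mask(suv, roi, p) for p in pcts]
    for coarse, fine in zip(masks, masks[1:]):
        assert not (fine.mask & ~coarse.mask).any(), "mask series is not nested"
    return masks


def extract_values(volume: VoxelGrid, mask: ROIMask) -> np.ndarray:
    """Voxel values under the mask, in C-order (row-major) scan order."""
    _check_mask_grid(volume, mask)
    if not mask.mask.any():  # pragma: no cover - ROIMask forbids empty masks
        raise ValueError("cannot extract values from an empty mask")
    return volume.values[mask.mask]
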