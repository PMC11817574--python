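"""First-order histogram features of masked voxel values.

Six statistics per lesion and modality: mean, max, min, median, excess
(Fisher) kurtosis and skewness. Shape statistics use population moments
(divisor n, no small-sample bias correction): skewness is
``g1 = m3 / m2**1.5`` and kurtosis is ``m4 / m2**2 - 3``, so platykurtic
regions come out negative, matching the clinical reporting convention for
SUV histograms.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .masking import ROIMask, extract_values, threshold_mask
from .quantitation import VoxelGrid, compute_adc, compute_suv

__all__ = ["FEATURE_NAMES", "FeatureSet", "histogram_features", "cohort_feature_table"]

logger = logging.getLogger(__name__)

#: Fixed feature ordering used everywhere (tables, correlation grids, plots).
FEATURE_NAMES = ("mean", "max", "min", "median", "kurtosis", "skewness")

#: Smallest region the shape statistics are computed on.
MIN_REGION_VOXELS = 4


@dataclass(frozen=True)
class FeatureSet:
    """The six histogram statistics for one lesion/modality/threshold."""

    mean: float
    max: float
    min: float
    median: float
    kurtosis: float
    skewness: float
    modality: str = ""
    method_label: str = ""
    zone: str = ""
    threshold_pct: int = 0
    n_voxels: int = 0

    def __post_init__(self) -> None:
        if not (self.min <= self.median <= self.max and self.min <= self.mean <= self.max):
            raise ValueError("order statistics violate min <= median/mean <= max")

    def as_dict(self, prefix: str = "") -> dict[str, float]:
        d = asdict(self)
        return {prefix + k: d[k] for k in FEATURE_NAMES}


def histogram_features(
    values: Iterable[float],
    *,
    modality: str = "",
    method_label: str = "",
    zone: str = "",
    threshold_pct: int = 0,
) -> FeatureSet:
    """Compute the six-statistic feature set on a list of voxel values.

    Requires at least :data:`MIN_REGION_VOXELS` values (kurtosis is
    meaningless below that) and nonzero variance (a constant region has no
    histogram shape and is rejected with a diagnostic).
    """
    arr = np.asarray(list(values) if not isinstance(values, np.ndarray) else values, dtype=float)
    if arr.ndim != 1:
        arr = arr.ravel()
    if arr.size < MIN_REGION_VOXELS:
        raise ValueError(
            f"need at least {MIN_REGION_VOXELS} voxels for histogram features, got {arr.size}"
        )
    if not np.all(np.isfinite(arr)):
        raise ValueError("histogram features require finite values")
    if np.var(arr) == 0:
        raise ValueError("constant region: histogram shape statistics are undefined")
    return FeatureSet(
        mean=float(arr.mean()),
        max=float(arr.max()),
        min=float(arr.min()),
        median=float(np.median(arr)),
        kurtosis=float(stats.kurtosis(arr, fisher=True, bias=True)),
        skewness=float(stats.skew(arr, bias=True)),
        modality=modality,
        method_label=method_label,
        zone=zone,
        threshold_pct=int(threshold_pct),
        n_voxels=int(arr.size),
    )


def _subject_mask(subject, threshold_pct: int, reference_label: str) -> ROIMask:
    """Lesion mask at a threshold, always derived from the reference PET.

    Deriving every mask from the reference reconstruction (and reusing it
    for all methods) makes cross-method feature differences reflect voxel
    values only, never segmentation differences.
    """
    if threshold_pct == 0:
        return subject.roi
    suv_ref = compute_suv(subject.pet_by_method[reference_label], subject.dose)
    return threshold_mask(suv_ref, subject.roi, threshold_pct)


def subject_features(
    subject,
    method_label: str,
    threshold_pct: int = 0,
    *,
    b_value_s_mm2: float = 800.0,
    reference_label: str = "CT_reference",
) -> tuple[FeatureSet, FeatureSet]:
    """(ADC, SUV) feature sets for one subject at one threshold/method."""
    if method_label not in subject.pet_by_method:
        raise KeyError(f"subject {subject.subject_id} has no PET method {method_label!r}")
    adc_map = compute_adc(subject.dwi_b0, subject.dwi_b800, b_value_s_mm2)
    suv_map = compute_suv(subject.pet_by_method[method_label], subject.dose)
    mask = _subject_mask(subject, threshold_pct, reference_label)
    ctx = dict(method_label=method_label, zone=subject.roi.zone, threshold_pct=threshold_pct)
    adc_fs = histogram_features(extract_values(adc_map, mask), modality="ADC", **ctx)
    suv_fs = histogram_features(extract_values(suv_map, mask), modality="SUV", **ctx)
    return adc_fs, suv_fs


def cohort_feature_table(
    subjects: Sequence,
    method_label: str,
    threshold_pct: int = 0,
    *,
    b_value_s_mm2: float = 800.0,
    reference_label: str = "CT_reference",
) -> pd.DataFrame:
    """One row per subject with the 12 ADC/SUV feature columns.

    Subjects whose features cannot be computed (missing method, empty or
    degenerate mask) are excluded with the reason recorded in
    ``table.attrs['exclusions']`` and logged, and the table proceeds with
    the survivors — fewer than 3 survivors is an error, because the
    downstream correlation is undefined.
    """
    rows: list[dict] = []
    exclusions: dict[str, str] = {}
    for subject in subjects:
        try:
            adc_fs, suv_fs = subject_features(
                subject,
                method_label,
                threshold_pct,
                b_value_s_mm2=b_value_s_mm2,
                reference_label=reference_label,
            )
        except (KeyError, ValueError) as exc:
            exclusions[subject.subject_id] = str(exc)
            logger.warning("excluding subject %s: %s", subject.subject_id, exc)
            continue
        row: dict = {
            "subject_id": subject.subject_id,
            "zone": subject.roi.zone,
            "method_label": method_label,
            "threshold_pct": threshold_pct,
            "n_voxels": adc_fs.n_voxels,
        }
        row.update(adc_fs.as_dict("adc_"))
        row.update(suv_fs.as_dict("suv_"))
        rows.append(row)
    if len(rows) < 3:
        raise ValueError(
            f"only {len(rows)} subjects with valid features (need >= 3); "
            f"exclusions: {exclusions}"
        )
    table = pd.DataFrame(rows)
    table.attrs["exclusions"] = exclusions
    return table
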