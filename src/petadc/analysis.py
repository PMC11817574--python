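"""Cross-subject statistics: Spearman grids, avg.RAE, method comparisons.

The scientific questions answered here are (a) whether lesion-level ADC
and SUV histogram features are rank-correlated across a cohort, reported
as a 6x6 Spearman grid per PET reconstruction method and threshold, and
(b) how much an alternative attenuation-correction method perturbs SUV
features relative to the reference reconstruction, quantified with the
average relative absolute error

    avg.RAE = (1/N) * sum_i |P_x,i - P_ref,i| / P_ref,i * 100 .

Applied to a single feature value per subject (N = 1) and averaged over
the cohort, this yields one error per feature per method, compared
between methods with a paired t-test and a Mann-Whitney-Wilcoxon test.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .features import FEATURE_NAMES, cohort_feature_table

__all__ = [
    "CorrelationGrid",
    "ErrorReport",
    "spearman_rho",
    "correlation_grid",
    "avg_rae",
    "feature_error_report",
    "mann_whitney",
]

logger = logging.getLogger(__name__)

#: Below this sample size the Spearman p-value is computed by exhaustive
#: permutation; at or above it, by the t approximation.
EXACT_SPEARMAN_N = 8

#: Reference feature values smaller than this in magnitude make the
#: relative error unstable (kurtosis sits near 0) and exclude the subject
#: from that feature's error cell.
FEATURE_REF_EPS = 0.05


def _rank_rho(rx: np.ndarray, ry: np.ndarray) -> float:
    """Pearson correlation of two rank vectors, clipped to [-1, 1]."""
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = math.sqrt(float(rx @ rx) * float(ry @ ry))
    if denom == 0:
        raise ValueError("constant input: ranks are degenerate")
    return float(np.clip(float(rx @ ry) / denom, -1.0, 1.0))


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with average ranks for ties.

    The two-sided p-value is exact (exhaustive permutation of one rank
    vector) for n < 8 and uses the usual t approximation with n - 2
    degrees of freedom otherwise.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.shape != ya.shape or xa.ndim != 1:
        raise ValueError("x and y must be 1D sequences of equal length")
    n = xa.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    rx = stats.rankdata(xa)
    ry = stats.rankdata(ya)
    rho = _rank_rho(rx, ry)
    if n < EXACT_SPEARMAN_N:
        total = 0
        hits = 0
        target = abs(rho) - 1e-12
        for perm in itertools.permutations(range(n)):
            total += 1
            if abs(_rank_rho(rx, ry[list(perm)])) >= target:
                hits += 1
        p = hits / total
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
            p = float(2.0 * stats.t.sf(abs(t), df=n - 2))
    return rho, p


@dataclass
class CorrelationGrid:
    """6x6 Spearman grid: rows are ADC features, columns SUV features."""

    rho: np.ndarray
    p_values: np.ndarray
    n: int
    method_label: str
    threshold_pct: int
    feature_names: tuple[str, ...] = FEATURE_NAMES
    missing_cells: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        k = len(self.feature_names)
        self.rho = np.asarray(self.rho, dtype=float)
        self.p_values = np.asarray(self.p_values, dtype=float)
        if self.rho.shape != (k, k) or self.p_values.shape != (k, k):
            raise ValueError(f"grid must be {k}x{k}")
        with np.errstate(invalid="ignore"):
            if np.nanmax(np.abs(self.rho)) > 1 + 1e-12:
                raise ValueError("|rho| must not exceed 1")

    def to_frame(self, which: str = "rho") -> pd.DataFrame:
        mat = self.rho if which == "rho" else self.p_values
        idx = [f"adc_{f}" for f in self.feature_names]
        cols = [f"suv_{f}" for f in self.feature_names]
        return pd.DataFrame(mat, index=idx, columns=cols)


def correlation_grid(
    feature_table: pd.DataFrame, method_label: str, threshold_pct: int
) -> CorrelationGrid:
    """Spearman rho and p for every ADC-feature x SUV-feature pair.

    A degenerate (constant) feature column makes its cells NaN and lists
    them in ``missing_cells`` — never a silent zero.
    """
    if len(feature_table) < 3:
        raise ValueError("need at least 3 subjects for a correlation grid")
    k = len(FEATURE_NAMES)
    rho = np.full((k, k), np.nan)
    pvals = np.full((k, k), np.nan)
    missing: list[tuple[str, str]] = []
    for i, fa in enumerate(FEATURE_NAMES):
        for j, fs in enumerate(FEATURE_NAMES):
            x = feature_table[f"adc_{fa}"].to_numpy()
            y = feature_table[f"suv_{fs}"].to_numpy()
            try:
                rho[i, j], pvals[i, j] = spearman_rho(x, y)
            except ValueError:
                missing.append((fa, fs))
    return CorrelationGrid(
        rho=rho,
        p_values=pvals,
        n=len(feature_table),
        method_label=method_label,
        threshold_pct=int(threshold_pct),
        missing_cells=missing,
    )


def avg_rae(
    px: Sequence[float],
    pref: Sequence[float],
    *,
    eps: float = 1e-6,
    with_count: bool = False,
):
    """Average relative absolute error (%) of ``px`` against ``pref``.

    Voxels whose reference value is <= ``eps`` are excluded from the mean
    and counted (the ratio would be unbounded); if every voxel is
    excluded the error is undefined and a ValueError is raised. Pass
    ``with_count=True`` to also get the exclusion count.
    """
    xa = np.asarray(px, dtype=float)
    ra = np.asarray(pref, dtype=float)
    if xa.shape != ra.shape or xa.ndim != 1 or xa.size < 1:
        raise ValueError("px and pref must be 1D sequences of equal nonzero length")
    keep = ra > eps
    n_excluded = int((~keep).sum())
    if not keep.any():
        raise ValueError("all reference values at or below the floor; avg.RAE undefined")
    value = float(np.mean(np.abs(xa[keep] - ra[keep]) / ra[keep]) * 100.0)
    if with_count:
        return value, n_excluded
    return value


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p-value.

    Exact distribution when the combined sample is small (<= 12) and tie
    free; otherwise the tie-corrected normal approximation with
    continuity correction.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if xa.size < 3 or ya.size < 3:
        raise ValueError("each sample needs at least 3 observations")
    pooled = np.concatenate([xa, ya])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (pooled.size <= 12 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, ya, alternative="two-sided", method=method)
    return float(res.pvalue)


@dataclass
class ErrorReport:
    """Cohort avg.RAE per SUV feature for each non-reference method.

    ``table`` has one row per feature with columns
    ``<method>_mean``, ``<method>_sd``, ``<method>_n`` for each method,
    plus ``t_test_p`` and ``mann_whitney_p`` comparing the two methods'
    per-subject errors (NaN when degenerate, e.g. all-zero differences).
    """

    table: pd.DataFrame
    reference_label: str
    method_labels: tuple[str, ...]
    threshold_pct: int
    excluded: dict[str, int] = field(default_factory=dict)


def _feature_rae(x: float, x_ref: float, eps: float) -> Optional[float]:
    if abs(x_ref) < eps:
        return None
    return abs(x - x_ref) / abs(x_ref) * 100.0


def feature_error_report(
    subjects: Sequence,
    reference_label: str = "CT_reference",
    other_labels: Sequence[str] = ("MRI_like", "DL_like"),
    *,
    threshold_pct: int = 0,
    b_value_s_mm2: float = 800.0,
    ref_eps: float = FEATURE_REF_EPS,
) -> ErrorReport:
    """Per-feature avg.RAE of each method's SUV features vs the reference.

    For every subject and SUV feature, the scalar (N = 1) relative
    absolute error against the reference reconstruction is computed, then
    averaged over the cohort (mean +/- sd). Subjects whose reference
    feature is within ``ref_eps`` of zero are excluded from that feature
    cell with a logged count — kurtosis hovers near zero and would
    otherwise produce unbounded errors.
    """
    tables = {
        label: cohort_feature_table(
            subjects,
            label,
            threshold_pct,
            b_value_s_mm2=b_value_s_mm2,
            reference_label=reference_label,
        ).set_index("subject_id")
        for label in (reference_label, *other_labels)
    }
    ref = tables[reference_label]
    common = ref.index
    for label in other_labels:
        common = common.intersection(tables[label].index)

    rows = []
    excluded: dict[str, int] = {}
    per_subject: dict[tuple[str, str], pd.Series] = {}
    for feat in FEATURE_NAMES:
        col = f"suv_{feat}"
        row: dict = {"feature": feat}
        for label in other_labels:
            errs = {}
            n_excl = 0
            for sid in common:
                e = _feature_rae(
                    float(tables[label].loc[sid, col]), float(ref.loc[sid, col]), ref_eps
                )
                if e is None:
                    n_excl += 1
                else:
                    errs[sid] = e
            series = pd.Series(errs, dtype=float)
            per_subject[(label, feat)] = series
            if n_excl:
                excluded[f"{label}/{feat}"] = n_excl
                logger.info(
                    "feature %s, method %s: excluded %d subjects with |reference| < %g",
                    feat, label, n_excl, ref_eps,
                )
            if len(series) == 0:
                row[f"{label}_mean"] = np.nan
                row[f"{label}_sd"] = np.nan
                row[f"{label}_n"] = 0
            else:
                row[f"{label}_mean"] = float(series.mean())
                row[f"{label}_sd"] = float(series.std(ddof=1)) if len(series) > 1 else np.nan
                row[f"{label}_n"] = int(len(series))
        # paired comparison between the first two non-reference methods
        row["t_test_p"] = np.nan
        row["mann_whitney_p"] = np.nan
        if len(other_labels) >= 2:
            a = per_subject[(other_labels[0], feat)]
            b = per_subject[(other_labels[1], feat)]
            paired = a.index.intersection(b.index)
            if len(paired) >= 3:
                diffs = a[paired].to_numpy() - b[paired].to_numpy()
                if np.any(diffs != 0):
                    row["t_test_p"] = float(
                        stats.ttest_rel(a[paired], b[paired]).pvalue
                    )
                    try:
                        row["mann_whitney_p"] = mann_whitney(
                            a[paired].to_numpy(), b[paired].to_numpy()
                        )
                    except ValueError:
                        pass
        rows.append(row)

    table = pd.DataFrame(rows).set_index("feature")
    return ErrorReport(
        table=table,
        reference_label=reference_label,
        method_labels=tuple(other_labels),
        threshold_pct=int(threshold_pct),
        excluded=excluded,
    )
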