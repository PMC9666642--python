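"""Duplicate-aliquot agreement and cross-dataset correlation of AF vectors.

Genotyping concordance between two independently extracted aliquots of the
same sample is measured with the intraclass correlation coefficient (ICC)
rather than plain correlation: two AF vectors can correlate perfectly while
disagreeing by a systematic shift, which the ICC penalizes.  The variant
used is the two-way, absolute-agreement, single-measurement coefficient
(McGraw & Wong's ICC(A,1)) with the two aliquots as raters and the markers
as targets:

    ICC(A,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E + (k/n)(MS_C - MS_E))

where MS_R, MS_C and MS_E are the rows (markers), columns (aliquots) and
residual mean squares of the standard two-way ANOVA decomposition, k = 2
raters and n = markers.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .afstats import AFMatrix
from .panel_io import SampleRecord

logger = logging.getLogger(__name__)


@dataclass
class ConcordanceResult:
    """Agreement statistics for one duplicate pair."""

    pair_id: str
    sample_a: str
    sample_b: str
    icc: float
    pearson_r: float
    spearman_rho: float
    n_markers_used: int
    outlier_markers: list[str]


def icc_agreement(x: Sequence[float], y: Sequence[float]) -> float:
    """Two-way absolute-agreement single-measure ICC between two vectors.

    Vectors must already be aligned (same markers, no missing values).
    Both vectors being constant and equal yields 1.0 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be aligned 1-D vectors")
    n = x.size
    if n < 3:
        raise ValueError(f"need at least 3 paired observations, got {n}")
    k = 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    if ss_total == 0.0:
        logger.info("both AF vectors constant and equal; ICC = 1 by convention")
        return 1.0
    ms_rows = ss_rows / (n - 1)
    ms_cols = ss_cols / (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    denom = ms_rows + (k - 1) * ms_err + (k / n) * (ms_cols - ms_err)
    return float((ms_rows - ms_err) / denom)


def _paired_complete(x: pd.Series, y: pd.Series) -> tuple[pd.Series, pd.Series]:
    mask = x.notna() & y.notna()
    return x[mask], y[mask]


def duplicate_concordance(
    af: AFMatrix,
    sheet: Sequence[SampleRecord],
    outlier_delta: float = 20.0,
) -> list[ConcordanceResult]:
    """Per-duplicate-group ICC / Pearson / Spearman on pairwise-complete markers.

    Each duplicate group must contain exactly two aliquots.  Markers whose AF
    differs between aliquots by more than ``outlier_delta`` percentage points
    are reported as outliers.
    """
    groups: dict[str, list[str]] = {}
    for rec in sheet:
        if rec.duplicate_group and rec.sample_id in af.sample_ids:
            groups.setdefault(rec.duplicate_group, []).append(rec.sample_id)
    results = []
    for gid in sorted(groups):
        members = groups[gid]
        if len(members) != 2:
            raise ValueError(
                f"duplicate_group {gid!r} has {len(members)} members in the AF "
                "matrix; exactly 2 aliquots are required"
            )
        a, b = members
        x, y = _paired_complete(af.row(a), af.row(b))
        pear = stats.pearsonr(x, y).statistic if x.std() > 0 and y.std() > 0 else np.nan
        spear = stats.spearmanr(x, y).statistic if x.std() > 0 and y.std() > 0 else np.nan
        delta = (x - y).abs()
        results.append(
            ConcordanceResult(
                pair_id=gid,
                sample_a=a,
                sample_b=b,
                icc=icc_agreement(x.values, y.values),
                pearson_r=float(pear),
                spearman_rho=float(spear),
                n_markers_used=len(x),
                outlier_markers=list(delta.index[delta > outlier_delta]),
            )
        )
    return results


def concordance_table(results: Sequence[ConcordanceResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "pair_id": [r.pair_id for r in results],
            "sample_a": [r.sample_a for r in results],
            "sample_b": [r.sample_b for r in results],
            "icc": [r.icc for r in results],
            "pearson_r": [r.pearson_r for r in results],
            "spearman_rho": [r.spearman_rho for r in results],
            "n_markers": [r.n_markers_used for r in results],
            "outlier_markers": [",".join(r.outlier_markers) for r in results],
        }
    )


def dataset_correlation(
    af_a: pd.Series,
    af_b: pd.Series,
    marker_subset: Optional[Sequence[str]] = None,
) -> tuple[float, float, int]:
    """Pearson r and Spearman rho between two per-marker mean AF vectors.

    Vectors are aligned on shared, pairwise non-missing markers (optionally
    restricted to ``marker_subset``, e.g. the ancestry or the trait markers).
    Spearman uses average ranks for ties.  A constant vector makes both
    correlations undefined; NaN is returned with a warning.
    """
    if marker_subset is not None:
        subset = [m for m in marker_subset if m in af_a.index and m in af_b.index]
        af_a, af_b = af_a[subset], af_b[subset]
    else:
        shared = af_a.index.intersection(af_b.index)
        af_a, af_b = af_a[shared], af_b[shared]
    x, y = _paired_complete(af_a, af_b)
    n = len(x)
    if n < 3:
        raise ValueError(f"need at least 3 shared non-missing markers, got {n}")
    if x.std() == 0 or y.std() == 0:
        logger.warning("constant AF vector: correlation undefined, reporting NaN")
        return (float("nan"), float("nan"), n)
    pear = stats.pearsonr(x, y).statistic
    spear = stats.spearmanr(x, y).statistic
    return (float(pear), float(spear), n)
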