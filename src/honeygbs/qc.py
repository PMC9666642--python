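"""Call-rate QC for targeted genotyping count matrices.

A marker is "called" in a sample when its sequencing depth reaches a cutoff
(DP >= min_dp, default 1 read).  The sample call rate is the fraction of
panel markers called in a sample; the SNP call rate is the fraction of
samples in which a marker was called.  Markers falling below a call-rate
threshold (default 90%) within a stratum — typically the degraded honey
matrices — are flagged as unreliable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import CountMatrix, MatrixType, Panel, SampleRecord, sheet_by_id


@dataclass
class QCSummary:
    """Per-sample and per-marker call rates plus coverage accounting."""

    sample_call_rate: pd.Series
    snp_call_rate: pd.Series
    low_call_markers: list[str]
    n_markers_covered_in_all: int

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        per_sample = self.sample_call_rate.rename("call_rate").to_frame()
        per_sample.index.name = "sample_id"
        per_marker = self.snp_call_rate.rename("call_rate").to_frame()
        per_marker["low_call"] = per_marker.index.isin(self.low_call_markers)
        per_marker.index.name = "marker_id"
        return per_sample, per_marker


def _called(counts: CountMatrix, min_dp: int) -> pd.DataFrame:
    if min_dp < 1:
        raise ValueError("min_dp must be >= 1")
    dp = counts.depth()
    return dp.ge(min_dp) & dp.notna()


def sample_call_rate(counts: CountMatrix, panel: Panel, min_dp: int = 1) -> pd.Series:
    """Fraction of panel markers called per sample (denominator = panel size)."""
    called = _called(counts, min_dp)
    return called.sum(axis=1) / len(panel)


def snp_call_rate(counts: CountMatrix, min_dp: int = 1) -> pd.Series:
    """Fraction of samples in which each marker was called."""
    called = _called(counts, min_dp)
    n = counts.shape[0]
    if n == 0:
        return pd.Series(0.0, index=counts.ref.columns)
    return called.sum(axis=0) / n


def flag_low_call_markers(
    counts: CountMatrix,
    threshold: float = 0.90,
    min_dp: int = 1,
    sheet: Optional[Sequence[SampleRecord]] = None,
    matrix_types: Optional[Iterable[MatrixType]] = None,
) -> list[str]:
    """Markers with call rate strictly below ``threshold``, in panel order.

    When ``matrix_types`` is given (with a sheet), call rates are computed
    within that stratum only — e.g. flagging markers that drop out in honey
    matrices while genotyping cleanly in bee DNA.
    """
    if not (0 < threshold <= 1):
        raise ValueError("threshold must lie in (0, 1]")
    if matrix_types is not None:
        if sheet is None:
            raise ValueError("stratified flagging requires the sample sheet")
        wanted = set(matrix_types)
        by_id = sheet_by_id(sheet)
        keep = [
            sid for sid in counts.sample_ids
            if sid in by_id and by_id[sid].matrix_type in wanted
        ]
        counts = counts.subset_samples(keep)
    rates = snp_call_rate(counts, min_dp)
    return [m for m in counts.marker_ids if rates[m] < threshold]


def markers_covered_in_all(counts: CountMatrix) -> int:
    """Number of markers covered by at least one read in every sample."""
    if counts.shape[0] == 0:
        raise ValueError("empty count matrix")
    dp = counts.depth()
    return int((dp.ge(1) & dp.notna()).all(axis=0).sum())


def qc_summary(
    counts: CountMatrix,
    panel: Panel,
    min_dp: int = 1,
    threshold: float = 0.90,
    sheet: Optional[Sequence[SampleRecord]] = None,
    matrix_types: Optional[Iterable[MatrixType]] = None,
) -> QCSummary:
    return QCSummary(
        sample_call_rate=sample_call_rate(counts, panel, min_dp),
        snp_call_rate=snp_call_rate(counts, min_dp),
        low_call_markers=flag_low_call_markers(
            counts, threshold=threshold, min_dp=min_dp,
            sheet=sheet, matrix_types=matrix_types,
        ),
        n_markers_covered_in_all=markers_covered_in_all(counts),
    )
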