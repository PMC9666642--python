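"""Trait-associated marker reporting: group mean AFs and fixation status.

Beyond ancestry, the panel carries markers associated with colony traits
(calmness, gentleness, varroa resistance).  For these the interesting
outputs are the per-group mean alternative-allele frequency — reported on
the 0-1 scale — and whether a marker is fixed for the reference allele
(AF 0) or the alternative allele (AF 100) within a group; markers fixed for
the reference allele in every examined group carry no usable signal for the
populations at hand.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import pandas as pd

from .afstats import AFMatrix, group_mean_af
from .panel_io import CountMatrix, SampleRecord


class FixationStatus(str, Enum):
    FIXED_REF = "fixed_ref"
    FIXED_ALT = "fixed_alt"
    SEGREGATING = "segregating"
    MISSING = "missing"


@dataclass
class FixationReport:
    """Fixation status and mean AF per trait marker and group."""

    status: pd.DataFrame          # markers x groups of FixationStatus values
    mean_af: pd.DataFrame         # markers x groups, percent
    n_fixed_ref_in_all_groups: int

    @property
    def fixed_ref_in_all_groups(self) -> list[str]:
        mask = (self.status == FixationStatus.FIXED_REF).all(axis=1)
        return list(self.status.index[mask])


def fixation_report(
    af: AFMatrix,
    sheet: Sequence[SampleRecord],
    markers: Sequence[str],
    grouping: Mapping[str, Sequence[str]],
    tol: float = 0.0,
    include_duplicates: bool = True,
    counts: Optional[CountMatrix] = None,
) -> FixationReport:
    """Classify each trait marker as fixed or segregating within each group.

    A marker is fixed_ref in a group when every non-missing AF there is
    <= ``tol`` percent (default 0: strict fixation), fixed_alt when every one
    is >= 100 - tol, missing when no sample covers it, and segregating
    otherwise.  The summary counts markers fixed_ref in all groups at once.
    """
    if not markers:
        raise ValueError("empty trait marker subset")
    for label, members in grouping.items():
        if not members:
            raise ValueError(f"group {label!r} has zero samples")
    sub = af.subset_markers(list(markers))
    means = group_mean_af(sub, sheet, grouping, include_duplicates, counts)
    status = pd.DataFrame(index=list(markers), columns=list(grouping), dtype=object)
    for label, members in grouping.items():
        block = sub.values.loc[[m for m in members if m in sub.sample_ids]]
        for marker in markers:
            col = block[marker].dropna()
            if col.empty:
                status.at[marker, label] = FixationStatus.MISSING
            elif (col <= tol).all():
                status.at[marker, label] = FixationStatus.FIXED_REF
            elif (col >= 100.0 - tol).all():
                status.at[marker, label] = FixationStatus.FIXED_ALT
            else:
                status.at[marker, label] = FixationStatus.SEGREGATING
    n_all = int((status == FixationStatus.FIXED_REF).all(axis=1).sum())
    return FixationReport(status=status, mean_af=means, n_fixed_ref_in_all_groups=n_all)


def trait_af_table(
    af: AFMatrix,
    sheet: Sequence[SampleRecord],
    markers: Sequence[str],
    grouping: Mapping[str, Sequence[str]],
    include_duplicates: bool = True,
    counts: Optional[CountMatrix] = None,
) -> pd.DataFrame:
    """Per-marker, per-group mean alternative-allele frequency on 0-1 scale."""
    means = group_mean_af(
        af.subset_markers(list(markers)), sheet, grouping, include_duplicates, counts
    )
    return means / 100.0
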