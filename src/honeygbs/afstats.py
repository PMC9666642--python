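"""Allele-frequency estimation, allele-copy accounting and depth summaries.

The central estimator is deliberately simple: the alternative-allele
frequency (AF) of a marker in a sample is 100 * ALT / (REF + ALT), computed
from the read depths supporting each allele.  For honey and worker-pool DNA
this estimates the pooled colony allele frequency; for a single diploid
larva it can only take the values 0, 50 or 100.  Frequencies are carried in
percent (0-100) throughout, matching the genotype-reference encoding
0/50/100 used for individual bees.
"""

from __future__ import annotations

import enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .panel_io import (
    AlleleDepth,
    CountMatrix,
    HONEY_MATRIX_TYPES,
    SampleRecord,
    sheet_by_id,
)


class AFProvenance(str, enum.Enum):
    READ_COUNT = "read_count_derived"
    GENOTYPE = "genotype_derived"


class AFMatrix:
    """Samples x markers matrix of alternative-allele frequencies in percent.

    ``values`` is a float DataFrame in [0, 100] with NaN for missing cells;
    ``provenance`` records per row whether the frequencies came from read
    counts (continuous) or from called genotypes (restricted to 0/50/100).
    """

    def __init__(self, values: pd.DataFrame, provenance: pd.Series):
        if not values.index.equals(provenance.index):
            raise ValueError("provenance must be indexed by the sample ids")
        if values.index.has_duplicates:
            raise ValueError("duplicate sample ids in AF matrix")
        vals = values.astype(float)
        finite = vals.values[~np.isnan(vals.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("allele frequencies must lie in [0, 100] percent")
        geno = provenance == AFProvenance.GENOTYPE
        if geno.any():
            g = vals.loc[geno].values
            g = g[~np.isnan(g)]
            if g.size and not np.isin(g, (0.0, 50.0, 100.0)).all():
                raise ValueError("genotype-derived rows may only contain 0/50/100")
        self.values = vals
        self.provenance = provenance.copy()

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def row(self, sample_id: str) -> pd.Series:
        return self.values.loc[sample_id]

    def subset_markers(self, marker_ids: Sequence[str]) -> "AFMatrix":
        return AFMatrix(self.values[list(marker_ids)], self.provenance)

    def subset_samples(self, sample_ids: Sequence[str]) -> "AFMatrix":
        ids = list(sample_ids)
        return AFMatrix(self.values.loc[ids], self.provenance.loc[ids])

    def call_rate(self) -> pd.Series:
        """Fraction of non-missing markers per sample."""
        return self.values.notna().mean(axis=1)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AFMatrix):
            return NotImplemented
        return (
            self.values.index.equals(other.values.index)
            and self.values.columns.equals(other.values.columns)
            and np.array_equal(self.values.values, other.values.values, equal_nan=True)
            and (self.provenance == other.provenance).all()
        )

    # -- TSV round trip --------------------------------------------------
    def to_tsv(self, path) -> None:
        """AF table TSV: sample_id, one column per marker, 'NA' for missing.

        A trailing ``provenance`` column preserves the per-row flag.
        """
        out = self.values.copy()
        out.insert(len(out.columns), "provenance", [p.value for p in self.provenance])
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA", float_format="%.10g")

    @classmethod
    def from_tsv(cls, path) -> "AFMatrix":
        df = pd.read_csv(path, sep="\t", index_col="sample_id", na_values=["NA"])
        if "provenance" in df.columns:
            prov = df.pop("provenance").map(AFProvenance)
        else:
            prov = pd.Series(AFProvenance.READ_COUNT, index=df.index)
        return cls(df.astype(float), prov)


def write_af_table(af: AFMatrix, path) -> None:
    af.to_tsv(path)


def read_af_table(path) -> AFMatrix:
    return AFMatrix.from_tsv(path)


# ---------------------------------------------------------------------------
# Estimation

def estimate_af(cell: Optional[AlleleDepth], min_dp: int = 1) -> Optional[float]:
    """AF in percent from one cell's read counts; None below the depth cutoff.

    The default ``min_dp`` of 1 treats a marker as informative as soon as a
    single read covers it; raise the cutoff for stricter genotyping.
    """
    if min_dp < 1:
        raise ValueError("min_dp must be >= 1")
    if cell is None:
        return None
    dp = cell.ref_reads + cell.alt_reads
    if dp < min_dp:
        return None
    return 100.0 * cell.alt_reads / dp


def af_matrix(counts: CountMatrix, min_dp: int = 1) -> AFMatrix:
    """Element-wise AF estimation over a count matrix."""
    if min_dp < 1:
        raise ValueError("min_dp must be >= 1")
    dp = counts.ref.values + counts.alt.values
    with np.errstate(invalid="ignore", divide="ignore"):
        vals = 100.0 * counts.alt.values / dp
    vals = np.where(np.nan_to_num(dp, nan=0.0) >= min_dp, vals, np.nan)
    frame = pd.DataFrame(vals, index=counts.ref.index, columns=counts.ref.columns)
    prov = pd.Series(AFProvenance.READ_COUNT, index=frame.index)
    return AFMatrix(frame, prov)


def genotype_af_matrix(values: pd.DataFrame) -> AFMatrix:
    """Wrap a 0/50/100 genotype table as a genotype-derived AFMatrix."""
    return AFMatrix(values, pd.Series(AFProvenance.GENOTYPE, index=values.index))


def allele_copies(samples: Iterable[SampleRecord]) -> int:
    """Total chromosomal allele copies per SNP contributed by a sample set.

    Sum of ploidy * n_individuals.  Honey matrices contribute an undefined
    number of copies (traces of thousands of workers) and are refused rather
    than guessed at.
    """
    total = 0
    for s in samples:
        if s.matrix_type in HONEY_MATRIX_TYPES or s.n_individuals is None:
            raise ValueError(
                f"sample {s.sample_id}: undefined copy number "
                f"(matrix_type {s.matrix_type.value})"
            )
        total += s.ploidy * s.n_individuals
    return total


# ---------------------------------------------------------------------------
# Summaries

def depth_summary(counts: CountMatrix, sheet: Sequence[SampleRecord]) -> pd.DataFrame:
    """Per-matrix-type summary of per-sample total sequencing depth.

    For each sample the DP values are summed across markers; mean, sample
    standard deviation (n-1 denominator), median, min and max are then taken
    within each matrix type.  A single-sample group reports NaN s.d.
    """
    by_id = sheet_by_id(sheet)
    totals = counts.depth().sum(axis=1, skipna=True)
    groups: dict[str, list[float]] = {}
    for sid, total in totals.items():
        rec = by_id.get(sid)
        if rec is None:
            continue
        groups.setdefault(rec.matrix_type.value, []).append(float(total))
    rows = {}
    for mt, vals in groups.items():
        arr = np.asarray(vals, dtype=float)
        rows[mt] = {
            "n": len(arr),
            "mean": arr.mean(),
            "sd": arr.std(ddof=1) if len(arr) > 1 else np.nan,
            "median": float(np.median(arr)),
            "min": arr.min(),
            "max": arr.max(),
        }
    return pd.DataFrame.from_dict(rows, orient="index")


def select_unique_samples(
    af: AFMatrix,
    sheet: Sequence[SampleRecord],
    counts: Optional[CountMatrix] = None,
) -> list[str]:
    """Sample ids with duplicates collapsed to one representative per group.

    Within each duplicate group the member with the highest call rate is
    retained; ties fall back to the highest read total (when counts are
    available) and then to the lexicographically smallest sample id.
    """
    call_rates = af.call_rate()
    reads = counts.depth().sum(axis=1, skipna=True) if counts is not None else None
    kept: list[str] = []
    seen_groups: set[str] = set()
    by_id = sheet_by_id(sheet)
    for sid in af.sample_ids:
        rec = by_id.get(sid)
        group = rec.duplicate_group if rec else None
        if not group:
            kept.append(sid)
            continue
        if group in seen_groups:
            continue
        seen_groups.add(group)
        members = [
            m for m in af.sample_ids
            if (r := by_id.get(m)) is not None and r.duplicate_group == group
        ]
        def rank(m: str):
            nreads = float(reads.get(m, 0.0)) if reads is not None else 0.0
            return (-call_rates[m], -nreads, m)
        kept.append(min(members, key=rank))
    return kept


def group_mean_af(
    af: AFMatrix,
    sheet: Sequence[SampleRecord],
    grouping: Mapping[str, Sequence[str]],
    include_duplicates: bool = True,
    counts: Optional[CountMatrix] = None,
) -> pd.DataFrame:
    """Per-marker mean AF (percent) for named groups of samples.

    ``grouping`` maps a group label to its member sample ids.  Means are over
    non-missing cells only.  With ``include_duplicates=False`` each duplicate
    group is represented by its best aliquot (see select_unique_samples).
    """
    if not grouping:
        raise ValueError("no groups supplied")
    retained = set(af.sample_ids) if include_duplicates else set(
        select_unique_samples(af, sheet, counts)
    )
    out = {}
    for label, members in grouping.items():
        members = [m for m in members if m in retained]
        if not members:
            raise ValueError(f"group {label!r} has no samples after duplicate filtering")
        out[label] = af.values.loc[members].mean(axis=0, skipna=True)
    return pd.DataFrame(out)
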