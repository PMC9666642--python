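"""Data model and I/O for targeted SNP panels, sample sheets and allele-depth VCFs.

The genotyping assay targets a fixed panel of biallelic SNPs (by default 121:
97 ancestry-informative plus 24 trait-associated markers).  Each sequenced
specimen — a single larva, a pool of worker bees, or honey — yields one VCF
with per-marker read depths for the reference (REF) and alternative (ALT)
alleles.  This module loads the panel and sample-sheet tables, extracts
allele depths from VCFs into a samples x markers count matrix, and tallies
off-target variants detected by the same amplicons.

Positions are 1-based (VCF convention) throughout.  Marker matching against
VCF records is exact on (chrom, pos, ref, alt); a record with swapped
alleles is treated as missing, with a warning, never auto-flipped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

_NUCLEOTIDES = frozenset("ACGT")


class MarkerCategory(str, Enum):
    """Functional category of a panel marker."""

    ANCESTRY = "ancestry"
    CALMNESS = "calmness"
    GENTLENESS = "gentleness"
    VARROA_RESISTANCE = "varroa_resistance"


#: Panel composition of the published assay: 97 ancestry-informative SNPs,
#: 3 calmness, 3 gentleness and 18 varroa-resistance markers (121 total).
DEFAULT_EXPECTED_COUNTS: dict[MarkerCategory, int] = {
    MarkerCategory.ANCESTRY: 97,
    MarkerCategory.CALMNESS: 3,
    MarkerCategory.GENTLENESS: 3,
    MarkerCategory.VARROA_RESISTANCE: 18,
}


class MatrixType(str, Enum):
    """Source matrix of a sequenced specimen."""

    LARVA = "larva"
    WORKER_POOL = "worker_pool"
    HONEYCOMB_HONEY = "honeycomb_honey"
    BULK_HONEY = "bulk_honey"
    WGS_REFERENCE = "wgs_reference"
    GENOTYPE_REFERENCE = "genotype_reference"


#: Matrix types for which the number of contributing individuals is unknown.
HONEY_MATRIX_TYPES = frozenset({MatrixType.HONEYCOMB_HONEY, MatrixType.BULK_HONEY})

#: Matrix types carrying reference (individual-bee) genotypes.
REFERENCE_MATRIX_TYPES = frozenset({MatrixType.WGS_REFERENCE, MatrixType.GENOTYPE_REFERENCE})


class Lineage(str, Enum):
    """Honey bee evolutionary lineages (plus an explicit unknown)."""

    A = "A"
    C = "C"
    M = "M"
    O = "O"
    Y = "Y"
    UNKNOWN = "unknown"


@dataclass(frozen=True)
class PanelMarker:
    """One targeted biallelic SNP."""

    marker_id: str
    chrom: str
    pos: int  # 1-based
    ref_allele: str
    alt_allele: str
    category: MarkerCategory

    def __post_init__(self) -> None:
        if self.ref_allele not in _NUCLEOTIDES or self.alt_allele not in _NUCLEOTIDES:
            raise ValueError(
                f"marker {self.marker_id}: alleles must be single nucleotides in "
                f"ACGT, got ref={self.ref_allele!r} alt={self.alt_allele!r}"
            )
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"marker {self.marker_id}: ref and alt alleles are identical")
        if self.pos < 1:
            raise ValueError(f"marker {self.marker_id}: position must be >= 1 (1-based)")


@dataclass
class Panel:
    """An ordered SNP panel; marker order defines matrix column order."""

    markers: list[PanelMarker]
    expected_counts: dict[MarkerCategory, int] = field(
        default_factory=lambda: dict(DEFAULT_EXPECTED_COUNTS)
    )

    def __post_init__(self) -> None:
        ids = [m.marker_id for m in self.markers]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate marker_id in panel: {dup}")
        sites = [(m.chrom, m.pos) for m in self.markers]
        if len(set(sites)) != len(sites):
            dup = sorted({s for s in sites if sites.count(s) > 1})
            raise ValueError(f"duplicate (chrom,pos) in panel: {dup}")

    def __len__(self) -> int:
        return len(self.markers)

    def __iter__(self):
        return iter(self.markers)

    @property
    def marker_ids(self) -> list[str]:
        return [m.marker_id for m in self.markers]

    def markers_in_category(self, category: MarkerCategory) -> list[PanelMarker]:
        return [m for m in self.markers if m.category == category]

    def category_ids(self, *categories: MarkerCategory) -> list[str]:
        wanted = set(categories)
        return [m.marker_id for m in self.markers if m.category in wanted]

    @property
    def trait_marker_ids(self) -> list[str]:
        """The non-ancestry (trait-associated) markers, in panel order."""
        return [m.marker_id for m in self.markers if m.category != MarkerCategory.ANCESTRY]

    def by_site(self) -> dict[tuple[str, int], PanelMarker]:
        return {(m.chrom, m.pos): m for m in self.markers}


@dataclass(frozen=True)
class SampleRecord:
    """One sequenced specimen (or one reference genotype row)."""

    sample_id: str
    matrix_type: MatrixType
    subspecies_label: Optional[str] = None
    lineage_label: Optional[Lineage] = None
    duplicate_group: Optional[str] = None
    n_individuals: Optional[int] = None
    ploidy: int = 2
    mitotype: Optional[str] = None

    def __post_init__(self) -> None:
        has_n = self.n_individuals is not None
        if self.matrix_type in HONEY_MATRIX_TYPES:
            if has_n:
                raise ValueError(
                    f"sample {self.sample_id}: honey matrices have an undefined "
                    "number of contributing individuals; n_individuals must be absent"
                )
        elif not has_n:
            raise ValueError(
                f"sample {self.sample_id}: n_individuals required for "
                f"matrix_type {self.matrix_type.value}"
            )
        if has_n and self.n_individuals < 1:
            raise ValueError(f"sample {self.sample_id}: n_individuals must be positive")
        if self.ploidy < 1:
            raise ValueError(f"sample {self.sample_id}: ploidy must be positive")

    @property
    def mitotypes(self) -> list[str]:
        """Recorded mitotype labels (a comma-joined set for mixed apiaries)."""
        if not self.mitotype:
            return []
        return [m.strip() for m in self.mitotype.split(",") if m.strip()]


class AlleleDepth(NamedTuple):
    """Read support for the reference and alternative allele at one marker."""

    ref_reads: int
    alt_reads: int

    @property
    def dp(self) -> int:
        return self.ref_reads + self.alt_reads


class CountMatrix:
    """Samples x markers matrix of allele depths.

    Internally two aligned float DataFrames (ref and alt reads) where NaN in
    both marks a missing cell.  Column order is the panel order; row order is
    the sample-sheet order.
    """

    def __init__(self, ref: pd.DataFrame, alt: pd.DataFrame):
        if not ref.index.equals(alt.index) or not ref.columns.equals(alt.columns):
            raise ValueError("ref and alt depth frames must be aligned")
        if ref.index.has_duplicates:
            raise ValueError(f"duplicate sample ids: {sorted(ref.index[ref.index.duplicated()])}")
        if (ref.isna() != alt.isna()).any().any():
            raise ValueError("ref/alt missingness must coincide")
        self.ref = ref.astype(float)
        self.alt = alt.astype(float)

    # -- construction ----------------------------------------------------
    @classmethod
    def empty(cls, sample_ids: Sequence[str], marker_ids: Sequence[str]) -> "CountMatrix":
        shape = (len(sample_ids), len(marker_ids))
        nan = np.full(shape, np.nan)
        return cls(
            pd.DataFrame(nan, index=list(sample_ids), columns=list(marker_ids)),
            pd.DataFrame(nan.copy(), index=list(sample_ids), columns=list(marker_ids)),
        )

    @classmethod
    def from_rows(cls, rows: Mapping[str, Mapping[str, AlleleDepth]],
                  marker_ids: Sequence[str]) -> "CountMatrix":
        """Build from {sample_id: {marker_id: AlleleDepth}}; absent keys are missing."""
        cm = cls.empty(list(rows), marker_ids)
        for sid, cells in rows.items():
            for mid, ad in cells.items():
                cm.ref.at[sid, mid] = ad.ref_reads
                cm.alt.at[sid, mid] = ad.alt_reads
        return cm

    # -- accessors -------------------------------------------------------
    @property
    def sample_ids(self) -> list[str]:
        return list(self.ref.index)

    @property
    def marker_ids(self) -> list[str]:
        return list(self.ref.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref.shape

    def depth(self) -> pd.DataFrame:
        """Total depth DP = ref + alt per cell (NaN where missing)."""
        return self.ref + self.alt

    def is_missing(self) -> pd.DataFrame:
        return self.ref.isna()

    def cell(self, sample_id: str, marker_id: str) -> Optional[AlleleDepth]:
        r = self.ref.at[sample_id, marker_id]
        if np.isnan(r):
            return None
        return AlleleDepth(int(r), int(self.alt.at[sample_id, marker_id]))

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.ref.loc[list(sample_ids)], self.alt.loc[list(sample_ids)])

    def append(self, other: "CountMatrix") -> "CountMatrix":
        if list(other.marker_ids) != list(self.marker_ids):
            raise ValueError("marker columns differ")
        return CountMatrix(
            pd.concat([self.ref, other.ref]), pd.concat([self.alt, other.alt])
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CountMatrix):
            return NotImplemented
        return (
            self.ref.index.equals(other.ref.index)
            and self.ref.columns.equals(other.ref.columns)
            and np.array_equal(self.ref.values, other.ref.values, equal_nan=True)
            and np.array_equal(self.alt.values, other.alt.values, equal_nan=True)
        )

    # -- TSV round trip --------------------------------------------------
    def to_tsv(self, path: str | Path) -> None:
        """Write as TSV: cells are 'ref,alt' or 'NA'."""
        out = pd.DataFrame(index=self.ref.index, columns=self.ref.columns, dtype=object)
        miss = self.is_missing().values
        r, a = self.ref.values, self.alt.values
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                out.iat[i, j] = "NA" if miss[i, j] else f"{int(r[i, j])},{int(a[i, j])}"
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CountMatrix":
        raw = pd.read_csv(
            path, sep="\t", index_col="sample_id", dtype=str, keep_default_na=False
        )
        ref = pd.DataFrame(np.nan, index=raw.index, columns=raw.columns)
        alt = ref.copy()
        for i in range(raw.shape[0]):
            for j in range(raw.shape[1]):
                cell = raw.iat[i, j]
                if cell != "NA":
                    r, a = cell.split(",")
                    ref.iat[i, j] = int(r)
                    alt.iat[i, j] = int(a)
        return cls(ref, alt)


# ---------------------------------------------------------------------------
# Panel I/O

PANEL_COLUMNS = ["marker_id", "chrom", "pos", "ref", "alt", "category"]


def load_panel(path: str | Path,
               expected_counts: Optional[Mapping[MarkerCategory, int]] = None) -> Panel:
    """Load a panel definition TSV (columns marker_id, chrom, pos, ref, alt, category).

    File row order becomes the canonical marker (column) order.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    if df.empty:
        raise ValueError(f"empty panel: {path}")
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"panel file {path} lacks columns {missing}")
    markers = [
        PanelMarker(
            marker_id=str(row.marker_id),
            chrom=str(row.chrom),
            pos=int(row.pos),
            ref_allele=str(row.ref),
            alt_allele=str(row.alt),
            category=MarkerCategory(row.category),
        )
        for row in df.itertuples()
    ]
    panel = Panel(markers)
    if expected_counts is not None:
        panel.expected_counts = dict(expected_counts)
    return panel


def write_panel(panel: Panel, path: str | Path) -> None:
    pd.DataFrame(
        {
            "marker_id": [m.marker_id for m in panel],
            "chrom": [m.chrom for m in panel],
            "pos": [m.pos for m in panel],
            "ref": [m.ref_allele for m in panel],
            "alt": [m.alt_allele for m in panel],
            "category": [m.category.value for m in panel],
        }
    ).to_csv(path, sep="\t", index=False)


@dataclass
class PanelValidationReport:
    observed: dict[MarkerCategory, int]
    expected: dict[MarkerCategory, int]
    total: int
    passed: bool

    def __str__(self) -> str:
        lines = [f"panel composition: total {self.total} markers"]
        for cat in MarkerCategory:
            obs = self.observed.get(cat, 0)
            exp = self.expected.get(cat, 0)
            mark = "ok" if obs == exp else f"FAIL (expected {exp})"
            lines.append(f"  {cat.value}: {obs} {mark}")
        lines.append("PASS" if self.passed else "FAIL")
        return "\n".join(lines)


def validate_panel_composition(panel: Panel) -> PanelValidationReport:
    """Check per-category marker counts against the panel's expected composition."""
    observed = {cat: 0 for cat in MarkerCategory}
    for m in panel:
        observed[m.category] += 1
    passed = all(observed.get(c, 0) == n for c, n in panel.expected_counts.items()) and all(
        panel.expected_counts.get(c, 0) == n for c, n in observed.items() if n
    )
    return PanelValidationReport(
        observed=observed,
        expected=dict(panel.expected_counts),
        total=len(panel),
        passed=passed,
    )


# ---------------------------------------------------------------------------
# VCF reading

def _vcf_records(vcf_path: str | Path):
    from cyvcf2 import VCF

    try:
        vcf = VCF(str(vcf_path))
    except Exception as exc:  # cyvcf2 raises bare Exception on bad files
        raise ValueError(f"cannot read VCF {vcf_path}: {exc}") from exc
    try:
        yield from vcf
    finally:
        vcf.close()


def _record_allele_depth(variant, alt_allele: str) -> Optional[AlleleDepth]:
    """Extract (ref_reads, alt_reads) for one alt allele from a cyvcf2 variant.

    For multi-allelic records only the requested alt allele's depth is used;
    other alt alleles contribute to neither count.  Returns None when the
    record carries no per-allele depth (AD) information.
    """
    try:
        ad = variant.format("AD")
    except KeyError:
        ad = None
    if ad is None:
        return None
    ad = np.asarray(ad)[0]  # single-sample VCFs
    alts = list(variant.ALT)
    if alt_allele not in alts:
        return None
    ai = 1 + alts.index(alt_allele)
    if ai >= len(ad):
        return None
    ref_reads, alt_reads = int(ad[0]), int(ad[ai])
    if ref_reads < 0 or alt_reads < 0:  # cyvcf2 encodes missing AD as negative
        return None
    return AlleleDepth(ref_reads, alt_reads)


def read_allele_depths(vcf_path: str | Path, panel: Panel) -> dict[str, AlleleDepth]:
    """Read one sample's per-marker allele depths from a single-sample VCF.

    Returns a {marker_id: AlleleDepth} mapping covering only the markers
    found with usable depth; panel markers absent from the VCF (or present
    without depth information, or with mismatched alleles) are simply absent
    from the result and become missing matrix cells.
    """
    by_site = panel.by_site()
    panel_chroms = {m.chrom for m in panel}
    row: dict[str, AlleleDepth] = {}
    seen_chroms: set[str] = set()
    for variant in _vcf_records(vcf_path):
        seen_chroms.add(variant.CHROM)
        marker = by_site.get((variant.CHROM, variant.POS))
        if marker is None:
            continue
        if variant.REF != marker.ref_allele:
            if marker.alt_allele == variant.REF and marker.ref_allele in variant.ALT:
                logger.warning(
                    "%s: alleles at %s:%d appear swapped relative to the panel "
                    "(%s/%s vs %s/%s); cell left missing, not flipped",
                    vcf_path, marker.chrom, marker.pos, variant.REF,
                    ",".join(variant.ALT), marker.ref_allele, marker.alt_allele,
                )
            continue
        ad = _record_allele_depth(variant, marker.alt_allele)
        if ad is not None:
            row[marker.marker_id] = ad
    if seen_chroms and not (seen_chroms & panel_chroms):
        logger.warning(
            "%s: no chromosome name matches any panel marker (saw %s); "
            "returning an all-missing row", vcf_path, sorted(seen_chroms),
        )
    return row


def build_count_matrix(vcf_paths: Mapping[str, str | Path], panel: Panel) -> CountMatrix:
    """Assemble a CountMatrix from {sample_id: vcf_path}, in mapping order."""
    rows = {sid: read_allele_depths(p, panel) for sid, p in vcf_paths.items()}
    return CountMatrix.from_rows(rows, panel.marker_ids)


def classify_variant(ref: str, alt: str) -> str:
    """Classify an off-target variant: SNP, indel, or complex."""
    if len(ref) == 1 and len(alt) == 1:
        return "SNP"
    if len(ref) != len(alt):
        return "indel"
    return "complex"


def tally_offtarget_variants(
    vcf_paths: Iterable[str | Path],
    panel: Panel,
    fraction_thresholds: Sequence[float] = (0.05, 0.50, 0.90),
) -> pd.DataFrame:
    """Count non-panel variants observed in at least a given fraction of samples.

    Returns a DataFrame indexed by threshold with columns SNP/indel/complex/total.
    A variant is keyed by (chrom, pos, ref, alt); it is counted at threshold t
    iff it appears in >= t of the supplied VCFs.
    """
    vcf_paths = list(vcf_paths)
    if not vcf_paths:
        raise ValueError("no VCF files supplied")
    for t in fraction_thresholds:
        if not (0 < t <= 1):
            raise ValueError(f"threshold {t} outside (0, 1]")
    panel_sites = {(m.chrom, m.pos, m.ref_allele, m.alt_allele) for m in panel}
    n_samples = len(vcf_paths)
    presence: dict[tuple[str, int, str, str], int] = {}
    for path in vcf_paths:
        seen: set[tuple[str, int, str, str]] = set()
        for variant in _vcf_records(path):
            for alt in variant.ALT:
                key = (variant.CHROM, variant.POS, variant.REF, alt)
                if key not in panel_sites:
                    seen.add(key)
        for key in seen:
            presence[key] = presence.get(key, 0) + 1
    classes = ("SNP", "indel", "complex")
    rows = []
    for t in fraction_thresholds:
        counts = {c: 0 for c in classes}
        for (chrom, pos, ref, alt), n in presence.items():
            if n / n_samples >= t:
                counts[classify_variant(ref, alt)] += 1
        counts["total"] = sum(counts[c] for c in classes)
        rows.append(counts)
    return pd.DataFrame(rows, index=pd.Index(list(fraction_thresholds), name="threshold"))


# ---------------------------------------------------------------------------
# Sample sheet I/O

SHEET_COLUMNS = [
    "sample_id", "matrix_type", "subspecies", "lineage",
    "duplicate_group", "n_individuals", "ploidy", "mitotype",
]


def load_sample_sheet(path: str | Path) -> list[SampleRecord]:
    """Load the sample sheet TSV; empty strings mark absent optional fields."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in SHEET_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"sample sheet {path} lacks columns {missing}")
    records = []
    for row in df.itertuples():
        try:
            mt = MatrixType(row.matrix_type)
        except ValueError:
            raise ValueError(
                f"sample {row.sample_id}: unknown matrix_type {row.matrix_type!r}"
            ) from None
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                matrix_type=mt,
                subspecies_label=row.subspecies or None,
                lineage_label=Lineage(row.lineage) if row.lineage else None,
                duplicate_group=row.duplicate_group or None,
                n_individuals=int(row.n_individuals) if row.n_individuals else None,
                ploidy=int(row.ploidy) if row.ploidy else 2,
                mitotype=row.mitotype or None,
            )
        )
    validate_sample_sheet(records)
    return records


def validate_sample_sheet(records: Sequence[SampleRecord]) -> None:
    ids = [r.sample_id for r in records]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate sample_id in sheet: {dup}")
    group_sizes: dict[str, int] = {}
    for r in records:
        if r.duplicate_group:
            group_sizes[r.duplicate_group] = group_sizes.get(r.duplicate_group, 0) + 1
    singletons = sorted(g for g, n in group_sizes.items() if n < 2)
    if singletons:
        raise ValueError(
            f"duplicate_group shared by fewer than 2 samples: {singletons}"
        )


def write_sample_sheet(records: Sequence[SampleRecord], path: str | Path) -> None:
    pd.DataFrame(
        {
            "sample_id": [r.sample_id for r in records],
            "matrix_type": [r.matrix_type.value for r in records],
            "subspecies": [r.subspecies_label or "" for r in records],
            "lineage": [r.lineage_label.value if r.lineage_label else "" for r in records],
            "duplicate_group": [r.duplicate_group or "" for r in records],
            "n_individuals": [
                "" if r.n_individuals is None else str(r.n_individuals) for r in records
            ],
            "ploidy": [str(r.ploidy) for r in records],
            "mitotype": [r.mitotype or "" for r in records],
        }
    ).to_csv(path, sep="\t", index=False)


def sheet_by_id(records: Sequence[SampleRecord]) -> dict[str, SampleRecord]:
    return {r.sample_id: r for r in records}
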