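import numpy as np
import pytest

from honeygbs.panel_io import (
    CountMatrix,
    Lineage,
    MarkerCategory,
    MatrixType,
    Panel,
    PanelMarker,
    SampleRecord,
)
from honeygbs.simulate import default_panel


@pytest.fixture(scope="session")
def panel121() -> Panel:
    """The synthetic 121-marker panel (97 ancestry + 3 + 3 + 18)."""
    return default_panel()


@pytest.fixture()
def small_panel() -> Panel:
    markers = [
        PanelMarker("snp1", "chr1", 100, "A", "G", MarkerCategory.ANCESTRY),
        PanelMarker("snp2", "chr1", 200, "C", "T", MarkerCategory.ANCESTRY),
        PanelMarker("snp3", "chr2", 150, "G", "A", MarkerCategory.CALMNESS),
        PanelMarker("snp4", "chr2", 900, "T", "C", MarkerCategory.VARROA_RESISTANCE),
    ]
    return Panel(markers, expected_counts={MarkerCategory.ANCESTRY: 2,
                                           MarkerCategory.CALMNESS: 1,
                                           MarkerCategory.VARROA_RESISTANCE: 1})


def build_table1_sheet() -> list[SampleRecord]:
    """The study cohort: 61 sequenced samples, 8 duplicate pairs.

    4 larvae + 5 pool samples (3 sources, 2 duplicated) + 38 honeycomb
    samples (34 sources, 4 duplicated) + 14 bulk honey samples (12 sources,
    2 duplicated).
    """
    records: list[SampleRecord] = []
    for i in range(4):
        records.append(SampleRecord(
            sample_id=f"larva_{i+1}", matrix_type=MatrixType.LARVA,
            subspecies_label="ligustica", lineage_label=Lineage.C,
            n_individuals=1, mitotype="C1"))
    for i in range(3):
        dup = f"pool_dup_{i+1}" if i < 2 else None
        records.append(SampleRecord(
            sample_id=f"pool_{i+1}a", matrix_type=MatrixType.WORKER_POOL,
            subspecies_label="ligustica", lineage_label=Lineage.C,
            duplicate_group=dup, n_individuals=35, mitotype="C1"))
        if dup:
            records.append(SampleRecord(
                sample_id=f"pool_{i+1}b", matrix_type=MatrixType.WORKER_POOL,
                subspecies_label="ligustica", lineage_label=Lineage.C,
                duplicate_group=dup, n_individuals=35, mitotype="C1"))
    n_comb = 0
    for sub, lin, n in (("ligustica", Lineage.C, 32), ("mellifera", Lineage.M, 1),
                        ("siciliana", Lineage.A, 1)):
        for i in range(n):
            n_comb += 1
            dup = f"comb_dup_{n_comb}" if sub == "ligustica" and i < 4 else None
            records.append(SampleRecord(
                sample_id=f"comb_{n_comb}a", matrix_type=MatrixType.HONEYCOMB_HONEY,
                subspecies_label=sub, lineage_label=lin, duplicate_group=dup,
                mitotype="C1" if lin == Lineage.C else lin.value))
            if dup:
                records.append(SampleRecord(
                    sample_id=f"comb_{n_comb}b", matrix_type=MatrixType.HONEYCOMB_HONEY,
                    subspecies_label=sub, lineage_label=lin, duplicate_group=dup,
                    mitotype="C1"))
    n_honey = 0
    for sub, lin, n in (("mellifera", Lineage.M, 2), ("siciliana", Lineage.A, 10)):
        for i in range(n):
            n_honey += 1
            dup = f"honey_dup_{n_honey}" if sub == "siciliana" and i < 2 else None
            records.append(SampleRecord(
                sample_id=f"honey_{n_honey}a", matrix_type=MatrixType.BULK_HONEY,
                subspecies_label=sub, lineage_label=lin, duplicate_group=dup,
                mitotype=lin.value))
            if dup:
                records.append(SampleRecord(
                    sample_id=f"honey_{n_honey}b", matrix_type=MatrixType.BULK_HONEY,
                    subspecies_label=sub, lineage_label=lin, duplicate_group=dup,
                    mitotype=lin.value))
    return records


@pytest.fixture()
def table1_sheet() -> list[SampleRecord]:
    return build_table1_sheet()


def random_count_matrix(rng: np.random.Generator, n_samples: int, n_markers: int,
                        missing_frac: float = 0.2, max_depth: int = 40) -> CountMatrix:
    ref = rng.integers(0, max_depth, size=(n_samples, n_markers)).astype(float)
    alt = rng.integers(0, max_depth, size=(n_samples, n_markers)).astype(float)
    miss = rng.random((n_samples, n_markers)) < missing_frac
    ref[miss] = np.nan
    alt[miss] = np.nan
    import pandas as pd

    sids = [f"s{i}" for i in range(n_samples)]
    mids = [f"m{j}" for j in range(n_markers)]
    return CountMatrix(pd.DataFrame(ref, index=sids, columns=mids),
                       pd.DataFrame(alt, index=sids, columns=mids))
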