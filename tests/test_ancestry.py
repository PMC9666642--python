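import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist

from honeygbs.afstats import AFMatrix, AFProvenance, af_matrix, genotype_af_matrix
from honeygbs.ancestry import (
    AncestryAssignment,
    MitoStatus,
    annotate_mito_status,
    assemble_matrix,
    assign_lineage,
    classical_mds,
    mito_concordance,
)
from honeygbs.panel_io import Lineage, MarkerCategory, MatrixType, SampleRecord
from honeygbs.simulate import (
    SimConfig,
    default_panel,
    make_lineage_profiles,
    simulate_reference_panel,
    simulate_study,
)


def _read_count_af(values: pd.DataFrame) -> AFMatrix:
    return AFMatrix(values, pd.Series(AFProvenance.READ_COUNT, index=values.index))


# ---------------------------------------------------------------------------
# matrix assembly

def test_assemble_combined_cohort_has_672_rows(panel121):
    """61 assay samples + 450 genotype-reference bees + 161 WGS bees stack
    into a 672 x 97 ancestry matrix."""
    rng = np.random.default_rng(0)
    prof = make_lineage_profiles(panel121, seed=1)
    gbs = _read_count_af(pd.DataFrame(
        rng.uniform(0, 100, (61, 121)),
        index=[f"gbs_{i}" for i in range(61)], columns=panel121.marker_ids,
    ))
    geno_ref, _ = simulate_reference_panel(
        prof, {"C": 10 + 34, "M": 406}, seed=2, id_prefix="geno")
    wgs, _ = simulate_reference_panel(
        prof, {"A": 68 + 28, "C": 22 + 10, "M": 24, "O": 9}, seed=3, id_prefix="wgs")
    combined = assemble_matrix([gbs, geno_ref, wgs], panel121)
    assert combined.shape == (61 + 450 + 161, 97)
    assert combined.shape == (672, 97)
    # row order: sources in order, each preserving its own order
    assert combined.sample_ids[:61] == gbs.sample_ids
    assert combined.sample_ids[61:511] == geno_ref.sample_ids


def test_assemble_restricts_to_ancestry_columns(panel121):
    af = _read_count_af(pd.DataFrame(
        np.full((3, 121), 50.0), index=list("abc"), columns=panel121.marker_ids))
    out = assemble_matrix([af], panel121)
    assert out.shape[1] == 97
    assert set(out.marker_ids) == set(panel121.category_ids(MarkerCategory.ANCESTRY))


def test_assemble_imputes_missing_with_column_mean(panel121):
    vals = pd.DataFrame(
        np.full((3, 121), 50.0), index=list("abc"), columns=panel121.marker_ids)
    first_anc = panel121.category_ids(MarkerCategory.ANCESTRY)[0]
    vals.loc["a", first_anc] = 0.0
    vals.loc["b", first_anc] = 100.0
    vals.loc["c", first_anc] = np.nan
    out = assemble_matrix([_read_count_af(vals)], panel121)
    assert out.values.loc["c", first_anc] == pytest.approx(50.0)


def test_assemble_rejects_duplicate_sample_ids(panel121):
    af = _read_count_af(pd.DataFrame(
        np.full((2, 121), 10.0), index=["x", "y"], columns=panel121.marker_ids))
    with pytest.raises(ValueError, match="duplicate sample ids"):
        assemble_matrix([af, af], panel121)


def test_assemble_drops_fully_missing_column_with_warning(panel121, caplog):
    vals = pd.DataFrame(
        np.full((3, 121), 50.0), index=list("abc"), columns=panel121.marker_ids)
    dead = panel121.category_ids(MarkerCategory.ANCESTRY)[5]
    vals[dead] = np.nan
    with caplog.at_level("WARNING"):
        out = assemble_matrix([_read_count_af(vals)], panel121)
    assert dead not in out.marker_ids
    assert out.shape[1] == 96


# ---------------------------------------------------------------------------
# classical MDS

def test_collinear_points_recover_unit_spacing():
    # three samples at 1-D positions 0, 1, 2 embedded in marker space
    vals = pd.DataFrame(
        {"m1": [0.0, 1.0, 2.0], "m2": [0.0, 1.0, 2.0]}, index=list("abc")
    ) * (1 / np.sqrt(2))
    res = classical_mds(_read_count_af(vals), k=1)
    np.testing.assert_allclose(
        res.coordinates["dim1"].values, [-1.0, 0.0, 1.0], atol=1e-10
    )


def test_identical_rows_land_on_identical_coordinates():
    vals = pd.DataFrame(
        {"m1": [10.0, 10.0, 50.0, 90.0], "m2": [5.0, 5.0, 40.0, 80.0]},
        index=list("abcd"),
    )
    res = classical_mds(_read_count_af(vals), k=2)
    np.testing.assert_allclose(
        res.coordinates.loc["a"].values, res.coordinates.loc["b"].values, atol=1e-9
    )


def test_mds_reproduces_pairwise_distances_of_plane_point_sets():
    rng = np.random.default_rng(11)
    for _ in range(20):
        n = int(rng.integers(4, 30))
        pts = rng.uniform(0, 100, (n, 2))
        vals = pd.DataFrame(pts, index=[f"s{i}" for i in range(n)],
                            columns=["m1", "m2"])
        res = classical_mds(_read_count_af(vals), k=2)
        orig = pdist(pts)
        emb = pdist(res.coordinates.values)
        assert np.max(np.abs(emb - orig) / np.maximum(orig, 1e-12)) < 1e-8


def test_eigenvalues_sorted_and_coordinates_centered():
    rng = np.random.default_rng(5)
    vals = pd.DataFrame(rng.uniform(0, 100, (12, 6)),
                        index=[f"s{i}" for i in range(12)],
                        columns=[f"m{j}" for j in range(6)])
    res = classical_mds(_read_count_af(vals), k=3)
    assert (np.diff(res.eigenvalues) <= 1e-8).all()
    np.testing.assert_allclose(res.coordinates.mean(axis=0), 0.0, atol=1e-8)
    # Torgerson identity: sum of positive eigenvalues = trace of B
    assert res.variance_explained.sum() <= 1.0 + 1e-12


def test_mds_rejects_missing_cells_and_excess_k():
    vals = pd.DataFrame({"m1": [0.0, np.nan, 3.0]}, index=list("abc"))
    with pytest.raises(ValueError, match="missing"):
        classical_mds(_read_count_af(vals), k=1)
    collinear = pd.DataFrame({"m1": [0.0, 1.0, 2.0]}, index=list("abc"))
    with pytest.raises(ValueError, match="positive eigenvalues"):
        classical_mds(_read_count_af(collinear), k=2)


# ---------------------------------------------------------------------------
# lineage assignment

def _toy_mds_and_sheet():
    coords = pd.DataFrame(
        {
            "dim1": [0.0, 0.0, 10.0, 10.0, 0.1, 5.0],
            "dim2": [0.0, 0.2, 0.0, 0.2, 0.0, 0.1],
        },
        index=["refC1", "refC2", "refM1", "refM2", "queryC", "querymid"],
    )
    from honeygbs.ancestry import MDSResult

    res = MDSResult(coords, np.array([1.0, 0.5]), np.array([0.6, 0.3]))
    sheet = [
        SampleRecord("refC1", MatrixType.GENOTYPE_REFERENCE,
                     lineage_label=Lineage.C, n_individuals=1),
        SampleRecord("refC2", MatrixType.GENOTYPE_REFERENCE,
                     lineage_label=Lineage.C, n_individuals=1),
        SampleRecord("refM1", MatrixType.GENOTYPE_REFERENCE,
                     lineage_label=Lineage.M, n_individuals=1),
        SampleRecord("refM2", MatrixType.GENOTYPE_REFERENCE,
                     lineage_label=Lineage.M, n_individuals=1),
        SampleRecord("queryC", MatrixType.HONEYCOMB_HONEY, mitotype="C1"),
        SampleRecord("querymid", MatrixType.HONEYCOMB_HONEY, mitotype="C1,A"),
    ]
    return res, sheet


def test_nearest_centroid_assignment_and_admixture_flag():
    res, sheet = _toy_mds_and_sheet()
    assignments = {a.sample_id: a for a in assign_lineage(res, sheet, tau=0.8)}
    assert set(assignments) == {"queryC", "querymid"}
    q = assignments["queryC"]
    assert q.assigned_lineage == "C" and not q.admixture_flag
    mid = assignments["querymid"]
    assert mid.distance_ratio > 0.8 and mid.admixture_flag


def test_query_exactly_at_centroid_has_zero_ratio():
    res, sheet = _toy_mds_and_sheet()
    res.coordinates.loc["queryC"] = [0.0, 0.1]  # the C centroid
    q = {a.sample_id: a for a in assign_lineage(res, sheet)}["queryC"]
    assert q.distance_to_assigned == pytest.approx(0.0)
    assert q.distance_ratio == pytest.approx(0.0)
    assert not q.admixture_flag


def test_assignment_requires_two_reference_lineages():
    res, sheet = _toy_mds_and_sheet()
    only_c = [r for r in sheet if r.lineage_label in (Lineage.C, None)]
    with pytest.raises(ValueError, match="at least 2 lineages"):
        assign_lineage(res, only_c)


# ---------------------------------------------------------------------------
# mitotype cross-check

def _assignment(lineage):
    return AncestryAssignment(
        sample_id="s", assigned_lineage=lineage, distance_to_assigned=0.1,
        distance_ratio=0.2, admixture_flag=False,
    )


@pytest.mark.parametrize(
    "assigned, mitotype, expected",
    [
        ("C", "C1", MitoStatus.CONCORDANT),
        ("M", "C1", MitoStatus.DISCORDANT),   # introgression signal
        ("C", "C1,A", MitoStatus.MIXED),
        ("C", None, MitoStatus.UNAVAILABLE),
    ],
)
def test_mito_concordance_states(assigned, mitotype, expected):
    rec = SampleRecord("s", MatrixType.HONEYCOMB_HONEY, mitotype=mitotype)
    assert mito_concordance(_assignment(assigned), rec) == expected


def test_unmapped_mitotype_rejected():
    rec = SampleRecord("s", MatrixType.HONEYCOMB_HONEY, mitotype="Q9")
    with pytest.raises(ValueError, match="mitotype 'Q9'"):
        mito_concordance(_assignment("C"), rec)


def test_annotate_mito_status_end_to_end():
    res, sheet = _toy_mds_and_sheet()
    assignments = assign_lineage(res, sheet)
    annotate_mito_status(assignments, sheet)
    by_id = {a.sample_id: a for a in assignments}
    assert by_id["queryC"].mito_status == MitoStatus.CONCORDANT
    assert by_id["querymid"].mito_status == MitoStatus.MIXED


# ---------------------------------------------------------------------------
# simulation round trip: honey samples recover their maternal lineage

def test_simulated_colonies_assigned_to_maternal_lineage():
    panel = default_panel()
    study = simulate_study(
        panel, SimConfig(seed=99), n_colonies_per_lineage=5, n_duplicate_pairs=0,
        n_reference_per_lineage=15, F=0.2, seed=99,
    )
    af = af_matrix(study.counts)
    combined = assemble_matrix([af, study.reference_af], panel)
    mds = classical_mds(combined, k=2)
    sheet = study.sheet + study.reference_sheet
    assignments = assign_lineage(mds, sheet)
    truth = {r.sample_id: r.lineage_label.value for r in study.sheet}
    correct = sum(a.assigned_lineage == truth[a.sample_id] for a in assignments)
    assert correct == len(assignments) == 20
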