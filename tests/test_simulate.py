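import numpy as np
import pandas as pd
import pytest

from honeygbs.afstats import af_matrix
from honeygbs.panel_io import AlleleDepth, CountMatrix, MatrixType, SampleRecord
from honeygbs.concordance import duplicate_concordance
from honeygbs.simulate import (
    SimConfig,
    default_panel,
    found_colony,
    make_lineage_profiles,
    simulate_counts,
    simulate_duplicate,
    simulate_reference_panel,
    simulate_study,
    write_sample_vcf,
)


@pytest.fixture(scope="module")
def panel():
    return default_panel()


@pytest.fixture(scope="module")
def profiles(panel):
    return make_lineage_profiles(panel, seed=5)


# ---------------------------------------------------------------------------
# lineage profiles

def test_profiles_deterministic_for_fixed_seed(panel):
    a = make_lineage_profiles(panel, seed=9)
    b = make_lineage_profiles(panel, seed=9)
    pd.testing.assert_frame_equal(a.lineage_freq, b.lineage_freq)
    assert not a.lineage_freq.equals(make_lineage_profiles(panel, seed=10).lineage_freq)


def test_tiny_divergence_keeps_lineages_near_ancestor(panel):
    prof = make_lineage_profiles(panel, F=0.001, seed=1)
    # Beta variance p(1-p)F -> sd < 0.016; 0.05 is > 3 sigma
    close = np.abs(prof.lineage_freq.values - prof.ancestral_freq) < 0.05
    assert close.mean() >= 0.99


def test_balding_nichols_mean_matches_ancestral():
    from honeygbs.panel_io import MarkerCategory, Panel, PanelMarker

    markers = [
        PanelMarker(f"m{i}", "chr1", i + 1, "A", "G", MarkerCategory.ANCESTRY)
        for i in range(10_000)
    ]
    big = Panel(markers, expected_counts={MarkerCategory.ANCESTRY: len(markers)})
    prof = make_lineage_profiles(big, lineages=("C",), F=0.2, seed=3)
    diff = prof.lineage_freq.loc["C"].values - prof.ancestral_freq
    # E[lineage freq] = p marker-wise; mean difference ~ N(0, ~0.13/sqrt(1e4))
    assert abs(diff.mean()) < 0.005


def test_invalid_divergence_rejected(panel):
    with pytest.raises(ValueError, match="divergence"):
        make_lineage_profiles(panel, F=0.0)
    with pytest.raises(ValueError, match="divergence"):
        make_lineage_profiles(panel, F=1.0)


# ---------------------------------------------------------------------------
# colony founding

def test_colony_truth_is_realized_worker_mean(profiles):
    colony = found_colony(profiles, "A", seed=2, n_workers=37)
    np.testing.assert_allclose(
        colony.true_colony_af, colony.worker_dosages.mean(axis=0) / 2.0
    )
    assert colony.mitotype == "A"
    assert set(np.unique(colony.worker_dosages)) <= {0, 1, 2}


def test_single_worker_colony_af_in_half_steps(profiles):
    colony = found_colony(profiles, "C", seed=4, n_workers=1)
    assert set(np.unique(colony.true_colony_af)) <= {0.0, 0.5, 1.0}
    assert colony.mitotype == "C1"


def test_unknown_lineage_rejected(profiles):
    with pytest.raises(ValueError, match="unknown lineage"):
        found_colony(profiles, "Z", seed=0)


def test_colony_af_concentrates_on_lineage_frequency(panel):
    """Averaged over many colonies, the realized colony AF per marker
    approaches the maternal lineage frequency (alpha = 0)."""
    prof = make_lineage_profiles(panel, F=0.2, seed=8)
    target = prof.freq("M")
    mean_af = np.zeros(len(panel))
    n_col = 300
    for i in range(n_col):
        mean_af += found_colony(prof, "M", seed=1000 + i, n_drones=10,
                                n_workers=40).true_colony_af
    mean_af /= n_col
    # colony AF has variance ~ p(1-p) * O(1/4) across colonies; with 300
    # colonies the per-marker Monte-Carlo s.e. is < 0.02
    assert np.max(np.abs(mean_af - target)) < 0.08
    assert abs((mean_af - target).mean()) < 0.01


# ---------------------------------------------------------------------------
# sequencing simulation

def _cfg(**kw):
    defaults = dict(
        depth_tier_mean={MatrixType.WORKER_POOL: 10_000.0},
        depth_dispersion=None,
        base_error_rate=0.0,
        dropout_logistic_params=(-50.0, 0.0),
        fragile_marker_ids=frozenset(),
    )
    defaults.update(kw)
    return SimConfig(**defaults)


def test_fixed_alternative_yields_pure_alt_reads(profiles):
    colony = found_colony(profiles, "C", seed=6)
    colony.true_colony_af[:] = 1.0
    row = simulate_counts(colony, MatrixType.WORKER_POOL, _cfg(), seed=1)
    assert len(row) == 121
    assert all(ad.ref_reads == 0 and ad.alt_reads == ad.dp for ad in row.values())


def test_read_conservation_and_determinism(profiles):
    colony = found_colony(profiles, "C", seed=6)
    cfg = SimConfig()
    a = simulate_counts(colony, MatrixType.HONEYCOMB_HONEY, cfg, seed=3)
    b = simulate_counts(colony, MatrixType.HONEYCOMB_HONEY, cfg, seed=3)
    assert a == b
    assert all(ad.ref_reads + ad.alt_reads == ad.dp for ad in a.values())


def test_binomial_noise_matches_depth(profiles):
    """At DP 10,000 and f = 0.5 the estimate lies in [48, 52]% for >= 95%
    of markers (binomial 95% interval is +-0.98 points)."""
    colony = found_colony(profiles, "C", seed=6)
    colony.true_colony_af[:] = 0.5
    row = simulate_counts(colony, MatrixType.WORKER_POOL, _cfg(), seed=9)
    afs = np.array([100.0 * ad.alt_reads / ad.dp for ad in row.values()])
    assert np.mean((afs >= 48.0) & (afs <= 52.0)) >= 0.95


def test_unconfigured_tier_rejected(profiles):
    colony = found_colony(profiles, "C", seed=6)
    with pytest.raises(ValueError, match="depth tier"):
        simulate_counts(colony, MatrixType.BULK_HONEY, _cfg(), seed=0)


# ---------------------------------------------------------------------------
# duplicates

def test_duplicates_share_truth_but_differ(panel, profiles):
    colony = found_colony(profiles, "C", seed=12)
    a, b = simulate_duplicate(
        colony, MatrixType.WORKER_POOL, SimConfig(), 1, 2, panel.marker_ids
    )
    assert a != b
    with pytest.raises(ValueError, match="seeds must differ"):
        simulate_duplicate(colony, MatrixType.WORKER_POOL, SimConfig(), 5, 5)


def test_honey_duplicates_less_concordant_than_pool_duplicates(panel, profiles):
    """Duplicate ICC at the shallow bulk-honey tier sits below the deep
    worker-pool tier for the same colonies (paired comparison)."""
    cfg = SimConfig()
    iccs = {MatrixType.WORKER_POOL: [], MatrixType.BULK_HONEY: []}
    for i in range(15):
        colony = found_colony(profiles, "C", seed=2000 + i)
        for mt in iccs:
            a, b = simulate_duplicate(colony, mt, cfg, 10_000 + i, 20_000 + i,
                                      panel.marker_ids)
            cm = CountMatrix.from_rows({"x": a, "y": b}, panel.marker_ids)
            af = af_matrix(cm)
            n_ind = 35 if mt is MatrixType.WORKER_POOL else None
            sheet = [
                SampleRecord("x", mt, duplicate_group="g", n_individuals=n_ind),
                SampleRecord("y", mt, duplicate_group="g", n_individuals=n_ind),
            ]
            iccs[mt].append(duplicate_concordance(af, sheet)[0].icc)
    assert np.median(iccs[MatrixType.BULK_HONEY]) < np.median(iccs[MatrixType.WORKER_POOL])


# ---------------------------------------------------------------------------
# reference panel

def test_reference_genotypes_encoded_0_50_100(profiles):
    af, records = simulate_reference_panel(profiles, {"A": 5, "C": 3}, seed=1)
    assert af.shape == (8, 121)
    assert set(np.unique(af.values.values)) <= {0.0, 50.0, 100.0}
    assert len(records) == 8
    assert all(r.n_individuals == 1 and r.ploidy == 2 for r in records)


def test_reference_sizes_reproduce_wgs_cohort(profiles):
    # 68 + 22 + 9 + 10 + 24 + 28 individuals across subspecies groups = 161
    n_per = {"A": 68 + 28, "C": 22 + 10, "M": 24, "O": 9}
    af, _ = simulate_reference_panel(profiles, n_per, seed=2)
    assert af.shape[0] == 161


def test_degenerate_frequency_fixes_all_individuals(panel):
    prof = make_lineage_profiles(panel, lineages=("C",), F=0.2, seed=1)
    prof.lineage_freq.loc["C"] = 0.0
    af, _ = simulate_reference_panel(prof, {"C": 20}, seed=3)
    assert (af.values.values == 0.0).all()


def test_reference_mean_matches_lineage_frequency(panel):
    prof = make_lineage_profiles(panel, lineages=("C",), F=0.2, seed=4)
    af, _ = simulate_reference_panel(prof, {"C": 2000}, seed=5)
    est = af.values.values.mean(axis=0) / 100.0
    # binomial s.e. <= 0.5/sqrt(2*2000) ~ 0.008
    assert np.max(np.abs(est - prof.freq("C"))) < 0.05


# ---------------------------------------------------------------------------
# parameter recovery and whole-study simulation

def test_estimated_af_regresses_on_truth_with_unit_slope(panel):
    """Regressing estimated AF on the true colony AF at the worker-pool
    depth tier gives a slope within 2% of 1."""
    prof = make_lineage_profiles(panel, F=0.2, seed=21)
    cfg = SimConfig(base_error_rate=0.0)
    xs, ys = [], []
    for i in range(50):
        colony = found_colony(prof, "C", seed=3000 + i)
        row = simulate_counts(colony, MatrixType.WORKER_POOL, cfg, seed=4000 + i,
                              marker_ids=panel.marker_ids)
        for j, mid in enumerate(panel.marker_ids):
            if mid in row:
                xs.append(colony.true_colony_af[j] * 100.0)
                ys.append(100.0 * row[mid].alt_reads / row[mid].dp)
    slope = np.polyfit(xs, ys, 1)[0]
    assert 0.98 <= slope <= 1.02


def test_simulate_study_layout_and_determinism(panel):
    kw = dict(n_colonies_per_lineage=2, n_duplicate_pairs=2,
              n_reference_per_lineage=3, seed=17)
    study = simulate_study(panel, **kw)
    # 4 lineages x 2 colonies, first 2 colonies sequenced twice
    assert study.counts.shape == (10, 121)
    assert len(study.sheet) == 10
    assert study.reference_af.shape == (12, 121)
    groups = [r.duplicate_group for r in study.sheet if r.duplicate_group]
    assert len(groups) == 4 and len(set(groups)) == 2
    again = simulate_study(panel, **kw)
    assert study.counts == again.counts
    pd.testing.assert_frame_equal(study.truth, again.truth)


def test_written_vcf_read_back_identically(tmp_path, panel, profiles):
    """VCF emission and panel_io parsing are exact inverses."""
    from honeygbs.panel_io import read_allele_depths

    colony = found_colony(profiles, "M", seed=31)
    row = simulate_counts(colony, MatrixType.HONEYCOMB_HONEY, SimConfig(), seed=32,
                          marker_ids=panel.marker_ids)
    path = tmp_path / "s.vcf"
    write_sample_vcf(row, panel, "s", path)
    assert read_allele_depths(path, panel) == row
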