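"""Synthetic honey bee colony and pooled-sequencing data generator.

Real honey eDNA genotyping data comes from sequencing runs; this module
stands in for them with a generative model whose truth is known, so the
estimation pipeline can be tested end to end:

* **Lineage allele-frequency profiles.**  Each evolutionary lineage (A, C,
  M, O) gets per-marker alternative-allele frequencies drawn from the
  Balding-Nichols model: an ancestral frequency p per marker, and lineage
  frequencies ~ Beta(p(1-F)/F, (1-p)(1-F)/F), where F controls divergence.
* **Haplodiploid colony founding.**  A colony is one diploid queen (two
  allele draws from her lineage) mated to ``n_drones`` haploid drones; with
  probability ``alpha`` a drone comes from a second (paternal) lineage,
  modeling admixture.  Each worker inherits one random queen allele and the
  allele of one uniformly chosen drone father.  The colony's true allele
  frequency is the realized mean worker dosage / 2.
* **Targeted pooled sequencing.**  Per marker, total depth DP is negative
  binomial with a matrix-dependent mean (single larvae deepest, bulk honey
  shallowest, mirroring DNA quality), markers drop out with a probability
  logistic in log-depth (inflated for a configurable set of fragile markers
  and for the degraded honey matrices), and the ALT read count is binomial
  with success probability f(1-eps) + (1-f)eps where f is the true colony
  AF and eps a symmetric base-calling error rate.

All randomness flows from explicit integer seeds; identical inputs and seed
give bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .afstats import AFMatrix, genotype_af_matrix
from .panel_io import (
    AlleleDepth,
    CountMatrix,
    HONEY_MATRIX_TYPES,
    Lineage,
    MatrixType,
    Panel,
    SampleRecord,
)

#: Maternal lineage -> mitochondrial haplotype label.  Lineage C colonies
#: carry the C1 mitotype; other lineages are labelled by their letter.
MITOTYPE_BY_LINEAGE: dict[str, str] = {"A": "A", "C": "C1", "M": "M", "O": "O", "Y": "Y"}

#: Default per-marker depth means by matrix type.  Magnitudes follow the
#: mean sequencing depths observed per matrix in the assay (in reads):
#: single larvae ~26,450x, worker DNA pools ~17,480x, honeycomb honey
#: ~5,560x, undifferentiated bulk honey ~1,140x.
DEFAULT_DEPTH_TIERS: dict[MatrixType, float] = {
    MatrixType.LARVA: 26450.0,
    MatrixType.WORKER_POOL: 17480.0,
    MatrixType.HONEYCOMB_HONEY: 5560.0,
    MatrixType.BULK_HONEY: 1140.0,
}

#: Default fragile markers: a small set that degrades preferentially in
#: honey matrices, emulating the handful of assay markers with < 90% call
#: rate there.  Ids refer to the default synthetic panel layout.
DEFAULT_FRAGILE_MARKERS = frozenset(
    {"bee_snp_42", "bee_snp_78", "bee_snp_79", "bee_snp_93", "bee_calm_3", "Var_res_15"}
)


@dataclass
class SimConfig:
    """Tunable parameters of the sequencing simulator."""

    depth_tier_mean: dict[MatrixType, float] = field(
        default_factory=lambda: dict(DEFAULT_DEPTH_TIERS)
    )
    #: negative-binomial size parameter; None makes depth deterministic
    depth_dispersion: Optional[float] = 2.0
    base_error_rate: float = 0.005
    fragile_marker_ids: frozenset[str] = DEFAULT_FRAGILE_MARKERS
    #: (intercept, slope) of the dropout logit vs ln(DP + 1)
    dropout_logistic_params: tuple[float, float] = (2.0, -1.0)
    #: additive logit offsets for fragile markers and honey matrices
    fragile_logit_offset: float = 4.0
    honey_logit_offset: float = 1.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.base_error_rate <= 1):
            raise ValueError("base_error_rate must lie in [0, 1]")
        for mt, mean in self.depth_tier_mean.items():
            if mean <= 0:
                raise ValueError(f"depth mean for {mt} must be positive")


@dataclass
class LineageProfiles:
    """Per-lineage alternative-allele frequency profiles over the panel."""

    lineages: list[str]
    marker_ids: list[str]
    ancestral_freq: np.ndarray          # (n_markers,)
    lineage_freq: pd.DataFrame          # lineages x markers, proportions
    divergence: dict[str, float]

    def freq(self, lineage: str) -> np.ndarray:
        if lineage not in self.lineage_freq.index:
            raise ValueError(f"unknown lineage {lineage!r}; have {self.lineages}")
        return self.lineage_freq.loc[lineage].values


@dataclass
class ColonyModel:
    """Simulator ground truth for one colony."""

    colony_id: str
    maternal_lineage: str
    paternal_lineage: str
    admixture_alpha: float
    queen_genotype: np.ndarray      # (n_markers,) dosage in {0,1,2}
    drone_haplotypes: np.ndarray    # (n_drones, n_markers) alleles in {0,1}
    worker_dosages: np.ndarray      # (n_workers, n_markers) dosage in {0,1,2}
    true_colony_af: np.ndarray      # (n_markers,) proportion in [0,1]
    mitotype: str

    @property
    def n_workers(self) -> int:
        return self.worker_dosages.shape[0]


def make_lineage_profiles(
    panel: Panel,
    lineages: Sequence[str] = ("A", "C", "M", "O"),
    F: float | Mapping[str, float] = 0.2,
    seed: int = 0,
) -> LineageProfiles:
    """Draw Balding-Nichols lineage frequencies for every panel marker.

    Ancestral frequencies are Uniform(0.05, 0.95); each lineage's frequency
    at a marker is Beta(p(1-F)/F, (1-p)(1-F)/F), so E = p and Var = p(1-p)F.
    """
    if len(panel) == 0:
        raise ValueError("empty panel")
    lineages = list(lineages)
    divergence = (
        {lin: float(F) for lin in lineages} if np.isscalar(F) else dict(F)
    )
    for lin in lineages:
        f = divergence.get(lin)
        if f is None or not (0 < f < 1):
            raise ValueError(f"divergence F for lineage {lin} must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    m = len(panel)
    p = rng.uniform(0.05, 0.95, size=m)
    freqs = {}
    for lin in lineages:
        f = divergence[lin]
        freqs[lin] = rng.beta(p * (1 - f) / f, (1 - p) * (1 - f) / f)
    return LineageProfiles(
        lineages=lineages,
        marker_ids=panel.marker_ids,
        ancestral_freq=p,
        lineage_freq=pd.DataFrame(freqs, index=panel.marker_ids).T,
        divergence=divergence,
    )


def found_colony(
    profiles: LineageProfiles,
    maternal: str,
    paternal: Optional[str] = None,
    alpha: float = 0.0,
    n_drones: int = 15,
    n_workers: int = 500,
    seed: int = 0,
    colony_id: str = "colony",
) -> ColonyModel:
    """Found one haplodiploid colony and realize its worker pool.

    The queen is two Bernoulli draws per marker from the maternal lineage
    frequency.  Each drone's haplotype comes from the paternal lineage with
    probability ``alpha`` (else maternal).  Each worker inherits one
    uniformly chosen queen allele plus the allele of one uniformly chosen
    drone father.  ``true_colony_af`` is recomputed from the realized
    workers, not taken from the expectation.
    """
    if n_drones < 1 or n_workers < 1:
        raise ValueError("n_drones and n_workers must be >= 1")
    if not (0 <= alpha <= 1):
        raise ValueError("alpha must lie in [0, 1]")
    paternal = paternal if paternal is not None else maternal
    p_mat = profiles.freq(maternal)
    p_pat = profiles.freq(paternal)
    m = p_mat.size
    rng = np.random.default_rng(seed)

    queen_alleles = (rng.random((2, m)) < p_mat).astype(np.int8)
    from_pat = rng.random(n_drones) < alpha
    drone_p = np.where(from_pat[:, None], p_pat[None, :], p_mat[None, :])
    drones = (rng.random((n_drones, m)) < drone_p).astype(np.int8)

    queen_pick = rng.integers(0, 2, size=(n_workers, m))
    maternal_allele = queen_alleles[queen_pick, np.arange(m)[None, :]]
    fathers = rng.integers(0, n_drones, size=n_workers)
    paternal_allele = drones[fathers]
    workers = (maternal_allele + paternal_allele).astype(np.int8)

    return ColonyModel(
        colony_id=colony_id,
        maternal_lineage=maternal,
        paternal_lineage=paternal,
        admixture_alpha=float(alpha),
        queen_genotype=queen_alleles.sum(axis=0),
        drone_haplotypes=drones,
        worker_dosages=workers,
        true_colony_af=workers.mean(axis=0) / 2.0,
        mitotype=MITOTYPE_BY_LINEAGE[maternal],
    )


def simulate_counts(
    colony: ColonyModel,
    matrix_type: MatrixType,
    cfg: SimConfig,
    seed: int = 0,
    marker_ids: Optional[Sequence[str]] = None,
) -> dict[str, AlleleDepth]:
    """Simulate one sample's per-marker read counts from a colony's true AF.

    Returns a {marker_id: AlleleDepth} row; dropped-out markers are absent.
    """
    mean = cfg.depth_tier_mean.get(matrix_type)
    if mean is None:
        raise ValueError(f"no depth tier configured for {matrix_type}")
    if marker_ids is None:
        marker_ids = [f"m{i}" for i in range(colony.true_colony_af.size)]
    marker_ids = list(marker_ids)
    f = np.asarray(colony.true_colony_af, dtype=float)
    if len(marker_ids) != f.size:
        raise ValueError("marker_ids length does not match the colony's markers")
    rng = np.random.default_rng(seed)
    m = f.size
    if cfg.depth_dispersion is None:
        dp = np.full(m, int(round(mean)), dtype=np.int64)
    else:
        size = cfg.depth_dispersion
        dp = rng.negative_binomial(size, size / (size + mean), size=m)
    intercept, slope = cfg.dropout_logistic_params
    logit = intercept + slope * np.log(dp + 1.0)
    fragile = np.array([mid in cfg.fragile_marker_ids for mid in marker_ids])
    logit = logit + cfg.fragile_logit_offset * fragile
    if matrix_type in HONEY_MATRIX_TYPES:
        logit = logit + cfg.honey_logit_offset
    dropped = rng.random(m) < expit(logit)
    eps = cfg.base_error_rate
    q = f * (1 - eps) + (1 - f) * eps
    alt = rng.binomial(dp, q)
    row = {}
    for j, mid in enumerate(marker_ids):
        if dropped[j] or dp[j] == 0:
            continue
        row[mid] = AlleleDepth(int(dp[j] - alt[j]), int(alt[j]))
    return row


def simulate_duplicate(
    colony: ColonyModel,
    matrix_type: MatrixType,
    cfg: SimConfig,
    seed_a: int,
    seed_b: int,
    marker_ids: Optional[Sequence[str]] = None,
) -> tuple[dict[str, AlleleDepth], dict[str, AlleleDepth]]:
    """Two independently sequenced aliquots of the same colony sample."""
    if seed_a == seed_b:
        raise ValueError("aliquot seeds must differ")
    return (
        simulate_counts(colony, matrix_type, cfg, seed_a, marker_ids),
        simulate_counts(colony, matrix_type, cfg, seed_b, marker_ids),
    )


def simulate_reference_panel(
    profiles: LineageProfiles,
    n_per_lineage: Mapping[str, int],
    seed: int = 0,
    matrix_type: MatrixType = MatrixType.GENOTYPE_REFERENCE,
    id_prefix: str = "ref",
) -> tuple[AFMatrix, list[SampleRecord]]:
    """Simulate individual reference bees with genotypes encoded 0/50/100.

    Each individual is two Bernoulli draws per marker from its lineage
    frequency; the resulting diploid dosage maps to an alternative-allele
    frequency of 0, 50 or 100 percent.
    """
    rng = np.random.default_rng(seed)
    rows, records = [], []
    index = []
    for lineage in profiles.lineages:
        n = int(n_per_lineage.get(lineage, 0))
        if n < 0:
            raise ValueError("n_per_lineage must be non-negative")
        if n == 0:
            continue
        p = profiles.freq(lineage)
        dosage = (rng.random((n, p.size)) < p).astype(int) + (
            rng.random((n, p.size)) < p
        ).astype(int)
        for i in range(n):
            sid = f"{id_prefix}_{lineage}_{i + 1}"
            index.append(sid)
            rows.append(dosage[i] * 50.0)
            records.append(
                SampleRecord(
                    sample_id=sid,
                    matrix_type=matrix_type,
                    lineage_label=Lineage(lineage),
                    n_individuals=1,
                    ploidy=2,
                )
            )
    values = pd.DataFrame(rows, index=index, columns=profiles.marker_ids)
    return genotype_af_matrix(values), records


# ---------------------------------------------------------------------------
# VCF emission

_VCF_HEADER = """\
##fileformat=VCFv4.2
##source=honeygbs-simulate
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths (ref,alt)">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
"""


def write_sample_vcf(
    row: Mapping[str, AlleleDepth],
    panel: Panel,
    sample_id: str,
    path: str | Path,
) -> None:
    """Write one sample's simulated allele depths as a single-sample VCF."""
    lines = [_VCF_HEADER]
    for chrom in dict.fromkeys(m.chrom for m in panel):
        lines.append(f"##contig=<ID={chrom}>\n")
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample_id + "\n"
    )
    for m in panel:
        ad = row.get(m.marker_id)
        if ad is None:
            continue
        lines.append(
            f"{m.chrom}\t{m.pos}\t{m.marker_id}\t{m.ref_allele}\t{m.alt_allele}"
            f"\t.\tPASS\t.\tGT:AD:DP\t./.:{ad.ref_reads},{ad.alt_reads}:{ad.dp}\n"
        )
    Path(path).write_text("".join(lines))


# ---------------------------------------------------------------------------
# Default panel and whole-study simulation

def default_panel(seed: int = 7) -> Panel:
    """A synthetic 121-marker panel with the assay's category composition.

    97 ancestry-informative markers (bee_snp_1..97), 3 calmness (bee_calm),
    3 gentleness (bee_gent) and 18 varroa-resistance (Var_res) markers, laid
    out on 16 chromosomes with arbitrary but reproducible coordinates.
    """
    from .panel_io import MarkerCategory, PanelMarker

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGT"))
    specs = (
        [("bee_snp", i + 1, MarkerCategory.ANCESTRY) for i in range(97)]
        + [("bee_calm", i + 1, MarkerCategory.CALMNESS) for i in range(3)]
        + [("bee_gent", i + 1, MarkerCategory.GENTLENESS) for i in range(3)]
        + [("Var_res", i + 1, MarkerCategory.VARROA_RESISTANCE) for i in range(18)]
    )
    markers = []
    used_pos: set[tuple[str, int]] = set()
    for prefix, num, cat in specs:
        chrom = f"NC_{1 + rng.integers(0, 16):02d}"
        pos = int(rng.integers(1, 30_000_000))
        while (chrom, pos) in used_pos:
            pos = int(rng.integers(1, 30_000_000))
        used_pos.add((chrom, pos))
        ref, alt = rng.choice(4, size=2, replace=False)
        markers.append(
            PanelMarker(
                marker_id=f"{prefix}_{num}",
                chrom=chrom,
                pos=pos,
                ref_allele=str(bases[ref]),
                alt_allele=str(bases[alt]),
                category=cat,
            )
        )
    return Panel(markers)


@dataclass
class SimulatedStudy:
    """Everything one simulated study run produced."""

    panel: Panel
    profiles: LineageProfiles
    colonies: list[ColonyModel]
    counts: CountMatrix
    sheet: list[SampleRecord]
    reference_af: AFMatrix
    reference_sheet: list[SampleRecord]
    truth: pd.DataFrame  # colony_id x marker true AF (proportion)


def simulate_study(
    panel: Panel,
    cfg: Optional[SimConfig] = None,
    n_colonies_per_lineage: int = 8,
    n_duplicate_pairs: int = 4,
    n_reference_per_lineage: int = 30,
    lineages: Sequence[str] = ("A", "C", "M", "O"),
    F: float = 0.2,
    admixed_fraction: float = 0.0,
    alpha: float = 0.5,
    n_drones: int = 15,
    n_workers: int = 500,
    matrix_type: MatrixType = MatrixType.HONEYCOMB_HONEY,
    seed: int = 0,
) -> SimulatedStudy:
    """Simulate a full study: colonies, sequenced samples and reference bees.

    Per lineage, ``n_colonies_per_lineage`` colonies are founded and
    sequenced once as the requested matrix type; the first
    ``n_duplicate_pairs`` colonies overall are additionally sequenced a
    second time as duplicate aliquots.  When ``admixed_fraction`` > 0, that
    fraction of each lineage's colonies (rounded down) is admixed with a
    randomly chosen second lineage at drone fraction ``alpha``.
    """
    cfg = cfg or SimConfig(seed=seed)
    ss = np.random.SeedSequence(seed)
    seeds = iter(ss.generate_state(4 + 10 * n_colonies_per_lineage * len(lineages)) % (2**31))
    profiles = make_lineage_profiles(panel, lineages, F, seed=int(next(seeds)))
    rng = np.random.default_rng(int(next(seeds)))

    colonies: list[ColonyModel] = []
    rows: dict[str, dict[str, AlleleDepth]] = {}
    sheet: list[SampleRecord] = []
    n_admixed = int(admixed_fraction * n_colonies_per_lineage)
    pair_counter = 0
    for lineage in lineages:
        for i in range(n_colonies_per_lineage):
            admixed = i < n_admixed
            paternal = lineage
            a = 0.0
            if admixed:
                others = [l for l in lineages if l != lineage]
                paternal = others[rng.integers(0, len(others))]
                a = alpha
            cid = f"colony_{lineage}_{i + 1}"
            colony = found_colony(
                profiles, lineage, paternal, a, n_drones, n_workers,
                seed=int(next(seeds)), colony_id=cid,
            )
            colonies.append(colony)
            duplicate = pair_counter < n_duplicate_pairs
            n_aliquots = 2 if duplicate else 1
            group = f"dup_{cid}" if duplicate else None
            if duplicate:
                pair_counter += 1
            for k in range(n_aliquots):
                sid = f"{cid}_s{k + 1}"
                rows[sid] = simulate_counts(
                    colony, matrix_type, cfg, seed=int(next(seeds)),
                    marker_ids=panel.marker_ids,
                )
                sheet.append(
                    SampleRecord(
                        sample_id=sid,
                        matrix_type=matrix_type,
                        lineage_label=Lineage(lineage),
                        duplicate_group=group,
                        n_individuals=(
                            None if matrix_type in HONEY_MATRIX_TYPES else n_workers
                        ),
                        ploidy=2,
                        mitotype=colony.mitotype,
                    )
                )
    counts = CountMatrix.from_rows(rows, panel.marker_ids)
    ref_af, ref_sheet = simulate_reference_panel(
        profiles,
        {lin: n_reference_per_lineage for lin in lineages},
        seed=int(next(seeds)),
    )
    truth = pd.DataFrame(
        [c.true_colony_af for c in colonies],
        index=[c.colony_id for c in colonies],
        columns=panel.marker_ids,
    )
    return SimulatedStudy(
        panel=panel,
        profiles=profiles,
        colonies=colonies,
        counts=counts,
        sheet=sheet,
        reference_af=ref_af,
        reference_sheet=ref_sheet,
        truth=truth,
    )
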