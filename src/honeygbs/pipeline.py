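"""End-to-end pipeline: simulate/load -> AF -> QC -> concordance -> MDS -> traits.

Each stage writes its outputs under the configured output directory and the
run closes with a manifest (JSON) listing every emitted file with a SHA-256
content hash, so reruns with the same configuration and seed can be checked
for byte-identical results.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import yaml

from . import afstats, ancestry, concordance, qc, simulate, traits
from .panel_io import (
    MatrixType,
    build_count_matrix,
    load_panel,
    load_sample_sheet,
    write_panel,
    write_sample_sheet,
)

logger = logging.getLogger(__name__)


@dataclass
class SimBlock:
    """Simulation settings for the `simulate` stage of a pipeline run."""

    n_colonies_per_lineage: int = 8
    n_duplicate_pairs: int = 4
    n_reference_per_lineage: int = 30
    lineages: tuple[str, ...] = ("A", "C", "M", "O")
    divergence: float = 0.2
    admixed_fraction: float = 0.0
    alpha: float = 0.5
    n_drones: int = 15
    n_workers: int = 500
    matrix_type: str = MatrixType.HONEYCOMB_HONEY.value


@dataclass
class PipelineConfig:
    outdir: Path
    panel_path: Optional[Path] = None       # None: use the default synthetic panel
    sample_sheet: Optional[Path] = None     # required unless simulating
    vcf_dir: Optional[Path] = None
    min_dp: int = 1
    call_rate_threshold: float = 0.90
    outlier_delta: float = 20.0
    mds_k: int = 2
    tau: float = 0.8
    seed: int = 0
    sim: Optional[SimBlock] = field(default_factory=SimBlock)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        sim = raw.pop("sim", None)
        cfg = cls(
            outdir=Path(raw.pop("outdir", "honeygbs_out")),
            panel_path=Path(raw["panel_path"]) if raw.get("panel_path") else None,
            sample_sheet=Path(raw["sample_sheet"]) if raw.get("sample_sheet") else None,
            vcf_dir=Path(raw["vcf_dir"]) if raw.get("vcf_dir") else None,
            min_dp=int(raw.pop("min_dp", 1)),
            call_rate_threshold=float(raw.pop("call_rate_threshold", 0.90)),
            outlier_delta=float(raw.pop("outlier_delta", 20.0)),
            mds_k=int(raw.pop("mds_k", 2)),
            tau=float(raw.pop("tau", 0.8)),
            seed=int(raw.pop("seed", 0)),
        )
        if sim is not None:
            if "lineages" in sim:
                sim["lineages"] = tuple(sim["lineages"])
            cfg.sim = SimBlock(**sim)
        return cfg


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage; returns the manifest (also written to the outdir)."""
    out = Path(config.outdir)
    if config.panel_path is None and config.sim is None:
        raise ValueError("config error: either panel_path or a sim block is required")
    if config.sim is None and (config.sample_sheet is None or config.vcf_dir is None):
        raise ValueError("config error: without simulation, sample_sheet and vcf_dir are required")
    if config.panel_path is not None and not Path(config.panel_path).exists():
        raise ValueError(f"config error: panel file {config.panel_path} does not exist")
    out.mkdir(parents=True, exist_ok=True)
    emitted: list[Path] = []

    panel = load_panel(config.panel_path) if config.panel_path else simulate.default_panel()

    # -- stage: simulate (optional) --------------------------------------
    reference_af = None
    reference_sheet: list = []
    if config.sim is not None:
        sim = config.sim
        study = simulate.simulate_study(
            panel,
            simulate.SimConfig(seed=config.seed),
            n_colonies_per_lineage=sim.n_colonies_per_lineage,
            n_duplicate_pairs=sim.n_duplicate_pairs,
            n_reference_per_lineage=sim.n_reference_per_lineage,
            lineages=sim.lineages,
            F=sim.divergence,
            admixed_fraction=sim.admixed_fraction,
            alpha=sim.alpha,
            n_drones=sim.n_drones,
            n_workers=sim.n_workers,
            matrix_type=MatrixType(sim.matrix_type),
            seed=config.seed,
        )
        simdir = out / "sim"
        vcfdir = simdir / "vcf"
        vcfdir.mkdir(parents=True, exist_ok=True)
        write_panel(panel, simdir / "panel.tsv")
        emitted.append(simdir / "panel.tsv")
        for sid in study.counts.sample_ids:
            row = {
                mid: ad
                for mid in study.counts.marker_ids
                if (ad := study.counts.cell(sid, mid)) is not None
            }
            vcf_path = vcfdir / f"{sid}.vcf"
            simulate.write_sample_vcf(row, panel, sid, vcf_path)
            emitted.append(vcf_path)
        write_sample_sheet(study.sheet, simdir / "sample_sheet.tsv")
        emitted.append(simdir / "sample_sheet.tsv")
        truth = study.truth.stack().rename("true_af").reset_index()
        truth.columns = ["colony_id", "marker_id", "true_af"]
        truth.to_csv(simdir / "truth.tsv", sep="\t", index=False)
        emitted.append(simdir / "truth.tsv")
        sheet = study.sheet
        vcf_paths = {sid: vcfdir / f"{sid}.vcf" for sid in study.counts.sample_ids}
        reference_af = study.reference_af
        reference_sheet = study.reference_sheet
    else:
        sheet = load_sample_sheet(config.sample_sheet)
        vcf_paths = {
            r.sample_id: Path(config.vcf_dir) / f"{r.sample_id}.vcf" for r in sheet
        }
        vcf_paths = {sid: p for sid, p in vcf_paths.items() if p.exists()}

    # -- stage: allele frequencies ---------------------------------------
    counts = build_count_matrix(vcf_paths, panel)
    logger.info("count matrix: %d samples x %d markers", *counts.shape)
    af = afstats.af_matrix(counts, min_dp=config.min_dp)
    af.to_tsv(out / "af_matrix.tsv")
    emitted.append(out / "af_matrix.tsv")

    # -- stage: QC --------------------------------------------------------
    summary = qc.qc_summary(
        counts, panel, min_dp=config.min_dp, threshold=config.call_rate_threshold
    )
    per_sample, per_marker = summary.to_frames()
    per_sample.to_csv(out / "qc_samples.tsv", sep="\t")
    per_marker.to_csv(out / "qc_markers.tsv", sep="\t")
    emitted += [out / "qc_samples.tsv", out / "qc_markers.tsv"]
    depth = afstats.depth_summary(counts, sheet)
    depth.to_csv(out / "depth_summary.tsv", sep="\t")
    emitted.append(out / "depth_summary.tsv")

    # -- stage: concordance ------------------------------------------------
    pairs = concordance.duplicate_concordance(af, sheet, config.outlier_delta)
    concordance.concordance_table(pairs).to_csv(
        out / "concordance.tsv", sep="\t", index=False
    )
    emitted.append(out / "concordance.tsv")

    # -- stage: MDS + lineage assignment ----------------------------------
    sources = [af] + ([reference_af] if reference_af is not None else [])
    combined = ancestry.assemble_matrix(sources, panel)
    mds = ancestry.classical_mds(combined, k=config.mds_k)
    coords = mds.coordinates.copy()
    coords.index.name = "sample_id"
    coords.to_csv(out / "mds_coordinates.tsv", sep="\t")
    emitted.append(out / "mds_coordinates.tsv")
    full_sheet = list(sheet) + list(reference_sheet)
    assignments = ancestry.assign_lineage(mds, full_sheet, tau=config.tau)
    ancestry.annotate_mito_status(assignments, full_sheet)
    ancestry.assignment_table(assignments).to_csv(
        out / "assignments.tsv", sep="\t", index=False
    )
    emitted.append(out / "assignments.tsv")

    # -- stage: trait report ----------------------------------------------
    trait_ids = panel.trait_marker_ids
    grouping = {"all_samples": [r.sample_id for r in sheet if r.sample_id in af.sample_ids]}
    report = traits.fixation_report(af, sheet, trait_ids, grouping, counts=counts)
    table = traits.trait_af_table(af, sheet, trait_ids, grouping, counts=counts)
    table.index.name = "marker_id"
    table.to_csv(out / "trait_af.tsv", sep="\t", na_rep="NA")
    status = report.status.map(lambda s: s.value)
    status.index.name = "marker_id"
    status.to_csv(out / "trait_fixation.tsv", sep="\t")
    emitted += [out / "trait_af.tsv", out / "trait_fixation.tsv"]

    manifest = {
        "seed": config.seed,
        "n_samples": counts.shape[0],
        "n_markers": counts.shape[1],
        "n_duplicate_pairs": len(pairs),
        "n_fixed_ref_trait_markers": report.n_fixed_ref_in_all_groups,
        "files": {
            str(p.relative_to(out)): _sha256(p) for p in sorted(emitted)
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
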