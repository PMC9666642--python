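"""Lineage assignment by classical multidimensional scaling.

Honey, pool and larval samples are placed in a common low-dimensional space
together with reference individuals of known lineage by classical
(Torgerson) MDS on Euclidean distances between ancestry-marker AF vectors:
with D the pairwise distance matrix, B = -1/2 J D^2 J (J the centering
projector) is eigendecomposed and the top-k eigenpairs give coordinates
X = V sqrt(Lambda).  Queries are then assigned to the nearest reference
lineage centroid; a nearest/second-nearest distance ratio close to 1 marks
samples sitting between clusters, the signature of admixed colonies.  The
maternally inherited mitotype provides an independent cross-check: a sample
assigned to one lineage but carrying another lineage's mitotype suggests
nuclear introgression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .afstats import AFMatrix, AFProvenance
from .panel_io import (
    MarkerCategory,
    Panel,
    REFERENCE_MATRIX_TYPES,
    SampleRecord,
    sheet_by_id,
)

logger = logging.getLogger(__name__)


@dataclass
class MDSResult:
    """Classical-MDS coordinates with their eigenvalue spectrum."""

    coordinates: pd.DataFrame       # samples x k, columns dim1..dimk
    eigenvalues: np.ndarray         # all eigenvalues, non-increasing
    variance_explained: np.ndarray  # per retained dimension

    @property
    def sample_ids(self) -> list[str]:
        return list(self.coordinates.index)


class MitoStatus(str, Enum):
    CONCORDANT = "concordant"
    DISCORDANT = "discordant"
    MIXED = "mixed"
    UNAVAILABLE = "unavailable"


@dataclass
class AncestryAssignment:
    sample_id: str
    assigned_lineage: str
    distance_to_assigned: float
    distance_ratio: float           # nearest / second-nearest centroid distance
    admixture_flag: bool
    mito_status: MitoStatus = MitoStatus.UNAVAILABLE


def assemble_matrix(
    sources: Sequence[AFMatrix],
    panel: Panel,
    category: MarkerCategory = MarkerCategory.ANCESTRY,
    impute: bool = True,
) -> AFMatrix:
    """Stack AF matrices and restrict to one marker category.

    Rows are concatenated in source order; columns are restricted to the
    requested category (panel order).  Missing cells are imputed with the
    column mean over all stacked rows; a fully missing column is dropped
    with a warning.  Duplicate sample ids across sources are a hard error.
    """
    wanted = panel.category_ids(category)
    frames, provs = [], []
    for src in sources:
        cols = [c for c in wanted if c in src.values.columns]
        if cols != wanted:
            raise ValueError("source AF matrix lacks some panel markers of the category")
        frames.append(src.values[wanted])
        provs.append(src.provenance)
    values = pd.concat(frames)
    if values.index.has_duplicates:
        dup = sorted(values.index[values.index.duplicated()].unique())
        raise ValueError(f"duplicate sample ids across sources: {dup}")
    prov = pd.concat(provs)
    if impute:
        col_means = values.mean(axis=0, skipna=True)
        empty = col_means.index[col_means.isna()]
        if len(empty):
            logger.warning("dropping fully missing marker columns: %s", list(empty))
            values = values.drop(columns=list(empty))
            col_means = col_means.drop(list(empty))
        values = values.fillna(col_means)
        # imputed values break the 0/50/100 pattern of genotype rows
        prov = pd.Series(AFProvenance.READ_COUNT, index=values.index)
    return AFMatrix(values, prov)


def classical_mds(af: AFMatrix, k: int = 2) -> MDSResult:
    """Torgerson MDS of the samples on Euclidean AF distances (percent scale).

    Reflection indeterminacy is fixed per dimension by making the
    largest-magnitude coordinate positive.  Negative eigenvalues (absent for
    genuinely Euclidean input) are truncated to zero for the variance-
    explained denominators.
    """
    X = af.values.values
    if np.isnan(X).any():
        raise ValueError("AF matrix contains missing cells; impute before MDS")
    n = X.shape[0]
    if n < k + 1:
        raise ValueError(f"need at least {k + 1} samples for k={k}")
    d2 = squareform(pdist(X, metric="sqeuclidean"))
    J = np.eye(n) - np.full((n, n), 1.0 / n)
    B = -0.5 * J @ d2 @ J
    B = (B + B.T) / 2.0
    eigvals, eigvecs = np.linalg.eigh(B)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(eigvals.max(), 0.0) * 1e-9
    if eigvals[k - 1] <= tol:
        raise ValueError(
            f"only {(eigvals > tol).sum()} positive eigenvalues; cannot embed in {k} dims"
        )
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    for j in range(k):
        mags = np.abs(coords[:, j])
        # ties on magnitude resolved toward the last sample in row order
        i_max = np.where(mags >= mags.max() - 1e-12 * max(mags.max(), 1.0))[0][-1]
        if coords[i_max, j] < 0:
            coords[:, j] = -coords[:, j]
    positive = np.clip(eigvals, 0.0, None)
    var_exp = positive[:k] / positive.sum()
    return MDSResult(
        coordinates=pd.DataFrame(
            coords, index=af.values.index, columns=[f"dim{j + 1}" for j in range(k)]
        ),
        eigenvalues=eigvals,
        variance_explained=var_exp,
    )


def assign_lineage(
    mds: MDSResult,
    sheet: Sequence[SampleRecord],
    tau: float = 0.8,
) -> list[AncestryAssignment]:
    """Nearest-centroid lineage assignment with an admixture flag.

    Reference samples are sheet records with a lineage label and a reference
    matrix type; their per-lineage centroid is the mean of their MDS
    coordinates.  Every other sample in the MDS result is a query, assigned
    to the nearest centroid.  The admixture flag is raised when the ratio of
    the nearest to the second-nearest centroid distance exceeds ``tau`` —
    the sample sits between clusters rather than inside one.
    """
    by_id = sheet_by_id(sheet)
    coords = mds.coordinates
    ref_coords: dict[str, list[np.ndarray]] = {}
    for sid in coords.index:
        rec = by_id.get(sid)
        if rec and rec.lineage_label and rec.matrix_type in REFERENCE_MATRIX_TYPES:
            ref_coords.setdefault(rec.lineage_label.value, []).append(
                coords.loc[sid].values
            )
    centroids = {lin: np.mean(v, axis=0) for lin, v in ref_coords.items() if v}
    if len(centroids) < 2:
        raise ValueError(
            f"need reference samples for at least 2 lineages, have {sorted(centroids)}"
        )
    lineages = sorted(centroids)
    cent = np.vstack([centroids[lin] for lin in lineages])
    out = []
    for sid in coords.index:
        rec = by_id.get(sid)
        if rec and rec.lineage_label and rec.matrix_type in REFERENCE_MATRIX_TYPES:
            continue  # reference rows are not queries
        d = np.linalg.norm(cent - coords.loc[sid].values, axis=1)
        order = np.argsort(d, kind="stable")  # stable sort = lexicographic tie-break
        if d[order[0]] == d[order[1]]:
            logger.warning(
                "sample %s equidistant from lineages %s and %s; assigned to %s",
                sid, lineages[order[0]], lineages[order[1]], lineages[order[0]],
            )
        nearest, second = d[order[0]], d[order[1]]
        ratio = 0.0 if second == 0 else nearest / second
        out.append(
            AncestryAssignment(
                sample_id=sid,
                assigned_lineage=lineages[order[0]],
                distance_to_assigned=float(nearest),
                distance_ratio=float(ratio),
                admixture_flag=bool(ratio > tau),
            )
        )
    return out


#: Default mitotype -> lineage mapping (the C1 mitotype marks lineage C).
DEFAULT_MITO_LINEAGE_MAP: dict[str, str] = {
    "A": "A", "C": "C", "C1": "C", "C2": "C", "M": "M", "O": "O", "Y": "Y",
}


def mito_concordance(
    assignment: AncestryAssignment,
    record: SampleRecord,
    mito_lineage_map: Optional[Mapping[str, str]] = None,
) -> MitoStatus:
    """Cross-check a nuclear lineage assignment against recorded mitotypes.

    A single mitotype mapping to the assigned lineage is concordant; a
    single mismatching one is discordant (an introgression signal — e.g. an
    M-assigned colony carrying the C1 mitotype); multiple distinct recorded
    mitotypes give ``mixed``; no mitotype gives ``unavailable``.
    """
    mapping = DEFAULT_MITO_LINEAGE_MAP if mito_lineage_map is None else mito_lineage_map
    mitos = record.mitotypes
    if not mitos:
        return MitoStatus.UNAVAILABLE
    lineages = []
    for m in mitos:
        if m not in mapping:
            raise ValueError(f"mitotype {m!r} not covered by the mitotype-lineage map")
        lineages.append(mapping[m])
    if len(set(mitos)) > 1:
        return MitoStatus.MIXED
    if lineages[0] == assignment.assigned_lineage:
        return MitoStatus.CONCORDANT
    return MitoStatus.DISCORDANT


def annotate_mito_status(
    assignments: Sequence[AncestryAssignment],
    sheet: Sequence[SampleRecord],
    mito_lineage_map: Optional[Mapping[str, str]] = None,
) -> list[AncestryAssignment]:
    by_id = sheet_by_id(sheet)
    for a in assignments:
        rec = by_id.get(a.sample_id)
        a.mito_status = (
            mito_concordance(a, rec, mito_lineage_map) if rec else MitoStatus.UNAVAILABLE
        )
    return list(assignments)


def assignment_table(assignments: Sequence[AncestryAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in assignments],
            "lineage": [a.assigned_lineage for a in assignments],
            "distance": [a.distance_to_assigned for a in assignments],
            "distance_ratio": [a.distance_ratio for a in assignments],
            "admixture_flag": [a.admixture_flag for a in assignments],
            "mito_status": [a.mito_status.value for a in assignments],
        }
    )
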