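"""Disease-map and radar-plot layout computation.

The global map embeds the disease catalog in 1-3 dimensions by classical
(Torgerson) multidimensional scaling of a dissimilarity matrix obtained
by subtracting every similarity from the maximum observed similarity.  A
patient query is projected into the map as the convex combination of its
m nearest semantic neighbors, weighted by similarity.

The radar plot is the local alternative: the query sits at the origin,
each of the top n candidate diseases at radius

    r_D = (S(Q,Q) - S(Q,D)) / S(Q,Q)

so radial distance is exact (not an MDS approximation), while the
circumferential angle comes from a one-dimensional MDS of the candidates
scaled across the circle.  Point size encodes the (log-scaled) allele
frequency of the most pathogenic patient variant in any gene linked to
the disease, and color encodes that variant's pathogenicity.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .catalog import DiseaseCatalog
from .prioritize import VariantRecord
from .similarity import ScoredDisease

logger = logging.getLogger(__name__)

MAF_FLOOR = 1e-6


class MappingError(ValueError):
    pass


@dataclass
class DissimilarityMatrix:
    ids: list[str]
    values: np.ndarray


@dataclass
class MapLayout:
    ids: list[str]
    coords: np.ndarray  # (n, k)
    eigenvalues: np.ndarray  # (k,)


@dataclass
class RadarPoint:
    disease_id: str
    r: float
    theta: float
    size_value: Optional[float]
    color_value: Optional[float]
    excluded: bool = False


def to_dissimilarity(scores: np.ndarray, ids: list[str]) -> DissimilarityMatrix:
    """d_ij = max(S) - s_ij, diagonal forced to 0.

    The self-score is the maximum for overlap metrics but not guaranteed
    for Resnik, so the diagonal is zeroed explicitly.
    """
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 2 or scores.shape[0] != scores.shape[1] or scores.shape[0] != len(ids):
        raise MappingError("similarity matrix must be square and match ids")
    if not np.all(np.isfinite(scores)):
        raise MappingError("similarity matrix contains non-finite values")
    if np.max(np.abs(scores - scores.T)) > 1e-9:
        raise MappingError("similarity matrix is not symmetric (tolerance 1e-9)")
    d = scores.max() - scores
    np.fill_diagonal(d, 0.0)
    return DissimilarityMatrix(ids=list(ids), values=d)


def classical_mds(d: DissimilarityMatrix, k: int = 2) -> MapLayout:
    """Torgerson scaling: double-center -D^2/2, eigendecompose, embed.

    Coordinates are the top-k eigenvectors scaled by sqrt(eigenvalue).
    Axes whose eigenvalue is not positive (the dissimilarities are not
    Euclidean-embeddable in that many dimensions) are zeroed with a
    warning.  Columns are sign-canonicalized (first nonzero entry
    positive) so layouts are reproducible.
    """
    if not 1 <= k <= 3:
        raise MappingError("k must be 1, 2 or 3")
    n = len(d.ids)
    if n < 2:
        raise MappingError("need at least 2 points for MDS")
    dd = np.asarray(d.values, dtype=float)
    j = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * j @ (dd ** 2) @ j
    evals, evecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(evals)[::-1][:k]
    lam = evals[order]
    vec = evecs[:, order]
    coords = np.zeros((n, k))
    for i in range(k):
        if lam[i] > 0:
            coords[:, i] = vec[:, i] * math.sqrt(lam[i])
        else:
            logger.warning("MDS axis %d has non-positive eigenvalue %.3g; zeroed", i, lam[i])
    # sign canonicalization: first nonzero coordinate of each column positive
    for i in range(k):
        col = coords[:, i]
        nz = np.nonzero(col)[0]
        if nz.size and col[nz[0]] < 0:
            coords[:, i] = -col
    return MapLayout(ids=list(d.ids), coords=coords, eigenvalues=lam)


def project_query(layout: MapLayout, top: list[ScoredDisease], m: int = 5) -> np.ndarray:
    """Similarity-weighted convex combination of the m nearest neighbors.

    Weights are each neighbor's similarity divided by the sum over the m
    neighbors, so they sum to 1 and the projection lies in the convex
    hull of the neighbor coordinates.
    """
    index = {did: i for i, did in enumerate(layout.ids)}
    neighbors = [sd for sd in top if sd.disease_id in index][:m]
    if len(neighbors) < m:
        raise MappingError(f"need {m} scored diseases present in the layout, have {len(neighbors)}")
    scores = np.array([sd.score for sd in neighbors], dtype=float)
    if np.any(scores < 0):
        raise MappingError("negative similarity scores cannot weight a convex combination")
    total = scores.sum()
    if total == 0:
        raise MappingError(
            "all neighbor similarities are 0; the projection is undefined "
            "— try a different similarity metric"
        )
    w = scores / total
    pts = np.stack([layout.coords[index[sd.disease_id]] for sd in neighbors])
    return w @ pts


def _best_variant(variants: list[VariantRecord]) -> Optional[VariantRecord]:
    # "best" = most pathogenic; missing pathogenicity sorts last.
    if not variants:
        return None
    return max(
        variants,
        key=lambda v: (v.pathogenicity if v.pathogenicity is not None else -1.0),
    )


def maf_size_value(maf: Optional[float]) -> float:
    """Log-scale a minor allele frequency for point sizing.

    Missing MAF is rendered at maximum size (rarest); observed MAFs are
    floored at 1e-6 before the log.
    """
    if maf is None:
        maf = MAF_FLOOR
    return -math.log10(max(maf, MAF_FLOOR))


def radar_layout(
    top: list[ScoredDisease],
    self_score: float,
    one_d: MapLayout,
    variants_by_gene: dict[str, list[VariantRecord]],
    catalog: DiseaseCatalog,
    excluded: set[str] = frozenset(),
) -> list[RadarPoint]:
    """Polar layout of the top candidate diseases around the query.

    ``one_d`` must be a k=1 MDS layout over the same diseases.  Angles
    scale the observed 1-D range over [0, 360*(n-1)/n) degrees so the two
    extremes do not coincide; a single candidate sits at 0.
    """
    if self_score <= 0:
        raise MappingError("self-similarity S(Q,Q) must be positive for the radar radius")
    index = {did: i for i, did in enumerate(one_d.ids)}
    missing = [sd.disease_id for sd in top if sd.disease_id not in index]
    if missing:
        raise MappingError(f"1-D layout lacks diseases: {missing}")
    n = len(top)
    xs = np.array([one_d.coords[index[sd.disease_id], 0] for sd in top])
    span = xs.max() - xs.min() if n > 1 else 0.0
    points: list[RadarPoint] = []
    for sd, x in zip(top, xs):
        if span > 0:
            theta = 360.0 * (n - 1) / n * (x - xs.min()) / span
        else:
            theta = 0.0
        r = (self_score - sd.score) / self_score
        linked = catalog.diseases[sd.disease_id].gene_symbols
        candidates = [v for g in sorted(linked) for v in variants_by_gene.get(g, [])]
        best = _best_variant(candidates)
        if best is None:
            size_value = color_value = None
        else:
            size_value = maf_size_value(best.maf)
            color_value = best.pathogenicity
        points.append(
            RadarPoint(
                disease_id=sd.disease_id,
                r=r,
                theta=theta,
                size_value=size_value,
                color_value=color_value,
                excluded=sd.disease_id in excluded,
            )
        )
    return points
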