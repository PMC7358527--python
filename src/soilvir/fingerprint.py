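"""Genetic-fingerprint similarity analysis for gel banding patterns.

RAPD-PCR of a viral assemblage produces a lane of bands; each (month, site)
pair contributes one binary band profile.  This module covers the numeric
chain from lane traces to ordination:

* band calling from a densitometric trace (prominence thresholds standing in
  for the "minimum profiling" / "grey zone" screening criteria),
* band matching across lanes into shared columns,
* pairwise Dice similarity ``x_ij`` (percent) and the dissimilarity
  transform ``y_ij = 100 - x_ij``,
* average and maximum pairwise dissimilarity,
* UPGMA clustering into an ultrametric dendrogram, and
* Kruskal nonmetric multidimensional scaling (stress-1).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import isotonic_regression
from scipy.signal import find_peaks
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)

__all__ = [
    "BandProfile",
    "SimilarityMatrix",
    "DissimilarityMatrix",
    "Dendrogram",
    "DendrogramNode",
    "MdsResult",
    "DissimilaritySummary",
    "call_bands",
    "match_bands",
    "dice_similarity",
    "similarity_matrix",
    "to_dissimilarity",
    "average_dissimilarity",
    "upgma",
    "nmds",
    "fingerprint_pipeline",
]


@dataclass(frozen=True)
class BandProfile:
    """Binary band fingerprint of one lane, labelled by (month, site) or similar."""

    label: str
    bands: np.ndarray
    uncertain: np.ndarray = field(default_factory=lambda: np.empty(0))

    def __post_init__(self) -> None:
        bands = np.unique(np.asarray(self.bands, dtype=float))
        object.__setattr__(self, "bands", bands)
        object.__setattr__(
            self, "uncertain", np.unique(np.asarray(self.uncertain, dtype=float))
        )


def _check_square(values: np.ndarray, labels: tuple[str, ...]) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    n = len(labels)
    if values.shape != (n, n):
        raise ValueError(f"matrix shape {values.shape} does not match {n} labels")
    if not np.allclose(values, values.T):
        raise ValueError("matrix must be symmetric")
    return values


@dataclass(frozen=True)
class SimilarityMatrix:
    """Pairwise banding-pattern similarity in percent (diagonal 100)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_square(self.values, self.labels))


@dataclass(frozen=True)
class DissimilarityMatrix:
    """Pairwise dissimilarity y = 100 - similarity (zero diagonal)."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", _check_square(self.values, self.labels))

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)


class DissimilaritySummary(tuple):
    """(mean, max) of the strictly-upper-triangle dissimilarities."""

    def __new__(cls, mean: float, max_: float):
        return super().__new__(cls, (mean, max_))

    @property
    def mean(self) -> float:
        return self[0]

    @property
    def max(self) -> float:
        return self[1]


# ---------------------------------------------------------------------------
# band calling and matching


def call_bands(
    positions: np.ndarray,
    intensities: np.ndarray,
    label: str,
    min_profiling: float = 0.05,
    grey_zone: float = 0.02,
) -> BandProfile:
    """Call bands from a densitometric lane trace.

    Local maxima with prominence at least ``min_profiling`` of the maximum
    trace intensity become bands; maxima whose prominence lies between
    ``grey_zone`` and ``min_profiling`` are recorded as uncertain (for manual
    review) and excluded from the band set.
    """
    positions = np.asarray(positions, dtype=float)
    intensities = np.asarray(intensities, dtype=float)
    if np.any(intensities < 0):
        raise ValueError("trace intensities must be non-negative")
    top = intensities.max(initial=0.0)
    if top <= 0:
        logger.warning("flat trace for %s: no bands called", label)
        return BandProfile(label=label, bands=np.empty(0))
    idx, props = find_peaks(intensities, prominence=grey_zone * top)
    prominence = props["prominences"]
    sure = prominence >= min_profiling * top
    return BandProfile(
        label=label, bands=positions[idx[sure]], uncertain=positions[idx[~sure]]
    )


def match_bands(
    profiles: list[BandProfile],
    tol_frac: float = 0.02,
    tol_abs: float | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cluster pooled band positions into shared columns.

    Greedy left-to-right clustering: a band joins the current cluster iff it
    lies within tolerance of the cluster's running mean position.  Tolerance
    is proportional to position (``tol_frac`` of the running mean; gel
    mobility error grows with fragment size) unless ``tol_abs`` is given.

    Returns (consensus positions, boolean presence matrix profiles x columns).
    """
    if tol_abs is None and tol_frac <= 0:
        raise ValueError("band-match tolerance must be positive")
    pooled = sorted(
        (pos, i) for i, prof in enumerate(profiles) for pos in prof.bands
    )
    clusters: list[list[tuple[float, int]]] = []
    for pos, i in pooled:
        if clusters:
            mean = float(np.mean([p for p, _ in clusters[-1]]))
            tol = tol_abs if tol_abs is not None else tol_frac * mean
            if abs(pos - mean) <= tol:
                clusters[-1].append((pos, i))
                continue
        clusters.append([(pos, i)])
    positions = np.array([float(np.mean([p for p, _ in c])) for c in clusters])
    presence = np.zeros((len(profiles), len(clusters)), dtype=bool)
    for j, members in enumerate(clusters):
        for _, i in members:
            presence[i, j] = True
    return positions, presence


def dice_similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Dice's binary coefficient 100 * 2|a AND b| / (|a| + |b|) in percent."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("band vectors must share the same column space")
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        raise ValueError("Dice similarity undefined for two empty band sets")
    return 100.0 * 2.0 * int((a & b).sum()) / (na + nb)


def similarity_matrix(
    profiles: list[BandProfile],
    tol_frac: float = 0.02,
    tol_abs: float | None = None,
) -> SimilarityMatrix:
    """All-pairs Dice similarity after band matching."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles for a similarity matrix")
    _, presence = match_bands(profiles, tol_frac=tol_frac, tol_abs=tol_abs)
    n = len(profiles)
    x = np.full((n, n), 100.0)
    for i in range(n):
        for j in range(i + 1, n):
            x[i, j] = x[j, i] = dice_similarity(presence[i], presence[j])
    return SimilarityMatrix(labels=tuple(p.label for p in profiles), values=x)


def to_dissimilarity(s: SimilarityMatrix) -> DissimilarityMatrix:
    """Elementwise transform y_ij = 100 - x_ij (an involution)."""
    return DissimilarityMatrix(labels=s.labels, values=100.0 - s.values)


def average_dissimilarity(d: DissimilarityMatrix) -> DissimilaritySummary:
    """Mean and max of the n(n-1)/2 strictly-upper-triangle entries."""
    n = len(d.labels)
    if n < 2:
        raise ValueError("average dissimilarity needs at least two labels")
    upper = d.values[np.triu_indices(n, k=1)]
    return DissimilaritySummary(float(upper.mean()), float(upper.max()))


# ---------------------------------------------------------------------------
# UPGMA


@dataclass(frozen=True)
class DendrogramNode:
    """Binary tree node; leaves carry a label, internal nodes a merge height."""

    height: float
    label: str | None = None
    children: tuple["DendrogramNode", "DendrogramNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.children is None

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.label]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass(frozen=True)
class Dendrogram:
    """Rooted ultrametric tree; merge heights are cophenetic distances.

    The height recorded at each internal node is the full average-linkage
    distance at which its children merged (not half of it), so the
    cophenetic distance between two leaves is simply the height of their
    lowest common ancestor.
    """

    root: DendrogramNode

    @property
    def labels(self) -> tuple[str, ...]:
        return tuple(self.root.leaves())

    def merge_heights(self) -> list[float]:
        heights = []

        def walk(node: DendrogramNode) -> None:
            if not node.is_leaf:
                heights.append(node.height)
                walk(node.children[0])
                walk(node.children[1])

        walk(self.root)
        return sorted(heights)

    def cophenetic_matrix(self) -> tuple[tuple[str, ...], np.ndarray]:
        """Leaf labels and the matrix of lowest-common-ancestor heights."""
        labels = self.labels
        index = {lab: i for i, lab in enumerate(labels)}
        n = len(labels)
        coph = np.zeros((n, n))

        def walk(node: DendrogramNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            left = walk(node.children[0])
            right = walk(node.children[1])
            for a in left:
                for b in right:
                    coph[index[a], index[b]] = coph[index[b], index[a]] = node.height
            return left + right

        walk(self.root)
        return labels, coph

    def to_newick(self) -> str:
        from .io import newick_string

        return newick_string(self)


def upgma(d: DissimilarityMatrix) -> Dendrogram:
    """Unweighted pair-group clustering with arithmetic-mean linkage.

    Iteratively merges the closest pair of clusters; the distance between two
    clusters is the unweighted mean of all member pairwise dissimilarities
    (maintained by the size-weighted update).  Merge height equals the full
    merging distance.  Ties are broken by the lexicographically smallest pair
    of cluster labels, a cluster's label being its smallest leaf label.
    """
    labels = list(d.labels)
    n = len(labels)
    if n < 2:
        raise ValueError("UPGMA needs at least two leaves")
    dist: dict[frozenset[int], float] = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[frozenset((i, j))] = float(d.values[i, j])
    clusters: dict[int, tuple[str, int, DendrogramNode]] = {
        i: (labels[i], 1, DendrogramNode(height=0.0, label=labels[i])) for i in range(n)
    }
    next_id = n
    while len(clusters) > 1:
        best = None
        for key, value in dist.items():
            i, j = sorted(key)
            pair_labels = tuple(sorted((clusters[i][0], clusters[j][0])))
            candidate = (value, pair_labels, key)
            if best is None or candidate < best:
                best = candidate
        height, _, key = best
        i, j = sorted(key)
        label_i, size_i, node_i = clusters.pop(i)
        label_j, size_j, node_j = clusters.pop(j)
        merged = DendrogramNode(height=height, children=(node_i, node_j))
        for k in list(clusters):
            d_ik = dist.pop(frozenset((i, k)))
            d_jk = dist.pop(frozenset((j, k)))
            dist[frozenset((next_id, k))] = (size_i * d_ik + size_j * d_jk) / (
                size_i + size_j
            )
        del dist[key]
        clusters[next_id] = (min(label_i, label_j), size_i + size_j, merged)
        next_id += 1
    (_, _, root) = next(iter(clusters.values()))
    return Dendrogram(root=root)


# ---------------------------------------------------------------------------
# nonmetric MDS


@dataclass(frozen=True)
class MdsResult:
    """Nonmetric MDS configuration with Kruskal stress-1."""

    labels: tuple[str, ...]
    coordinates: np.ndarray
    stress: float
    converged: bool
    n_iter: int
    stress_history: tuple[float, ...]


def _classical_scaling(dmat: np.ndarray, dim: int) -> np.ndarray:
    n = dmat.shape[0]
    j = np.eye(n) - np.full((n, n), 1.0 / n)
    b = -0.5 * j @ (dmat**2) @ j
    w, v = np.linalg.eigh(b)
    order = np.argsort(w)[::-1][:dim]
    coords = v[:, order] * np.sqrt(np.clip(w[order], 0.0, None))
    return coords


def _stress_and_dhat(
    coords: np.ndarray, y: np.ndarray, order: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    d = pdist(coords)
    d = np.maximum(d, 1e-12)
    dhat = np.empty_like(d)
    dhat[order] = isotonic_regression(d[order]).x
    t_star = float((d**2).sum())
    s_star = float(((d - dhat) ** 2).sum())
    stress = np.sqrt(s_star / t_star) if t_star > 0 else 0.0
    return stress, d, dhat


def _kruskal_descent(
    coords: np.ndarray,
    y: np.ndarray,
    order: np.ndarray,
    max_iter: int,
    tol: float,
) -> tuple[np.ndarray, float, bool, int, list[float]]:
    n = coords.shape[0]
    iu, ju = np.triu_indices(n, k=1)
    stress, d, dhat = _stress_and_dhat(coords, y, order)
    history = [stress]
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        if stress <= tol:
            converged = True
            break
        s_star = ((d - dhat) ** 2).sum()
        t_star = (d**2).sum()
        # Kruskal gradient of stress-1 with dhat held fixed
        coef = stress * ((d - dhat) / max(s_star, 1e-300) - d / t_star)
        grad = np.zeros_like(coords)
        diff = coords[iu] - coords[ju]
        contrib = (coef / d)[:, None] * diff
        np.add.at(grad, iu, contrib)
        np.add.at(grad, ju, -contrib)
        gnorm = np.linalg.norm(grad)
        if gnorm == 0:
            converged = True
            break
        scale = np.sqrt(t_star / len(d))  # typical distance, sets step units
        step = 0.5 * scale / gnorm
        improved = False
        for _ in range(25):
            candidate = coords - step * grad
            new_stress, new_d, new_dhat = _stress_and_dhat(candidate, y, order)
            if new_stress < stress:
                improved = True
                break
            step *= 0.5
        if not improved:
            converged = True
            break
        delta = stress - new_stress
        coords, stress, d, dhat = candidate, new_stress, new_d, new_dhat
        history.append(stress)
        if delta < tol:
            converged = True
            break
    return coords, stress, converged, it, history


def nmds(
    d: DissimilarityMatrix,
    dim: int = 2,
    max_iter: int = 300,
    tol: float = 1e-6,
    seed: int = 0,
    n_restarts: int = 4,
) -> MdsResult:
    """Kruskal nonmetric MDS of a dissimilarity matrix.

    Initializes from classical (metric) scaling, then alternates monotone
    regression of configuration distances onto the dissimilarity rank order
    (pool-adjacent-violators; primary treatment of ties) with a backtracking
    gradient step on Kruskal stress-1, so the accepted stress sequence is
    non-increasing.  ``n_restarts - 1`` seeded perturbed restarts guard
    against local minima; the lowest-stress solution is returned.

    Exact-zero off-diagonal dissimilarities (identical fingerprints) break
    the rank order and are replaced by half the smallest positive
    dissimilarity, with a logged warning.
    """
    n = len(d.labels)
    if n <= dim:
        raise ValueError(f"need more than dim={dim} objects, got {n}")
    values = d.values.copy()
    off = ~np.eye(n, dtype=bool)
    if np.all(values[off] == 0):
        raise ValueError("all dissimilarities are zero; ordination is degenerate")
    zeros = (values == 0) & off
    if zeros.any():
        fill = 0.5 * values[off & (values > 0)].min()
        logger.warning(
            "%d zero off-diagonal dissimilarities replaced by %g for NMDS",
            int(zeros.sum()) // 2,
            fill,
        )
        values[zeros] = fill
    y = squareform(values, checks=False)
    d_cond = y
    # primary ties: within equal-y blocks order by current distances is ideal,
    # but the block order must stay fixed across iterations for determinism;
    # sorting ties by the *initial* metric distances keeps PAV from charging
    # stress to tied dissimilarities while remaining reproducible.
    init = _classical_scaling(values, dim)
    d0 = np.maximum(pdist(init), 1e-12)
    order = np.lexsort((d0, d_cond))

    rng = np.random.default_rng(seed)
    best: tuple[np.ndarray, float, bool, int, list[float]] | None = None
    scale = float(np.sqrt((init**2).sum() / n)) or 1.0
    for restart in range(max(1, n_restarts)):
        start = init if restart == 0 else init + rng.normal(0, 0.2 * scale, init.shape)
        result = _kruskal_descent(start, y, order, max_iter=max_iter, tol=tol)
        if best is None or result[1] < best[1]:
            best = result
    coords, stress, converged, n_iter, history = best
    coords = coords - coords.mean(axis=0)
    return MdsResult(
        labels=d.labels,
        coordinates=coords,
        stress=float(stress),
        converged=converged,
        n_iter=n_iter,
        stress_history=tuple(history),
    )


# ---------------------------------------------------------------------------
# full chain


@dataclass(frozen=True)
class FingerprintResult:
    similarity: SimilarityMatrix
    dissimilarity: DissimilarityMatrix
    dendrogram: Dendrogram
    mds: MdsResult | None
    summary: DissimilaritySummary


def fingerprint_pipeline(
    profiles: list[BandProfile],
    tol_frac: float = 0.02,
    tol_abs: float | None = None,
    mds_dim: int = 2,
    seed: int = 0,
) -> FingerprintResult:
    """Band profiles -> similarity, dissimilarity, UPGMA tree, NMDS, summary.

    With fewer than three profiles the ordination is meaningless and an
    error is raised; an all-identical profile set yields a degenerate
    (all-zero) dissimilarity matrix, for which the MDS stage is skipped with
    a warning.
    """
    if len(profiles) < 3:
        raise ValueError("fingerprint pipeline needs at least three labelled profiles")
    sim = similarity_matrix(profiles, tol_frac=tol_frac, tol_abs=tol_abs)
    dis = to_dissimilarity(sim)
    tree = upgma(dis)
    summary = average_dissimilarity(dis)
    n = len(dis.labels)
    off = ~np.eye(n, dtype=bool)
    if np.all(dis.values[off] == 0):
        logger.warning("degenerate dissimilarity matrix (all profiles identical); MDS skipped")
        mds = None
    else:
        mds = nmds(dis, dim=mds_dim, seed=seed)
    return FingerprintResult(
        similarity=sim, dissimilarity=dis, dendrogram=tree, mds=mds, summary=summary
    )
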