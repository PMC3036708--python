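"""Monmonier maximum-difference barrier detection between population
centroids.

Genetic distances are first corrected for geography (residuals of an OLS
regression of pairwise F_ST on great-circle centroid distance); barriers
are then traced across a Delaunay triangulation of the centroids, each
step crossing the adjacent unused edge with the largest residual, from
both ends, until the convex hull or an existing barrier is reached.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError

from .ibsmds import SquareDistanceMatrix
from .spatial import _haversine_km


@dataclass
class CrossedEdge:
    pop_a: str
    pop_b: str
    weight: float


@dataclass
class Barrier:
    edges: list[CrossedEdge]

    @property
    def strength(self) -> float:
        return float(np.mean([e.weight for e in self.edges]))


@dataclass
class BarrierResult:
    barriers: list[Barrier]  # ordered by decreasing strength


def residual_fst(
    fst_matrix: SquareDistanceMatrix, centroids: dict[str, tuple[float, float]]
) -> SquareDistanceMatrix:
    """Residuals of F_ST regressed on great-circle centroid distance.

    centroids maps population id -> (lat, lon). OLS with intercept over
    the off-diagonal upper triangle; residuals returned as a symmetric
    matrix with zero diagonal.
    """
    ids = list(fst_matrix.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 populations")
    missing = [p for p in ids if p not in centroids]
    if missing:
        raise ValueError(f"no centroid for populations {missing}")
    n = len(ids)
    km = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            la1, lo1 = centroids[ids[i]]
            la2, lo2 = centroids[ids[j]]
            km[i, j] = km[j, i] = float(_haversine_km(la1, lo1, la2, lo2))
    iu = np.triu_indices(n, k=1)
    x = km[iu]
    y = fst_matrix.values[iu]
    if np.std(x) == 0:
        raise ValueError("constant geographic distances; regression undefined")
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = np.zeros((n, n))
    out[iu] = resid
    out = out + out.T
    return SquareDistanceMatrix(fst_matrix.ids.copy(), out, kind="fst")


def _edge_key(i: int, j: int) -> tuple[int, int]:
    return (i, j) if i < j else (j, i)


def monmonier_barriers(
    residuals: SquareDistanceMatrix,
    centroids: dict[str, tuple[float, float]],
    n_barriers: int = 1,
) -> BarrierResult:
    """Trace ``n_barriers`` Monmonier barriers on a Delaunay triangulation.

    Each triangulation edge is weighted by the residual distance of its
    endpoint populations. A barrier starts across the maximum-weight
    unused edge and grows from both ends; from the triangle just entered
    it crosses the heavier of the two remaining edges (ties broken by the
    sorted population-pair index), stopping at the convex hull or at an
    already-crossed edge. No edge is crossed twice across all barriers.
    """
    if n_barriers < 1:
        raise ValueError("n_barriers must be >= 1")
    ids = list(residuals.ids)
    pts = np.array([(centroids[p][1], centroids[p][0]) for p in ids])  # (lon, lat)
    if len(ids) < 3:
        raise ValueError("need at least 3 centroids")
    try:
        tri = Delaunay(pts)
    except QhullError as e:
        raise ValueError(f"triangulation failed (collinear centroids?): {e}") from None

    # edge -> adjacent triangles
    edge_tris: dict[tuple[int, int], list[int]] = {}
    for t_idx, simplex in enumerate(tri.simplices):
        for a in range(3):
            e = _edge_key(simplex[a], simplex[(a + 1) % 3])
            edge_tris.setdefault(e, []).append(t_idx)

    W = residuals.values

    def weight(e: tuple[int, int]) -> float:
        return W[e[0], e[1]]

    crossed: set[tuple[int, int]] = set()
    barriers: list[Barrier] = []

    for _ in range(n_barriers):
        unused = [e for e in edge_tris if e not in crossed]
        if not unused:
            break
        start = max(unused, key=lambda e: (weight(e), (-e[0], -e[1])))
        # deterministic tie-break: among equal weights prefer lowest pair index
        wmax = weight(start)
        start = sorted([e for e in unused if weight(e) == wmax])[0]
        crossed.add(start)
        path = [start]

        # two growing ends: each sits inside one triangle adjacent to the
        # start edge (or on the hull side, where it terminates at once)
        for t_idx in edge_tris[start]:
            cur_tri = t_idx
            cur_edge = start
            while True:
                simplex = tri.simplices[cur_tri]
                candidates = [
                    _edge_key(simplex[a], simplex[(a + 1) % 3]) for a in range(3)
                ]
                candidates = [e for e in candidates if e != cur_edge and e not in crossed]
                if not candidates:
                    break  # blocked by an existing barrier
                candidates.sort(key=lambda e: (-weight(e), e))
                nxt = candidates[0]
                crossed.add(nxt)
                path.append(nxt)
                adj = [t for t in edge_tris[nxt] if t != cur_tri]
                if not adj:
                    break  # reached the convex hull
                cur_tri = adj[0]
                cur_edge = nxt
        barriers.append(
            Barrier(edges=[CrossedEdge(ids[e[0]], ids[e[1]], weight(e)) for e in path])
        )

    barriers.sort(key=lambda b: -b.strength)
    return BarrierResult(barriers=barriers)


def barriers_to_rows(result: BarrierResult) -> list[tuple]:
    """(pop_a, pop_b, residual, barrier_rank) rows for TSV export."""
    rows = []
    for rank, b in enumerate(result.barriers, start=1):
        for e in b.edges:
            rows.append((e.pop_a, e.pop_b, e.weight, rank))
    return rows
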