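"""Simplicial filtrations and Z/2 persistent homology by matrix reduction.

Two filtrations over a 3-D point cloud are provided:

* **alpha**: faces of the Delaunay triangulation, each entering the
  filtration at the radius of the smallest empty circumscribing ball
  (Gabriel faces at their own circumradius, non-Gabriel faces inherited
  from their cofaces).  This is exact for the growing-balls construction
  in 3-D and keeps the simplex count linear in the number of points.
* **rips**: the Vietoris–Rips complex, every simplex entering at its
  diameter (longest pairwise distance).

Filtration values are returned on the *radius* scale by default — the
common radius of the balls placed on the points — so that alpha and Rips
outputs are directly comparable; Rips diameters are halved to get there.

Persistence pairs are computed by the standard column reduction R = D·V of
the Z/2 boundary matrix, with columns stored as Python integers used as
bitsets.  The V matrix is kept so that every finite interval carries a
*representative cycle*: the cycle created by its birth simplex (the column
of V at the creator index).  At birth only the feature's own simplices are
present, which makes the representative's vertex set reproducible across
noisy re-samplings of the same geometry — the property cycle tracking
relies on.  Simplices are ordered by (filtration value, dimension,
lexicographic vertex tuple), so the output is deterministic.
"""

from __future__ import annotations

import itertools
from typing import Iterator

import numpy as np
from scipy.spatial import Delaunay
from scipy.spatial.distance import pdist, squareform

Simplex = tuple[int, ...]

# ---------------------------------------------------------------------------
# Geometry helpers


def circumsphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Center and radius of the circumsphere of a k-simplex in R^3.

    The center is the point of the simplex's affine hull equidistant from
    all vertices (for k < 3 this is the smallest sphere through the
    vertices centred in their affine hull).
    """
    points = np.asarray(points, dtype=float)
    p0 = points[0]
    if len(points) == 1:
        return p0.copy(), 0.0
    V = points[1:] - p0
    G = V @ V.T
    b = 0.5 * np.diag(G)
    try:
        a = np.linalg.solve(G, b)
    except np.linalg.LinAlgError:
        a, *_ = np.linalg.lstsq(G, b, rcond=None)
    center = p0 + a @ V
    return center, float(np.linalg.norm(center - p0))


def _affine_rank(coords: np.ndarray, tol: float = 1e-9) -> tuple[int, np.ndarray]:
    """Affine dimension of the point set and the points projected onto an
    orthonormal basis of their affine hull (distance-preserving)."""
    centered = coords - coords.mean(axis=0)
    # SVD of the centred cloud: right singular vectors span the hull
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    scale = s[0] if len(s) and s[0] > 0 else 1.0
    rank = int(np.sum(s > tol * max(scale, 1.0)))
    return rank, centered @ vt[:rank].T


# ---------------------------------------------------------------------------
# Filtrations


def alpha_filtration(coords: np.ndarray) -> dict[Simplex, float]:
    """Alpha-complex filtration: simplex -> ball radius at which it enters.

    Degenerate clouds (coplanar or collinear) are triangulated in their
    affine hull, which yields the same growing-balls persistence as the
    ambient construction.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    rank, projected = _affine_rank(coords)

    if rank <= 1 or n <= 2:
        return _segment_filtration(coords)

    work = projected if rank < 3 else coords
    try:
        tri = Delaunay(work)
    except Exception:
        # Qhull can reject nearly-degenerate input the rank test kept;
        # retriangulate in a strictly lower-dimensional hull.
        _, projected = _affine_rank(coords, tol=1e-6)
        if projected.shape[1] <= 1:
            return _segment_filtration(coords)
        tri = Delaunay(projected)

    top_dim = tri.points.shape[1]
    by_dim: list[set[Simplex]] = [set() for _ in range(top_dim + 1)]
    for cell in tri.simplices:
        cell = tuple(sorted(int(v) for v in cell))
        for d in range(top_dim + 1):
            for face in itertools.combinations(cell, d + 1):
                by_dim[d].add(face)
    for v in range(n):
        by_dim[0].add((v,))

    filt: dict[Simplex, float] = {}
    centers: dict[Simplex, tuple[np.ndarray, float]] = {}

    def sphere(s: Simplex) -> tuple[np.ndarray, float]:
        if s not in centers:
            centers[s] = circumsphere(coords[list(s)])
        return centers[s]

    # top-down pass: Gabriel faces keep their circumradius, others inherit
    for d in range(top_dim, -1, -1):
        for s in sorted(by_dim[d]):
            if s not in filt:
                filt[s] = 0.0 if d == 0 else sphere(s)[1]
            if d == 0:
                continue
            for i in range(len(s)):
                face = s[:i] + s[i + 1:]
                extra = s[i]
                if face in filt:
                    filt[face] = min(filt[face], filt[s])
                else:
                    c, r = sphere(face)
                    if np.linalg.norm(coords[extra] - c) < r:  # not Gabriel
                        filt[face] = filt[s]

    # bottom-up clamp: round-off in circumradii must never let a face
    # enter after one of its cofaces
    for d in range(1, top_dim + 1):
        for s in sorted(by_dim[d]):
            face_max = max(filt[s[:i] + s[i + 1:]] for i in range(len(s)))
            if filt[s] < face_max:
                filt[s] = face_max
    return filt


def _segment_filtration(coords: np.ndarray) -> dict[Simplex, float]:
    """Filtration of (nearly) collinear points: consecutive edges only."""
    n = len(coords)
    filt: dict[Simplex, float] = {(v,): 0.0 for v in range(n)}
    if n < 2:
        return filt
    centered = coords - coords.mean(axis=0)
    if n == 2:
        order = [0, 1]
    else:
        _, _, vt = np.linalg.svd(centered, full_matrices=False)
        order = list(np.argsort(centered @ vt[0]))
    for a, b in zip(order, order[1:]):
        e = tuple(sorted((int(a), int(b))))
        filt[e] = 0.5 * float(np.linalg.norm(coords[a] - coords[b]))
    return filt


def rips_filtration(coords: np.ndarray, max_simplex_dim: int) -> dict[Simplex, float]:
    """Vietoris–Rips filtration up to ``max_simplex_dim``-simplices.

    Values are on the *diameter* (edge-length) scale; :func:`persistence`
    rescales to radius when asked.
    """
    coords = np.asarray(coords, dtype=float)
    n = len(coords)
    D = squareform(pdist(coords)) if n > 1 else np.zeros((1, 1))
    filt: dict[Simplex, float] = {}
    for d in range(min(max_simplex_dim, n - 1) + 1):
        for s in itertools.combinations(range(n), d + 1):
            if d == 0:
                filt[s] = 0.0
            elif d == 1:
                filt[s] = float(D[s[0], s[1]])
            else:
                filt[s] = max(float(D[i, j])
                              for i, j in itertools.combinations(s, 2))
    return filt


# ---------------------------------------------------------------------------
# Reduction


def _iter_bits(column: int) -> Iterator[int]:
    while column:
        low = column & -column
        yield low.bit_length() - 1
        column ^= low


def persistence_pairs(
    filt: dict[Simplex, float],
) -> list[tuple[int, float, float, frozenset[int]]]:
    """Reduce the boundary matrix of a filtration.

    Returns finite intervals as ``(dimension, birth, death, vertices)``
    where ``vertices`` is the vertex set of the representative cycle
    created at the birth simplex.  Essential (infinite) classes are
    dropped: only features that both appear and disappear as the balls
    grow are of interest here.
    """
    simplices = sorted(filt, key=lambda s: (filt[s], len(s), s))
    index = {s: i for i, s in enumerate(simplices)}

    R: list[int] = []
    Vmat: list[int] = []
    low_owner: dict[int, int] = {}
    pairs: list[tuple[int, int]] = []

    for j, s in enumerate(simplices):
        r = 0
        if len(s) > 1:
            for i in range(len(s)):
                r |= 1 << index[s[:i] + s[i + 1:]]
        v = 1 << j
        while r:
            low = r.bit_length() - 1
            owner = low_owner.get(low)
            if owner is None:
                break
            r ^= R[owner]
            v ^= Vmat[owner]
        R.append(r)
        Vmat.append(v)
        if r:
            low_owner[r.bit_length() - 1] = j
            pairs.append((r.bit_length() - 1, j))

    intervals = []
    for birth_idx, death_idx in pairs:
        birth = filt[simplices[birth_idx]]
        death = filt[simplices[death_idx]]
        if death <= birth:
            continue
        dim = len(simplices[birth_idx]) - 1
        vertices = frozenset(
            v for k in _iter_bits(Vmat[birth_idx]) for v in simplices[k])
        intervals.append((dim, birth, death, vertices))
    return intervals


def persistence(
    coords: np.ndarray,
    max_dimension: int = 2,
    filtration: str = "alpha",
    scale: str = "radius",
    min_persistence: float = 1e-9,
) -> list[tuple[int, float, float, frozenset[int]]]:
    """Finite persistence intervals of a point cloud.

    Parameters
    ----------
    coords : (n, 3) array
    max_dimension : {1, 2}
        Highest homology dimension reported (1 = loops, 2 = voids).
    filtration : {"alpha", "rips"}
    scale : {"radius", "diameter"}
        Units of the reported birth/death values: ball radius (default) or
        ball diameter (= Rips edge length).
    min_persistence : float
        Intervals with lifespan at or below this are dropped.  Exact ties
        in filtration values (zero-persistence pairs) acquire lifespans of
        order machine epsilon under floating point; the default floor is
        far below any physical feature but above that round-off.

    Returns
    -------
    list of (dimension, birth, death, representative vertex indices),
    restricted to dimensions 1..max_dimension, sorted by (dimension,
    birth, death, vertices).
    """
    if max_dimension not in (1, 2):
        raise ValueError("max_dimension must be 1 or 2")
    if filtration == "alpha":
        filt = alpha_filtration(coords)
        factor = 1.0 if scale == "radius" else 2.0
    elif filtration == "rips":
        filt = rips_filtration(coords, max_dimension + 1)
        factor = 0.5 if scale == "radius" else 1.0
    else:
        raise ValueError(f"unknown filtration {filtration!r}")
    if scale not in ("radius", "diameter"):
        raise ValueError(f"unknown scale {scale!r}")

    out = [(dim, birth * factor, death * factor, verts)
           for dim, birth, death, verts in persistence_pairs(filt)
           if 1 <= dim <= max_dimension
           and (death - birth) * factor > min_persistence]
    out.sort(key=lambda iv: (iv[0], iv[1], iv[2], tuple(sorted(iv[3]))))
    return out
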