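"""Translation-separation test for chromosome intertwining.

Two chromosome backbones (polylines through the bead centers, rooted at
the chromocenter) are *non-intertwining* when a rigid translation of one
of them along some direction — swept over a span longer than the nucleus
diameter — never crosses the other.  A fixed set of unit vectors that
uniformly cover the sphere (vertices of a geodesic subdivision of the
icosahedron, 162 by default) is tested; the pair intertwines when every
tested direction produces a crossing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .params import ARM_IDS

__all__ = [
    "DirectionSet",
    "geodesic_directions",
    "backbone",
    "crosses_during_translation",
    "pair_intertwined",
    "ensemble_intertwine_fraction",
    "DEFAULT_SPAN",
]

#: Translation span in microns; longer than the default nucleus diameter.
DEFAULT_SPAN = 35.0


@dataclass(frozen=True)
class DirectionSet:
    vectors: np.ndarray  # (m, 3) unit vectors
    count: int

    def __post_init__(self):
        norms = np.linalg.norm(self.vectors, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-9):
            raise ValueError("direction vectors must be unit length")


def _icosahedron() -> tuple[np.ndarray, np.ndarray]:
    """Vertices and faces of the regular icosahedron."""
    phi = (1.0 + np.sqrt(5.0)) / 2.0
    verts = np.array(
        [
            [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
            [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
            [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
        ],
        dtype=float,
    )
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = np.array(
        [
            [0, 11, 5], [0, 5, 1], [0, 1, 7], [0, 7, 10], [0, 10, 11],
            [1, 5, 9], [5, 11, 4], [11, 10, 2], [10, 7, 6], [7, 1, 8],
            [3, 9, 4], [3, 4, 2], [3, 2, 6], [3, 6, 8], [3, 8, 9],
            [4, 9, 5], [2, 4, 11], [6, 2, 10], [8, 6, 7], [9, 8, 1],
        ]
    )
    return verts, faces


def geodesic_directions(count: int = 162) -> DirectionSet:
    """Unit vectors uniformly covering the sphere.

    Vertices of a frequency-``f`` geodesic subdivision of the icosahedron,
    which has ``10 f^2 + 2`` vertices (f=4 gives the default 162).  When
    ``count`` is not of that form the nearest lower geodesic size is used
    with a warning.
    """
    if count < 12:
        raise ValueError("count must be at least 12 (icosahedron vertices)")
    f = int(np.sqrt((count - 2) / 10.0))
    if 10 * f * f + 2 != count:
        warnings.warn(
            f"count {count} is not a geodesic size 10 f^2 + 2; using {10 * f * f + 2}",
            stacklevel=2,
        )
    verts, faces = _icosahedron()
    pts = []
    for a, b, c in faces:
        va, vb, vc = verts[a], verts[b], verts[c]
        for i in range(f + 1):
            for j in range(f + 1 - i):
                k = f - i - j
                p = (i * va + j * vb + k * vc) / f
                pts.append(p / np.linalg.norm(p))
    pts = np.asarray(pts)
    # deduplicate shared edges/vertices between faces
    key = np.round(pts, 9)
    _, idx = np.unique(key, axis=0, return_index=True)
    vectors = pts[np.sort(idx)]
    return DirectionSet(vectors=vectors, count=len(vectors))


def backbone(nucleus, arm_id: str) -> np.ndarray:
    """Backbone polyline of one arm: chromocenter center followed by the
    bead centers."""
    return np.vstack([nucleus.chromocenter, nucleus.chains[arm_id]])


def _seg_box_crossing_2d(p0, p1, smax: float, tmin: float, tmax: float, tol: float) -> bool:
    """Does the 2D segment p0->p1 meet the box [0,smax] x [tmin,tmax]?
    Liang-Barsky clipping."""
    d = (p1[0] - p0[0], p1[1] - p0[1])
    t0, t1 = 0.0, 1.0
    for coord, dlt, lo, hi in (
        (p0[0], d[0], 0.0, smax),
        (p0[1], d[1], tmin, tmax),
    ):
        if abs(dlt) < tol:
            if coord < lo - tol or coord > hi + tol:
                return False
            continue
        ta = (lo - coord) / dlt
        tb = (hi - coord) / dlt
        if ta > tb:
            ta, tb = tb, ta
        t0 = max(t0, ta)
        t1 = min(t1, tb)
        if t0 > t1 + tol:
            return False
    return True


def _degenerate_pair_crosses(p, u, q, v, d, span: float, tol: float) -> bool:
    """Coplanar / rank-deficient fallback for one segment pair.

    The sweep of segment (p, p+u) along d over [0, span] is the
    parallelogram {p + s u + t d}; in (s, t) coordinates it is the box
    [0,1] x [0,span].
    """
    n = np.cross(u, d)
    nn = np.linalg.norm(n)
    if nn < tol:
        # u parallel to d (or zero): the sweep degenerates to a segment
        # along the common line from p to p + u + span d
        a0, a1 = p, p + u + span * d
        return _segments_min_dist(a0, a1, q, q + v) <= tol
    n = n / nn
    g0 = float(np.dot(q - p, n))
    g1 = float(np.dot(q + v - p, n))
    if abs(g0) > tol or abs(g1) > tol:
        # v is parallel to the sweep plane (that is what made the system
        # singular); off-plane segments cannot touch it
        return False
    # in-plane: express endpoints in (s, t) coordinates via least squares
    basis = np.stack([u, d], axis=1)
    st0, *_ = np.linalg.lstsq(basis, q - p, rcond=None)
    st1, *_ = np.linalg.lstsq(basis, q + v - p, rcond=None)
    return _seg_box_crossing_2d(st0, st1, 1.0, 1e-7, span, tol)


def _segments_min_dist(a0, a1, b0, b1) -> float:
    """Minimum distance between two 3D segments (scalar, robust)."""
    u = a1 - a0
    v = b1 - b0
    w = a0 - b0
    a = np.dot(u, u)
    b = np.dot(u, v)
    c = np.dot(v, v)
    d = np.dot(u, w)
    e = np.dot(v, w)
    den = a * c - b * b
    if den > 1e-14:
        s = np.clip((b * e - c * d) / den, 0.0, 1.0)
    else:
        s = 0.0
    t = (b * s + e) / c if c > 1e-14 else 0.0
    t = np.clip(t, 0.0, 1.0)
    s = np.clip((b * t - d) / a, 0.0, 1.0) if a > 1e-14 else 0.0
    return float(np.linalg.norm(a0 + s * u - (b0 + t * v)))


def crosses_during_translation(
    a: np.ndarray,
    b: np.ndarray,
    direction: np.ndarray,
    span: float = DEFAULT_SPAN,
    tol: float = 1e-9,
) -> bool:
    """Whether backbone ``a`` crosses backbone ``b`` while translated
    rigidly along ``direction`` over [0, span].

    Each segment pair is solved exactly: ``a_i(s) + t d = b_j(w)`` is a
    3x3 linear system in (s, t, w), a crossing being a solution inside
    [0,1] x (0,span] x [0,1].  The translation interval is open at zero:
    backbones of one nucleus share the chromocenter root point, and that
    initial contact is not a topological obstruction — only contacts met
    strictly during the translation count as crossings.  Rank-deficient
    systems fall back to a coplanar sweep test.
    """
    if span <= 0:
        raise ValueError("span must be positive")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    d = np.asarray(direction, dtype=float)
    P, U = a[:-1], np.diff(a, axis=0)
    Q, V = b[:-1], np.diff(b, axis=0)
    # Cramer solution of  s U + t d - w V = Q - P  for all segment pairs
    dxv = np.cross(d[None, :], V)  # (nb, 3)
    det = -np.einsum("id,jd->ij", U, dxv)  # (na, nb)
    r = Q[None, :, :] - P[:, None, :]  # (na, nb, 3)
    s_num = -np.einsum("ijd,jd->ij", r, dxv)
    rxv = np.cross(r, V[None, :, :])
    t_num = -np.einsum("id,ijd->ij", U, rxv)
    dxr = np.cross(d[None, None, :], r)
    w_num = np.einsum("id,ijd->ij", U, dxr)
    ok = np.abs(det) > tol
    with np.errstate(divide="ignore", invalid="ignore"):
        s = s_num / det
        t = t_num / det
        w = w_num / det
    t_open = 1e-7  # excludes the shared-root contact at t = 0
    hit = (
        ok
        & (s >= -tol)
        & (s <= 1.0 + tol)
        & (t >= t_open)
        & (t <= span + tol)
        & (w >= -tol)
        & (w <= 1.0 + tol)
    )
    if hit.any():
        return True
    # rank-deficient pairs need the coplanar fallback
    deg = ~ok
    if deg.any():
        for i, j in zip(*np.nonzero(deg)):
            if _degenerate_pair_crosses(P[i], U[i], Q[j], V[j], d, span, tol):
                return True
    return False


def pair_intertwined(
    a: np.ndarray,
    b: np.ndarray,
    dirs: DirectionSet,
    span: float = DEFAULT_SPAN,
) -> bool:
    """Whether two backbones intertwine: no tested translation direction
    separates them without crossing.

    Directions most aligned with the centroid offset (moving ``a`` away
    from ``b``) are tried first; the verdict does not depend on the order.
    """
    ca = np.asarray(a, float).mean(axis=0)
    cb = np.asarray(b, float).mean(axis=0)
    away = ca - cb
    order = np.argsort(-(dirs.vectors @ away))
    for idx in order:
        if not crosses_during_translation(a, b, dirs.vectors[idx], span):
            return False
    return True


def ensemble_intertwine_fraction(
    ensemble,
    dirs: DirectionSet | None = None,
    span: float = DEFAULT_SPAN,
) -> float:
    """Fraction of within-nucleus arm pairs (10 per nucleus) that
    intertwine."""
    if dirs is None:
        dirs = geodesic_directions(162)
    if not ensemble.nuclei:
        raise ValueError("empty ensemble")
    n_pairs = 0
    n_twined = 0
    for nuc in ensemble.nuclei:
        backbones = {arm: backbone(nuc, arm) for arm in ARM_IDS}
        for x, y in combinations(ARM_IDS, 2):
            n_pairs += 1
            if pair_intertwined(backbones[x], backbones[y], dirs, span):
                n_twined += 1
    return n_twined / n_pairs
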