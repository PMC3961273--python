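"""Convex-hull chromosome territories.

The territory index of an arm is the fraction of all chain bead centers
inside the arm's own convex hull that belong to that arm: 1 for a fully
territorial chromosome, and at worst (arm bead count / capacity of the
largest achievable hull) for a fully anti-territorial one.  The largest
achievable hull under spherical confinement is found with a pivot
optimizer: random rigid rotations of chain suffixes, accepted only when
they keep the chain valid and strictly increase the hull volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.transform import Rotation

from .nucleus import GeometryError, NucleusModel
from .params import ARM_IDS, ModelParams
from .saw import grow_single_chain

__all__ = [
    "TerritoryIndex",
    "MaxHullResult",
    "points_in_hull",
    "territory_index",
    "nucleus_territory_indices",
    "ensemble_mean_territory_index",
    "maximize_hull",
    "min_territory_index",
]


@dataclass(frozen=True)
class TerritoryIndex:
    arm_id: str
    own_points_inside: int
    total_points_inside: int
    index: float


@dataclass(frozen=True)
class MaxHullResult:
    arm_id: str
    v_max: float  # um^3
    n_max: int  # bead capacity of the maximal hull
    min_index: float
    iterations: int
    converged: bool
    volume_history: tuple = ()  # accepted hull volumes, strictly increasing


def points_in_hull(points: np.ndarray, hull: ConvexHull, tol: float = 1e-9) -> np.ndarray:
    """Boolean mask of points inside or on the hull (facet half-spaces)."""
    points = np.asarray(points, dtype=float)
    # hull.equations rows are (normal, offset) with normal . x + offset <= 0 inside
    values = points @ hull.equations[:, :-1].T + hull.equations[:, -1]
    return (values <= tol).all(axis=1)


def territory_index(nucleus: NucleusModel, arm_id: str, tol: float = 1e-9) -> TerritoryIndex:
    """Territory index of one arm of one nucleus.

    Builds the convex hull of the arm's bead centers and counts all chain
    bead centers (chromocenter excluded) inside or on it.
    """
    own = np.asarray(nucleus.chains[arm_id], dtype=float)
    try:
        hull = ConvexHull(own)
    except QhullError as err:
        raise GeometryError(
            f"arm {arm_id}: degenerate (coplanar or collinear) chain, no 3D hull"
        ) from err
    beads = nucleus.all_beads()
    inside = points_in_hull(beads, hull, tol)
    arm_mask = nucleus.bead_arm_index() == ARM_IDS.index(arm_id)
    own_inside = int((inside & arm_mask).sum())
    total_inside = int(inside.sum())
    return TerritoryIndex(
        arm_id=arm_id,
        own_points_inside=own_inside,
        total_points_inside=total_inside,
        index=own_inside / total_inside,
    )


def nucleus_territory_indices(nucleus: NucleusModel) -> dict[str, TerritoryIndex]:
    return {a: territory_index(nucleus, a) for a in ARM_IDS}


def ensemble_mean_territory_index(ensemble) -> float:
    """Mean territory index over all arms and nuclei of an ensemble."""
    vals = [
        territory_index(nuc, a).index for nuc in ensemble.nuclei for a in ARM_IDS
    ]
    return float(np.mean(vals))


def maximize_hull(
    arm_id: str,
    params: ModelParams,
    confined: bool = True,
    rng=None,
    window: int = 5000,
    max_proposals: int = 200_000,
) -> MaxHullResult:
    """Largest convex-hull volume reachable by one arm.

    Pivot optimization: pick a random bead, rigidly rotate the downstream
    sub-chain by a uniformly random rotation, reject the move if it leaves
    the confinement sphere (when ``confined``), violates self-avoidance,
    or does not strictly increase the hull volume.  Convergence is declared
    after ``window`` consecutive proposals without an accepted move.

    The bead capacity ``n_max`` follows the volume argument: if the
    maximal hull volume exceeds the total excluded volume of all chain
    beads, the hull can accommodate every bead in the model.
    """
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = params.arm_count(arm_id)
    if n < 4:
        raise GeometryError(f"arm {arm_id}: need >= 4 beads for a 3D hull")
    r_b = params.bead_radius
    confine = params.nucleus_radius if confined else None
    pos = grow_single_chain(
        n,
        params,
        rng,
        with_cylinder=False,
        confine_radius=confine,
    )
    best = ConvexHull(pos).volume
    history = [best]
    min_d2 = (2.0 * r_b - 1e-9) ** 2
    lim = (params.nucleus_radius - r_b + 1e-9) if confined else None
    since_accept = 0
    proposals = 0
    while since_accept < window and proposals < max_proposals:
        proposals += 1
        since_accept += 1
        j = int(rng.integers(1, n - 1))
        rot = Rotation.random(random_state=rng)
        pivot = pos[j]
        new_suffix = (pos[j + 1 :] - pivot) @ rot.as_matrix().T + pivot
        if confined and np.linalg.norm(new_suffix, axis=1).max() > lim:
            continue
        # self-avoidance: suffix vs prefix (intra-suffix distances are rigid);
        # the bond (j, j+1) is preserved by the rotation and exempt
        prefix = pos[: j + 1]
        d2 = ((new_suffix[:, None, :] - prefix[None, :, :]) ** 2).sum(-1)
        d2[0, j] = np.inf
        if d2.min() < min_d2:
            continue
        trial = np.concatenate([pos[: j + 1], new_suffix])
        try:
            vol = ConvexHull(trial).volume
        except QhullError:
            continue
        if vol > best:
            pos = trial
            best = vol
            history.append(vol)
            since_accept = 0
    bead_vol = 4.0 / 3.0 * math.pi * r_b**3
    total = params.total_beads
    if best >= total * bead_vol:
        n_max = total
    else:
        n_max = min(total, int(best // bead_vol))
    return MaxHullResult(
        arm_id=arm_id,
        v_max=float(best),
        n_max=n_max,
        min_index=n / n_max,
        iterations=proposals,
        converged=since_accept >= window,
        volume_history=tuple(history),
    )


def min_territory_index(arm_id: str, params: ModelParams, hull: MaxHullResult) -> float:
    """Minimum territory index of an arm: its bead count over the bead
    capacity of the maximal confined hull."""
    return params.arm_count(arm_id) / hull.n_max
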