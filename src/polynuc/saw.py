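"""Growth of one model nucleus.

The nucleus is built as in the experimentally observed configuration: the
chromocenter bead is placed touching the nuclear envelope (NE) at the north
pole, five initial beads are placed around it (touching both the
chromocenter and the NE, in a sampled circular arrangement), and the five
arms then grow simultaneously as self-avoiding walks with excluded volume
(bead spheres and connector cylinders), spherical confinement, a 2:1
right-handed chirality acceptance bias, and two-level backtracking to
escape dead ends.
"""

from __future__ import annotations

import math
from typing import Mapping

import numpy as np

from . import _growth_core
from .nucleus import GeometryError, GrowthError, NucleusModel
from .params import ARM_IDS, ModelParams, params_digest

__all__ = [
    "sample_arrangement",
    "place_initial_beads",
    "chirality_sign",
    "chirality_signs_along",
    "step_is_valid",
    "grow_nucleus",
    "validate_nucleus",
    "grow_single_chain",
]


def _as_rng(rng) -> np.random.Generator:
    if isinstance(rng, np.random.Generator):
        return rng
    return np.random.default_rng(rng)


def sample_arrangement(weights: Mapping[str, float], rng) -> str:
    """Draw an arrangement id with probability proportional to its weight."""
    rng = _as_rng(rng)
    ids = sorted(weights)
    w = np.array([float(weights[a]) for a in ids])
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("arrangement weights must be nonnegative and not all zero")
    return str(rng.choice(ids, p=w / w.sum()))


def place_initial_beads(arrangement_id: str, params: ModelParams, rng) -> np.ndarray:
    """Centers of the five initial beads, in canonical ``ARM_IDS`` order.

    Each bead touches both the chromocenter surface and the NE, which
    restricts its center to a circle around the polar axis; the angular
    order of the arms on that circle realizes ``arrangement_id`` (up to the
    rotations/reflections that define the arrangement class).
    """
    rng = _as_rng(rng)
    R = params.nucleus_radius
    r_b = params.bead_radius
    cc = np.asarray(params.chromocenter_position)
    zc = np.linalg.norm(cc)
    rc = R - r_b  # shell of bead centers touching the NE
    d = params.chromocenter_radius + r_b  # touch distance to the chromocenter
    # intersection circle of |p| = rc with |p - cc| = d
    pz = (rc**2 + zc**2 - d**2) / (2.0 * zc)
    rho2 = rc**2 - pz**2
    if rho2 <= 0:
        raise GeometryError(
            "no circle of centers touching both chromocenter and NE exists "
            f"(R={R:.3f}, bead_radius={r_b}, chromocenter_radius={params.chromocenter_radius})"
        )
    rho = math.sqrt(rho2)
    # equal spacing gives the largest minimum chord; if even that overlaps,
    # five touching beads cannot fit on the contact circle
    if 2.0 * rho * math.sin(math.pi / 5.0) < 2.0 * r_b - 1e-9:
        raise GeometryError(
            "five initial beads cannot fit on the chromocenter contact circle "
            f"(circle radius {rho:.3f} um, bead radius {r_b} um)"
        )
    seq = arrangement_id.split("-")
    if sorted(seq) != sorted(ARM_IDS):
        raise ValueError(f"malformed arrangement id {arrangement_id!r}")
    # minimum angular gap so that neighbouring beads on the circle clear
    # each other (their 3D distance equals the chord)
    gap_min = 2.0 * math.asin(min(1.0, r_b / rho))
    slack = 2.0 * math.pi - 5.0 * gap_min
    if slack < 0:
        raise GeometryError(
            "five initial beads cannot fit on the chromocenter contact circle"
        )
    for _ in range(1000):
        # exact conditional law of five uniform angles given the minimum
        # spacing: minimum gaps plus Dirichlet-distributed slack
        extra = rng.dirichlet(np.ones(5)) * slack
        gaps = gap_min + extra
        offset = rng.uniform(0.0, 2.0 * math.pi)
        angles = offset + np.concatenate([[0.0], np.cumsum(gaps[:-1])])
        direction = 1 if rng.random() < 0.5 else -1
        slot = {seq[i]: angles[(direction * i) % 5] for i in range(5)}
        centers = np.array(
            [[rho * math.cos(slot[a]), rho * math.sin(slot[a]), pz] for a in ARM_IDS]
        )
        if params.nucleolus_enabled:
            npos = np.asarray(params.nucleolus_position)
            lim = (params.nucleolus_radius + r_b - 1e-9) ** 2
            if (((centers - npos) ** 2).sum(-1) < lim).any():
                continue
        return centers
    raise GeometryError("could not place five initial beads clear of the nucleolus")


def chirality_sign(p0, p1, p2, p3) -> int:
    """Sign of the scalar triple product of three consecutive bond vectors.

    +1 denotes a right-handed local twist, -1 left-handed, 0 degenerate
    (collinear or coplanar within tolerance).
    """
    p0, p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p0, p1, p2, p3))
    a, b, c = p1 - p0, p2 - p1, p3 - p2
    t = float(np.dot(np.cross(a, b), c))
    scale = max(np.linalg.norm(a) * np.linalg.norm(b) * np.linalg.norm(c), 1.0)
    if abs(t) <= 1e-12 * scale:
        return 0
    return 1 if t > 0 else -1


def chirality_signs_along(chain: np.ndarray) -> np.ndarray:
    """Chirality signs of every consecutive 4-bead window of a chain."""
    chain = np.asarray(chain, dtype=float)
    if len(chain) < 4:
        return np.zeros(0, dtype=np.int64)
    v = np.diff(chain, axis=0)
    t = np.einsum("ij,ij->i", np.cross(v[:-2], v[1:-1]), v[2:])
    scale = np.maximum(
        np.linalg.norm(v[:-2], axis=1)
        * np.linalg.norm(v[1:-1], axis=1)
        * np.linalg.norm(v[2:], axis=1),
        1.0,
    )
    out = np.sign(t).astype(np.int64)
    out[np.abs(t) <= 1e-12 * scale] = 0
    return out


def _collision_segment(a: np.ndarray, b: np.ndarray, shrink: float):
    """Connector collision segment, trimmed by ``shrink`` of the bond at
    both ends (0 = full center-to-center span)."""
    u = b - a
    return a + shrink * u, b - shrink * u


def _point_segments_dist(p: np.ndarray, seg_a: np.ndarray, seg_b: np.ndarray) -> np.ndarray:
    """Distances from point ``p`` to each segment (vectorized)."""
    u = seg_b - seg_a
    denom = np.einsum("ij,ij->i", u, u)
    denom = np.where(denom <= 0, 1.0, denom)
    t = np.clip(np.einsum("ij,ij->i", p - seg_a, u) / denom, 0.0, 1.0)
    closest = seg_a + t[:, None] * u
    return np.linalg.norm(p - closest, axis=1)


def step_is_valid(
    chains: Mapping[str, np.ndarray],
    arm_id: str,
    candidate,
    params: ModelParams,
) -> bool:
    """Whether a candidate bead at the arm's tip satisfies all constraints.

    Checks confinement, sphere-sphere clearance to every non-adjacent bead
    and the chromocenter, the configured cylinder collision rule against
    every non-incident connector, clearance of existing beads to the
    would-be new connector, and (if enabled) clearance to the nucleolus.
    Pure numpy; the growth engine applies the same rules in its compiled
    inner loop.
    """
    c = np.asarray(candidate, dtype=float)
    R, r_b = params.nucleus_radius, params.bead_radius
    cyl_clear = params.cylinder_clearance
    shrink = params.cylinder_segment_shrink
    tol = _growth_core.TOL
    if np.linalg.norm(c) > R - r_b + tol:
        return False
    cc = np.asarray(params.chromocenter_position)
    if np.linalg.norm(c - cc) < params.chromocenter_radius + r_b - tol:
        return False
    if params.nucleolus_enabled:
        npos = np.asarray(params.nucleolus_position)
        if np.linalg.norm(c - npos) < params.nucleolus_radius + r_b - tol:
            return False
    tip = np.asarray(chains[arm_id][-1], dtype=float)
    do_cyl = cyl_clear > 0.0
    for arm, beads in chains.items():
        beads = np.asarray(beads, dtype=float)
        others = beads[:-1] if arm == arm_id else beads
        if len(others) and np.linalg.norm(others - c, axis=1).min() < 2.0 * r_b - tol:
            return False
        if not do_cyl or len(beads) < 2:
            continue
        ga, gb = _collision_segment(beads[:-1], beads[1:], shrink)
        if _point_segments_dist(c, ga, gb).min() < cyl_clear - tol:
            return False
    if do_cyl:
        na, nb = _collision_segment(tip[None, :], c[None, :], shrink)
        u = nb[0] - na[0]
        uu = float(np.dot(u, u))
        for arm, beads in chains.items():
            beads = np.asarray(beads, dtype=float)
            others = beads[:-1] if arm == arm_id else beads
            for p in others:
                t = np.clip(np.dot(p - na[0], u) / uu, 0.0, 1.0)
                if np.linalg.norm(p - (na[0] + t * u)) < cyl_clear - tol:
                    return False
    return True


def grow_nucleus(params: ModelParams, rng, nucleus_id: str = "") -> NucleusModel:
    """Grow one complete nucleus honoring all model constraints."""
    rng = _as_rng(rng)
    arrangement = sample_arrangement(params.arrangement_weights, rng)
    init = place_initial_beads(arrangement, params, rng)
    arm_n = np.array([params.arm_count(a) for a in ARM_IDS], dtype=np.int64)
    nmax = int(arm_n.max())
    pos = np.zeros((5, nmax, 3), dtype=np.float64)
    pos[:, 0, :] = init
    k = np.ones(5, dtype=np.int64)
    cc = params.chromocenter_position
    core_seed = int(rng.integers(1, 2**31 - 1))
    status, proposals, n_bt1, n_bt2 = _growth_core.grow_core(
        pos,
        k,
        arm_n,
        float(params.nucleus_radius),
        float(params.bead_radius),
        float(params.cylinder_clearance),
        float(params.cylinder_segment_shrink),
        float(params.bond_length),
        float(cc[0]),
        float(cc[1]),
        float(cc[2]),
        float(params.chromocenter_radius),
        float(params.chirality_right_accept),
        float(params.chirality_left_accept),
        int(params.bt1),
        int(params.bt2),
        {"lockstep": 0, "independent": 1, "joint": 2}[params.growth_mode],
        bool(params.reset_counters_on_accept),
        bool(params.count_failures_per_candidate),
        int(params.proposal_cap),
        bool(params.nucleolus_enabled),
        float(params.nucleolus_position[0]),
        float(params.nucleolus_position[1]),
        float(params.nucleolus_position[2]),
        float(params.nucleolus_radius),
        core_seed,
    )
    if status != _growth_core.STATUS_OK:
        raise GrowthError(
            f"growth aborted after {proposals} proposals (cap {params.proposal_cap}); "
            "the configuration may be too dense for the backtracking settings"
        )
    chains = {a: pos[i, : arm_n[i]].copy() for i, a in enumerate(ARM_IDS)}
    return NucleusModel(
        params_digest=params_digest(params),
        chromocenter=np.asarray(cc, dtype=float),
        arrangement_id=arrangement,
        chains=chains,
        rng_seed=core_seed,
        nucleus_id=nucleus_id,
    )


# ---------------------------------------------------------------------------
# independent post-hoc validator (separate code path from the growth checks)
# ---------------------------------------------------------------------------


def validate_nucleus(nucleus: NucleusModel, params: ModelParams, tol: float = 1e-6) -> list[str]:
    """All-pairs geometric audit of a finished nucleus.

    Returns a list of violation descriptions (empty when the nucleus is
    valid).  Uses brute-force pairwise distance matrices rather than the
    incremental checks of the growth engine.
    """
    from scipy.spatial.distance import cdist

    violations: list[str] = []
    R, r_b = params.nucleus_radius, params.bead_radius
    bond = params.bond_length
    cyl_clear = params.cylinder_clearance
    shrink = params.cylinder_segment_shrink
    beads = nucleus.all_beads()
    arm_idx = nucleus.bead_arm_index()
    pos_in_arm = np.concatenate(
        [np.arange(len(nucleus.chains[a])) for a in ARM_IDS]
    )
    for i, a in enumerate(ARM_IDS):
        if len(nucleus.chains[a]) != params.arm_count(a):
            violations.append(f"arm {a}: has {len(nucleus.chains[a])} beads, expected {params.arm_count(a)}")
    # bond lengths; the tolerance admits coordinates round-tripped through
    # the 1e-6 um trace format
    bond_tol = max(1e-9 * bond, 4e-6)
    for a in ARM_IDS:
        c = nucleus.chains[a]
        if len(c) > 1:
            lengths = np.linalg.norm(np.diff(c, axis=0), axis=1)
            bad = np.abs(lengths - bond) > bond_tol
            if bad.any():
                violations.append(f"arm {a}: {int(bad.sum())} bonds deviate from bond_length")
    # confinement
    radii = np.linalg.norm(beads, axis=1)
    n_out = int((radii > R - r_b + tol).sum())
    if n_out:
        violations.append(f"{n_out} beads outside the confinement shell")
    # chromocenter clearance
    cc = np.asarray(nucleus.chromocenter)
    d_cc = np.linalg.norm(beads - cc, axis=1)
    n_cc = int((d_cc < params.chromocenter_radius + r_b - tol).sum())
    if n_cc:
        violations.append(f"{n_cc} beads overlap the chromocenter")
    # pairwise bead clearance (non-adjacent: not consecutive on the same arm)
    d = cdist(beads, beads)
    same_arm = arm_idx[:, None] == arm_idx[None, :]
    consecutive = same_arm & (np.abs(pos_in_arm[:, None] - pos_in_arm[None, :]) == 1)
    np.fill_diagonal(d, np.inf)
    d[consecutive] = np.inf
    n_overlap = int((d < 2 * r_b - tol).sum() // 2)
    if n_overlap:
        violations.append(f"{n_overlap} non-adjacent bead pairs overlap")
    # beads vs non-adjacent connector cylinders (configured collision rule)
    if cyl_clear > 0.0:
        for a in ARM_IDS:
            starts, ends = nucleus.segments(a)
            if not len(starts):
                continue
            ga = starts + shrink * (ends - starts)
            gb = ends - shrink * (ends - starts)
            u = gb - ga
            denom = np.einsum("ij,ij->i", u, u)
            for j, (p, ai, pia) in enumerate(zip(beads, arm_idx, pos_in_arm)):
                if ARM_IDS[ai] == a:
                    # skip the two connectors this bead is an endpoint of
                    mask = np.ones(len(ga), bool)
                    if pia < len(ga):
                        mask[pia] = False
                    if pia - 1 >= 0:
                        mask[pia - 1] = False
                else:
                    mask = np.ones(len(ga), bool)
                if not mask.any():
                    continue
                t = np.clip(np.einsum("ij,ij->i", p[None, :] - ga, u) / denom, 0.0, 1.0)
                dist = np.linalg.norm(p - (ga + t[:, None] * u), axis=1)
                if dist[mask].min() < cyl_clear - tol:
                    violations.append(
                        f"bead {pia} of arm {ARM_IDS[ai]} overlaps a connector of arm {a}"
                    )
    return violations


# ---------------------------------------------------------------------------
# single free (optionally confined) chain, used by scaling and hull modules
# ---------------------------------------------------------------------------


def grow_single_chain(
    n_beads: int,
    params: ModelParams,
    rng,
    *,
    with_cylinder: bool = True,
    phantom: bool = False,
    confine_radius: float | None = None,
    start=None,
    backtrack_after: int = 500,
    proposal_cap: int = 2_000_000,
) -> np.ndarray:
    """Grow a single bead chain with the model's excluded volume rules.

    Unconfined by default (``confine_radius=None``); no chirality bias.
    ``phantom=True`` disables all excluded volume (ideal chain).  Returns an
    ``(n_beads, 3)`` array of centers.
    """
    if n_beads < 1:
        raise ValueError("n_beads must be >= 1")
    rng = _as_rng(rng)
    bond, r_b = params.bond_length, params.bead_radius
    cyl_clear = params.cylinder_clearance
    shrink = params.cylinder_segment_shrink
    if start is None:
        start = np.zeros(3)
    pos = np.zeros((n_beads, 3))
    pos[0] = start
    if n_beads == 1:
        return pos
    k = 1
    fails = 0
    proposals = 0
    do_cyl = with_cylinder and cyl_clear > 0.0 and not phantom
    while k < n_beads:
        proposals += 1
        if proposals > proposal_cap:
            raise GrowthError(f"single-chain growth aborted after {proposals} proposals")
        d = rng.standard_normal(3)
        norm = np.linalg.norm(d)
        if norm < 1e-9:
            continue
        c = pos[k - 1] + d * (bond / norm)
        ok = True
        if confine_radius is not None and np.linalg.norm(c) > confine_radius - r_b + 1e-9:
            ok = False
        if ok and not phantom and k > 1:
            if np.linalg.norm(pos[: k - 1] - c, axis=1).min() < 2 * r_b - 1e-9:
                ok = False
        if ok and do_cyl and k > 1:
            ga, gb = _collision_segment(pos[: k - 1], pos[1:k], shrink)
            if _point_segments_dist(c, ga, gb).min() < cyl_clear - 1e-9:
                ok = False
            if ok:
                na, nb_ = _collision_segment(pos[k - 1][None, :], c[None, :], shrink)
                u = nb_[0] - na[0]
                uu = np.dot(u, u)
                t = np.clip((pos[: k - 1] - na[0]) @ u / uu, 0.0, 1.0)
                dist = np.linalg.norm(pos[: k - 1] - (na[0] + t[:, None] * u), axis=1)
                if dist.min() < cyl_clear - 1e-9:
                    ok = False
        if ok:
            pos[k] = c
            k += 1
            fails = 0
        else:
            fails += 1
            if fails >= backtrack_after:
                if k > 1:
                    k -= 1
                fails = 0
    return pos
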