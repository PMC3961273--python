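"""Numba inner loop for simultaneous five-arm constrained chain growth.

Everything here operates on flat float64 arrays; the public API lives in
:mod:`polynuc.saw`.  The connector-cylinder collision rule is configurable
through ``cyl_clear`` (required bead-center-to-axis distance) and
``cyl_shrink`` (fraction of the bond trimmed from each connector end), so
both the center-exclusion and the surface-exclusion readings of the
cylinder excluded volume are available.
"""

import numpy as np
from numba import njit

# clearance slack so exactly-touching configurations (initial beads on the
# chromocenter, beads on the envelope) are accepted despite float rounding
TOL = 1e-7

STATUS_OK = 0
STATUS_CAP = 1


@njit(cache=True, inline="always")
def _dist2(ax, ay, az, bx, by, bz):
    dx = ax - bx
    dy = ay - by
    dz = az - bz
    return dx * dx + dy * dy + dz * dz


@njit(cache=True, inline="always")
def _point_seg_dist2(px, py, pz, ax, ay, az, bx, by, bz):
    ux = bx - ax
    uy = by - ay
    uz = bz - az
    denom = ux * ux + uy * uy + uz * uz
    if denom <= 0.0:
        return _dist2(px, py, pz, ax, ay, az)
    t = ((px - ax) * ux + (py - ay) * uy + (pz - az) * uz) / denom
    if t < 0.0:
        t = 0.0
    elif t > 1.0:
        t = 1.0
    return _dist2(px, py, pz, ax + t * ux, ay + t * uy, az + t * uz)


@njit(cache=True, inline="always")
def _chir_sign(p0x, p0y, p0z, p1x, p1y, p1z, p2x, p2y, p2z, p3x, p3y, p3z):
    """Sign of (p1-p0) x (p2-p1) . (p3-p2); +1 right-handed, 0 degenerate."""
    ax = p1x - p0x
    ay = p1y - p0y
    az = p1z - p0z
    bx = p2x - p1x
    by = p2y - p1y
    bz = p2z - p1z
    cx = p3x - p2x
    cy = p3y - p2y
    cz = p3z - p2z
    t = (ay * bz - az * by) * cx + (az * bx - ax * bz) * cy + (ax * by - ay * bx) * cz
    if t > 1e-12:
        return 1
    if t < -1e-12:
        return -1
    return 0


@njit(cache=True)
def _candidate_ok(
    pos,
    k,
    a_idx,
    cx,
    cy,
    cz,
    tipx,
    tipy,
    tipz,
    R,
    r_b,
    cyl_clear,
    ccx,
    ccy,
    ccz,
    r_cc,
    shrink,
    nuc_on,
    nx,
    ny,
    nz,
    nr,
):
    """Geometric validity of one candidate bead against the placed beads.

    ``cyl_clear`` is the required bead-center-to-connector-axis distance
    (<= 0 disables cylinder checks); ``shrink`` trims each connector
    segment by that fraction of the bond at both ends (0 = full
    center-to-center span).
    """
    lim = R - r_b + TOL
    if cx * cx + cy * cy + cz * cz > lim * lim:
        return False
    dcc = r_cc + r_b - TOL
    if _dist2(cx, cy, cz, ccx, ccy, ccz) < dcc * dcc:
        return False
    if nuc_on:
        dn = nr + r_b - TOL
        if _dist2(cx, cy, cz, nx, ny, nz) < dn * dn:
            return False
    min_bead2 = (2.0 * r_b - TOL) ** 2
    min_cyl2 = (cyl_clear - TOL) ** 2
    do_cyl = cyl_clear > 0.0 and shrink < 0.5
    s0 = shrink
    s1 = 1.0 - shrink
    for b in range(5):
        kb = k[b]
        for i in range(kb):
            if b == a_idx and i == kb - 1:
                continue  # the bonded tip is adjacent to the candidate
            if _dist2(cx, cy, cz, pos[b, i, 0], pos[b, i, 1], pos[b, i, 2]) < min_bead2:
                return False
        if not do_cyl:
            continue
        for i in range(kb - 1):
            ax = pos[b, i, 0]
            ay = pos[b, i, 1]
            az = pos[b, i, 2]
            bx = pos[b, i + 1, 0]
            by = pos[b, i + 1, 1]
            bz = pos[b, i + 1, 2]
            gax = ax + (bx - ax) * s0
            gay = ay + (by - ay) * s0
            gaz = az + (bz - az) * s0
            gbx = ax + (bx - ax) * s1
            gby = ay + (by - ay) * s1
            gbz = az + (bz - az) * s1
            if _point_seg_dist2(cx, cy, cz, gax, gay, gaz, gbx, gby, gbz) < min_cyl2:
                return False
        # existing beads against the new connector (tip -> candidate)
        gax = tipx + (cx - tipx) * s0
        gay = tipy + (cy - tipy) * s0
        gaz = tipz + (cz - tipz) * s0
        gbx = tipx + (cx - tipx) * s1
        gby = tipy + (cy - tipy) * s1
        gbz = tipz + (cz - tipz) * s1
        for i in range(kb):
            if b == a_idx and i == kb - 1:
                continue
            if (
                _point_seg_dist2(
                    pos[b, i, 0], pos[b, i, 1], pos[b, i, 2], gax, gay, gaz, gbx, gby, gbz
                )
                < min_cyl2
            ):
                return False
    return True


@njit(cache=True)
def _cross_candidate_ok(cand, cand_ok, a_idx, cx, cy, cz, tips, r_b, cyl_clear, shrink):
    """Candidate against the candidates already accepted this round."""
    min_bead2 = (2.0 * r_b - TOL) ** 2
    min_cyl2 = (cyl_clear - TOL) ** 2
    do_cyl = cyl_clear > 0.0 and shrink < 0.5
    s0 = shrink
    s1 = 1.0 - shrink
    for b in range(5):
        if b == a_idx or cand_ok[b] == 0:
            continue
        ox = cand[b, 0]
        oy = cand[b, 1]
        oz = cand[b, 2]
        if _dist2(cx, cy, cz, ox, oy, oz) < min_bead2:
            return False
        if not do_cyl:
            continue
        # this candidate's bead vs the other candidate's new connector
        tx = tips[b, 0]
        ty = tips[b, 1]
        tz = tips[b, 2]
        gax = tx + (ox - tx) * s0
        gay = ty + (oy - ty) * s0
        gaz = tz + (oz - tz) * s0
        gbx = tx + (ox - tx) * s1
        gby = ty + (oy - ty) * s1
        gbz = tz + (oz - tz) * s1
        if _point_seg_dist2(cx, cy, cz, gax, gay, gaz, gbx, gby, gbz) < min_cyl2:
            return False
        # the other candidate's bead vs this candidate's new connector
        tx = tips[a_idx, 0]
        ty = tips[a_idx, 1]
        tz = tips[a_idx, 2]
        gax = tx + (cx - tx) * s0
        gay = ty + (cy - ty) * s0
        gaz = tz + (cz - tz) * s0
        gbx = tx + (cx - tx) * s1
        gby = ty + (cy - ty) * s1
        gbz = tz + (cz - tz) * s1
        if _point_seg_dist2(ox, oy, oz, gax, gay, gaz, gbx, gby, gbz) < min_cyl2:
            return False
    return True


@njit(cache=True)
def grow_core(
    pos,
    k,
    arm_n,
    R,
    r_b,
    cyl_clear,
    cyl_shrink,
    bond,
    ccx,
    ccy,
    ccz,
    r_cc,
    p_right,
    p_left,
    bt1,
    bt2,
    mode,
    reset_on_accept,
    count_per_candidate,
    proposal_cap,
    nuc_on,
    nx,
    ny,
    nz,
    nr,
    seed,
):
    """Grow the five arms in place until each reaches its configured count.

    Growth proceeds in rounds that extend every unfinished arm by one bead.
    ``mode`` selects how a round commits:

    * 0 (lockstep): each arm redraws directions until it holds a valid
      candidate; the round commits only when every unfinished arm holds
      one, so all arms advance together and no arm can outrun the others.
    * 1 (independent): each arm's candidate commits on its own as soon as
      it passes.
    * 2 (joint): all candidates are redrawn afresh every round and commit
      only if all pass simultaneously.

    Each candidate is tested against all placed beads and connectors, the
    other candidates held for this round, and an independent chirality
    acceptance draw.  Failures advance two counters whose thresholds
    trigger a single-bead backtrack (bt1, on the arm that failed most
    since the last reset) or a one-bead-per-chain backtrack (bt2; finished
    arms reopen).  ``reset_on_accept`` zeroes the counters on every commit;
    otherwise they tally until their own backtrack resets them.
    ``count_per_candidate`` counts each failed candidate rather than each
    failed round.
    """
    np.random.seed(seed)
    shrink = cyl_shrink
    fail1 = 0
    fail2 = 0
    win_fail = np.zeros(5, dtype=np.int64)
    cand = np.zeros((5, 3), dtype=np.float64)
    cand_ok = np.zeros(5, dtype=np.uint8)
    tips = np.zeros((5, 3), dtype=np.float64)
    proposals = 0
    n_bt1 = 0
    n_bt2 = 0
    use_chir = (p_right < 1.0) or (p_left < 1.0)
    while True:
        done = True
        for a in range(5):
            if k[a] < arm_n[a]:
                done = False
                break
        if done:
            return STATUS_OK, proposals, n_bt1, n_bt2
        if mode == 2:
            for a in range(5):
                cand_ok[a] = 0
        n_failed = 0
        for a in range(5):
            if k[a] >= arm_n[a]:
                cand_ok[a] = 0
                continue
            if mode == 0 and cand_ok[a] == 1:
                continue  # holds a reserved candidate from an earlier pass
            proposals += 1
            if proposals > proposal_cap:
                return STATUS_CAP, proposals, n_bt1, n_bt2
            # uniform direction on the sphere via normalized Gaussian triple
            n2 = 0.0
            dx = 0.0
            dy = 0.0
            dz = 0.0
            while n2 < 1e-12:
                dx = np.random.standard_normal()
                dy = np.random.standard_normal()
                dz = np.random.standard_normal()
                n2 = dx * dx + dy * dy + dz * dz
            scale = bond / np.sqrt(n2)
            tipx = pos[a, k[a] - 1, 0]
            tipy = pos[a, k[a] - 1, 1]
            tipz = pos[a, k[a] - 1, 2]
            tips[a, 0] = tipx
            tips[a, 1] = tipy
            tips[a, 2] = tipz
            cx = tipx + dx * scale
            cy = tipy + dy * scale
            cz = tipz + dz * scale
            ok = _candidate_ok(
                pos, k, a, cx, cy, cz, tipx, tipy, tipz, R, r_b, cyl_clear,
                ccx, ccy, ccz, r_cc, shrink, nuc_on, nx, ny, nz, nr,
            )
            if ok:
                ok = _cross_candidate_ok(
                    cand, cand_ok, a, cx, cy, cz, tips, r_b, cyl_clear, shrink
                )
            if ok and use_chir and k[a] >= 3:
                s = _chir_sign(
                    pos[a, k[a] - 3, 0], pos[a, k[a] - 3, 1], pos[a, k[a] - 3, 2],
                    pos[a, k[a] - 2, 0], pos[a, k[a] - 2, 1], pos[a, k[a] - 2, 2],
                    tipx, tipy, tipz, cx, cy, cz,
                )
                if s > 0:
                    p = p_right
                elif s < 0:
                    p = p_left
                else:
                    p = 1.0
                if p < 1.0 and np.random.random() >= p:
                    ok = False
            if ok:
                cand[a, 0] = cx
                cand[a, 1] = cy
                cand[a, 2] = cz
                cand_ok[a] = 1
            else:
                win_fail[a] += 1
                n_failed += 1
        # commit decision
        if mode == 1:
            commit = True  # independent: commit whichever passed
        else:
            commit = True
            for a in range(5):
                if k[a] < arm_n[a] and cand_ok[a] == 0:
                    commit = False
        accepted_any = False
        if commit:
            for a in range(5):
                if k[a] < arm_n[a] and cand_ok[a] == 1:
                    pos[a, k[a], 0] = cand[a, 0]
                    pos[a, k[a], 1] = cand[a, 1]
                    pos[a, k[a], 2] = cand[a, 2]
                    k[a] += 1
                    cand_ok[a] = 0
                    accepted_any = True
        if accepted_any and reset_on_accept:
            fail1 = 0
            fail2 = 0
            for a in range(5):
                win_fail[a] = 0
        if accepted_any and n_failed == 0:
            continue
        if count_per_candidate:
            fail1 += n_failed
            fail2 += n_failed
        elif n_failed > 0 and not accepted_any:
            fail1 += 1
            fail2 += 1
        if fail2 >= bt2:
            n_bt2 += 1
            # one bead from each of the five chains; completed arms reopen
            # and resume growth in later rounds
            for a in range(5):
                if k[a] > 1:
                    k[a] -= 1
                cand_ok[a] = 0
            fail1 = 0
            fail2 = 0
            for a in range(5):
                win_fail[a] = 0
        elif fail1 >= bt1:
            n_bt1 += 1
            best = -1
            bestf = -1
            for a in range(5):
                if k[a] < arm_n[a] and k[a] > 1 and win_fail[a] > bestf:
                    bestf = win_fail[a]
                    best = a
            if best >= 0:
                k[best] -= 1
                cand_ok[best] = 0
            fail1 = 0
            for a in range(5):
                win_fail[a] = 0
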