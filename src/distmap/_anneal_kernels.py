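"""Numba kernels for the simulated-annealing trace refinement.

All constraint kinds are funnelled into one representation: per-pair
flat-bottom intervals [lo, hi] (lo == hi for real-valued distance targets,
hi = inf for open intervals), plus per-strand end-to-end intervals.  The
pair penalty is the distance to the interval; bond and clash terms are
added from the sequence separation, so the kernels never need to know
which map kind produced the intervals.
"""

from __future__ import annotations

import numpy as np
from numba import njit

LN2 = 0.6931471805599453


@njit(cache=True, fastmath=False)
def _pair_penalty(d, lo, hi, sep, a0a1, a2, db, dcl, clash_exp):
    # map term: distance to the [lo, hi] interval, weighted alpha0*alpha1
    if d < lo:
        e = a0a1 * (lo - d)
    elif d > hi:
        e = a0a1 * (d - hi)
    else:
        e = 0.0
    if sep == 1:
        diff = d - db
        e += diff * diff
    else:
        if clash_exp == 1:
            e += a2 * 10.0 ** (dcl - d)
        else:
            if d < dcl:
                e += a2 * 10.0 * (dcl - d)
    return e


@njit(cache=True)
def _strand_energy(coords, strand_a, strand_b, strand_lo, strand_hi, a3):
    e = 0.0
    for s in range(strand_a.shape[0]):
        a = strand_a[s]
        b = strand_b[s]
        dx = coords[a, 0] - coords[b, 0]
        dy = coords[a, 1] - coords[b, 1]
        dz = coords[a, 2] - coords[b, 2]
        d = np.sqrt(dx * dx + dy * dy + dz * dz)
        if d < strand_lo[s]:
            v = strand_lo[s] - d
        elif d > strand_hi[s]:
            v = d - strand_hi[s]
        else:
            v = 0.0
        e += a3 * v * v
    return e


@njit(cache=True)
def total_energy(coords, lo, hi, strand_a, strand_b, strand_lo, strand_hi,
                 a0a1, a2, a3, db, dcl, clash_exp):
    n = coords.shape[0]
    e = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            dx = coords[i, 0] - coords[j, 0]
            dy = coords[i, 1] - coords[j, 1]
            dz = coords[i, 2] - coords[j, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            e += _pair_penalty(d, lo[i, j], hi[i, j], j - i, a0a1, a2, db, dcl,
                               clash_exp)
    e += _strand_energy(coords, strand_a, strand_b, strand_lo, strand_hi, a3)
    return e


@njit(cache=True)
def _delta_energy(coords, i, new_pos, lo, hi, strand_a, strand_b,
                  strand_lo, strand_hi, a0a1, a2, a3, db, dcl, clash_exp):
    n = coords.shape[0]
    de = 0.0
    for j in range(n):
        if j == i:
            continue
        sep = i - j if i > j else j - i
        dx = coords[i, 0] - coords[j, 0]
        dy = coords[i, 1] - coords[j, 1]
        dz = coords[i, 2] - coords[j, 2]
        d_old = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx = new_pos[0] - coords[j, 0]
        dy = new_pos[1] - coords[j, 1]
        dz = new_pos[2] - coords[j, 2]
        d_new = np.sqrt(dx * dx + dy * dy + dz * dz)
        l_ij = lo[i, j] if i < j else lo[j, i]
        h_ij = hi[i, j] if i < j else hi[j, i]
        de += _pair_penalty(d_new, l_ij, h_ij, sep, a0a1, a2, db, dcl, clash_exp)
        de -= _pair_penalty(d_old, l_ij, h_ij, sep, a0a1, a2, db, dcl, clash_exp)
    for s in range(strand_a.shape[0]):
        a = strand_a[s]
        b = strand_b[s]
        if a != i and b != i:
            continue
        o = b if a == i else a
        dx = coords[i, 0] - coords[o, 0]
        dy = coords[i, 1] - coords[o, 1]
        dz = coords[i, 2] - coords[o, 2]
        d_old = np.sqrt(dx * dx + dy * dy + dz * dz)
        dx = new_pos[0] - coords[o, 0]
        dy = new_pos[1] - coords[o, 1]
        dz = new_pos[2] - coords[o, 2]
        d_new = np.sqrt(dx * dx + dy * dy + dz * dz)
        for d, sign in ((d_old, -1.0), (d_new, 1.0)):
            if d < strand_lo[s]:
                v = strand_lo[s] - d
            elif d > strand_hi[s]:
                v = d - strand_hi[s]
            else:
                v = 0.0
            de += sign * a3 * v * v
    return de


@njit(cache=True)
def _propose(coords, i, theta_max):
    """Rotate residue i about the axis through its sequence neighbours.

    Interior residues rotate about the (i-1, i+1) axis, which preserves
    both neighbour distances exactly; chain ends rotate about a random
    axis through their single neighbour, preserving the bond length.
    Returns the proposed position.
    """
    n = coords.shape[0]
    theta = np.random.uniform(-theta_max, theta_max)
    if 0 < i < n - 1:
        cx = coords[i - 1, 0]
        cy = coords[i - 1, 1]
        cz = coords[i - 1, 2]
        ax = coords[i + 1, 0] - cx
        ay = coords[i + 1, 1] - cy
        az = coords[i + 1, 2] - cz
    else:
        o = 1 if i == 0 else n - 2
        cx = coords[o, 0]
        cy = coords[o, 1]
        cz = coords[o, 2]
        # random axis direction (gaussian -> uniform on the sphere)
        ax = np.random.normal()
        ay = np.random.normal()
        az = np.random.normal()
    norm = np.sqrt(ax * ax + ay * ay + az * az)
    new_pos = np.empty(3)
    if norm < 1e-9:
        new_pos[0] = coords[i, 0]
        new_pos[1] = coords[i, 1]
        new_pos[2] = coords[i, 2]
        return new_pos
    ax /= norm
    ay /= norm
    az /= norm
    vx = coords[i, 0] - cx
    vy = coords[i, 1] - cy
    vz = coords[i, 2] - cz
    ct = np.cos(theta)
    st = np.sin(theta)
    dot = ax * vx + ay * vy + az * vz
    # Rodrigues rotation of v about unit axis a
    new_pos[0] = cx + vx * ct + (ay * vz - az * vy) * st + ax * dot * (1.0 - ct)
    new_pos[1] = cy + vy * ct + (az * vx - ax * vz) * st + ay * dot * (1.0 - ct)
    new_pos[2] = cz + vz * ct + (ax * vy - ay * vx) * st + az * dot * (1.0 - ct)
    return new_pos


@njit(cache=True)
def calibrate_t0(coords, lo, hi, strand_a, strand_b, strand_lo, strand_hi,
                 a0a1, a2, a3, db, dcl, clash_exp, n_probe, theta_max, seed):
    """Initial temperature giving ~50% acceptance of uphill moves.

    Samples ``n_probe`` proposals from the start conformation (without
    applying them) and sets T0 = mean positive delta / ln 2, so that
    exp(-mean_dE/T0) = 0.5.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    pos_sum = 0.0
    pos_cnt = 0
    for _ in range(n_probe):
        i = np.random.randint(0, n)
        new_pos = _propose(coords, i, theta_max)
        de = _delta_energy(coords, i, new_pos, lo, hi, strand_a, strand_b,
                           strand_lo, strand_hi, a0a1, a2, a3, db, dcl,
                           clash_exp)
        if de > 0.0:
            pos_sum += de
            pos_cnt += 1
    if pos_cnt == 0:
        return 1.0
    return (pos_sum / pos_cnt) / LN2


@njit(cache=True)
def anneal_kernel(coords, lo, hi, strand_a, strand_b, strand_lo, strand_hi,
                  a0a1, a2, a3, db, dcl, clash_exp,
                  n_iters, t0, t_end_frac, theta_max0, theta_min, seed):
    """Metropolis annealing with geometric cooling; mutates ``coords``.

    The temperature decays geometrically from t0 to t0*t_end_frac over
    n_iters proposals; the move amplitude shrinks linearly with the
    iteration count from theta_max0 to theta_min (i.e. linearly in log T,
    which keeps exploratory moves alive through the mid-schedule).
    Returns the final energy.
    """
    np.random.seed(seed)
    n = coords.shape[0]
    energy = total_energy(coords, lo, hi, strand_a, strand_b, strand_lo,
                          strand_hi, a0a1, a2, a3, db, dcl, clash_exp)
    if n_iters <= 0:
        return energy
    gamma = t_end_frac ** (1.0 / n_iters)
    t = t0
    theta_span = theta_max0 - theta_min
    for k in range(n_iters):
        frac = 1.0 - k / n_iters
        theta_max = theta_min + theta_span * frac
        i = np.random.randint(0, n)
        new_pos = _propose(coords, i, theta_max)
        de = _delta_energy(coords, i, new_pos, lo, hi, strand_a, strand_b,
                           strand_lo, strand_hi, a0a1, a2, a3, db, dcl,
                           clash_exp)
        if de <= 0.0 or np.random.random() < np.exp(-de / t):
            coords[i, 0] = new_pos[0]
            coords[i, 1] = new_pos[1]
            coords[i, 2] = new_pos[2]
            energy += de
        t *= gamma
        if (k & 0x3FFFF) == 0x3FFFF:  # periodic resync against float drift
            energy = total_energy(coords, lo, hi, strand_a, strand_b,
                                  strand_lo, strand_hi, a0a1, a2, a3, db,
                                  dcl, clash_exp)
    return total_energy(coords, lo, hi, strand_a, strand_b, strand_lo,
                        strand_hi, a0a1, a2, a3, db, dcl, clash_exp)
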