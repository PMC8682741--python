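"""Numba kernels: forces, wall admissibility, and the Langevin inner loop.

The integrator is the overdamped update

    x <- x + (D/kT) F dt + sqrt(2 D dt) eta,

with hard walls handled by rejection: a proposed displacement landing in
a forbidden region is re-drawn with fresh noise (up to a fixed number of
attempts, after which the bead stays put for the step). A bead whose
*current* position is already forbidden (e.g. the gate closed behind it)
moves freely so it can diffuse back out.

Parameter packing (see :mod:`prfkit.cgmd.params`):
  par  = [dt, D, kT, bond_k, bond_r0, ev_k, ev_sigma, tether_k]
  geom = [enabled, z_ptc, tunnel_bottom, r_tunnel, mem_half, r_channel,
          w_z, w_x, box_xy, z_floor, z_cap, r_vestibule, x_lipid, x_floor,
          x_corridor, ribosome_detached]
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAX_REJECT_ATTEMPTS = 8


@njit(cache=True, fastmath=True)
def allowed(x, y, z, gate_open, geom):
    if geom[0] == 0.0:
        return True
    if z > geom[10] or z < geom[9]:
        return False
    if abs(x) > geom[8] or abs(y) > geom[8]:
        return False
    if z > geom[4]:  # above the membrane
        if geom[15] == 1.0:
            return True  # ribosome gone: open cytosol
        if z > geom[2]:  # exit-tunnel stub
            return x * x + y * y <= geom[3] * geom[3]
        return x * x + y * y <= geom[11] * geom[11]  # sealed junction
    if abs(z) <= geom[4]:  # membrane slab
        if x * x + y * y <= geom[5] * geom[5]:
            return True  # translocon channel
        if gate_open == 1 and 0.0 < x <= geom[14] and abs(y) <= geom[5]:
            return True  # lateral-gate corridor into the bilayer patch
        return False
    return True  # lumen


@njit(cache=True, fastmath=True)
def lipid_exposure(x, z, geom):
    """Smooth 0..1 bilayer-exposure factor of a position."""
    sz = 0.5 * (np.tanh((geom[4] - abs(z)) / geom[6]) + 1.0)
    sx = 0.5 * (np.tanh((x - geom[12]) / geom[7]) + 1.0)
    return sz * sx


@njit(cache=True, fastmath=True)
def compute_forces(pos, h, kang, n, gate_open, tether_on, par, geom, F):
    """Fill F[:n] with forces (kcal/mol/nm) on the active beads."""
    for i in range(n):
        F[i, 0] = 0.0
        F[i, 1] = 0.0
        F[i, 2] = 0.0
    # bonds
    k = par[3]
    r0 = par[4]
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > 1e-12:
            f = -k * (r - r0) / r
            F[i + 1, 0] += f * dx
            F[i + 1, 1] += f * dy
            F[i + 1, 2] += f * dz
            F[i, 0] -= f * dx
            F[i, 1] -= f * dy
            F[i, 2] -= f * dz
    # bending stiffness: E = kang_i (1 - cos theta_i) at each interior
    # bead; hydrophobic (helix-forming) stretches are stiff rods, polar
    # linkers floppy
    for i in range(1, n - 1):
        ki = kang[i]
        if ki > 0.0:
            ax = pos[i, 0] - pos[i - 1, 0]
            ay = pos[i, 1] - pos[i - 1, 1]
            az = pos[i, 2] - pos[i - 1, 2]
            bx = pos[i + 1, 0] - pos[i, 0]
            by = pos[i + 1, 1] - pos[i, 1]
            bz = pos[i + 1, 2] - pos[i, 2]
            la = np.sqrt(ax * ax + ay * ay + az * az)
            lb = np.sqrt(bx * bx + by * by + bz * bz)
            if la > 1e-9 and lb > 1e-9:
                ux, uy, uz = ax / la, ay / la, az / la
                vx, vy, vz = bx / lb, by / lb, bz / lb
                c = ux * vx + uy * vy + uz * vz
                # dc/d(prev) = -(v - c u)/la ; dc/d(next) = (u - c v)/lb
                pax = (vx - c * ux) / la
                pay = (vy - c * uy) / la
                paz = (vz - c * uz) / la
                pbx = (ux - c * vx) / lb
                pby = (uy - c * vy) / lb
                pbz = (uz - c * vz) / lb
                # F = -dE/dr = +k dc/dr
                F[i - 1, 0] -= ki * pax
                F[i - 1, 1] -= ki * pay
                F[i - 1, 2] -= ki * paz
                F[i, 0] += ki * (pax - pbx)
                F[i, 1] += ki * (pay - pby)
                F[i, 2] += ki * (paz - pbz)
                F[i + 1, 0] += ki * pbx
                F[i + 1, 1] += ki * pby
                F[i + 1, 2] += ki * pbz
    # soft excluded volume, non-bonded pairs only
    ek = par[5]
    sig = par[6]
    sig2 = sig * sig
    for i in range(n - 2):
        xi = pos[i, 0]
        yi = pos[i, 1]
        zi = pos[i, 2]
        fxi = 0.0
        fyi = 0.0
        fzi = 0.0
        for j in range(i + 2, n):
            dx = pos[j, 0] - xi
            dy = pos[j, 1] - yi
            dz = pos[j, 2] - zi
            r2 = dx * dx + dy * dy + dz * dz
            if r2 < sig2 and r2 > 1e-24:
                r = np.sqrt(r2)
                f = 2.0 * ek * (1.0 - r / sig) / (sig * r)
                F[j, 0] += f * dx
                F[j, 1] += f * dy
                F[j, 2] += f * dz
                fxi -= f * dx
                fyi -= f * dy
                fzi -= f * dz
        F[i, 0] += fxi
        F[i, 1] += fyi
        F[i, 2] += fzi
    # PTC tether on the most recently emitted bead
    if tether_on == 1 and n > 0:
        i = n - 1
        F[i, 0] += par[7] * (0.0 - pos[i, 0])
        F[i, 1] += par[7] * (0.0 - pos[i, 1])
        F[i, 2] += par[7] * (geom[1] - pos[i, 2])
    # implicit-membrane coupling
    if geom[0] != 0.0:
        for i in range(n):
            if h[i] != 0.0:
                x = pos[i, 0]
                z = pos[i, 2]
                tz = np.tanh((geom[4] - abs(z)) / geom[6])
                tx = np.tanh((x - geom[12]) / geom[7])
                sz = 0.5 * (tz + 1.0)
                dsz = -np.sign(z) * 0.5 * (1.0 - tz * tz) / geom[6]
                if h[i] < 0.0:
                    # hydrophobic beads keep a residual slab affinity even
                    # inside the channel (the gate-facing pore surface)
                    sx = geom[13] + (1.0 - geom[13]) * 0.5 * (tx + 1.0)
                    dsx = (1.0 - geom[13]) * 0.5 * (1.0 - tx * tx) / geom[7]
                else:
                    # polar/charged beads see the aqueous pore: the lateral
                    # coupling only reaches the actual bilayer
                    sx = 0.5 * (tx + 1.0)
                    dsx = 0.5 * (1.0 - tx * tx) / geom[7]
                # E = h * sz * sx; F = -dE/dx
                F[i, 0] -= h[i] * sz * dsx
                F[i, 2] -= h[i] * dsz * sx
    return F


RESTRAINT_CAP_NM = 1.0  # harmonic restraints act like a constant-force
# leash beyond this displacement, so a far-away (just-emitted) bead is
# steered, not slammed through the chain


@njit(cache=True, fastmath=True)
def apply_restraints(pos, n, r_mode, r_k, r_pos, mem_half, F):
    for i in range(n):
        if r_mode[i] == 1:  # full harmonic with force cap
            dx = r_pos[i, 0] - pos[i, 0]
            dy = r_pos[i, 1] - pos[i, 1]
            dz = r_pos[i, 2] - pos[i, 2]
            d = np.sqrt(dx * dx + dy * dy + dz * dz)
            if d > 1e-12:
                scale = r_k[i] * min(d, RESTRAINT_CAP_NM) / d
                F[i, 0] += scale * dx
                F[i, 1] += scale * dy
                F[i, 2] += scale * dz
        elif r_mode[i] == 2:  # one-sided push below the lumenal face
            if pos[i, 2] > -mem_half:
                dz = -mem_half - pos[i, 2]
                F[i, 2] += r_k[i] * max(dz, -RESTRAINT_CAP_NM)


@njit(cache=True, fastmath=True)
def run_steps(pos, h, kang, n, gate_open, tether_on, par, geom,
              r_mode, r_k, r_pos, noise, seed, ext_f):
    """Advance the active chain by ``noise.shape[0]`` steps.

    ``noise`` holds pre-drawn, pre-scaled thermal displacements of shape
    (n_steps, n_active, 3); re-drawn noise for rejected (wall-colliding)
    proposals comes from the kernel's own RNG seeded with ``seed``, so a
    segment is deterministic given (noise, seed).
    """
    np.random.seed(seed)
    mob = par[1] * par[0] / par[2]  # D dt / kT
    sig = np.sqrt(2.0 * par[1] * par[0])
    n_steps = noise.shape[0]
    F = np.empty((pos.shape[0], 3))
    any_restraint = False
    for i in range(pos.shape[0]):
        if r_mode[i] != 0:
            any_restraint = True
            break
    for s in range(n_steps):
        compute_forces(pos, h, kang, n, gate_open, tether_on, par, geom, F)
        if any_restraint:
            apply_restraints(pos, n, r_mode, r_k, r_pos, geom[4], F)
        for i in range(n):
            ddx = mob * (F[i, 0] + ext_f[0])
            ddy = mob * (F[i, 1] + ext_f[1])
            ddz = mob * (F[i, 2] + ext_f[2])
            # fast path: first proposal admissible (the common case)
            nx = pos[i, 0] + ddx + noise[s, i, 0]
            ny = pos[i, 1] + ddy + noise[s, i, 1]
            nz = pos[i, 2] + ddz + noise[s, i, 2]
            if allowed(nx, ny, nz, gate_open, geom):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                continue
            # a bead already in a forbidden spot (gate closed on it) is free
            if not allowed(pos[i, 0], pos[i, 1], pos[i, 2], gate_open, geom):
                pos[i, 0] = nx
                pos[i, 1] = ny
                pos[i, 2] = nz
                continue
            for _try in range(MAX_REJECT_ATTEMPTS - 1):
                nx = pos[i, 0] + ddx + sig * np.random.normal()
                ny = pos[i, 1] + ddy + sig * np.random.normal()
                nz = pos[i, 2] + ddz + sig * np.random.normal()
                if allowed(nx, ny, nz, gate_open, geom):
                    pos[i, 0] = nx
                    pos[i, 1] = ny
                    pos[i, 2] = nz
                    break
    return pos


@njit(cache=True)
def max_bond_length(pos, n):
    m = 0.0
    for i in range(n - 1):
        dx = pos[i + 1, 0] - pos[i, 0]
        dy = pos[i + 1, 1] - pos[i, 1]
        dz = pos[i + 1, 2] - pos[i, 2]
        r = np.sqrt(dx * dx + dy * dy + dz * dz)
        if r > m:
            m = r
    return m
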