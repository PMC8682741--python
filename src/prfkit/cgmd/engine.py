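"""Chain state, growth, gate switching, and the protocol-facing engine.

Time is discretized internally in integer Langevin steps of ``dt``; gate
attempts, force samples and bead additions are scheduled on that grid.
All randomness flows from one ``numpy.random.Generator``: the engine
draws a fresh 31-bit seed from it for every kernel segment, so a protocol
run is bit-reproducible given its seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .beads import BeadSpec, bead_arrays, coarsen
from .kernel import (
    allowed,
    compute_forces,
    apply_restraints,
    max_bond_length,
    run_steps,
)
from .params import Geometry, GateModel, SimParams, KCAL_PER_MOL_NM_TO_PN

RIBOSOME_QC_OFFSET = 33  # translation starts 33 residues before TM1


def default_start_residue(tm1_start: int) -> int:
    """First translated residue of a construct: 33 residues upstream of
    TM1 (696 - 33 = 663 for the study's polyprotein)."""
    return tm1_start - RIBOSOME_QC_OFFSET


def arrest_condition(n_beads: int, start_res: int, slip_res: int,
                     offset: int = 27) -> bool:
    """True once the ribosome occupies the slip-site.

    The exit tunnel is truncated, so ``offset`` (27) unmodeled residues
    are added to the index of the final bead before comparing against the
    slip-site position.
    """
    if slip_res < start_res:
        raise ValueError("slip_res must be >= start_res")
    return 3 * n_beads + offset >= slip_res - start_res + 1


def arrest_bead_count(start_res: int, slip_res: int, offset: int = 27) -> int:
    """Smallest bead count satisfying :func:`arrest_condition`."""
    needed = slip_res - start_res + 1 - offset
    return max(int(math.ceil(needed / 3.0)), 1)


def gate_update(gate_open: bool, dg_open: float, kT: float,
                rng: np.random.Generator) -> bool:
    """Metropolis switch between gate states.

    ``dg_open`` is the open-minus-closed free energy at the current
    occupancy; the flip to the proposed state is accepted with
    min(1, exp(-dE/kT)), which satisfies detailed balance.
    """
    d_e = -dg_open if gate_open else dg_open  # energy change of flipping
    if d_e <= 0 or rng.random() < math.exp(-d_e / kT):
        return not gate_open
    return gate_open


@dataclass
class ChainState:
    """Mutable configuration of the nascent chain."""

    positions: np.ndarray  # (capacity, 3)
    specs: list[BeadSpec]
    n_active: int = 0
    tether_on: bool = True
    gate_open: bool = False
    t: float = 0.0

    @property
    def active_positions(self) -> np.ndarray:
        return self.positions[: self.n_active]


def langevin_step(state: ChainState, params: SimParams, geometry: Geometry,
                  rng: np.random.Generator,
                  noise: bool = True,
                  ext_force: np.ndarray | None = None) -> ChainState:
    """One overdamped Langevin step (in place); step-level API for tests
    and custom protocols. Shares the force routine with the fast kernel."""
    n = state.n_active
    if n == 0:
        return state
    g, q = bead_arrays(state.specs[:n])
    h = params.lipid_scale * g + params.charge_penalty * np.abs(q)
    kang = np.where(g < 0.0, params.angle_k_tm, params.angle_k_polar)
    par = params.to_array()
    geom = geometry.to_array()
    F = np.empty((len(state.positions), 3))
    compute_forces(state.positions, h, kang, n, int(state.gate_open),
                   int(state.tether_on), par, geom, F)
    ext = np.zeros(3) if ext_force is None else np.asarray(ext_force, float)
    mob = params.D * params.dt / params.kT
    sig = math.sqrt(2.0 * params.D * params.dt) if noise else 0.0
    for i in range(n):
        drift = mob * (F[i] + ext)
        cur_free = not allowed(*state.positions[i], int(state.gate_open), geom)
        for _ in range(8):
            prop = state.positions[i] + drift + sig * rng.standard_normal(3)
            if cur_free or allowed(prop[0], prop[1], prop[2],
                                   int(state.gate_open), geom):
                state.positions[i] = prop
                break
    state.t += params.dt
    return state


class Engine:
    """Drives one trajectory: growth, holds, sampling, gate kinetics."""

    def __init__(self, specs: list[BeadSpec], params: SimParams,
                 geometry: Geometry, seed: int,
                 gate: GateModel | None = None):
        self.specs = specs
        self.params = params
        self.geometry = geometry
        self.gate = gate or GateModel(dg0=params.gate_dg0,
                                      coupling=params.gate_coupling)
        self.rng = np.random.default_rng(seed)
        cap = max(len(specs), 1)
        self.state = ChainState(
            positions=np.zeros((cap, 3)), specs=specs, n_active=0,
        )
        g, q = bead_arrays(specs)
        self._g = g
        self._h = params.lipid_scale * g + params.charge_penalty * np.abs(q)
        self._kang = np.where(g < 0.0, params.angle_k_tm,
                              params.angle_k_polar).astype(np.float64)
        self._par = params.to_array()
        self._geom = geometry.to_array()
        self._r_mode = np.zeros(cap, dtype=np.int64)
        self._r_k = np.zeros(cap, dtype=np.float64)
        self._r_pos = np.zeros((cap, 3), dtype=np.float64)
        self._steps_per_gate = max(int(round(params.gate_interval / params.dt)), 1)
        self._steps_to_gate = self._steps_per_gate
        self.max_stretch_seen = 0.0

    # -- construction -------------------------------------------------

    def add_bead(self) -> None:
        """Emit the next bead at the PTC anchor and move the tether to it."""
        i = self.state.n_active
        if i >= len(self.specs):
            raise RuntimeError("no beads left to emit")
        jitter = 0.05 * self.rng.standard_normal(3)
        self.state.positions[i] = np.array(
            [0.0, 0.0, self.geometry.z_ptc]
        ) + jitter
        self.state.n_active = i + 1

    def set_restraint(self, bead: int, mode: int, k: float,
                      target=(0.0, 0.0, 0.0)) -> None:
        self._r_mode[bead] = mode
        self._r_k[bead] = k
        self._r_pos[bead] = target

    def release_tether(self) -> None:
        self.state.tether_on = False

    def detach_ribosome(self) -> None:
        """Release the chain and remove the ribosome walls (termination)."""
        self.state.tether_on = False
        self.geometry = self.geometry.detached()
        self._geom = self.geometry.to_array()

    # -- dynamics -----------------------------------------------------

    def _gate_occupancy_g(self) -> float:
        geo = self.geometry
        occ = 0.0
        pos = self.state.active_positions
        for i in range(self.state.n_active):
            x, y, z = pos[i]
            if (abs(z) <= geo.mem_half
                    and x * x + y * y <= (geo.r_channel + geo.gate_region_pad) ** 2):
                occ += self._g[i]
        return occ

    def attempt_gate(self) -> None:
        dg = self.gate.delta_g_open(self._gate_occupancy_g())
        self.state.gate_open = gate_update(
            self.state.gate_open, dg, self.params.kT, self.rng
        )

    def advance_steps(self, n_steps: int) -> None:
        """Advance with gate attempts interleaved on their schedule."""
        sig = math.sqrt(2.0 * self.params.D * self.params.dt)
        remaining = int(n_steps)
        while remaining > 0:
            chunk = min(remaining, self._steps_to_gate)
            seed = int(self.rng.integers(0, 2**31 - 1))
            noise = sig * self.rng.standard_normal(
                (chunk, self.state.n_active, 3)
            )
            run_steps(
                self.state.positions, self._h, self._kang,
                self.state.n_active,
                int(self.state.gate_open), int(self.state.tether_on),
                self._par, self._geom, self._r_mode, self._r_k, self._r_pos,
                noise, seed, np.zeros(3),
            )
            remaining -= chunk
            self._steps_to_gate -= chunk
            if self._steps_to_gate == 0:
                self.attempt_gate()
                self._steps_to_gate = self._steps_per_gate
            self.state.t += chunk * self.params.dt
        stretch = max_bond_length(self.state.positions, self.state.n_active)
        if stretch > self.max_stretch_seen:
            self.max_stretch_seen = stretch

    def advance_time(self, duration: float) -> None:
        self.advance_steps(int(round(duration / self.params.dt)))

    def grow(self, n_beads: int) -> None:
        """Emit ``n_beads`` beads at the translation schedule."""
        steps = max(int(round(self.params.growth_interval / self.params.dt)), 1)
        for _ in range(n_beads):
            self.add_bead()
            self.advance_steps(steps)

    # -- measurement --------------------------------------------------

    def tether_tension_pn(self) -> float:
        """Pulling force on the ribosome anchor, projected on the tunnel
        axis (positive = chain pulls toward the membrane)."""
        i = self.state.n_active - 1
        dz = self.geometry.z_ptc - self.state.positions[i, 2]
        return self.params.tether_k * dz * KCAL_PER_MOL_NM_TO_PN

    def nbead_force_pn(self) -> float:
        """Net axial force on the most N-terminal bead (config alternative
        reading of the measured observable)."""
        n = self.state.n_active
        F = np.empty((len(self.state.positions), 3))
        compute_forces(self.state.positions, self._h, self._kang, n,
                       int(self.state.gate_open), int(self.state.tether_on),
                       self._par, self._geom, F)
        apply_restraints(self.state.positions, n, self._r_mode, self._r_k,
                         self._r_pos, self._geom[4], F)
        return -float(F[0, 2]) * KCAL_PER_MOL_NM_TO_PN

    def sample_force_pn(self) -> float:
        if self.params.force_mode == "tether":
            return self.tether_tension_pn()
        return self.nbead_force_pn()
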