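"""Simulation parameters and idealized ribosome/translocon geometry.

The geometry is idealized-parametric rather than a cryo-EM mesh: a
cylindrical exit-tunnel stub above the membrane (the tunnel is truncated;
the unmodeled ~27 residues are handled by the arrest-index offset), a
cytosolic vestibule between ribosome and translocon, a channel of radius
``r_channel`` through a planar membrane slab of half-thickness
``mem_half``, and a lateral-gate corridor opening toward +x. The lumen is
the half-space below the slab, the cytosol the region above it.

All energies are in kcal/mol, lengths in nm, times in s. kT = 0.593
kcal/mol (300 K); forces converted to pN with 1 kcal/mol/nm = 6.9477 pN.
"""

from __future__ import annotations

from dataclasses import dataclass, replace, asdict

import numpy as np
import yaml

KCAL_PER_MOL_NM_TO_PN = 6.9477


@dataclass(frozen=True)
class SimParams:
    """Langevin integration, chain force field and protocol timing."""

    dt: float = 300e-9  # s
    D: float = 253.0  # nm^2/s
    kT: float = 0.593  # kcal/mol (300 K)
    translation_rate: float = 5.0  # residues/s
    growth_time_scale: float = 1.0  # compression factor on growth intervals
    bond_k: float = 10.0  # kcal/mol/nm^2
    bond_r0: float = 0.8  # nm (3-residue bead spacing)
    ev_k: float = 10.0  # kcal/mol, soft excluded-volume strength
    ev_sigma: float = 0.6  # nm
    tether_k: float = 10.0  # kcal/mol/nm^2, PTC tether spring
    charge_penalty: float = 1.5  # kcal/mol per |e| of bilayer exposure
    lipid_scale: float = 2.5  # scaling of per-bead transfer energies in the
    # membrane coupling (CG calibration of the water->bilayer scale)
    angle_k_polar: float = 0.3  # kcal/mol bending stiffness, flexible linkers
    angle_k_tm: float = 4.0  # kcal/mol, helix-forming (hydrophobic) stretches
    gate_dg0: float = 2.0  # kcal/mol, open - closed for an empty gate
    gate_coupling: float = 0.75  # per kcal/mol of bead transfer energy in gate
    gate_interval: float = 1.0e-3  # s between gate switching attempts
    sample_interval: float = 3.0e-3  # s between force samples
    force_mode: str = "tether"  # "tether" | "nbead"
    arrest_offset: int = 27  # unmodeled residues in the truncated tunnel
    max_bond_stretch: float = 2.5  # nm, connectivity assertion threshold

    def __post_init__(self):
        if self.dt <= 0 or self.D <= 0 or self.kT <= 0:
            raise ValueError("dt, D and kT must be positive")
        if self.translation_rate <= 0:
            raise ValueError("translation rate must be positive")
        if self.force_mode not in ("tether", "nbead"):
            raise ValueError("force_mode must be 'tether' or 'nbead'")

    def with_(self, **kw) -> "SimParams":
        return replace(self, **kw)

    @property
    def growth_interval(self) -> float:
        """Simulated seconds between bead additions (one bead = 3 residues)."""
        return (3.0 / self.translation_rate) * self.growth_time_scale

    def to_array(self) -> np.ndarray:
        return np.array(
            [self.dt, self.D, self.kT, self.bond_k, self.bond_r0,
             self.ev_k, self.ev_sigma, self.tether_k],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class Geometry:
    """Idealized compartment geometry (nm). +z is cytosolic, -z lumenal."""

    z_ptc: float = 3.8  # PTC tether anchor height
    tunnel_bottom: float = 3.0  # exit-tunnel mouth
    r_tunnel: float = 0.9
    mem_half: float = 2.0  # membrane slab |z| <= mem_half
    r_channel: float = 1.2  # translocon channel radius
    r_vestibule: float = 1.2  # sealed ribosome-translocon junction radius
    w_z: float = 0.3  # z smoothing width of the lipid coupling
    w_x: float = 0.5  # lateral smoothing width of the lipid coupling
    x_lipid: float = 1.0  # lateral center of the bilayer coupling basin
    x_floor: float = 0.35  # residual slab coupling inside the channel
    # (hydrophobic beads only: the gate-facing pore surface)
    x_corridor: float = 3.0  # lateral extent of the modeled bilayer patch
    box_xy: float = 6.0
    z_floor: float = -3.0
    z_cap: float = 4.1
    gate_region_pad: float = 0.6  # gate-occupancy shell beyond r_channel
    enabled: bool = True
    ribosome_detached: bool = False  # post-release: tunnel walls removed,
    # cytosolic half-space opened

    def __post_init__(self):
        if not (self.z_floor < -self.mem_half < self.mem_half
                < self.tunnel_bottom < self.z_ptc < self.z_cap):
            raise ValueError("geometry layers must be ordered along z")
        if min(self.r_tunnel, self.r_channel) <= 0:
            raise ValueError("radii must be positive")

    def to_array(self) -> np.ndarray:
        return np.array(
            [1.0 if self.enabled else 0.0, self.z_ptc, self.tunnel_bottom,
             self.r_tunnel, self.mem_half, self.r_channel, self.w_z,
             self.w_x, self.box_xy, self.z_floor, self.z_cap,
             self.r_vestibule, self.x_lipid, self.x_floor,
             self.x_corridor, 1.0 if self.ribosome_detached else 0.0],
            dtype=np.float64,
        )

    def free_space(self) -> "Geometry":
        """Geometry with all walls and the membrane coupling disabled."""
        return replace(self, enabled=False)

    def detached(self) -> "Geometry":
        """Geometry after the nascent chain is released from the ribosome."""
        return replace(self, ribosome_detached=True)


@dataclass(frozen=True)
class GateModel:
    """Two-state lateral gate with hydrophobicity-coupled free energy.

    The open-minus-closed free energy of the gate is
    ``dg0 + coupling * sum(g_bead)`` over beads currently inside the gate
    region (channel interior plus a thin shell, within the slab); a
    hydrophobic occupant (negative transfer free energy) therefore favors
    the open state. Switching is Metropolis, preserving detailed balance
    at fixed occupancy.
    """

    dg0: float = 2.0
    coupling: float = 0.75

    def delta_g_open(self, occupancy_g: float) -> float:
        return self.dg0 + self.coupling * occupancy_g


def load_config(path) -> tuple[SimParams, Geometry]:
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    return (
        SimParams(**cfg.get("params", {})),
        Geometry(**cfg.get("geometry", {})),
    )


def dump_config(params: SimParams, geometry: Geometry, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {"params": asdict(params), "geometry": asdict(geometry)}, fh
        )
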