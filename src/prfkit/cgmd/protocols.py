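"""The three simulation protocols of the study.

* Force protocol: translate to the slip-site, arrest, hold, and sample
  the nascent-chain pulling force every 3 ms; trajectories in which TM1
  has not reached its N_out topology are excluded from the ensemble.
* Topology protocol: translate the full construct without pausing (TM1
  restrained to its membrane-spanning N_out pose), release the chain,
  relax, and classify the final TM2 topology; repeated trajectories give
  an integration probability with a binomial confidence interval.
* Rate sweep: the force protocol at several translation rates with a
  0.8 s averaging window, reproducing the force-vs-rate trend.

Sampling convention: a window of length W sampled every ``dt_s`` yields
``ceil(W / dt_s)`` samples taken at the start of each interval (3 s ->
1000 samples, 0.8 s -> 267).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .beads import coarsen
from .engine import (
    Engine,
    arrest_bead_count,
    default_start_residue,
)
from .params import Geometry, SimParams


@dataclass(frozen=True)
class Construct:
    """A translated sequence with its TM annotations and slip-site."""

    aa_seq: str  # residues start_res, start_res+1, ...
    tm1: tuple[int, int]  # residue span
    tm2: tuple[int, int]
    slip_res: int  # residue of the slip-site P-site codon
    start_res: int | None = None  # default: 33 residues before TM1

    @property
    def start(self) -> int:
        return (self.start_res if self.start_res is not None
                else default_start_residue(self.tm1[0]))

    def __post_init__(self):
        if self.tm1[0] > self.tm1[1] or self.tm2[0] > self.tm2[1]:
            raise ValueError("TM spans must be ordered")
        if self.slip_res <= self.tm2[1]:
            raise ValueError("slip-site must lie downstream of TM2")
        if self.tm1[0] < self.start:
            raise ValueError("TM1 must lie within the translated sequence")

    def bead_index(self, residue: int) -> int:
        return max((residue - self.start) // 3, 0)


@dataclass
class ForceTrace:
    """Force samples from one arrested trajectory."""

    times: np.ndarray  # s, relative to arrest
    forces_pn: np.ndarray
    tm1_n_out: bool
    trajectory: int

    @property
    def mean_force(self) -> float:
        return float(self.forces_pn.mean())


@dataclass
class ForceEnsemble:
    traces: list[ForceTrace]
    mean_force: float
    sem: float
    n_pass: int
    valid: bool
    max_bond_stretch: float = 0.0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trajectory": [t.trajectory for t in self.traces],
                "mean_force_pN": [t.mean_force for t in self.traces],
                "tm1_n_out": [t.tm1_n_out for t in self.traces],
            }
        )


def _ensemble(traces: list[ForceTrace], max_stretch: float) -> ForceEnsemble:
    means = np.array([t.mean_force for t in traces if t.tm1_n_out])
    n_pass = len(means)
    return ForceEnsemble(
        traces=traces,
        mean_force=float(means.mean()) if n_pass else float("nan"),
        sem=(float(means.std(ddof=1) / math.sqrt(n_pass)) if n_pass > 1
             else float("nan")),
        n_pass=n_pass,
        valid=n_pass > 0,
        max_bond_stretch=max_stretch,
    )


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def run_force_protocol(
    construct: Construct,
    params: SimParams | None = None,
    geometry: Geometry | None = None,
    n_traj: int = 100,
    seed: int = 0,
    window: float = 3.0,
    n_out_z: float | None = None,
    restrain_tm1: bool = False,
    tm1_restraint_k: float = 5.0,
) -> ForceEnsemble:
    """Arrest-and-pull force measurement at the slip-site.

    Each trajectory grows the chain to the arrest bead count (slip-site
    position minus the 27 unmodeled tunnel residues, 3 residues per
    bead), holds translation for ``window`` seconds sampling the force
    every ``params.sample_interval``, and checks the TM1 N_out flag (the
    bead flanking TM1 on its N side must sit below the lumenal membrane
    face) at the end of the hold.

    With ``restrain_tm1`` the TM1 topology is enforced instead of merely
    filtered: its central bead is held at the lateral-gate exit and the
    N-flank bead below the lumenal face (the same device the topology
    protocol uses), which isolates the TM2 contribution to the force at
    small trajectory counts.
    """
    params = params or SimParams()
    geometry = geometry or Geometry()
    n_arrest = arrest_bead_count(construct.start, construct.slip_res,
                                 params.arrest_offset)
    if 3 * n_arrest > len(construct.aa_seq):
        raise ValueError("construct too short to reach the slip-site")
    specs = coarsen(construct.aa_seq[: 3 * n_arrest])
    if n_out_z is None:
        n_out_z = -0.9 * geometry.mem_half
    flank_bead = construct.bead_index(construct.tm1[0] - 1)
    n_samples = int(math.ceil(window / params.sample_interval))
    sample_steps = int(round(params.sample_interval / params.dt))

    traces = []
    max_stretch = 0.0
    tm1_mid = construct.bead_index((construct.tm1[0] + construct.tm1[1]) // 2)
    for traj, s in enumerate(_spawn_seeds(seed, n_traj)):
        eng = Engine(specs, params, geometry, seed=s)
        if restrain_tm1:
            eng.set_restraint(
                tm1_mid, mode=1, k=tm1_restraint_k,
                target=(geometry.x_lipid + 1.0, 0.0, 0.0),
            )
            eng.set_restraint(flank_bead, mode=2, k=tm1_restraint_k)
        eng.grow(n_arrest)
        forces = np.empty(n_samples)
        for k in range(n_samples):
            forces[k] = eng.sample_force_pn()
            eng.advance_steps(sample_steps)
        n_out = bool(eng.state.positions[flank_bead, 2] < n_out_z)
        traces.append(
            ForceTrace(
                times=np.arange(n_samples) * params.sample_interval,
                forces_pn=forces,
                tm1_n_out=n_out,
                trajectory=traj,
            )
        )
        max_stretch = max(max_stretch, eng.max_stretch_seen)
        if max_stretch > params.max_bond_stretch:
            raise AssertionError(
                f"bond stretch {max_stretch:.2f} nm exceeded "
                f"{params.max_bond_stretch} nm — unstable integration"
            )
    return _ensemble(traces, max_stretch)


@dataclass
class TopologyOutcome:
    """Per-trajectory TM2 topology labels and the integration probability."""

    labels: list[str]  # integrated | translocated | cytosolic/other
    p_integrated: float
    ci_low: float
    ci_high: float
    n_traj: int

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for lab in self.labels:
            out[lab] = out.get(lab, 0) + 1
        return out


def _classify_tm2(eng: Engine, construct: Construct, geometry: Geometry) -> str:
    pos = eng.state.positions
    start = construct.bead_index(construct.tm2[0])
    end = min(construct.bead_index(construct.tm2[1]),
              eng.state.n_active - 1)
    span = list(range(start, end + 1))
    third = max(len(span) // 3, 1)
    central = span[third: len(span) - third] or [span[len(span) // 2]]
    z = pos[span, 2]
    mh = geometry.mem_half
    n_flank = max(start - 1, 0)
    c_flank = min(end + 1, eng.state.n_active - 1)
    in_slab = np.all(np.abs(pos[central, 2]) <= mh + 0.3)
    in_lipid = np.mean(pos[central, 0]) > 0.9 * geometry.r_channel
    flanks_opposite = pos[n_flank, 2] * pos[c_flank, 2] < 0
    if in_slab and in_lipid and flanks_opposite:
        return "integrated"
    if z.mean() < -mh:
        return "translocated"
    return "cytosolic/other"


def run_topology_protocol(
    construct: Construct,
    params: SimParams | None = None,
    geometry: Geometry | None = None,
    n_traj: int = 100,
    seed: int = 0,
    relax_window: float = 3.0,
    tm1_restraint_k: float = 5.0,
) -> TopologyOutcome:
    """Full-length translation, release, relaxation, TM2 classification.

    TM1 is restrained throughout: its central bead is held at the
    lateral-gate exit in the membrane plane and its N-flank bead is
    pushed below the lumenal face, enforcing the membrane-spanning N_out
    pose the experiment presupposes. TM2 is unrestrained. A trajectory is
    "integrated" when the central TM2 beads sit inside the slab, laterally
    in the bilayer (beyond the channel radius), with the flanking beads on
    opposite membrane faces.
    """
    params = params or SimParams()
    geometry = geometry or Geometry()
    n_total = int(math.ceil(len(construct.aa_seq) / 3))
    specs = coarsen(construct.aa_seq)
    tm1_mid = construct.bead_index((construct.tm1[0] + construct.tm1[1]) // 2)
    tm1_nflank = construct.bead_index(construct.tm1[0] - 1)
    labels = []
    for s in _spawn_seeds(seed, n_traj):
        eng = Engine(specs, params, geometry, seed=s)
        eng.set_restraint(
            tm1_mid, mode=1, k=tm1_restraint_k,
            target=(geometry.x_lipid + 1.0, 0.0, 0.0),
        )
        eng.set_restraint(tm1_nflank, mode=2, k=tm1_restraint_k)
        eng.grow(n_total)
        # the chain leaves the PTC; the ribosome stays docked on the
        # translocon, so the compartment geometry is unchanged
        eng.release_tether()
        eng.advance_time(relax_window)
        labels.append(_classify_tm2(eng, construct, geometry))
    k = sum(1 for lab in labels if lab == "integrated")
    lo, hi = proportion_confint(k, n_traj, alpha=0.05, method="wilson")
    return TopologyOutcome(
        labels=labels,
        p_integrated=k / n_traj,
        ci_low=float(lo),
        ci_high=float(hi),
        n_traj=n_traj,
    )


def rate_sweep(
    construct: Construct,
    rates: list[float],
    params: SimParams | None = None,
    geometry: Geometry | None = None,
    n_traj: int = 100,
    seed: int = 0,
    window: float = 0.8,
    restrain_tm1: bool = False,
) -> pd.DataFrame:
    """Mean arrest force (+/- SEM) at each translation rate.

    Forces are averaged over ``window`` (0.8 s in the study) once the
    ribosome occupies the slip-site.
    """
    params = params or SimParams()
    rows = []
    for rate in rates:
        if rate <= 0:
            raise ValueError("translation rates must be positive")
        ens = run_force_protocol(
            construct,
            params=params.with_(translation_rate=float(rate)),
            geometry=geometry,
            n_traj=n_traj,
            seed=seed,
            window=window,
            restrain_tm1=restrain_tm1,
        )
        rows.append(
            {
                "rate": float(rate),
                "mean_force_pN": ens.mean_force,
                "sem": ens.sem,
                "n_pass": ens.n_pass,
            }
        )
    return pd.DataFrame(rows)
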