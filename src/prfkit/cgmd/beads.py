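"""Coarse-graining of the amino-acid sequence into 3-residue beads."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .._scales import AMINO_ACIDS, TRANSFER_DG, CHARGE


@dataclass(frozen=True)
class BeadSpec:
    """One bead: up to three residues, summed transfer free energy and
    net formal charge."""

    index: int
    residues: str  # 1-3 residue window, N->C
    g: float  # kcal/mol, water->bilayer (negative = hydrophobic)
    q: int  # net formal charge


def coarsen(aa_seq: str) -> list[BeadSpec]:
    """N->C beads of three residues each; a short final bead keeps its
    actual residues, with g and q summed over them."""
    specs = []
    for i in range(0, len(aa_seq), 3):
        window = aa_seq[i: i + 3]
        for aa in window:
            if aa not in AMINO_ACIDS:
                raise ValueError(f"non-standard amino acid {aa!r} at position {i + 1}")
        specs.append(
            BeadSpec(
                index=len(specs),
                residues=window,
                g=float(sum(TRANSFER_DG[aa] for aa in window)),
                q=int(sum(CHARGE[aa] for aa in window)),
            )
        )
    return specs


def bead_arrays(specs: list[BeadSpec]) -> tuple[np.ndarray, np.ndarray]:
    g = np.array([s.g for s in specs], dtype=np.float64)
    q = np.array([s.q for s in specs], dtype=np.float64)
    return g, q
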