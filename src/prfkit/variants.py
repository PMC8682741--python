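"""Variant universes of the mutational scan.

Three libraries are generated: the NNN single-codon library over a residue
window (all 63 non-wild-type codons at every position, the design that
makes 122 positions x 63 = 7686 possible variants), the exhaustive
single/double/triple nucleotide mutants of the slippery heptanucleotide,
and plain amino-acid missense sets (19 x length) used for simulations.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import pandas as pd

from .polyprotein import (
    RNA_BASES,
    PolyproteinRecord,
    SlipSite,
    _check_rna,
    translate,
)
from ._scales import AMINO_ACIDS

WT_ID = "WT"

ALL_CODONS = tuple(
    a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES
)


def classify_codon_change(wt_codon: str, mut_codon: str) -> str:
    wt_aa = translate(wt_codon)
    mut_aa = translate(mut_codon)
    if mut_aa == wt_aa:
        return "synonymous"
    if mut_aa == "*":
        return "nonsense"
    return "missense"


@dataclass(frozen=True, order=True)
class CodonVariant:
    """One single-codon substitution in the polyprotein reporter."""

    residue: int
    wt_codon: str
    mut_codon: str

    def __post_init__(self):
        if self.mut_codon == self.wt_codon:
            raise ValueError("mut_codon must differ from wt_codon")
        _check_rna(self.wt_codon, "wt_codon")
        _check_rna(self.mut_codon, "mut_codon")

    @property
    def wt_aa(self) -> str:
        return translate(self.wt_codon)

    @property
    def mut_aa(self) -> str:
        return translate(self.mut_codon)

    @property
    def vclass(self) -> str:
        return classify_codon_change(self.wt_codon, self.mut_codon)

    @property
    def variant_id(self) -> str:
        return f"{self.wt_aa}{self.residue}:{self.wt_codon}>{self.mut_codon}"


def parse_variant_id(variant_id: str) -> CodonVariant:
    """Inverse of :attr:`CodonVariant.variant_id`."""
    head, _, change = variant_id.partition(":")
    wt_codon, _, mut_codon = change.partition(">")
    residue = int(head[1:])
    v = CodonVariant(residue=residue, wt_codon=wt_codon, mut_codon=mut_codon)
    if v.variant_id != variant_id:
        raise ValueError(f"non-canonical variant id {variant_id!r}")
    return v


def enumerate_region_codon_variants(
    record: PolyproteinRecord, start_res: int, end_res: int
) -> list[CodonVariant]:
    """All 63 non-WT codons at every position of [start_res, end_res].

    Deterministic ordering by (residue, codon); over the study's window
    696-817 this yields the printed 7686 possible variants.
    """
    if start_res > end_res:
        raise ValueError("start_res > end_res")
    if (start_res < record.first_residue_number
            or end_res > record.last_residue_number):
        raise ValueError("region outside record")
    out = []
    for res in range(start_res, end_res + 1):
        wt = record.codon_at(res)
        for codon in ALL_CODONS:
            if codon != wt:
                out.append(CodonVariant(res, wt, codon))
    return out


@dataclass(frozen=True)
class ResidueSubstitution:
    """An amino-acid level substitution (simulation input, no codons)."""

    residue: int
    wt_aa: str
    mut_aa: str

    @property
    def sub_id(self) -> str:
        return f"{self.wt_aa}{self.residue}{self.mut_aa}"


def enumerate_missense(aa_seq: str, offset: int = 1) -> list[ResidueSubstitution]:
    """All 19 x len(aa_seq) single missense substitutions.

    ``offset`` is the residue number of the first position (e.g. 725 for
    TM2, giving the 437-variant simulation set).
    """
    subs = []
    for i, wt in enumerate(aa_seq):
        if wt not in AMINO_ACIDS:
            raise ValueError(f"non-standard amino acid {wt!r} at position {i + 1}")
        for mut in AMINO_ACIDS:
            if mut != wt:
                subs.append(ResidueSubstitution(offset + i, wt, mut))
    return subs


@dataclass(frozen=True)
class NtVariantSet:
    """A set of simultaneous point mutations (slip-site multi-mutants).

    Positions are 1-based within the heptamer window (1..7); position
    values <= 0 address the adjacent upstream (E-site) codon.
    """

    muts: tuple[tuple[int, str, str], ...]

    def __post_init__(self):
        positions = [p for p, _, _ in self.muts]
        if len(set(positions)) != len(positions):
            raise ValueError("duplicate mutated position")
        for _, wt, alt in self.muts:
            if wt == alt:
                raise ValueError("alt base equals wt base")

    @property
    def load(self) -> int:
        return len(self.muts)

    @property
    def set_id(self) -> str:
        return ";".join(f"{p}{wt}>{alt}" for p, wt, alt in sorted(self.muts))

    def apply(self, heptamer: str) -> str:
        out = list(heptamer)
        for p, wt, alt in self.muts:
            if out[p - 1] != wt:
                raise ValueError(f"wt base mismatch at heptamer position {p}")
            out[p - 1] = alt
        return "".join(out)


def enumerate_slipsite_mutants(heptamer: str, max_load: int = 3) -> list[NtVariantSet]:
    """Every combination of 1..max_load point mutations in the heptamer.

    21 singles, 189 doubles, 945 triples (1155 total at max_load=3); the
    wild type (load 0) is never emitted.
    """
    if len(heptamer) != 7:
        raise ValueError("heptamer must have 7 bases")
    if max_load not in (1, 2, 3):
        raise ValueError("max_load must be 1, 2 or 3")
    _check_rna(heptamer, "heptamer")
    out = []
    for k in range(1, max_load + 1):
        for positions in itertools.combinations(range(1, 8), k):
            alt_choices = [
                [b for b in RNA_BASES if b != heptamer[p - 1]] for p in positions
            ]
            for alts in itertools.product(*alt_choices):
                out.append(
                    NtVariantSet(
                        tuple(
                            (p, heptamer[p - 1], a)
                            for p, a in zip(positions, alts)
                        )
                    )
                )
    return out


def codon_load_classify(
    v: NtVariantSet, slip: SlipSite | None = None
) -> tuple[int, int, bool]:
    """(P-site load, A-site load, E-site hit) of a slip-site mutant.

    P-site codon = heptamer positions 2-4, A-site codon = positions 5-7;
    position 1 (and any position of the adjacent upstream codon, encoded
    as positions <= 0) counts as an E-site hit.
    """
    p_load = a_load = 0
    e_hit = False
    for pos, _, _ in v.muts:
        if pos < -2 or pos > 7:
            raise ValueError(f"position {pos} outside the slip-site window")
        if 2 <= pos <= 4:
            p_load += 1
        elif 5 <= pos <= 7:
            a_load += 1
        else:
            e_hit = True
    return p_load, a_load, e_hit


# ---------------------------------------------------------------------------
# Tables


def variants_to_table(variants: list[CodonVariant]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "variant_id": [v.variant_id for v in variants],
            "residue": [v.residue for v in variants],
            "wt_codon": [v.wt_codon for v in variants],
            "mut_codon": [v.mut_codon for v in variants],
            "wt_aa": [v.wt_aa for v in variants],
            "mut_aa": [v.mut_aa for v in variants],
            "vclass": [v.vclass for v in variants],
        }
    )


def nt_sets_to_table(sets: list[NtVariantSet]) -> pd.DataFrame:
    rows = []
    for s in sets:
        for p, wt, alt in s.muts:
            rows.append({"set_id": s.set_id, "pos": p, "ref": wt, "alt": alt})
    return pd.DataFrame(rows)
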