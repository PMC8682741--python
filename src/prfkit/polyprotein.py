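"""Sequence and coordinate backbone for the polyprotein reporter.

Everything downstream (variant enumeration, effect maps, simulations) is
expressed in the polyprotein's own coordinates: 1-based residue numbers
(e.g. the mutagenized window I696-P817) and 1-based transcript base
numbers (e.g. the stem-loop bases 2390-2419). A :class:`PolyproteinRecord`
pins the two numbering systems to a concrete sequence fragment; regions,
the slippery heptanucleotide, and stem base-pair lists are annotations on
top of it.

Coordinates are 1-based inclusive throughout; the RNA alphabet {A,C,G,U}
is used internally (FASTA I/O maps T<->U at the file boundary).
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

import pandas as pd
import yaml
from Bio.Seq import Seq
from Bio import SeqIO

RNA_BASES = "ACGU"

_SENSE_CODONS = None


def _sense_codons() -> list[str]:
    global _SENSE_CODONS
    if _SENSE_CODONS is None:
        _SENSE_CODONS = [
            a + b + c
            for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES
            if str(Seq((a + b + c).replace("U", "T")).translate()) != "*"
        ]
    return _SENSE_CODONS


def _check_rna(seq: str, what: str = "sequence") -> None:
    for i, b in enumerate(seq):
        if b not in RNA_BASES:
            raise ValueError(
                f"invalid base {b!r} at position {i + 1} of {what} "
                f"(expected one of {RNA_BASES})"
            )


def translate(nt_seq: str, frame: int = 0) -> str:
    """Translate an RNA string in the 0 or -1 reading frame.

    ``frame=0`` reads codons from the first base. ``frame=-1`` re-reads
    the transcript with the ribosome slipped one base toward the 5' end;
    on a fragment whose first base is the base 5' of the original frame
    (slip-site context is normally supplied with that one extra base),
    this is the frame beginning at the third base of the fragment.
    Stop codons appear as ``*``; a trailing partial codon is dropped.
    """
    if frame not in (0, -1):
        raise ValueError(f"frame must be 0 or -1, got {frame}")
    _check_rna(nt_seq)
    start = 0 if frame == 0 else 2
    sub = nt_seq[start:]
    sub = sub[: len(sub) - len(sub) % 3]
    if not sub:
        raise ValueError("sequence too short to translate in this frame")
    return str(Seq(sub.replace("U", "T")).translate())


def is_canonical_slip_site(heptamer: str) -> bool:
    """True iff the heptamer matches the canonical slippery motif X XXY YYZ.

    Bases 1-3 identical (X), bases 4-6 identical and in {A,U} (Y), base 7
    in {A,C,U} (Z). The wild-type site U UUU UUA satisfies it.
    """
    if len(heptamer) != 7:
        raise ValueError(f"heptamer must have length 7, got {len(heptamer)}")
    _check_rna(heptamer, "heptamer")
    x, y, z = heptamer[0], heptamer[3], heptamer[6]
    return (
        heptamer[1] == x and heptamer[2] == x
        and heptamer[4] == y and heptamer[5] == y
        and y in "AU" and z in "ACU"
    )


@dataclass
class PolyproteinRecord:
    """A polyprotein fragment with residue and transcript numbering."""

    id: str
    aa_seq: str
    nt_seq: str
    first_residue_number: int = 1
    first_nt_number: int = 1

    def __post_init__(self) -> None:
        _check_rna(self.nt_seq, f"nt_seq of {self.id}")
        if len(self.nt_seq) != 3 * len(self.aa_seq):
            raise ValueError(
                f"{self.id}: nt_seq length {len(self.nt_seq)} is not 3x "
                f"aa_seq length {len(self.aa_seq)}"
            )
        if translate(self.nt_seq, 0) != self.aa_seq:
            raise ValueError(f"{self.id}: nt_seq does not translate to aa_seq")

    @property
    def last_residue_number(self) -> int:
        return self.first_residue_number + len(self.aa_seq) - 1

    @property
    def last_nt_number(self) -> int:
        return self.first_nt_number + len(self.nt_seq) - 1

    def residue_to_nt(self, residue: int) -> tuple[int, int]:
        """1-based inclusive transcript span of a residue's codon."""
        if not self.first_residue_number <= residue <= self.last_residue_number:
            raise ValueError(
                f"residue {residue} outside record range "
                f"[{self.first_residue_number}, {self.last_residue_number}]"
            )
        start = self.first_nt_number + 3 * (residue - self.first_residue_number)
        return start, start + 2

    def nt_to_residue(self, nt: int) -> int:
        """Residue whose codon covers transcript base ``nt``."""
        if not self.first_nt_number <= nt <= self.last_nt_number:
            raise ValueError(f"base {nt} outside record range")
        return self.first_residue_number + (nt - self.first_nt_number) // 3

    def codon_at(self, residue: int) -> str:
        s, e = self.residue_to_nt(residue)
        off = s - self.first_nt_number
        return self.nt_seq[off: off + 3]

    def aa_at(self, residue: int) -> str:
        return self.aa_seq[residue - self.first_residue_number]

    def subsequence_nt(self, nt_start: int, nt_end: int) -> str:
        if nt_start > nt_end:
            raise ValueError("nt_start > nt_end")
        if nt_start < self.first_nt_number or nt_end > self.last_nt_number:
            raise ValueError("window outside record")
        a = nt_start - self.first_nt_number
        return self.nt_seq[a: a + (nt_end - nt_start + 1)]


@dataclass
class RegionAnnotation:
    """A named region (TM domain, slip_site, stem...) in residue or nt space."""

    name: str
    start: int
    end: int
    level: str = "residue"  # "residue" or "nt"
    kind: str = ""

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"region {self.name}: start {self.start} > end {self.end}")
        if self.level not in ("residue", "nt"):
            raise ValueError(f"region {self.name}: level must be residue|nt")

    def check_within(self, record: PolyproteinRecord) -> None:
        lo, hi = (
            (record.first_residue_number, record.last_residue_number)
            if self.level == "residue"
            else (record.first_nt_number, record.last_nt_number)
        )
        if self.start < lo or self.end > hi:
            raise ValueError(f"region {self.name} outside record {record.id}")


@dataclass
class SlipSite:
    """The slippery heptanucleotide U1 UUU4 UUA7 and its codon anatomy."""

    heptamer: str
    start_nt: int = 1

    def __post_init__(self) -> None:
        if len(self.heptamer) != 7:
            raise ValueError("slip-site heptamer must have 7 bases")
        _check_rna(self.heptamer, "heptamer")

    @property
    def e_site_base(self) -> str:
        return self.heptamer[0]

    @property
    def p_codon(self) -> str:
        return self.heptamer[1:4]

    @property
    def a_codon(self) -> str:
        return self.heptamer[4:7]

    @property
    def is_canonical(self) -> bool:
        return is_canonical_slip_site(self.heptamer)


@dataclass
class BasePairList:
    """Predicted stem base pairs, consumed as input (never predicted here)."""

    pairs: list[tuple[int, int]] = field(default_factory=list)
    stems: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.pairs) != len(self.stems):
            raise ValueError("pairs and stems must have equal length")
        seen: dict[str, set[int]] = {}
        for (i, j), stem in zip(self.pairs, self.stems):
            if i >= j:
                raise ValueError(f"pair ({i},{j}) must have i < j")
            s = seen.setdefault(stem, set())
            if i in s or j in s:
                raise ValueError(f"coordinate reused within stem {stem}")
            s.update((i, j))

    def for_stem(self, stem: str) -> list[tuple[int, int]]:
        return [p for p, s in zip(self.pairs, self.stems) if s == stem]


# ---------------------------------------------------------------------------
# File I/O


def read_fasta(path) -> dict[str, str]:
    """Read sequences as RNA (T mapped to U)."""
    return {r.id: str(r.seq).upper().replace("T", "U") for r in SeqIO.parse(path, "fasta")}


def write_fasta(seqs: dict[str, str], path, dialect: str = "rna") -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            out = seq.replace("U", "T") if dialect == "dna" else seq
            fh.write(f">{name}\n{out}\n")


def read_regions(path) -> list[RegionAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [
        RegionAnnotation(
            name=row["name"], start=int(row["start"]), end=int(row["end"]),
            level=row.get("level", "residue") if isinstance(row, dict) else row["level"],
            kind=str(row.get("kind", "")),
        )
        for row in df.to_dict("records")
    ]


def write_regions(regions: list[RegionAnnotation], path) -> None:
    pd.DataFrame(
        [{"name": r.name, "start": r.start, "end": r.end, "level": r.level, "kind": r.kind}
         for r in regions]
    ).to_csv(path, sep="\t", index=False)


def read_base_pairs(path) -> BasePairList:
    df = pd.read_csv(path, sep="\t")
    return BasePairList(
        pairs=[(int(i), int(j)) for i, j in zip(df["i"], df["j"])],
        stems=list(df["stem"].astype(str)),
    )


def write_base_pairs(bp: BasePairList, path) -> None:
    pd.DataFrame(
        [{"i": i, "j": j, "stem": s} for (i, j), s in zip(bp.pairs, bp.stems)]
    ).to_csv(path, sep="\t", index=False)


def read_numbering_config(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


# ---------------------------------------------------------------------------
# Fixture generation

TM2_AA = "LTPYALAPNAVIPTSLALLCCVR"
TM2_START_RES = 725
SLIP_HEPTAMER = "UUUUUUA"


def make_polyprotein_fixture(
    seed: int = 0,
    first_residue_number: int = 663,
    n_residues: int = 178,
    first_nt_number: int = 1998,
    tm2_start: int = TM2_START_RES,
    slip_p_site_residue: int = 789,
    stem1_span: tuple[int, int] = (2390, 2419),
) -> tuple[PolyproteinRecord, list[RegionAnnotation], SlipSite, BasePairList]:
    """Random polyprotein fragment embedding the study's printed pieces.

    The full viral sequence is not an input anywhere in the package; tests
    and demos instead use a random fragment that carries the TM2 23-mer at
    its native residue coordinates, the slippery heptanucleotide placed so
    that its P-site codon sits at ``slip_p_site_residue``, and a toy stem-1
    base-pair ladder over ``stem1_span``.
    """
    rng = random.Random(seed)
    codons = [rng.choice(_sense_codons()) for _ in range(n_residues)]

    def set_residue_codon(res: int, codon: str) -> None:
        codons[res - first_residue_number] = codon

    # TM2 at its native coordinates (one codon per residue, arbitrary choice).
    aa_to_codon = {}
    for c in _sense_codons():
        aa_to_codon.setdefault(translate(c), c)
    for k, aa in enumerate(TM2_AA):
        set_residue_codon(tm2_start + k, aa_to_codon[aa])

    # Slippery site: base 1 is the last base of the E-site codon, bases 2-4
    # the P-site codon (UUU, Phe), bases 5-7 the A-site codon (UUA, Leu).
    r = slip_p_site_residue
    set_residue_codon(r - 1, "UGU")  # Cys codon ending in U supplies base 1
    set_residue_codon(r, "UUU")
    set_residue_codon(r + 1, "UUA")

    nt_seq = "".join(codons)
    record = PolyproteinRecord(
        id="sinv_fragment_synthetic",
        aa_seq=translate(nt_seq, 0),
        nt_seq=nt_seq,
        first_residue_number=first_residue_number,
        first_nt_number=first_nt_number,
    )

    slip_start_nt = record.residue_to_nt(r)[0] - 1
    slip = SlipSite(heptamer=SLIP_HEPTAMER, start_nt=slip_start_nt)

    regions = [
        RegionAnnotation("TM1", 696, 718, "residue", "tm"),
        RegionAnnotation("TM2", tm2_start, tm2_start + len(TM2_AA) - 1, "residue", "tm"),
        RegionAnnotation("slip_site", slip_start_nt, slip_start_nt + 6, "nt", "slip"),
        RegionAnnotation("stem1", stem1_span[0], stem1_span[1], "nt", "stem"),
    ]
    for reg in regions:
        reg.check_within(record)

    n_bp = (stem1_span[1] - stem1_span[0] + 1) // 2 - 6
    bp = BasePairList(
        pairs=[(stem1_span[0] + k, stem1_span[1] - k) for k in range(max(n_bp, 4))],
        stems=["stem1"] * max(n_bp, 4),
    )
    return record, regions, slip, bp
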