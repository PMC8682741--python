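"""Ready-made constructs for simulations and tests.

``make_test_construct`` builds a compact synthetic membrane-protein
construct (polar N-flank, hydrophobic TM1, loop, an exchangeable TM2,
polar C-linker to the slip-site) whose arrest point leaves a short taut
linker between TM2 and the ribosome — the geometry that generates
slip-site pulling forces. ``make_polyprotein_construct`` maps the
polyprotein fixture of :mod:`prfkit.polyprotein` onto a Construct.
"""

from __future__ import annotations

from itertools import cycle, islice

from ..polyprotein import PolyproteinRecord, RegionAnnotation, TM2_AA, TM2_START_RES
from .engine import default_start_residue
from .protocols import Construct

POLAR_PATTERN = "GSAT"
TM1_TEST = "L" * 15  # strongly hydrophobic, integrates reliably


def _polar(n: int) -> str:
    return "".join(islice(cycle(POLAR_PATTERN), n))


def make_test_construct(
    tm2_seq: str = "L" * 18,
    total_residues: int | None = None,
) -> Construct:
    """Synthetic construct with an exchangeable TM2.

    Layout (start_res = 1): 6 mildly polar residues, TM1 (15), a
    6-residue loop, TM2, then a mildly polar linker; the slip-site sits
    36 residues past the TM2 C-terminus so that, with the 27-residue
    tunnel offset, arrest leaves 3 beads between TM2 and the tether — a
    linker short enough to stay taut while TM2 is membrane-inserted,
    which is what transmits the integration force to the ribosome.
    """
    flank, loop = _polar(6), _polar(6)
    head = flank + TM1_TEST + loop + tm2_seq
    tm2_end = len(head)
    slip_res = tm2_end + 36
    n_total = total_residues or slip_res + 21
    if n_total < slip_res:
        raise ValueError("construct must reach the slip-site")
    aa_seq = head + _polar(n_total - len(head))
    return Construct(
        aa_seq=aa_seq,
        tm1=(len(flank) + 1, len(flank) + len(TM1_TEST)),
        tm2=(len(flank) + len(TM1_TEST) + len(loop) + 1, tm2_end),
        slip_res=slip_res,
        start_res=1,
    )


def tm2_polarity_ladder(n_steps: int = 5, length: int = 18) -> list[str]:
    """TM2 sequences from most polar (poly-Asn) to most hydrophobic
    (poly-Leu), interpolated as a growing N-terminal Leu block.

    The block boundary is aligned to the 3-residue coarse-graining so
    intermediate rungs contain genuinely hydrophobic beads rather than
    mixed (net-polar) ones.
    """
    if n_steps < 2:
        raise ValueError("need at least two ladder steps")
    n_beads = length // 3
    out = []
    for k in range(n_steps):
        leu_beads = round(k * n_beads / (n_steps - 1))
        n_leu = min(3 * leu_beads, length)
        out.append("L" * n_leu + "N" * (length - n_leu))
    return out


def make_polyprotein_construct(
    record: PolyproteinRecord,
    regions: list[RegionAnnotation],
    slip_res: int,
    end_res: int | None = None,
) -> Construct:
    """Construct over the polyprotein fixture's coordinates.

    Translation starts 33 residues before TM1 (P663 for TM1 at I696); the
    topology protocol translates through ``end_res`` (I837 equivalent).
    """
    by_name = {r.name: r for r in regions}
    tm1 = by_name["TM1"]
    tm2 = by_name["TM2"]
    start = default_start_residue(tm1.start)
    end = end_res or record.last_residue_number
    a = start - record.first_residue_number
    b = end - record.first_residue_number + 1
    if a < 0 or b > len(record.aa_seq):
        raise ValueError("record does not cover the construct span")
    return Construct(
        aa_seq=record.aa_seq[a:b],
        tm1=(tm1.start, tm1.end),
        tm2=(tm2.start, tm2.end),
        slip_res=slip_res,
        start_res=start,
    )
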