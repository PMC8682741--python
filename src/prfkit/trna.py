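"""Codon decoding scores from tRNA anticodon abundances.

The score of a sense codon is the summed relative abundance of every tRNA
whose anticodon can decode it: strict Watson-Crick pairing at codon
positions 1-2 and configurable wobble pairing between codon position 3 and
anticodon position 34. Abundance tables (e.g. the HEK293 measurements the
study averaged) are user-supplied TSV; a seeded synthetic table ships for
download-free tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .polyprotein import RNA_BASES, _check_rna, translate

WATSON_CRICK = {"A": "U", "U": "A", "G": "C", "C": "G"}

# Crick wobble with A34 read as inosine: anticodon position 34 -> codon
# third bases it can pair with.
CRICK_WOBBLE = {
    "A": frozenset("UCA"),  # A34 deaminated to inosine pairs U, C, A
    "G": frozenset("CU"),
    "U": frozenset("AG"),
    "C": frozenset("G"),
}

STRICT_WC = {b: frozenset(WATSON_CRICK[b]) for b in RNA_BASES}


@dataclass(frozen=True)
class DecodingRuleSet:
    """Allowed codon-position-3 partners per anticodon-position-34 base."""

    position34: dict = field(default_factory=lambda: dict(CRICK_WOBBLE))

    def __post_init__(self):
        missing = set(RNA_BASES) - set(self.position34)
        if missing:
            raise ValueError(f"rule table missing anticodon bases {sorted(missing)}")

    def pairs(self, anticodon34: str, codon3: str) -> bool:
        return codon3 in self.position34[anticodon34]


DEFAULT_RULES = DecodingRuleSet()
STRICT_RULES = DecodingRuleSet(position34=dict(STRICT_WC))

ALL_ANTICODONS = tuple(
    a + b + c for a in RNA_BASES for b in RNA_BASES for c in RNA_BASES
)


def _require_sense(codon: str) -> None:
    _check_rna(codon, "codon")
    if len(codon) != 3:
        raise ValueError("codon must have 3 bases")
    if translate(codon) == "*":
        raise ValueError(
            f"stop codon {codon} has no decoding score (no tRNA occupies "
            "the A site productively)"
        )


def decoders_of(codon: str, rules: DecodingRuleSet = DEFAULT_RULES) -> set[str]:
    """Anticodons (5'->3') capable of decoding a sense codon.

    Anticodon position 36 pairs codon position 1 and position 35 pairs
    codon position 2, both strict Watson-Crick; anticodon position 34
    pairs codon position 3 under the wobble rules.
    """
    _require_sense(codon)
    ac36 = WATSON_CRICK[codon[0]]
    ac35 = WATSON_CRICK[codon[1]]
    return {
        b34 + ac35 + ac36
        for b34 in RNA_BASES
        if rules.pairs(b34, codon[2])
    }


@dataclass
class TrnaAbundanceTable:
    """Relative tRNA abundance keyed by anticodon (5'->3', RNA)."""

    abundance: dict

    def __post_init__(self):
        for ac, a in self.abundance.items():
            _check_rna(ac, f"anticodon {ac}")
            if len(ac) != 3:
                raise ValueError(f"anticodon {ac!r} is not a triplet")
            if a < 0:
                raise ValueError(f"negative abundance for {ac}")

    @classmethod
    def from_tsv(cls, path) -> "TrnaAbundanceTable":
        df = pd.read_csv(path, sep="\t")
        reps = [c for c in df.columns if c != "anticodon"]
        return replicate_average(df[["anticodon", *reps]])

    def to_tsv(self, path) -> None:
        pd.DataFrame(
            {"anticodon": list(self.abundance), "abundance": list(self.abundance.values())}
        ).to_csv(path, sep="\t", index=False)


def replicate_average(raw: pd.DataFrame) -> TrnaAbundanceTable:
    """Unweighted mean over replicate abundance columns."""
    reps = [c for c in raw.columns if c != "anticodon"]
    if not reps:
        raise ValueError("no replicate columns")
    vals = raw[reps].to_numpy(dtype=float)
    if (vals < 0).any():
        raise ValueError("negative abundance")
    return TrnaAbundanceTable(
        abundance=dict(zip(raw["anticodon"].str.upper().str.replace("T", "U"),
                           vals.mean(axis=1)))
    )


def codon_score(
    codon: str,
    table: TrnaAbundanceTable,
    rules: DecodingRuleSet = DEFAULT_RULES,
) -> float:
    """Sum of abundances of every tRNA capable of decoding the codon.

    Decoders absent from the table contribute 0.
    """
    return float(
        sum(table.abundance.get(ac, 0.0) for ac in decoders_of(codon, rules))
    )


def all_codon_scores(
    table: TrnaAbundanceTable, rules: DecodingRuleSet = DEFAULT_RULES
) -> pd.DataFrame:
    rows = []
    for codon in sorted({c for c in ALL_ANTICODONS if translate(c) != "*"}):
        decs = decoders_of(codon, rules)
        rows.append(
            {
                "codon": codon,
                "aa": translate(codon),
                "score": sum(table.abundance.get(a, 0.0) for a in decs),
                "n_decoders": len(decs & set(table.abundance)),
            }
        )
    return pd.DataFrame(rows)


def synthetic_abundance_table(seed: int = 0) -> TrnaAbundanceTable:
    """Seeded log-normal abundances for every anticodon that decodes a
    sense codon under the default wobble rules (synthetic stand-in for a
    measured cellular tRNA pool)."""
    rng = np.random.default_rng(seed)
    acs = sorted(
        {
            ac
            for codon in ALL_ANTICODONS
            if translate(codon) != "*"
            for ac in decoders_of(codon, DEFAULT_RULES)
        }
    )
    vals = rng.lognormal(mean=0.0, sigma=1.0, size=len(acs))
    vals /= vals.sum()
    return TrnaAbundanceTable(abundance=dict(zip(acs, vals)))
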