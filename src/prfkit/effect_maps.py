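"""Figure-level aggregations of variant scores.

Heatmap matrices (nucleotide, amino-acid and codon level), per-position
aggregates, and the box statistics of slip-site mutational load. All
aggregations propagate missingness explicitly (NA, never 0) and mask
wild-type cells, mirroring the black squares of the published heatmaps.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._scales import AMINO_ACIDS, HYDROPHOBICITY_SCALES
from .polyprotein import RNA_BASES, PolyproteinRecord
from .variants import parse_variant_id, WT_ID

PERCENTILES = (10, 25, 50, 75, 90)


@dataclass
class EffectMatrix:
    """positions x substitutions matrix of mean relative scores."""

    values: pd.DataFrame  # rows: substitutions, cols: positions; NaN = missing
    mask: pd.DataFrame  # True where the cell is the WT identity (always masked)
    row_order: str = ""

    def __post_init__(self):
        if not self.values.index.equals(self.mask.index) or not self.values.columns.equals(self.mask.columns):
            raise ValueError("values and mask must share axes")

    def to_tsv(self, path, form: str = "wide") -> None:
        if form == "wide":
            out = self.values.where(~self.mask)
            out.to_csv(path, sep="\t", na_rep="NA")
        else:
            long = (
                self.values.where(~self.mask)
                .reset_index(names="substitution")
                .melt(id_vars="substitution", var_name="position", value_name="rel_score")
            )
            long.to_csv(path, sep="\t", index=False, na_rep="NA")


def snv_scores(scores: pd.DataFrame, record: PolyproteinRecord) -> pd.DataFrame:
    """Project codon-variant scores onto single-nucleotide variants.

    Keeps codon variants whose mutant codon differs from WT at exactly one
    base; returns columns nt_pos (transcript coords), wt_base, alt_base,
    rel_score.
    """
    rows = []
    for vid, rel in zip(scores["variant_id"], scores["rel_score"]):
        if vid == WT_ID:
            continue
        v = parse_variant_id(vid)
        diffs = [k for k in range(3) if v.wt_codon[k] != v.mut_codon[k]]
        if len(diffs) != 1:
            continue
        k = diffs[0]
        nt_start, _ = record.residue_to_nt(v.residue)
        rows.append(
            {
                "nt_pos": nt_start + k,
                "wt_base": v.wt_codon[k],
                "alt_base": v.mut_codon[k],
                "rel_score": rel,
            }
        )
    return pd.DataFrame(rows, columns=["nt_pos", "wt_base", "alt_base", "rel_score"])


def nt_effect_matrix(
    snvs: pd.DataFrame, record: PolyproteinRecord, window: tuple[int, int]
) -> EffectMatrix:
    """4 bases x positions matrix of SNV effects over an nt window."""
    lo, hi = window
    if lo < record.first_nt_number or hi > record.last_nt_number:
        raise ValueError("window outside record")
    positions = list(range(lo, hi + 1))
    values = pd.DataFrame(np.nan, index=list(RNA_BASES), columns=positions)
    mask = pd.DataFrame(False, index=list(RNA_BASES), columns=positions)
    for pos in positions:
        off = pos - record.first_nt_number
        mask.loc[record.nt_seq[off], pos] = True
    sub = snvs[(snvs["nt_pos"] >= lo) & (snvs["nt_pos"] <= hi)]
    grouped = sub.groupby(["nt_pos", "alt_base"])["rel_score"].mean()
    for (pos, alt), val in grouped.items():
        values.loc[alt, pos] = val
    return EffectMatrix(values, mask, row_order="ACGU")


def position_mean_3snv(snvs: pd.DataFrame, nt_position: int) -> tuple[float, int]:
    """Mean relative score over the (up to 3) SNVs at one transcript base.

    Returns (mean, contributor count); (nan, 0) when none is scored.
    """
    vals = snvs.loc[snvs["nt_pos"] == nt_position, "rel_score"].dropna()
    if len(vals) == 0:
        return float("nan"), 0
    return float(vals.mean()), int(len(vals))


def aa_level_scores(scores: pd.DataFrame) -> pd.DataFrame:
    """Collapse codon variants to (residue, mut_aa) mean relative scores,
    missense only."""
    rows = []
    for vid, rel in zip(scores["variant_id"], scores["rel_score"]):
        if vid == WT_ID:
            continue
        v = parse_variant_id(vid)
        if v.vclass != "missense":
            continue
        rows.append({"residue": v.residue, "wt_aa": v.wt_aa,
                     "mut_aa": v.mut_aa, "rel_score": rel})
    df = pd.DataFrame(rows, columns=["residue", "wt_aa", "mut_aa", "rel_score"])
    if df.empty:
        return df
    return (
        df.groupby(["residue", "wt_aa", "mut_aa"], as_index=False)["rel_score"]
        .mean()
    )


def residue_sd_19(aa_scores: pd.DataFrame, residue: int) -> float:
    """Sample SD (n-1) of missense effects at one residue.

    NaN when fewer than two substitutions are scored — the statistic
    plotted per residue across the 19 possible substitutions.
    """
    vals = aa_scores.loc[aa_scores["residue"] == residue, "rel_score"].dropna()
    if len(vals) < 2:
        return float("nan")
    return float(np.std(vals.to_numpy(), ddof=1))


def load_distribution(
    rel_scores: pd.Series, loads: pd.Series
) -> pd.DataFrame:
    """Box statistics of relative score per slip-site mutational load.

    ``rel_scores`` and ``loads`` are aligned (indexed by mutant set id).
    Returns one row per load with the 10/25/50/75/90th percentiles
    (linear interpolation between order statistics) and the mean; loads
    with no scored members are flagged by NaN statistics and n=0.
    """
    out = []
    for load in sorted(loads.unique()):
        vals = rel_scores[loads == load].dropna().to_numpy()
        row = {"load": int(load), "n": len(vals)}
        if len(vals) == 0:
            row.update({f"p{p}": float("nan") for p in PERCENTILES})
            row["mean"] = float("nan")
        else:
            for p in PERCENTILES:
                row[f"p{p}"] = float(
                    np.percentile(vals, p, method="linear")
                )
            row["mean"] = float(vals.mean())
        out.append(row)
    return pd.DataFrame(out)


def _ordered_rows(scale: dict, universe: list[str]) -> list[str]:
    missing = [u for u in universe if u not in scale]
    if missing:
        raise ValueError(f"scale missing entries for {missing}")
    return sorted(universe, key=lambda s: (-scale[s], s))


def aa_matrix_ordered(
    aa_scores: pd.DataFrame,
    region: tuple[int, int],
    record: PolyproteinRecord,
    scale: str | dict = "biological",
) -> EffectMatrix:
    """20-row amino-acid effect matrix, rows from most hydrophobic (top)
    to most polar (bottom); ties broken alphabetically."""
    if isinstance(scale, str):
        scale = HYDROPHOBICITY_SCALES[scale]
    rows = _ordered_rows(scale, list(AMINO_ACIDS))
    lo, hi = region
    positions = list(range(lo, hi + 1))
    values = pd.DataFrame(np.nan, index=rows, columns=positions)
    mask = pd.DataFrame(False, index=rows, columns=positions)
    for pos in positions:
        mask.loc[record.aa_at(pos), pos] = True
    sub = aa_scores[(aa_scores["residue"] >= lo) & (aa_scores["residue"] <= hi)]
    for _, r in sub.iterrows():
        values.loc[r["mut_aa"], r["residue"]] = r["rel_score"]
    return EffectMatrix(values, mask, row_order="hydrophobicity_desc")


def codon_level_scores(scores: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for vid, rel in zip(scores["variant_id"], scores["rel_score"]):
        if vid == WT_ID:
            continue
        v = parse_variant_id(vid)
        if v.vclass == "nonsense":
            continue
        rows.append({"residue": v.residue, "mut_codon": v.mut_codon,
                     "rel_score": rel})
    df = pd.DataFrame(rows, columns=["residue", "mut_codon", "rel_score"])
    if df.empty:
        return df
    return df.groupby(["residue", "mut_codon"], as_index=False)["rel_score"].mean()


def codon_matrix_by_decoding(
    codon_scores_df: pd.DataFrame,
    region: tuple[int, int],
    record: PolyproteinRecord,
    trna_scores: dict,
) -> EffectMatrix:
    """61-row codon effect matrix ordered by descending decoding
    abundance (sum of decoding tRNA abundances); stop codons excluded,
    cells without coverage left NA."""
    from .variants import ALL_CODONS
    from .polyprotein import translate as _tr

    sense = [c for c in ALL_CODONS if _tr(c) != "*"]
    missing = [c for c in sense if c not in trna_scores]
    if missing:
        raise ValueError(f"trna_scores missing sense codons {missing[:5]}...")
    rows = _ordered_rows(trna_scores, sense)
    lo, hi = region
    positions = list(range(lo, hi + 1))
    values = pd.DataFrame(np.nan, index=rows, columns=positions)
    mask = pd.DataFrame(False, index=rows, columns=positions)
    for pos in positions:
        mask.loc[record.codon_at(pos), pos] = True
    sub = codon_scores_df[
        (codon_scores_df["residue"] >= lo) & (codon_scores_df["residue"] <= hi)
    ]
    for _, r in sub.iterrows():
        values.loc[r["mut_codon"], r["residue"]] = r["rel_score"]
    return EffectMatrix(values, mask, row_order="decoding_abundance_desc")


def plot_effect_matrix(matrix: EffectMatrix, ax=None, cmap: str = "viridis"):
    """Heatmap with masked (WT / no-coverage) cells in black."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(
            figsize=(max(4, 0.2 * matrix.values.shape[1]),
                     max(3, 0.2 * matrix.values.shape[0]))
        )
    data = np.ma.masked_invalid(matrix.values.where(~matrix.mask).to_numpy())
    cm = plt.get_cmap(cmap).copy()
    cm.set_bad("black")
    im = ax.pcolormesh(data, cmap=cm)
    ax.set_yticks(np.arange(len(matrix.values.index)) + 0.5,
                  matrix.values.index, fontsize=6)
    ax.set_xticks(np.arange(0, len(matrix.values.columns), 5) + 0.5,
                  matrix.values.columns[::5], fontsize=6)
    ax.invert_yaxis()
    ax.figure.colorbar(im, ax=ax, label="relative mKate:eGFP ratio")
    return ax
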