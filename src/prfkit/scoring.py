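"""Count-based sort-seq score inference.

The estimator is the standard sort-seq weighted bin mean: a variant's read
fraction in each bin is rescaled to a cell fraction using the sorted-cell
fractions F_b, and the score is the weighted mean of the bin mean
intensities I_b,

    w_vb = (c_vb / sum_v c_vb) * F_b,
    raw_v = sum_b w_vb * I_b / sum_b w_vb,

normalized to the wild type (rel_v = raw_v / raw_WT). Because raw scores
are convex combinations of the bin means, no variant can score below the
lowest bin: the smallest assignable relative score is I_1 / raw_WT (0.35
in the experiment this package models).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .sortseq import BinCountTable, SortCalibration
from .variants import WT_ID

logger = logging.getLogger(__name__)


@dataclass
class ScoreTable:
    """Per-variant inferred relative mKate:eGFP ratios for one replicate."""

    table: pd.DataFrame  # variant_id, raw_score, rel_score, n_reads, pass_filter
    replicate: str = "rep1"
    wt_raw: float = float("nan")
    floor: float = float("nan")

    @property
    def rel(self) -> pd.Series:
        return self.table.set_index("variant_id")["rel_score"]

    def passing(self) -> pd.DataFrame:
        return self.table[self.table["pass_filter"]]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["replicate"] = self.replicate
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ScoreTable":
        df = pd.read_csv(path, sep="\t")
        rep = str(df["replicate"].iloc[0]) if "replicate" in df else "rep1"
        wt = df.loc[df["variant_id"] == WT_ID, "raw_score"]
        return cls(
            df.drop(columns=["replicate"], errors="ignore"),
            replicate=rep,
            wt_raw=float(wt.iloc[0]) if len(wt) else float("nan"),
        )


def score_floor(cal: SortCalibration, wt_raw: float) -> float:
    """Lowest assignable relative score: mean ratio of the lowest bin
    divided by the WT raw score."""
    if wt_raw <= 0:
        raise ValueError("wt_raw must be positive")
    return float(cal.bin_means[0] / wt_raw)


def estimate_scores(
    counts: BinCountTable,
    cal: SortCalibration,
    min_reads: int = 20,
    wt_id: str = WT_ID,
) -> ScoreTable:
    """Infer per-variant scores from bin read counts.

    Variants with zero reads everywhere are omitted (logged); variants
    below ``min_reads`` total reads are kept but flagged
    ``pass_filter=False`` so downstream maps can exclude them. A missing
    or under-covered wild type is fatal since every score is normalized
    to it.
    """
    C = counts.counts.to_numpy(dtype=float)
    depth = C.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        read_frac = np.where(depth > 0, C / np.where(depth > 0, depth, 1), 0.0)
    w = read_frac * cal.bin_fractions
    wsum = w.sum(axis=1)
    n_reads = counts.counts.to_numpy().sum(axis=1)

    covered = wsum > 0
    n_dropped = int((~covered).sum())
    if n_dropped:
        logger.info("omitting %d variants with zero reads in all bins", n_dropped)

    ids = np.asarray(counts.counts.index)
    if wt_id not in set(ids[covered]):
        raise ValueError(f"wild type {wt_id!r} has no reads; cannot normalize")
    raw = np.full(len(ids), np.nan)
    raw[covered] = (w[covered] @ cal.bin_means) / wsum[covered]
    wt_raw = float(raw[ids == wt_id][0])
    wt_reads = int(n_reads[ids == wt_id][0])
    if wt_reads < min_reads:
        raise ValueError(
            f"wild type has {wt_reads} reads, below min_reads={min_reads}"
        )

    df = pd.DataFrame(
        {
            "variant_id": ids[covered],
            "raw_score": raw[covered],
            "rel_score": raw[covered] / wt_raw,
            "n_reads": n_reads[covered],
            "pass_filter": n_reads[covered] >= min_reads,
        }
    ).reset_index(drop=True)
    return ScoreTable(
        df,
        replicate=counts.replicate,
        wt_raw=wt_raw,
        floor=score_floor(cal, wt_raw),
    )


def merge_replicates(
    tables: list[ScoreTable],
) -> tuple[ScoreTable, dict[tuple[str, str], float | None]]:
    """Merge replicate score tables and report replicate agreement.

    The merged relative score is the unweighted mean over replicates in
    which the variant passes the read filter; pairwise Pearson r on the
    shared passing variants is returned per replicate pair (None when
    fewer than 3 variants overlap).
    """
    if len(tables) < 2:
        raise ValueError("need at least two replicates to merge")
    passing = {
        t.replicate: t.passing().set_index("variant_id") for t in tables
    }
    correlations: dict[tuple[str, str], float | None] = {}
    for (ra, da), (rb, db) in itertools.combinations(passing.items(), 2):
        shared = da.index.intersection(db.index)
        if len(shared) >= 3:
            r, _ = stats.pearsonr(
                da.loc[shared, "rel_score"], db.loc[shared, "rel_score"]
            )
            correlations[(ra, rb)] = float(r)
        else:
            correlations[(ra, rb)] = None

    all_ids = sorted(set().union(*[set(d.index) for d in passing.values()]))
    rel = pd.DataFrame(
        {rep: d["rel_score"].reindex(all_ids) for rep, d in passing.items()},
        index=all_ids,
    )
    nreads = pd.DataFrame(
        {rep: d["n_reads"].reindex(all_ids) for rep, d in passing.items()},
        index=all_ids,
    )
    merged = pd.DataFrame(
        {
            "variant_id": all_ids,
            "raw_score": np.nan,
            "rel_score": rel.mean(axis=1, skipna=True).to_numpy(),
            "n_reads": nreads.sum(axis=1, skipna=True).astype(int).to_numpy(),
            "pass_filter": True,
            "n_replicates": rel.notna().sum(axis=1).to_numpy(),
        }
    )
    return ScoreTable(merged, replicate="merged"), correlations


def qc_report(tables: list[ScoreTable]) -> dict:
    """JSON-ready replicate QC: pairwise r, per-replicate floor and WT raw."""
    _, corr = merge_replicates(tables)
    return {
        "pairwise_pearson_r": {f"{a}|{b}": r for (a, b), r in corr.items()},
        "replicates": [
            {"replicate": t.replicate, "wt_raw": t.wt_raw, "floor": t.floor}
            for t in tables
        ],
    }
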