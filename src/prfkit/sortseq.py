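"""Synthetic FACS sort-seq data with known ground truth.

Emulates the study's experiment end to end: each cell of a pooled library
expresses one variant; its mKate:eGFP ratio is log-normally distributed
around the variant's true mean (WT == 1); the pooled population is sorted
into intensity quartiles; each quartile is deep-sequenced, giving
per-variant, per-bin read counts. Because the ground-truth table is kept,
the count-based estimator in :mod:`prfkit.scoring` can be tested for
parameter recovery without any real dataset.

Scale defaults are the desk-test settings (1e5 cells, 2e4 reads/bin); the
experiment's scale (~2e6 cells and reads per fraction) is reachable by
argument.
"""

from __future__ import annotations

from dataclasses import dataclass

import json
import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord

from .variants import WT_ID, parse_variant_id
from .polyprotein import PolyproteinRecord

N_BINS = 4


@dataclass
class MixtureParams:
    """Shape of the true -1PRF ratio distribution across the library.

    A majority null class scattered log-normally about the WT ratio, a
    "down" class uniform over a band bounded below by the assay's score
    floor, and an "up" class uniform above 1.
    """

    w_null: float = 0.7
    w_down: float = 0.2
    w_up: float = 0.1
    null_sigma: float = 0.1
    down_band: tuple[float, float] = (0.35, 0.8)
    up_band: tuple[float, float] = (1.0, 2.5)

    def __post_init__(self):
        w = self.w_null + self.w_down + self.w_up
        if not np.isclose(w, 1.0):
            raise ValueError(f"mixture weights must sum to 1, got {w}")
        if min(self.w_null, self.w_down, self.w_up) < 0:
            raise ValueError("mixture weights must be non-negative")


@dataclass
class TruthTable:
    """variant_id -> true mean ratio mu (WT == 1) plus class labels."""

    table: pd.DataFrame  # columns: variant_id, mu, label
    sigma_cell: float = 0.25

    def __post_init__(self):
        if (self.table["mu"] <= 0).any():
            raise ValueError("true ratios must be positive")
        if WT_ID not in set(self.table["variant_id"]):
            raise ValueError("truth table must contain WT")

    @property
    def variant_ids(self) -> list[str]:
        return list(self.table["variant_id"])

    @property
    def mu(self) -> pd.Series:
        return self.table.set_index("variant_id")["mu"]

    def to_tsv(self, path) -> None:
        df = self.table.copy()
        df["sigma_cell"] = self.sigma_cell
        df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "TruthTable":
        df = pd.read_csv(path, sep="\t")
        sigma = float(df["sigma_cell"].iloc[0]) if "sigma_cell" in df else 0.25
        return cls(df[["variant_id", "mu", "label"]], sigma_cell=sigma)


def make_truth(
    variant_ids: list[str],
    mixture: MixtureParams | None = None,
    seed: int = 0,
    sigma_cell: float = 0.25,
) -> TruthTable:
    """Draw a ground-truth ratio for every variant (WT pinned to 1)."""
    mixture = mixture or MixtureParams()
    rng = np.random.default_rng(seed)
    ids = [v for v in variant_ids if v != WT_ID]
    labels = rng.choice(
        ["null", "down", "up"],
        size=len(ids),
        p=[mixture.w_null, mixture.w_down, mixture.w_up],
    )
    mu = np.empty(len(ids))
    for name, draw in (
        ("null", lambda n: rng.lognormal(0.0, mixture.null_sigma, n)),
        ("down", lambda n: rng.uniform(*mixture.down_band, n)),
        ("up", lambda n: rng.uniform(*mixture.up_band, n)),
    ):
        mask = labels == name
        mu[mask] = draw(int(mask.sum()))
    df = pd.DataFrame(
        {
            "variant_id": [WT_ID, *ids],
            "mu": np.concatenate([[1.0], mu]),
            "label": ["wt", *labels],
        }
    )
    return TruthTable(df, sigma_cell=sigma_cell)


@dataclass
class SortCalibration:
    """Quartile gate boundaries and realized per-bin summaries."""

    boundaries: np.ndarray  # 3 increasing ratio values (25/50/75 percentiles)
    bin_means: np.ndarray  # I_b, mean ratio of cells in bin b
    bin_fractions: np.ndarray  # F_b, fraction of sorted cells per bin

    def __post_init__(self):
        self.boundaries = np.asarray(self.boundaries, dtype=float)
        self.bin_means = np.asarray(self.bin_means, dtype=float)
        self.bin_fractions = np.asarray(self.bin_fractions, dtype=float)
        if not np.all(np.diff(self.boundaries) >= 0):
            raise ValueError("gate boundaries must be non-decreasing")
        if not np.isclose(self.bin_fractions.sum(), 1.0):
            raise ValueError("bin fractions must sum to 1")

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "boundaries": self.boundaries.tolist(),
                    "bin_means": self.bin_means.tolist(),
                    "bin_fractions": self.bin_fractions.tolist(),
                },
                fh,
                indent=2,
            )

    @classmethod
    def from_json(cls, path) -> "SortCalibration":
        with open(path) as fh:
            d = json.load(fh)
        return cls(d["boundaries"], d["bin_means"], d["bin_fractions"])


@dataclass
class CellAssignment:
    """Realized cells per (variant, bin) after the quartile sort."""

    variant_ids: list[str]
    counts: np.ndarray  # shape (n_variants, 4)

    @property
    def cells_per_bin(self) -> np.ndarray:
        return self.counts.sum(axis=0)


def simulate_sort(
    truth: TruthTable,
    n_cells: int = 100_000,
    seed: int = 0,
    abundances: np.ndarray | None = None,
) -> tuple[SortCalibration, CellAssignment]:
    """Grow a cell population and sort it into intensity quartiles.

    Each cell draws a variant (uniformly, or per ``abundances``) and a
    ratio ``exp(Normal(ln mu_v, sigma_cell))``. Gating is by rank on the
    pooled population (the experiment gates the mixed library): cells are
    stably sorted by ratio, ties resolved by cell index, and split into
    four equal fractions, so F_b = 0.25 up to the division remainder even
    in degenerate (zero-noise) populations.
    """
    if n_cells < N_BINS:
        raise ValueError("need at least 4 cells")
    if truth.sigma_cell < 0:
        raise ValueError("sigma_cell must be non-negative")
    rng = np.random.default_rng(seed)
    ids = truth.variant_ids
    mu = truth.mu.to_numpy()
    var_idx = rng.choice(len(ids), size=n_cells, p=abundances)
    ratios = np.exp(rng.normal(np.log(mu[var_idx]), truth.sigma_cell))

    order = np.argsort(ratios, kind="stable")
    base, rem = divmod(n_cells, N_BINS)
    sizes = np.array([base + (1 if b < rem else 0) for b in range(N_BINS)])
    bins = np.empty(n_cells, dtype=np.int64)
    bins[order] = np.repeat(np.arange(N_BINS), sizes)

    cal = SortCalibration(
        boundaries=np.percentile(ratios, [25, 50, 75]),
        bin_means=np.array([ratios[bins == b].mean() for b in range(N_BINS)]),
        bin_fractions=sizes / n_cells,
    )
    counts = np.zeros((len(ids), N_BINS), dtype=np.int64)
    np.add.at(counts, (var_idx, bins), 1)
    return cal, CellAssignment(variant_ids=ids, counts=counts)


@dataclass
class BinCountTable:
    """Per-replicate variant x FACS-bin read counts."""

    counts: pd.DataFrame  # index variant_id, columns 1..4
    replicate: str = "rep1"
    empty: bool = False

    @property
    def depth_per_bin(self) -> np.ndarray:
        return self.counts.to_numpy().sum(axis=0)

    def to_tsv(self, path) -> None:
        long = self.counts.reset_index().melt(
            id_vars="variant_id", var_name="bin", value_name="count"
        )
        long["replicate"] = self.replicate
        long.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "BinCountTable":
        long = pd.read_csv(path, sep="\t")
        wide = long.pivot_table(
            index="variant_id", columns="bin", values="count", aggfunc="sum"
        ).fillna(0).astype(int)
        wide.columns = [int(c) for c in wide.columns]
        rep = str(long["replicate"].iloc[0]) if "replicate" in long else "rep1"
        return cls(wide, replicate=rep, empty=bool(wide.to_numpy().sum() == 0))


def sequence_bins(
    assignment: CellAssignment,
    depth_per_bin: int = 20_000,
    seed: int = 0,
    eps: float = 0.0,
    replicate: str = "rep1",
) -> BinCountTable:
    """Multinomial read sampling from each bin's cellular composition.

    ``eps`` is an optional symmetric mis-assignment rate: each read lands
    in one of the other three bins with total probability eps.
    """
    if depth_per_bin < 0:
        raise ValueError("depth must be >= 0")
    if not 0.0 <= eps < 1.0:
        raise ValueError("eps must be in [0, 1)")
    rng = np.random.default_rng(seed)
    n_var = len(assignment.variant_ids)
    reads = np.zeros((n_var, N_BINS), dtype=np.int64)
    if depth_per_bin > 0:
        for b in range(N_BINS):
            tot = assignment.counts[:, b].sum()
            if tot == 0:
                continue
            reads[:, b] = rng.multinomial(
                depth_per_bin, assignment.counts[:, b] / tot
            )
        if eps > 0.0:
            kept = rng.binomial(reads, 1.0 - eps)
            stray = reads - kept
            reads = kept
            for b in range(N_BINS):
                others = [bb for bb in range(N_BINS) if bb != b]
                moved = rng.multinomial(stray[:, b], [1 / 3] * 3)
                for k, bb in enumerate(others):
                    reads[:, bb] += moved[:, k]
    df = pd.DataFrame(
        reads, index=pd.Index(assignment.variant_ids, name="variant_id"),
        columns=range(1, N_BINS + 1),
    )
    return BinCountTable(df, replicate=replicate, empty=depth_per_bin == 0)


# ---------------------------------------------------------------------------
# Optional FASTQ emission and exact-match calling


def _amplicon_for(record: PolyproteinRecord, start_res: int, end_res: int,
                  variant_id: str) -> str:
    s = record.residue_to_nt(start_res)[0] - record.first_nt_number
    e = record.residue_to_nt(end_res)[1] - record.first_nt_number
    amp = list(record.nt_seq[s: e + 1])
    if variant_id != WT_ID:
        v = parse_variant_id(variant_id)
        if not start_res <= v.residue <= end_res:
            raise ValueError(f"variant {variant_id} outside amplicon")
        off = 3 * (v.residue - start_res)
        if "".join(amp[off: off + 3]) != v.wt_codon:
            raise ValueError(f"wt codon mismatch for {variant_id}")
        amp[off: off + 3] = list(v.mut_codon)
    return "".join(amp)


def emit_read_pairs(
    table: BinCountTable,
    record: PolyproteinRecord,
    start_res: int,
    end_res: int,
    read_length: int,
    seed: int = 0,
):
    """Error-free paired reads for every counted read, per bin.

    Returns ``{bin: (list of R1 SeqRecord, list of R2 SeqRecord)}``; R1 is
    the amplicon 5' end, R2 the reverse complement of its 3' end. The two
    reads must jointly cover the amplicon (2 x read_length >= amplicon).
    """
    amp_len = 3 * (end_res - start_res + 1)
    if 2 * read_length < amp_len:
        raise ValueError(
            f"read pairs of length {read_length} cannot cover the "
            f"{amp_len}-base amplicon"
        )
    rng = np.random.default_rng(seed)
    out = {}
    for b in table.counts.columns:
        r1s, r2s = [], []
        rows = []
        for vid, n in table.counts[b].items():
            rows += [vid] * int(n)
        rng.shuffle(rows)
        for i, vid in enumerate(rows):
            amp = _amplicon_for(record, start_res, end_res, vid).replace("U", "T")
            fwd = amp[:read_length]
            rev = str(Seq(amp[-read_length:]).reverse_complement())
            qname = f"bin{b}_read{i}"
            for lst, seqstr, mate in ((r1s, fwd, 1), (r2s, rev, 2)):
                rec = SeqRecord(Seq(seqstr), id=qname, description=f"/{mate}")
                rec.letter_annotations["phred_quality"] = [40] * len(seqstr)
                lst.append(rec)
        out[int(b)] = (r1s, r2s)
    return out


def write_fastq(pairs: dict, prefix: str) -> list[str]:
    paths = []
    for b, (r1s, r2s) in pairs.items():
        for mate, recs in ((1, r1s), (2, r2s)):
            path = f"{prefix}_bin{b}_R{mate}.fastq"
            with open(path, "w") as fh:
                SeqIO.write(recs, fh, "fastq")
            paths.append(path)
    return paths


def call_read_pairs(
    pairs: dict,
    record: PolyproteinRecord,
    start_res: int,
    end_res: int,
    variant_ids: list[str],
) -> BinCountTable:
    """Exact-match amplicon calling; inverse of :func:`emit_read_pairs`."""
    amp_len = 3 * (end_res - start_res + 1)
    lookup = {
        _amplicon_for(record, start_res, end_res, vid).replace("U", "T"): vid
        for vid in variant_ids
    }
    counts = pd.DataFrame(
        0, index=pd.Index(variant_ids, name="variant_id"),
        columns=range(1, N_BINS + 1),
    )
    for b, (r1s, r2s) in pairs.items():
        for r1, r2 in zip(r1s, r2s):
            s1 = str(r1.seq)
            s2 = str(Seq(str(r2.seq)).reverse_complement())
            recon = s1 + s2[len(s1) + len(s2) - amp_len:]
            vid = lookup.get(recon)
            if vid is not None:
                counts.loc[vid, int(b)] += 1
    return BinCountTable(counts, replicate="fastq")
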