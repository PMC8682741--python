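"""Count-based score inference: estimator oracle, floor, replicate merge."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from prfkit import scoring as sc
from prfkit import sortseq as ss
from prfkit.variants import WT_ID


def make_cal(I=(0.3, 0.8, 1.0, 1.5), F=(0.25, 0.25, 0.25, 0.25)):
    return ss.SortCalibration(
        boundaries=np.array([0.5, 0.9, 1.2]),
        bin_means=np.array(I),
        bin_fractions=np.array(F),
    )


def make_counts(rows: dict) -> ss.BinCountTable:
    return ss.BinCountTable(
        pd.DataFrame.from_dict(rows, orient="index", columns=range(1, 5))
        .rename_axis("variant_id")
    )


def brute_force_score(counts_row, depth, I, F):
    """Independent weighted-mean oracle (no shared helpers)."""
    num = den = 0.0
    for b in range(4):
        if depth[b] == 0:
            continue
        w = (counts_row[b] / depth[b]) * F[b]
        num += w * I[b]
        den += w
    return num / den


class TestEstimator:
    def test_all_reads_in_one_bin_gives_bin_mean(self):
        cal = make_cal()
        counts = make_counts({WT_ID: [25, 25, 25, 25], "v": [0, 0, 40, 0]})
        table = sc.estimate_scores(counts, cal, min_reads=1)
        raw = table.table.set_index("variant_id")["raw_score"]
        assert raw["v"] == pytest.approx(1.0)  # I_3

    def test_equal_fractions_give_mean_of_bin_means(self):
        cal = make_cal()
        counts = make_counts({WT_ID: [10, 10, 10, 10], "v": [7, 7, 7, 7]})
        table = sc.estimate_scores(counts, cal, min_reads=1)
        raw = table.table.set_index("variant_id")["raw_score"]
        assert raw["v"] == pytest.approx(np.mean(cal.bin_means))

    def test_toy_table_matches_hand_arithmetic(self):
        # 90/10/0/0 for v; bin totals 100 each; F=0.25; I=0.3/0.8/1.0/1.5
        cal = make_cal()
        counts = make_counts(
            {WT_ID: [10, 90, 100, 100], "v": [90, 10, 0, 0]}
        )
        table = sc.estimate_scores(counts, cal, min_reads=1)
        raw = table.table.set_index("variant_id")["raw_score"]
        # independent arithmetic: w = read_fraction * 0.25
        expected = (0.9 * 0.3 + 0.1 * 0.8) / (0.9 + 0.1)
        assert raw["v"] == pytest.approx(expected, abs=1e-12)

    def test_matches_brute_force_oracle_on_random_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            I = np.sort(rng.uniform(0.2, 2.0, 4))
            F = rng.dirichlet(np.ones(4))
            cal = ss.SortCalibration(np.sort(rng.uniform(0.3, 1.5, 3)), I, F)
            n_var = rng.integers(2, 12)
            C = rng.integers(0, 50, size=(n_var, 4))
            C[0] += 1  # WT covered
            ids = [WT_ID] + [f"v{i}" for i in range(n_var - 1)]
            counts = ss.BinCountTable(
                pd.DataFrame(C, index=pd.Index(ids, name="variant_id"),
                             columns=range(1, 5))
            )
            table = sc.estimate_scores(counts, cal, min_reads=1)
            depth = C.sum(axis=0)
            got = table.table.set_index("variant_id")["raw_score"]
            for k, vid in enumerate(ids):
                if C[k].sum() == 0:
                    assert vid not in got.index
                    continue
                expected = brute_force_score(C[k], depth, I, F)
                assert got[vid] == pytest.approx(expected, abs=1e-12)

    def test_missing_wt_is_fatal(self):
        counts = make_counts({"v": [1, 1, 1, 1]})
        with pytest.raises(ValueError, match="wild type"):
            sc.estimate_scores(counts, make_cal(), min_reads=1)

    def test_undercovered_wt_is_fatal(self):
        counts = make_counts({WT_ID: [1, 0, 0, 0], "v": [9, 9, 9, 9]})
        with pytest.raises(ValueError, match="below min_reads"):
            sc.estimate_scores(counts, make_cal(), min_reads=5)

    def test_zero_read_variant_omitted(self, caplog):
        counts = make_counts({WT_ID: [10, 10, 10, 10], "v": [0, 0, 0, 0]})
        table = sc.estimate_scores(counts, make_cal(), min_reads=1)
        assert "v" not in set(table.table["variant_id"])

    def test_monotone_in_top_bin_counts(self):
        cal = make_cal()
        rng = np.random.default_rng(1)
        for _ in range(30):
            base = rng.integers(0, 30, 4)
            prev = -np.inf
            for extra in (0, 5, 20, 80):
                row = base.copy()
                row[3] += extra
                counts = make_counts({WT_ID: [50, 50, 50, 50],
                                      "v": row.tolist()})
                t = sc.estimate_scores(counts, cal, min_reads=1)
                raw = t.table.set_index("variant_id")["raw_score"]["v"]
                assert raw >= prev - 1e-12
                prev = raw

    def test_bounded_by_extreme_bins(self, small_sortseq):
        truth, cal, assign, counts = small_sortseq
        table = sc.estimate_scores(counts, cal, min_reads=1)
        rel = table.table["rel_score"]
        assert (rel >= table.floor - 1e-12).all()
        assert (rel <= cal.bin_means[3] / table.wt_raw + 1e-12).all()
        assert table.rel[WT_ID] == 1.0


class TestFloor:
    def test_examples(self):
        cal = make_cal(I=(0.35, 0.8, 1.0, 1.5))
        assert sc.score_floor(cal, wt_raw=1.0) == pytest.approx(0.35)
        assert sc.score_floor(cal, wt_raw=0.35) == pytest.approx(1.0)
        with pytest.raises(ValueError):
            sc.score_floor(cal, wt_raw=0.0)

    def test_all_bottom_bin_variant_sits_exactly_on_floor(self):
        cal = make_cal()
        counts = make_counts({WT_ID: [10, 10, 10, 70], "v": [33, 0, 0, 0]})
        table = sc.estimate_scores(counts, cal, min_reads=1)
        assert table.rel["v"] == pytest.approx(table.floor, abs=1e-12)


class TestMergeReplicates:
    def _table(self, rels, rep, n_reads=100):
        df = pd.DataFrame(
            {"variant_id": list(rels), "raw_score": np.nan,
             "rel_score": list(rels.values()),
             "n_reads": n_reads, "pass_filter": True}
        )
        return sc.ScoreTable(df, replicate=rep)

    def test_identical_replicates_correlate_perfectly(self):
        rels = {"a": 0.5, "b": 1.0, "c": 1.5}
        merged, corr = sc.merge_replicates(
            [self._table(rels, "r1"), self._table(rels, "r2")]
        )
        assert corr[("r1", "r2")] == pytest.approx(1.0)
        assert merged.rel["b"] == pytest.approx(1.0)

    def test_pearson_scale_invariance(self):
        rels = {"a": 0.5, "b": 1.0, "c": 1.5, "d": 0.8}
        doubled = {k: 2 * v for k, v in rels.items()}
        _, corr = sc.merge_replicates(
            [self._table(rels, "r1"), self._table(doubled, "r2")]
        )
        assert corr[("r1", "r2")] == pytest.approx(1.0)

    def test_no_overlap_reported_missing(self):
        _, corr = sc.merge_replicates(
            [self._table({"a": 1.0, "b": 2.0, "c": 3.0}, "r1"),
             self._table({"x": 1.0, "y": 2.0, "z": 3.0}, "r2")]
        )
        assert corr[("r1", "r2")] is None

    def test_merged_mean_over_passing_only(self):
        t1 = self._table({"a": 1.0, "b": 2.0, "c": 1.0}, "r1")
        t2 = self._table({"a": 3.0, "b": 2.0, "c": 1.0}, "r2")
        t2.table.loc[t2.table.variant_id == "b", "pass_filter"] = False
        merged, _ = sc.merge_replicates([t1, t2])
        assert merged.rel["a"] == pytest.approx(2.0)
        assert merged.rel["b"] == pytest.approx(2.0)  # r1 only

    def test_synthetic_replicates_correlate(self, small_sortseq):
        """Two independent replicates from the same truth agree strongly."""
        truth, cal, assign, counts = small_sortseq
        ab = np.full(len(truth.variant_ids), 0.98 / (len(truth.variant_ids) - 1))
        ab[0] = 0.02
        tables = []
        for r, (s1, s2) in enumerate(((4, 5), (14, 15)), start=1):
            c, a = ss.simulate_sort(truth, n_cells=60_000, seed=s1,
                                    abundances=ab)
            k = ss.sequence_bins(a, depth_per_bin=20_000, seed=s2,
                                 replicate=f"r{r}")
            tables.append(sc.estimate_scores(k, c, min_reads=10))
        _, corr = sc.merge_replicates(tables)
        assert corr[("r1", "r2")] > 0.6


class TestRecovery:
    def test_scores_track_truth_at_small_scale(self, small_sortseq):
        truth, cal, assign, counts = small_sortseq
        table = sc.estimate_scores(counts, cal, min_reads=10)
        m = table.passing().merge(truth.table, on="variant_id")
        m = m[m.variant_id != WT_ID]
        r, _ = stats.pearsonr(m["rel_score"], m["mu"])
        assert r > 0.75
        assert table.rel[WT_ID] == 1.0


def test_qc_report_shape(small_sortseq):
    truth, cal, assign, counts = small_sortseq
    t1 = sc.estimate_scores(counts, cal, min_reads=5)
    t2 = sc.ScoreTable(t1.table.copy(), replicate="rep2", wt_raw=t1.wt_raw,
                       floor=t1.floor)
    report = sc.qc_report([t1, t2])
    assert "rep1|rep2" in report["pairwise_pearson_r"]
    assert report["replicates"][0]["floor"] == pytest.approx(t1.floor)
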