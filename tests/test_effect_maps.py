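"""Figure-level aggregations: matrices, per-position stats, load boxes."""

import numpy as np
import pandas as pd
import pytest

from prfkit import effect_maps as em
from prfkit import trna
from prfkit._scales import AMINO_ACIDS, HYDROPHOBICITY_SCALES
from prfkit.polyprotein import translate
from prfkit.variants import ALL_CODONS, CodonVariant


def scores_df(entries):
    """entries: list of (variant, rel_score)."""
    return pd.DataFrame(
        {"variant_id": [v.variant_id for v, _ in entries],
         "rel_score": [r for _, r in entries]}
    )


class TestSnvProjection:
    def test_single_base_changes_mapped_to_transcript_coords(self, fixture_record):
        record, *_ = fixture_record
        wt = record.codon_at(730)
        alt = ("A" if wt[1] != "A" else "G")
        mut = wt[0] + alt + wt[2]
        df = scores_df([(CodonVariant(730, wt, mut), 0.7)])
        snvs = em.snv_scores(df, record)
        assert len(snvs) == 1
        s, _ = record.residue_to_nt(730)
        assert snvs.iloc[0]["nt_pos"] == s + 1
        assert snvs.iloc[0]["alt_base"] == alt

    def test_multi_base_changes_excluded(self, fixture_record):
        record, *_ = fixture_record
        wt = record.codon_at(730)
        mut = "".join("A" if b != "A" else "G" for b in wt)
        df = scores_df([(CodonVariant(730, wt, mut), 0.7)])
        assert em.snv_scores(df, record).empty


class TestNtMatrix:
    def test_single_cell_and_wt_mask(self, fixture_record):
        record, *_ = fixture_record
        s, _ = record.residue_to_nt(730)
        snvs = pd.DataFrame(
            [{"nt_pos": s, "wt_base": record.nt_seq[s - record.first_nt_number],
              "alt_base": "A", "rel_score": 0.4}]
        )
        if snvs.iloc[0]["wt_base"] == "A":
            snvs.loc[0, "alt_base"] = "G"
        m = em.nt_effect_matrix(snvs, record, (s, s + 5))
        filled = m.values.notna().to_numpy().sum()
        assert filled == 1
        assert m.values.loc[snvs.iloc[0]["alt_base"], s] == 0.4
        # exactly one masked (WT) cell per position
        assert (m.mask.sum(axis=0) == 1).all()

    def test_window_outside_record_rejected(self, fixture_record):
        record, *_ = fixture_record
        with pytest.raises(ValueError):
            em.nt_effect_matrix(pd.DataFrame(columns=["nt_pos", "wt_base",
                                                      "alt_base", "rel_score"]),
                                record, (1, 10))


class TestPositionMean:
    def test_arithmetic(self):
        snvs = pd.DataFrame(
            {"nt_pos": [5, 5, 5], "wt_base": "U", "alt_base": list("ACG"),
             "rel_score": [0.4, 0.5, 0.6]}
        )
        mean, n = em.position_mean_3snv(snvs, 5)
        assert mean == pytest.approx(0.5) and n == 3

    def test_single_contributor(self):
        snvs = pd.DataFrame({"nt_pos": [9], "wt_base": ["U"],
                             "alt_base": ["A"], "rel_score": [0.9]})
        assert em.position_mean_3snv(snvs, 9) == (0.9, 1)

    def test_none_scored_missing(self):
        snvs = pd.DataFrame(columns=["nt_pos", "wt_base", "alt_base",
                                     "rel_score"])
        mean, n = em.position_mean_3snv(snvs, 1)
        assert np.isnan(mean) and n == 0

    def test_matches_groupby_oracle(self):
        rng = np.random.default_rng(2)
        snvs = pd.DataFrame(
            {"nt_pos": rng.integers(1, 20, 200),
             "wt_base": "U",
             "alt_base": rng.choice(list("ACG"), 200),
             "rel_score": rng.uniform(0, 2, 200)}
        )
        oracle = snvs.groupby("nt_pos")["rel_score"].mean()
        for pos in oracle.index:
            mean, _ = em.position_mean_3snv(snvs, pos)
            assert mean == pytest.approx(oracle[pos])


class TestResidueSd:
    def test_all_equal_gives_zero(self):
        aa = pd.DataFrame({"residue": [5] * 19, "wt_aa": "L",
                           "mut_aa": list(AMINO_ACIDS.replace("L", "") + "V")[:19],
                           "rel_score": 0.8})
        assert em.residue_sd_19(aa, 5) == pytest.approx(0.0)

    def test_two_values_closed_form(self):
        aa = pd.DataFrame({"residue": [5, 5], "wt_aa": "L",
                           "mut_aa": ["A", "C"], "rel_score": [1.0, 3.0]})
        assert em.residue_sd_19(aa, 5) == pytest.approx(np.sqrt(2))

    def test_fewer_than_two_missing(self):
        aa = pd.DataFrame({"residue": [5], "wt_aa": ["L"], "mut_aa": ["A"],
                           "rel_score": [1.0]})
        assert np.isnan(em.residue_sd_19(aa, 5))

    def test_matches_numpy_oracle_on_random_tables(self):
        rng = np.random.default_rng(3)
        aa = pd.DataFrame(
            {"residue": rng.integers(1, 6, 100), "wt_aa": "L",
             "mut_aa": rng.choice(list(AMINO_ACIDS), 100),
             "rel_score": rng.uniform(0.3, 2.0, 100)}
        )
        for res in range(1, 6):
            vals = aa.loc[aa.residue == res, "rel_score"].to_numpy()
            assert em.residue_sd_19(aa, res) == pytest.approx(
                np.std(vals, ddof=1)
            )


class TestLoadDistribution:
    def test_simple_class(self):
        rel = pd.Series([1, 2, 3, 4, 5.0], index=list("abcde"))
        loads = pd.Series([1, 1, 1, 1, 1], index=list("abcde"))
        df = em.load_distribution(rel, loads).set_index("load")
        assert df.loc[1, "p50"] == 3 and df.loc[1, "mean"] == 3

    def test_singleton_class(self):
        rel = pd.Series([0.7], index=["a"])
        loads = pd.Series([2], index=["a"])
        row = em.load_distribution(rel, loads).iloc[0]
        for p in (10, 25, 50, 75, 90):
            assert row[f"p{p}"] == pytest.approx(0.7)

    def test_percentiles_match_numpy_linear(self):
        rng = np.random.default_rng(4)
        rel = pd.Series(rng.uniform(0.3, 2, 300))
        loads = pd.Series(rng.integers(1, 4, 300))
        df = em.load_distribution(rel, loads).set_index("load")
        for load in (1, 2, 3):
            vals = rel[loads == load].to_numpy()
            for p in (10, 25, 50, 75, 90):
                assert df.loc[load, f"p{p}"] == pytest.approx(
                    np.percentile(vals, p)
                )

    def test_empty_class_flagged(self):
        rel = pd.Series([0.5, np.nan], index=["a", "b"])
        loads = pd.Series([1, 2], index=["a", "b"])
        df = em.load_distribution(rel, loads).set_index("load")
        assert df.loc[2, "n"] == 0 and np.isnan(df.loc[2, "mean"])


class TestAaMatrix:
    def _aa_scores(self, record):
        rows = []
        for res in (725, 726):
            for mut in "ACD":
                if mut != record.aa_at(res):
                    rows.append({"residue": res, "wt_aa": record.aa_at(res),
                                 "mut_aa": mut, "rel_score": 0.9})
        return pd.DataFrame(rows)

    def test_top_row_is_scale_maximum(self, fixture_record):
        record, *_ = fixture_record
        m = em.aa_matrix_ordered(self._aa_scores(record), (725, 730), record)
        scale = HYDROPHOBICITY_SCALES["biological"]
        assert m.values.index[0] == max(AMINO_ACIDS, key=lambda a: (scale[a], a))

    def test_reversed_scale_reverses_rows(self, fixture_record):
        record, *_ = fixture_record
        scale = HYDROPHOBICITY_SCALES["biological"]
        fwd = em.aa_matrix_ordered(self._aa_scores(record), (725, 727),
                                   record, scale=scale)
        rev = em.aa_matrix_ordered(self._aa_scores(record), (725, 727),
                                   record, scale={k: -v for k, v in scale.items()})
        # antisymmetry up to alphabetical tie-breaks (no ties in this scale)
        assert list(rev.values.index) == list(fwd.values.index)[::-1]

    def test_order_matches_independent_sort(self, fixture_record):
        record, *_ = fixture_record
        scale = HYDROPHOBICITY_SCALES["kyte_doolittle"]
        m = em.aa_matrix_ordered(self._aa_scores(record), (725, 727),
                                 record, scale="kyte_doolittle")
        expected = sorted(AMINO_ACIDS, key=lambda a: (-scale[a], a))
        assert list(m.values.index) == expected

    def test_incomplete_scale_rejected(self, fixture_record):
        record, *_ = fixture_record
        with pytest.raises(ValueError):
            em.aa_matrix_ordered(self._aa_scores(record), (725, 727),
                                 record, scale={"A": 1.0})

    def test_wt_cells_masked(self, fixture_record):
        record, *_ = fixture_record
        m = em.aa_matrix_ordered(self._aa_scores(record), (725, 730), record)
        for pos in range(725, 731):
            assert m.mask.loc[record.aa_at(pos), pos]

    def test_row_order_invariance(self, fixture_record):
        record, *_ = fixture_record
        df = self._aa_scores(record)
        shuffled = df.sample(frac=1.0, random_state=0)
        duplicated = pd.concat([df, df]).reset_index(drop=True)
        a = em.aa_matrix_ordered(df, (725, 727), record)
        b = em.aa_matrix_ordered(shuffled, (725, 727), record)
        c = em.aa_matrix_ordered(duplicated, (725, 727), record)
        pd.testing.assert_frame_equal(a.values, b.values)
        pd.testing.assert_frame_equal(a.values, c.values)


class TestCodonMatrix:
    def test_order_and_permutation_invariance(self, fixture_record):
        record, *_ = fixture_record
        table = trna.synthetic_abundance_table(seed=1)
        tr_scores = {
            row["codon"]: row["score"]
            for _, row in trna.all_codon_scores(table).iterrows()
        }
        df = pd.DataFrame(
            [{"residue": 725, "mut_codon": "AAA", "rel_score": 0.5},
             {"residue": 726, "mut_codon": "CCC", "rel_score": 1.2}]
        )
        m1 = em.codon_matrix_by_decoding(df, (725, 727), record, tr_scores)
        m2 = em.codon_matrix_by_decoding(df.iloc[::-1], (725, 727), record,
                                         tr_scores)
        pd.testing.assert_frame_equal(m1.values, m2.values)
        expected = sorted(
            (c for c in ALL_CODONS if translate(c) != "*"),
            key=lambda c: (-tr_scores[c], c),
        )
        assert list(m1.values.index) == expected
        assert len(m1.values.index) == 61  # stops excluded

    def test_missing_codon_score_rejected(self, fixture_record):
        record, *_ = fixture_record
        with pytest.raises(ValueError):
            em.codon_matrix_by_decoding(
                pd.DataFrame(columns=["residue", "mut_codon", "rel_score"]),
                (725, 726), record, {"AAA": 1.0},
            )


def test_tsv_output_uses_na_sentinel(fixture_record, tmp_path):
    record, *_ = fixture_record
    df = pd.DataFrame([{"residue": 725, "wt_aa": record.aa_at(725),
                        "mut_aa": "A", "rel_score": 0.5}])
    m = em.aa_matrix_ordered(df, (725, 726), record)
    m.to_tsv(tmp_path / "m.tsv")
    text = (tmp_path / "m.tsv").read_text()
    assert "NA" in text and "0.5" in text


def test_plot_effect_matrix_returns_axes(fixture_record):
    import matplotlib
    matplotlib.use("Agg")
    record, *_ = fixture_record
    df = pd.DataFrame([{"residue": 725, "wt_aa": record.aa_at(725),
                        "mut_aa": "A", "rel_score": 0.5}])
    m = em.aa_matrix_ordered(df, (725, 728), record)
    ax = em.plot_effect_matrix(m)
    assert ax.figure is not None
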