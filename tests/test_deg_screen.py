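"""RBH pairing, fold changes, the ratio-of-ratios screen, and qPCR arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from camoil.deg_screen import (
    RATIO_UNDEFINED,
    DEGRecord,
    ExpressionTable,
    HomologPair,
    classify_group,
    ddct_fold,
    differential_expression,
    fold_change,
    load_candidate_table,
    ratio_of_ratios,
    rbh_pairs,
    read_expression,
    screen,
)
from camoil.synthetic_data import ScenarioSpec, gen_expression

SIG, NS = 0.01, 0.5


def make_table(early, late, cultivar="HG"):
    early, late = np.atleast_2d(early), np.atleast_2d(late)
    cols = pd.MultiIndex.from_product(
        [["early", "late"], range(1, early.shape[1] + 1)], names=["timepoint", "replicate"]
    )
    genes = [f"g{i}" for i in range(early.shape[0])]
    return ExpressionTable(cultivar, pd.DataFrame(np.hstack([early, late]), index=genes, columns=cols))


class TestRBH:
    def test_block_diagonal_best_hits(self):
        scores = pd.DataFrame([[9, 1], [1, 9]], index=["A1", "A2"], columns=["B1", "B2"])
        pairs = rbh_pairs(scores)
        assert [(p.gene_hg, p.gene_m43) for p in pairs] == [("A1", "B1"), ("A2", "B2")]

    def test_non_reciprocal_best_hit_dropped(self):
        # A2's best hit is B1, but B1 prefers A1 -> only (A1, B1) survives
        scores = pd.DataFrame([[9, 8], [7, 1]], index=["A1", "A2"], columns=["B1", "B2"])
        pairs = rbh_pairs(scores)
        assert [(p.gene_hg, p.gene_m43) for p in pairs] == [("A1", "B1")]

    def test_tie_broken_lexicographically(self):
        scores = pd.DataFrame([[9, 9], [1, 2]], index=["A1", "A2"], columns=["B1", "B2"])
        pairs = rbh_pairs(scores)
        # A1 ties B1/B2 -> picks B1; B1's best is A1 -> reciprocal
        assert ("A1", "B1") in [(p.gene_hg, p.gene_m43) for p in pairs]

    def test_empty_matrix(self):
        assert rbh_pairs(pd.DataFrame()) == []

    @given(
        arrays(
            float,
            st.tuples(st.integers(1, 6), st.integers(1, 6)),
            elements=st.floats(0.0, 100.0),
        )
    )
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_transpose_symmetry(self, mat):
        scores = pd.DataFrame(
            mat,
            index=[f"A{i}" for i in range(mat.shape[0])],
            columns=[f"B{j}" for j in range(mat.shape[1])],
        )
        fwd = {(p.gene_hg, p.gene_m43) for p in rbh_pairs(scores)}
        rev = {(p.gene_m43, p.gene_hg) for p in rbh_pairs(scores.T)}
        assert fwd == rev
        genes_a = [p[0] for p in fwd]
        assert len(genes_a) == len(set(genes_a))  # each gene in at most one pair


class TestFoldChange:
    def test_identical_values_fc_one_p_one(self):
        tbl = make_table([[5.0, 5.0]], [[5.0, 5.0]])
        fc, p = fold_change(tbl, "g0")
        assert fc == pytest.approx(1.0)
        assert p == 1.0

    def test_exact_doubling_in_pseudo_zero_limit(self):
        tbl = make_table([[10.0, 10.0]], [[20.0, 20.0]])
        fc, _ = fold_change(tbl, "g0", pseudo=1e-12)
        assert fc == pytest.approx(2.0)

    def test_absent_gene_raises(self):
        tbl = make_table([[1.0, 1.0]], [[1.0, 1.0]])
        with pytest.raises(LookupError):
            fold_change(tbl, "nope")

    def test_planted_threefold_log2_cohort_median(self):
        """500 genes with planted log2FC = 3 under NB noise: the median
        estimated fold change should sit near 8 (within [6, 10])."""
        spec = ScenarioSpec(
            seed=11,
            n_lipid_pairs=500,
            n_offpath_pairs=0,
            n_decoys=0,
            planted_degs=tuple(("V", 0.0, 3.0) for _ in range(500)),
        )
        _, tbl_m43, _, _, _ = gen_expression(spec)
        de = differential_expression(tbl_m43)
        assert 6.0 < de["fc"].median() < 10.0

    def test_moderated_and_welch_agree_on_fold_change(self):
        rng = np.random.default_rng(3)
        tbl = make_table(rng.uniform(1, 50, (20, 2)), rng.uniform(1, 50, (20, 2)))
        mod = differential_expression(tbl, method="moderated")
        welch = differential_expression(tbl, method="welch")
        assert np.allclose(mod["fc"], welch["fc"])


class TestRatioOfRatios:
    @pytest.mark.parametrize(
        "fc_hg, fc_m43, expected",
        [(3.03, 8.20, 2.71), (2.62, 32.56, 12.43), (2.30, 6.97, 3.03), (2.01, 5.79, 2.88)],
    )
    def test_published_worked_examples(self, fc_hg, fc_m43, expected):
        assert round(ratio_of_ratios(fc_hg, fc_m43), 2) == expected

    @pytest.mark.parametrize("x", [0.05, 1.0, 7.3])
    def test_identity(self, x):
        assert ratio_of_ratios(x, x) == pytest.approx(1.0)

    def test_zero_denominator_sentinel(self):
        assert ratio_of_ratios(0.0, 8.62) == RATIO_UNDEFINED

    def test_infinite_numerator_sentinel(self):
        assert ratio_of_ratios(8.62, math.inf) == RATIO_UNDEFINED
        assert ratio_of_ratios(2.44, RATIO_UNDEFINED) == RATIO_UNDEFINED

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            ratio_of_ratios(-1.0, 2.0)

    @given(st.floats(0.01, 100.0), st.floats(0.01, 100.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_reciprocal_product_is_one(self, a, b):
        assert ratio_of_ratios(a, b) * ratio_of_ratios(b, a) == pytest.approx(1.0)


class TestClassifyGroup:
    @pytest.mark.parametrize(
        "fc_hg, p_hg, fc_m43, p_m43, expected",
        [
            (3.03, SIG, 8.20, SIG, "I"),
            (0.15, SIG, 0.33, SIG, "II"),
            (0.31, SIG, 19.86, SIG, "III"),
            (0.37, SIG, 2.45, NS, "IV"),   # >2-fold change, not significant: constant
            (2.89, NS, 50.80, SIG, "V"),
            (8.62, SIG, 0.33, SIG, "other"),  # up/down has no group
            (1.0, SIG, 1.0, SIG, "other"),
        ],
    )
    def test_examples(self, fc_hg, p_hg, fc_m43, p_m43, expected):
        assert classify_group(fc_hg, p_hg, fc_m43, p_m43) == expected

    def test_undetected_reference_counts_as_up(self):
        assert classify_group(8.62, SIG, RATIO_UNDEFINED, SIG) == "I"

    @given(
        st.floats(0.0, 20.0), st.floats(0.0, 1.0), st.floats(0.0, 20.0), st.floats(0.0, 1.0)
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_total_partition(self, fc_hg, p_hg, fc_m43, p_m43):
        assert classify_group(fc_hg, p_hg, fc_m43, p_m43) in {"I", "II", "III", "IV", "V", "other"}


def make_record(fc_hg, p_hg, fc_m43, p_m43, kos=("ko00561",)):
    return DEGRecord(
        pair=HomologPair("h", "m", 1.0),
        fc_hg=fc_hg,
        fc_m43=fc_m43,
        p_hg=p_hg,
        p_m43=p_m43,
        ratio=ratio_of_ratios(fc_hg, fc_m43),
        pathways=frozenset(kos),
    )


class TestScreen:
    def test_below_cutoff_dropped(self):
        assert screen([make_record(3.0, SIG, 4.5, SIG)]) == []  # ratio 1.5

    def test_retained_candidate_carries_group(self):
        kept = screen([make_record(3.03, SIG, 8.20, SIG)])
        assert len(kept) == 1 and kept[0].group == "I"

    def test_sentinel_ratio_retained_and_sorted_first(self):
        recs = [make_record(0.0, SIG, 8.62, SIG), make_record(0.31, SIG, 19.86, SIG)]
        kept = screen(recs)
        assert kept[0].ratio == RATIO_UNDEFINED
        assert len(kept) == 2

    def test_off_pathway_dropped(self):
        assert screen([make_record(3.03, SIG, 8.20, SIG, kos=("ko00195",))]) == []

    def test_constant_in_both_dropped(self):
        # huge ratio but neither cultivar changes significantly
        assert screen([make_record(0.9, NS, 2.2, NS)]) == []

    def test_empty_ko_set_rejected(self):
        with pytest.raises(ValueError):
            screen([make_record(3.0, SIG, 8.0, SIG)], lipid_kos=frozenset())


class TestCandidateTableFixture:
    def test_table_shape_and_group_sizes(self):
        records, df = load_candidate_table()
        assert len(records) == 58
        assert df["group"].value_counts().to_dict() == {"V": 26, "IV": 15, "I": 6, "III": 6, "II": 5}

    def test_classifier_reproduces_printed_group_labels(self):
        records, df = load_candidate_table()
        for rec, printed in zip(records, df["group"]):
            assert classify_group(rec.fc_hg, rec.p_hg, rec.fc_m43, rec.p_m43) == printed

    def test_printed_ratios_consistent_with_fold_change_rounding(self):
        """Every printed ratio lies in the interval implied by its fold
        changes being rounded to 2 d.p. (the table's ratios were computed
        from unrounded values)."""
        _, df = load_candidate_table()
        n_checked = 0
        for row in df.itertuples():
            if RATIO_UNDEFINED in (row.fc_hg, row.fc_m43, row.ratio) or float(row.fc_hg) == 0:
                continue
            fc_hg, fc_m43, printed = float(row.fc_hg), float(row.fc_m43), float(row.ratio)
            lo = (fc_m43 - 0.005) / (fc_hg + 0.005)
            hi = (fc_m43 + 0.005) / (fc_hg - 0.005)
            assert lo - 0.005 <= printed <= hi + 0.005
            n_checked += 1
        assert n_checked > 50


class TestDdct:
    def test_equal_cts_give_unity(self):
        assert ddct_fold(20, 18, 20, 18) == pytest.approx(1.0)

    def test_one_cycle_earlier_doubles(self):
        # test sample reaches threshold one cycle earlier -> ddCt = -1 -> 2x
        assert ddct_fold(20, 18, 19, 18) == pytest.approx(2.0)

    def test_positive_ddct_three_point_three_two(self):
        assert ddct_fold(20.0, 18.0, 23.32, 18.0) == pytest.approx(2 ** -3.32)
        assert ddct_fold(20.0, 18.0, 23.32, 18.0) == pytest.approx(0.1, abs=2e-4)


class TestExpressionIO:
    def test_long_format_round_trip(self, tmp_path):
        rng = np.random.default_rng(0)
        tbl = make_table(rng.uniform(0, 30, (5, 2)), rng.uniform(0, 30, (5, 2)))
        rows = []
        for gene in tbl.genes:
            for tp in ("early", "late"):
                for i, v in enumerate(tbl.gene_values(gene, tp), start=1):
                    rows.append({"gene": gene, "timepoint": tp, "replicate": i, "fpkm": v})
        path = tmp_path / "expr.tsv"
        pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
        loaded = read_expression(path, cultivar="HG")
        for gene in tbl.genes:
            assert np.allclose(loaded.gene_values(gene, "late"), tbl.gene_values(gene, "late"))

    def test_single_replicate_rejected(self):
        cols = pd.MultiIndex.from_tuples(
            [("early", 1), ("late", 1)], names=["timepoint", "replicate"]
        )
        with pytest.raises(Exception):
            ExpressionTable("HG", pd.DataFrame([[1.0, 2.0]], index=["g0"], columns=cols))
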