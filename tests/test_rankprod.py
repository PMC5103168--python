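import math

import numpy as np
import pandas as pd
import pytest

import rankvec as rv
from rankvec.io_model import DesignError
from rankvec.rankprod import (
    expression_permutation_evalues,
    null_rank_products,
    pairwise_log_ratios,
    permutation_pfp,
    rank_product_statistic,
)


def _ratio_frame(values, genes=None):
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    return pd.DataFrame(values, index=genes,
                        columns=[f"c{k}" for k in range(values.shape[1])])


def brute_force_rp(values, direction):
    """Independent oracle: per-column ranks by sorting, geometric mean by
    exact integer product then K-th root."""
    values = np.asarray(values, dtype=float)
    G, K = values.shape
    ranks = np.zeros((G, K), dtype=int)
    for k in range(K):
        key = [(-values[g, k], g) if direction == "up" else (values[g, k], g)
               for g in range(G)]
        for rank, (_, g) in enumerate(sorted(key), start=1):
            ranks[g, k] = rank
    return np.array([math.prod(ranks[g]) ** (1 / K) for g in range(G)])


class TestPairwiseLogRatios:
    def test_three_by_three_gives_nine_major_ordered_columns(self, small_em, small_sim):
        _, ss, _ = small_sim
        spec = rv.make_contrast(ss, "hippocampus", "BC", "CC")
        ratios = pairwise_log_ratios(small_em, spec)
        assert ratios.shape[1] == 9
        expected = [f"{a}-{b}" for a in spec.class1_samples for b in spec.class2_samples]
        assert list(ratios.columns) == expected
        a, b = spec.class1_samples[1], spec.class2_samples[2]
        np.testing.assert_allclose(ratios[f"{a}-{b}"], small_em[a] - small_em[b])

    def test_identical_classes_give_zero_matrix(self):
        em = pd.DataFrame({"a1": [1.0, 2.0], "a2": [1.0, 2.0]}, index=["g1", "g2"])
        spec = rv.ContrastSpec("x_vs_y", ("a1",), ("a2",))
        assert (pairwise_log_ratios(em, spec) == 0).all().all()

    def test_single_pair_difference(self):
        em = pd.DataFrame({"a": [6.0], "b": [5.0]}, index=["g"])
        ratios = pairwise_log_ratios(em, rv.ContrastSpec("a_vs_b", ("a",), ("b",)))
        assert ratios.shape == (1, 1) and ratios.iloc[0, 0] == 1.0

    def test_missing_sample_is_an_error(self, small_em):
        spec = rv.ContrastSpec("bad", ("nope",), ("hip_CC_r1",))
        with pytest.raises(DesignError, match="nope"):
            pairwise_log_ratios(small_em, spec)

    def test_overlapping_classes_rejected(self):
        with pytest.raises(DesignError, match="overlap"):
            rv.ContrastSpec("bad", ("a", "b"), ("b", "c"))


class TestRankProductStatistic:
    def test_top_gene_in_every_column_has_rp_one(self):
        ratios = _ratio_frame([[9, 9, 9], [1, 2, 3], [0, 1, 2]])
        assert rank_product_statistic(ratios, "up")["g0"] == 1.0

    def test_geometric_mean_of_ranks(self):
        # gene g1 ranked 2 and 8 among 8 genes in two columns -> rp = 4
        col1 = [7, 6, 5, 4, 3, 2, 1, 0]
        col2 = [1, 0, 2, 3, 4, 5, 6, 7]
        ratios = _ratio_frame(np.c_[col1, col2])
        rp = rank_product_statistic(ratios, "up")
        assert rp["g1"] == pytest.approx(math.sqrt(2 * 8))

    def test_matches_bruteforce_oracle_on_toy(self):
        rng = np.random.default_rng(0)
        values = rng.normal(size=(5, 3))
        ratios = _ratio_frame(values)
        for direction in ("up", "down"):
            np.testing.assert_array_equal(
                rank_product_statistic(ratios, direction).to_numpy(),
                brute_force_rp(values, direction),
            )

    def test_ties_break_to_lower_gene_index(self):
        ratios = _ratio_frame([[1.0], [1.0], [0.0]])
        rp = rank_product_statistic(ratios, "up")
        assert rp.tolist() == [1.0, 2.0, 3.0]

    def test_invariant_to_affine_transform_of_expression(self):
        """Adding a constant to all expression values, or scaling them by a
        positive constant, leaves the rank products unchanged.  Values are
        dyadic rationals so both transforms are exact in floating point."""
        rng = np.random.default_rng(8)
        em = pd.DataFrame(
            rng.integers(0, 1024, size=(80, 6)) / 16.0,
            index=[f"g{i}" for i in range(80)],
            columns=list("abcdef"),
        )
        spec = rv.ContrastSpec("x_vs_y", ("a", "b", "c"), ("d", "e", "f"))
        base = pairwise_log_ratios(em, spec)
        shifted = pairwise_log_ratios(em + 7.0, spec)
        scaled = pairwise_log_ratios(em * 2.0, spec)
        for direction in ("up", "down"):
            ref = rank_product_statistic(base, direction)
            assert ref.equals(rank_product_statistic(shifted, direction))
            assert ref.equals(rank_product_statistic(scaled, direction))

    def test_needs_two_genes(self):
        with pytest.raises(ValueError):
            rank_product_statistic(_ratio_frame([[1.0]]), "up")


class TestPermutationPfp:
    def test_two_gene_single_column_exact_null(self):
        """G=2, K=1: every rank randomisation has exactly one gene at rank 1,
        so the expected null count at rp <= 1 is 1 and at rp <= 2 is 2; pfp
        is 1 for both genes."""
        ratios = _ratio_frame([[2.0], [1.0]])
        res = permutation_pfp(ratios, "up", 4000, rng=1)
        assert res.loc["g0", "rp"] == 1.0
        assert res.loc["g0", "e_value"] == pytest.approx(1.0, abs=0.05)
        assert res.loc["g1", "e_value"] == pytest.approx(2.0, abs=0.05)
        np.testing.assert_allclose(res["pfp"], 1.0, atol=0.05)

    def test_fully_tied_single_column_has_pfp_near_one(self):
        ratios = _ratio_frame(np.zeros((6, 1)))
        res = permutation_pfp(ratios, "up", 3000, rng=2)
        # index tie-break hands out ranks 1..6; under the K=1 null the
        # expected count at rp <= r is exactly r, so pfp ~ 1 everywhere
        np.testing.assert_allclose(res["pfp"], 1.0, atol=0.1)

    def test_seeded_reproducibility(self):
        rng = np.random.default_rng(3)
        ratios = _ratio_frame(rng.normal(size=(40, 4)))
        a = permutation_pfp(ratios, "down", 200, rng=7)
        b = permutation_pfp(ratios, "down", 200, rng=7)
        pd.testing.assert_frame_equal(a, b)

    def test_pfp_monotone_in_rank_order(self):
        rng = np.random.default_rng(4)
        ratios = _ratio_frame(rng.normal(size=(100, 3)))
        res = permutation_pfp(ratios, "up", 300, rng=5)
        ordered = res.sort_values("rank_position")
        assert (np.diff(ordered["pfp"]) >= -1e-12).all()

    def test_null_rank_products_range_and_determinism(self):
        a = null_rank_products(20, 3, 50, np.random.default_rng(9))
        b = null_rank_products(20, 3, 50, np.random.default_rng(9))
        np.testing.assert_array_equal(a, b)
        assert a.min() >= 1.0 and a.max() <= 20.0 and len(a) == 1000


class TestExpressionNull:
    def test_kernel_agrees_with_plain_numpy_reference(self):
        """The binned counting-sort null matches a literal numpy
        implementation of the same within-sample permutation null."""
        rng = np.random.default_rng(0)
        G = 120
        em = pd.DataFrame(
            rng.normal(size=(G, 6)),
            index=[f"g{i}" for i in range(G)],
            columns=list("abcdef"),
        )
        spec = rv.ContrastSpec("x_vs_y", ("a", "b", "c"), ("d", "e", "f"))
        ratios = pairwise_log_ratios(em, spec)
        rp_up = rank_product_statistic(ratios, "up").to_numpy()
        rp_down = rank_product_statistic(ratios, "down").to_numpy()
        e_up, e_down = expression_permutation_evalues(
            em, spec, rp_up, rp_down, 3000, np.random.default_rng(1)
        )

        ref_rng = np.random.default_rng(2)
        A = em[list(spec.class1_samples)].to_numpy()
        B = em[list(spec.class2_samples)].to_numpy()
        count_up = np.zeros(G)
        count_down = np.zeros(G)
        for _ in range(1500):
            Ap = ref_rng.permuted(A, axis=0)
            Bp = ref_rng.permuted(B, axis=0)
            d = (Ap[:, :, None] - Bp[:, None, :]).reshape(G, -1)
            null_frame = _ratio_frame(d, genes=list(em.index))
            nu = rank_product_statistic(null_frame, "up").to_numpy()
            nd = rank_product_statistic(null_frame, "down").to_numpy()
            count_up += np.searchsorted(np.sort(nu), rp_up, side="right")
            count_down += np.searchsorted(np.sort(nd), rp_down, side="right")
        ref_up, ref_down = count_up / 1500, count_down / 1500
        # agreement within Monte-Carlo noise, tightest where it matters (tail)
        for mine, ref in ((e_up, ref_up), (e_down, ref_down)):
            tail = ref < 5
            assert np.abs(mine[tail] - ref[tail]).max() < 1.0
            assert np.corrcoef(mine, ref)[0, 1] > 0.999


class TestRunContrast:
    def test_swapping_classes_mirrors_up_and_down(self, small_em, small_sim):
        _, ss, _ = small_sim
        cfg = rv.RunConfig(n_permutations_rp=60)
        spec = rv.make_contrast(ss, "hippocampus", "BC", "CC")
        fwd = rv.run_contrast(small_em, spec, cfg, rng=np.random.default_rng(3))
        rev = rv.run_contrast(small_em, spec.swapped(), cfg, rng=np.random.default_rng(3))
        for cols in (["gene_id", "rp", "e_value", "pfp", "rank_position"],):
            pd.testing.assert_frame_equal(fwd.up[cols], rev.down[cols])
            pd.testing.assert_frame_equal(fwd.down[cols], rev.up[cols])
        np.testing.assert_allclose(fwd.up["mean_log2fc"], -rev.down["mean_log2fc"])

    def test_significant_calls_are_direction_disjoint(self, small_six):
        for res in small_six:
            assert res.significant["gene_id"].is_unique
            assert res.n_up + res.n_down == len(res.significant)

    def test_mean_log2fc_is_column_mean(self, small_em, small_sim):
        _, ss, _ = small_sim
        cfg = rv.RunConfig(n_permutations_rp=30)
        spec = rv.make_contrast(ss, "hippocampus", "CB", "BC")
        res = rv.run_contrast(small_em, spec, cfg, rng=np.random.default_rng(1))
        ratios = pairwise_log_ratios(small_em, spec)
        table = res.up.set_index("gene_id")
        np.testing.assert_allclose(
            table["mean_log2fc"], ratios.mean(axis=1).loc[table.index]
        )


class TestSixContrasts:
    def test_summary_has_six_fixed_order_rows(self, small_six):
        assert small_six.summary["contrast"].tolist() == [
            "BC_vs_CC", "CB_vs_CC", "BB_vs_CC", "CB_vs_BC", "BB_vs_BC", "BB_vs_CB",
        ]

    def test_missing_group_is_a_hard_error(self, small_sim, small_em, fast_config):
        cm, ss, _ = small_sim
        no_bb = rv.SampleSheet(
            ss.table[~((ss.table.prenatal == "B") & (ss.table.postnatal == "B"))]
        )
        with pytest.raises(DesignError, match="BB"):
            rv.six_contrasts(small_em, no_bb, "hippocampus", fast_config)

    def test_planted_prenatal_genes_show_in_the_right_contrasts(self):
        """Category III up genes load BC_vs_CC and BB_vs_CC, not CB_vs_CC."""
        params = rv.SimulationParams(
            n_genes=1500,
            n_per_category={"III": 40},
            sign_fraction_up=1.0,
            effect_size=2.5,
            seed=13,
        )
        cm, ss, _ = rv.simulate_counts(params, tissues=("hippocampus",))
        em = rv.expression_matrix(cm)
        cfg = rv.RunConfig(n_permutations_rp=300)
        six = rv.six_contrasts(em, ss, "hippocampus", cfg, rng=np.random.default_rng(1))
        counts = six.summary.set_index("contrast")
        assert counts.loc["BC_vs_CC", "n_up"] >= 20
        assert counts.loc["BB_vs_CC", "n_up"] >= 20
        assert counts.loc["CB_vs_CC", "n_up"] <= 3


class TestLinearFoldChanges:
    def test_signed_ratio_convention(self):
        norm = pd.DataFrame(
            {"a1": [10.0, 2.0], "a2": [10.0, 2.0], "b1": [5.0, 8.0], "b2": [5.0, 8.0]},
            index=["up2", "down4"],
        )
        spec = rv.ContrastSpec("a_vs_b", ("a1", "a2"), ("b1", "b2"))
        fc = rv.linear_fold_changes(norm, spec)
        assert fc["up2"] == pytest.approx(2.0)
        assert fc["down4"] == pytest.approx(-4.0)
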