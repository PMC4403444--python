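"""DEG-calling machinery: exact test, permutation null, Stouffer, callers."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from corego import differential as de
from corego import normalization as nm
from corego import synthetic_data as sd
from corego.formats_io import CountMatrix, GeneAnnotation


def exact_test_oracle(a, b, phi, mu=5.0):
    """Independent enumeration oracle for the conditional exact test.

    Builds the conditional law of the group-A total from scipy pmf products
    (group sums of iid NB/Poisson replicates) and applies the
    minimum-likelihood two-sided rule.
    """
    a, b = np.asarray(a), np.asarray(b)
    n_a, n_b = len(a), len(b)
    t = int(a.sum() + b.sum())
    if t == 0:
        return 1.0
    s = np.arange(t + 1)
    if phi == 0:
        pa = stats.poisson.pmf(s, n_a * mu)
        pb = stats.poisson.pmf(t - s, n_b * mu)
    else:
        r = 1.0 / phi
        p = r / (r + mu)
        pa = stats.nbinom.pmf(s, n_a * r, p)
        pb = stats.nbinom.pmf(t - s, n_b * r, p)
    w = pa * pb
    w = w / w.sum()
    obs = w[int(a.sum())]
    return float(w[w <= obs * (1 + 1e-12)].sum())


class TestNbExactTest:
    def test_identical_groups_give_p_one(self):
        assert de.nb_exact_test([5, 5], [5, 5], 0.1) == 1.0

    def test_extreme_binomial_split(self):
        # 0 vs 10 with phi=0: 2 * C(10,0) / 2^10
        p = de.nb_exact_test([0], [10], 0.0)
        assert p == pytest.approx(0.001953125, abs=1e-15)

    def test_small_nb_instance_matches_enumeration(self):
        p = de.nb_exact_test([3], [9], 0.2)
        assert p == pytest.approx(exact_test_oracle([3], [9], 0.2), abs=1e-12)

    @pytest.mark.parametrize("phi", [0.0, 0.1, 0.5])
    @pytest.mark.parametrize("split", [(0, 12), (4, 8), (6, 6), (11, 1)])
    def test_various_splits_match_enumeration(self, phi, split):
        a, b = split
        p = de.nb_exact_test([a], [b], phi)
        assert p == pytest.approx(exact_test_oracle([a], [b], phi), abs=1e-12)

    def test_replicated_groups_match_enumeration(self):
        p = de.nb_exact_test([3, 4], [9, 8], 0.15)
        assert p == pytest.approx(
            exact_test_oracle([3, 4], [9, 8], 0.15), abs=1e-12
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            de.nb_exact_test([-1], [3], 0.1)

    def test_zero_total_gives_p_one(self):
        assert de.nb_exact_test([0, 0], [0, 0], 0.2) == 1.0


class TestCommonDispersion:
    def test_poisson_data_estimates_near_zero(self):
        spec = sd.ExpressionSimSpec(
            n_genes=2000, conditions=(("WT", 2), ("KD", 2)),
            dispersion=0.0, deg_fraction=0.0, seed=5,
        )
        cm, _ = sd.simulate_expression(spec)
        assert de.estimate_common_dispersion(cm) < 0.02

    def test_recovers_planted_dispersion(self):
        spec = sd.ExpressionSimSpec(
            n_genes=2000, conditions=(("WT", 2), ("KD", 2)),
            dispersion=0.2, deg_fraction=0.0, seed=5,
        )
        cm, _ = sd.simulate_expression(spec)
        assert 0.1 <= de.estimate_common_dispersion(cm) <= 0.3

    def test_identical_replicates_hit_zero_boundary(self):
        counts = pd.DataFrame(
            {"s1": [50], "s2": [50]}, index=pd.Index(["g"], name="gene_id")
        ).astype(np.int64)
        design = pd.DataFrame(
            {"condition": ["c", "c"], "replicate": [1, 2]},
            index=pd.Index(["s1", "s2"], name="sample_id"),
        )
        assert de.estimate_common_dispersion(CountMatrix(counts, design)) == 0.0

    def test_unreplicated_design_rejected(self, tiny_counts):
        with pytest.raises(ValueError, match="fold-change"):
            de.estimate_common_dispersion(tiny_counts)


class TestLog2MedianRatio:
    def test_direct_formula(self):
        # medians 4 and 8 with pseudocount 1
        got = de.log2_median_ratio([4, 4], [8, 8])
        assert got == pytest.approx(np.log2(5 / 9), abs=1e-12)

    def test_identical_vectors_zero(self):
        assert de.log2_median_ratio([3, 7], [3, 7]) == 0.0

    def test_zero_medians_guarded(self):
        assert de.log2_median_ratio([0, 0], [0, 0]) == 0.0


class TestPermutationNull:
    def _norm(self, values, conditions=("KD", "KD", "WT", "WT")):
        genes = pd.Index([f"g{i}" for i in range(values.shape[0])], name="gene_id")
        samples = [f"s{j}" for j in range(values.shape[1])]
        design = pd.DataFrame(
            {"condition": conditions, "replicate": [1, 2, 1, 2]},
            index=pd.Index(samples, name="sample_id"),
        )
        return nm.NormalizedMatrix(
            values=pd.DataFrame(values, index=genes, columns=samples),
            tmm_factors=pd.Series(1.0, index=samples),
            effective_library=pd.Series(1e6, index=samples),
            design=design,
        )

    def test_identical_samples_give_all_zero_null(self):
        v = np.tile(np.arange(10.0)[:, None], (1, 4))
        null = de.build_permutation_null(self._norm(v), "WT", "KD")
        assert np.all(null.statistics == 0)

    def test_pool_size_counts_partitions_times_genes(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(1, 100, size=(1000, 4))
        null = de.build_permutation_null(self._norm(v), "WT", "KD")
        assert null.n_partitions == 2  # 2v2: 3 distinct partitions minus identity
        assert len(null) == 2000

    def test_null_symmetric_about_zero(self):
        spec = sd.ExpressionSimSpec(
            n_genes=2000, conditions=(("WT", 2), ("KD", 2)),
            deg_fraction=0.0, seed=9,
        )
        cm, _ = sd.simulate_expression(spec)
        norm = nm.tmm_cpm(cm)
        null = de.build_permutation_null(norm, "WT", "KD", seed=9)
        se = null.statistics.std() / np.sqrt(len(null))
        assert abs(null.statistics.mean()) < 3 * se

    def test_single_samples_rejected(self):
        v = np.ones((5, 4))
        with pytest.raises(ValueError):
            de.build_permutation_null(
                self._norm(v, conditions=("A", "B", "WT", "WT")), "WT", "A"
            )


class TestEmpiricalP:
    def test_zero_statistic_gives_one(self):
        null = de.PermutationNull(np.array([-1.0, 0.5, 2.0]), 1, 0)
        assert de.empirical_p(0.0, null) == 1.0

    def test_extreme_statistic_hits_floor(self):
        null = de.PermutationNull(np.linspace(-1, 1, 999), 1, 0)
        assert de.empirical_p(5.0, null) == pytest.approx(1 / 1000)

    def test_never_below_add_one_floor(self):
        rng = np.random.default_rng(3)
        null = de.PermutationNull(rng.normal(size=500), 1, 0)
        p = de.empirical_p(rng.normal(size=200) * 10, null)
        assert (p >= 1 / 501).all()

    def test_calibration_on_uniform_null(self):
        """Empirical p of statistics drawn from the null itself is uniform."""
        rng = np.random.default_rng(13)
        null = de.PermutationNull(rng.uniform(-1, 1, size=4000), 1, 13)
        stats_ = rng.uniform(-1, 1, size=2000)
        p = de.empirical_p(stats_, null)
        assert stats.kstest(p, "uniform").statistic < 0.05


class TestStouffer:
    def test_half_half_gives_half(self):
        assert de.stouffer_combine([0.5, 0.5]) == pytest.approx(0.5, abs=1e-12)

    def test_two_p05_reference_value(self):
        # Z = 2 * 1.6448536... / sqrt(2) = 2.3261742...
        got = de.stouffer_combine([0.05, 0.05])
        expected = float(stats.norm.sf(2 * stats.norm.isf(0.05) / np.sqrt(2)))
        assert got == pytest.approx(expected, abs=1e-12)
        assert got == pytest.approx(0.0100046, abs=5e-6)

    def test_single_p_unchanged(self):
        assert de.stouffer_combine([0.2]) == pytest.approx(0.2, abs=1e-12)

    def test_monotone_in_k_for_small_p(self):
        ps = [de.stouffer_combine([0.3] * k) for k in range(1, 6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))

    def test_boundary_p_clamped_with_warning(self):
        with pytest.warns(UserWarning):
            p = de.stouffer_combine([0.0, 0.5])
        assert 0.0 < p < 0.5


class TestPermutationCutoff:
    def test_hand_percentiles(self):
        null = de.PermutationNull(np.array([-2.0, -1.0, 0.0, 1.0, 2.0]), 1, 0)
        # linear interpolation at 2.5/97.5 over 5 points: -1.9 and 1.9
        assert de.permutation_ratio_cutoff(null) == pytest.approx(1.9)

    def test_all_zero_null(self):
        null = de.PermutationNull(np.zeros(100), 1, 0)
        assert de.permutation_ratio_cutoff(null) == 0.0

    def test_symmetric_null_equals_single_tail(self):
        rng = np.random.default_rng(17)
        x = rng.normal(size=20_000)
        null = de.PermutationNull(np.concatenate([x, -x]), 1, 17)
        cutoff = de.permutation_ratio_cutoff(null)
        assert cutoff == pytest.approx(
            abs(np.percentile(null.statistics, 97.5)), abs=0.02
        )


class TestCallers:
    def test_fc_threshold_constant(self):
        assert de.FC_THRESHOLD == pytest.approx(0.58)

    @pytest.mark.parametrize(
        "lfc,expected", [(0.60, "up"), (-0.58, "none"), (0.0, "none"), (-0.7, "down")]
    )
    def test_fc_caller_boundaries(self, lfc, expected):
        calls = de.call_degs_by_fc(pd.Series([lfc], index=["g"]))
        assert calls.iloc[0] == expected

    def test_unexpressed_gene_never_called(self):
        calls = de.call_degs_by_fc(
            pd.Series([2.0], index=["g"]), expressed=pd.Series([False], index=["g"])
        )
        assert calls.iloc[0] == "none"

    @pytest.mark.parametrize(
        "p,lmr,expected",
        [(0.04, 0.5, "up"), (0.04, 0.2, "none"), (0.2, 2.0, "none"),
         (0.04, -0.5, "down")],
    )
    def test_replicated_caller_rules(self, p, lmr, expected):
        table = pd.DataFrame({"p_combined": [p], "lmr": [lmr]}, index=["g"])
        calls = de.call_degs_replicated(table, alpha=0.05, cutoff=0.378)
        assert calls.iloc[0] == expected

    def test_expressed_gene_flags(self):
        genes = pd.Index(["zero", "low", "boundary", "high"], name="gene_id")
        samples = ["a1", "b1"]
        values = pd.DataFrame(
            [[0.0, 0.0], [0.4, 0.6], [1.0, 1.0], [0.0, 1.5]],
            index=genes, columns=samples,
        )
        design = pd.DataFrame(
            {"condition": ["A", "B"], "replicate": [1, 1]},
            index=pd.Index(samples, name="sample_id"),
        )
        norm = nm.NormalizedMatrix(
            values=values, tmm_factors=pd.Series(1.0, index=samples),
            effective_library=pd.Series(1e6, index=samples), design=design,
        )
        flags = de.expressed_genes(norm, min_cpm=1.0)
        assert list(flags) == [False, False, False, True]

    def test_gene_order_invariance(self):
        spec = sd.ExpressionSimSpec(n_genes=300, seed=23)
        cm, _ = sd.simulate_expression(spec)
        table = de.run_fc_pipeline(cm, "WT", "KO_A")
        perm = np.random.default_rng(0).permutation(300)
        shuffled = CountMatrix(cm.counts.iloc[perm], cm.design)
        table2 = de.run_fc_pipeline(shuffled, "WT", "KO_A")
        pd.testing.assert_frame_equal(table2, table.iloc[perm])


class TestLincRnaSubset:
    def _annotation(self, gene_ids, linc_ids):
        table = pd.DataFrame(
            {
                "chrom": "chr1",
                "strand": "+",
                "tss": np.arange(len(gene_ids)) * 1000 + 100,
                "biotype": [
                    "lincRNA" if g in linc_ids else "protein_coding"
                    for g in gene_ids
                ],
            },
            index=pd.Index(gene_ids, name="gene_id"),
        )
        return GeneAnnotation(table=table)

    def test_biotype_filter_and_threshold(self):
        genes = ["linc_dn", "coding_dn", "linc_flat"]
        ann = self._annotation(genes, {"linc_dn", "linc_flat"})
        table = pd.DataFrame(
            {"log2fc": [-0.7, -0.7, 0.1],
             "expressed": [True, True, True]},
            index=pd.Index(genes, name="gene_id"),
        )
        out = de.differential_lincrnas(table, ann)
        assert set(out.index) == {"linc_dn", "linc_flat"}
        assert out.loc["linc_dn", "deg"] == "down"
        assert out.loc["linc_flat", "deg"] == "none"
        assert "coding_dn" not in out.index

    def test_result_bounded_by_universe_size(self):
        spec = sd.ExpressionSimSpec(n_genes=1000, lincrna_fraction=0.226, seed=31)
        cm, truth = sd.simulate_expression(spec)
        ann = self._annotation(
            list(cm.gene_ids), set(truth.index[truth["is_lincRNA"]])
        )
        table = de.run_fc_pipeline(cm, "WT", "KO_A")
        out = de.differential_lincrnas(table, ann)
        assert len(out) <= 226

    def test_empty_universe_warns(self):
        ann = self._annotation(["g1"], set())
        table = pd.DataFrame(
            {"log2fc": [1.0], "expressed": [True]},
            index=pd.Index(["g1"], name="gene_id"),
        )
        with pytest.warns(UserWarning, match="empty lincRNA"):
            out = de.differential_lincrnas(table, ann)
        assert out.empty
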