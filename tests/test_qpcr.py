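"""Stability algorithms against brute-force oracles and planted-order recovery."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

from vitismet import (
    bestkeeper,
    delta_ct_stability,
    generate_cq_table,
    genorm,
    goi_group_tests,
    normalize_goi,
    normfinder,
    relative_quantities,
    stability_report,
)
from vitismet.qpcr import composite_rank, rank_min_ties
from vitismet.simulate import make_sample_metadata


def cq_frame(rows, genes=None, samples=None):
    rows = np.asarray(rows, dtype=float)
    genes = genes or [f"g{i}" for i in range(rows.shape[0])]
    samples = samples or [f"s{j}" for j in range(rows.shape[1])]
    return pd.DataFrame(rows, index=genes, columns=samples)


class TestRelativeQuantities:
    def test_perfect_doubling_closed_form(self):
        q = relative_quantities(cq_frame([[20.0, 21.0, 22.0]]), 2.0)
        np.testing.assert_allclose(q.iloc[0], [1.0, 0.5, 0.25])

    def test_constant_row_gives_unit_quantities(self):
        q = relative_quantities(cq_frame([[25.0, 25.0, 25.0]]), 2.0)
        np.testing.assert_allclose(q.iloc[0], 1.0)

    def test_table4_efficiency_value(self):
        # FatB amplification efficiency 1.93; one cycle late = 1/1.93
        q = relative_quantities(cq_frame([[20.0, 21.0]]), 1.93)
        assert q.iloc[0, 1] == pytest.approx(1 / 1.93)

    def test_out_of_range_efficiency_rejected(self):
        with pytest.raises(ValueError):
            relative_quantities(cq_frame([[20.0, 21.0]]), 2.5)


def brute_force_genorm_m(q):
    """Direct pairwise-SD definition of the geNorm M value."""
    logq = np.log2(q.to_numpy())
    m = {}
    for j, gene in enumerate(q.index):
        sds = [np.std(logq[j] - logq[k], ddof=1)
               for k in range(q.shape[0]) if k != j]
        m[gene] = np.mean(sds)
    return pd.Series(m)


class TestGenorm:
    def test_m_values_match_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        cq = cq_frame(rng.uniform(18, 30, (5, 8)))
        q = relative_quantities(cq, 2.0)
        res = genorm(q)
        oracle = brute_force_genorm_m(q)
        np.testing.assert_allclose(res.m_values, oracle[res.m_values.index],
                                   atol=1e-12)

    def test_identical_genes_have_zero_m(self):
        q = relative_quantities(cq_frame([[20, 22, 24]] * 3), 2.0)
        res = genorm(q)
        np.testing.assert_allclose(res.m_values, 0.0, atol=1e-12)

    def test_proportional_pair_survives_iteration(self):
        rng = np.random.default_rng(1)
        common = rng.uniform(20, 24, 10)
        cq = cq_frame([common, common + 1.0, common + rng.normal(0, 2.0, 10)],
                      genes=["a", "b", "noisy"])
        res = genorm(relative_quantities(cq, 2.0))
        assert set(res.ranking[:2]) == {"a", "b"}
        assert res.ranks["a"] == res.ranks["b"] == 1
        assert res.ranks["noisy"] == 3

    def test_pairwise_v_length_and_positive(self):
        rng = np.random.default_rng(2)
        cq = cq_frame(rng.uniform(18, 30, (6, 10)))
        res = genorm(relative_quantities(cq, 2.0))
        assert len(res.pairwise_v) == 4  # V2/3 .. V5/6
        assert (res.pairwise_v >= 0).all()

    def test_requires_three_genes(self):
        with pytest.raises(ValueError):
            genorm(relative_quantities(cq_frame([[20, 21], [22, 23]]), 2.0))

    def test_sample_shift_invariance(self):
        """Adding a constant to every gene of one sample leaves M unchanged."""
        rng = np.random.default_rng(3)
        cq = cq_frame(rng.uniform(18, 30, (4, 6)))
        shifted = cq.copy()
        shifted.iloc[:, 2] += 3.0
        m1 = genorm(relative_quantities(cq, 2.0)).m_values
        m2 = genorm(relative_quantities(shifted, 2.0)).m_values
        np.testing.assert_allclose(m1, m2, atol=1e-10)


class TestNormfinder:
    def _groups(self, n_a, n_b):
        return pd.Series(["A"] * n_a + ["B"] * n_b,
                         index=[f"s{j}" for j in range(n_a + n_b)])

    def test_exchangeable_genes_have_similar_sv(self):
        rng = np.random.default_rng(4)
        svs = []
        for _ in range(50):
            cq = cq_frame(rng.normal(25, 0.3, (4, 12)))
            svs.append(normfinder(relative_quantities(cq, 2.0),
                                  self._groups(6, 6)).to_numpy())
        mean_sv = np.mean(svs, axis=0)
        assert mean_sv.std() / mean_sv.mean() < 0.1

    def test_group_shifted_gene_scores_worst(self):
        rng = np.random.default_rng(5)
        cq = cq_frame(rng.normal(25, 0.2, (4, 16)))
        cq.iloc[0, 8:] += 1.0       # +1 cycle in group B only
        sv = normfinder(relative_quantities(cq, 2.0), self._groups(8, 8))
        assert sv.idxmax() == "g0"

    def test_noise_sd_order_recovered(self):
        # per-sample centering spreads the noisiest gene's variance over all
        # genes, so ordering the close SV pair needs a generous sample size
        rng = np.random.default_rng(6)
        n = 200
        base = rng.normal(0, 1.0, n)
        rows = [25 + base + rng.normal(0, sd, n) for sd in (0.05, 0.2, 0.8)]
        sv = normfinder(relative_quantities(cq_frame(rows), 2.0),
                        self._groups(n // 2, n // 2))
        assert sv.iloc[0] < sv.iloc[1] < sv.iloc[2]

    def test_single_sample_group_excluded_with_warning(self):
        rng = np.random.default_rng(7)
        cq = cq_frame(rng.normal(25, 0.3, (3, 5)))
        groups = pd.Series(["A", "A", "A", "A", "B"],
                           index=cq.columns)
        with pytest.warns(UserWarning, match="single sample"):
            sv = normfinder(relative_quantities(cq, 2.0), groups)
        assert sv.notna().all()


class TestBestkeeper:
    def test_matches_direct_formula_oracle(self):
        rng = np.random.default_rng(8)
        cq = cq_frame(rng.uniform(18, 30, (4, 6)))
        res = bestkeeper(cq)
        bki = np.exp(np.log(cq.to_numpy()).mean(axis=0))
        for j, gene in enumerate(cq.index):
            x = cq.loc[gene].to_numpy()
            assert res.sd[gene] == pytest.approx(np.std(x, ddof=1), abs=1e-12)
            assert res.r[gene] == pytest.approx(np.corrcoef(x, bki)[0, 1],
                                                abs=1e-12)

    def test_gene_tracking_common_profile_fully_correlated(self):
        common = np.array([20.0, 22.0, 24.0, 26.0])
        cq = cq_frame([common, common + 1, common + 2])
        res = bestkeeper(cq)
        np.testing.assert_allclose(res.r, 1.0, atol=1e-12)

    def test_constant_gene_has_zero_sd_and_best_rank(self):
        rng = np.random.default_rng(9)
        cq = cq_frame(np.vstack([np.full(6, 25.0), rng.uniform(18, 30, (3, 6))]))
        res = bestkeeper(cq)
        assert res.sd.iloc[0] == 0.0
        assert rank_min_ties(res.sd).iloc[0] == 1
        assert not res.unstable.iloc[0]

    def test_sd_above_one_flagged_unstable(self):
        cq = cq_frame([[20.0, 24.0, 28.0], [25.0, 25.1, 25.2]])
        res = bestkeeper(cq)
        assert bool(res.unstable.iloc[0]) and not bool(res.unstable.iloc[1])


class TestDeltaCt:
    def test_identical_genes_score_zero(self):
        cq = cq_frame([[20, 22, 24]] * 3)
        np.testing.assert_allclose(delta_ct_stability(cq), 0.0, atol=1e-12)

    def test_noisy_gene_scores_highest(self):
        rng = np.random.default_rng(10)
        common = rng.uniform(20, 24, 10)
        cq = cq_frame([common, common + 0.5,
                       common + rng.normal(0, 2.0, 10)])
        scores = delta_ct_stability(cq)
        assert scores.idxmax() == "g2"

    def test_matches_brute_force_pairwise_oracle(self):
        rng = np.random.default_rng(11)
        cq = cq_frame(rng.uniform(18, 30, (5, 7)))
        scores = delta_ct_stability(cq)
        values = cq.to_numpy()
        for j, gene in enumerate(cq.index):
            sds = [np.std(values[j] - values[k], ddof=1)
                   for k in range(5) if k != j]
            assert scores[gene] == pytest.approx(np.mean(sds), abs=1e-12)

    def test_agrees_with_genorm_order_at_perfect_efficiency(self):
        rng = np.random.default_rng(12)
        base = rng.uniform(20, 24, 12)
        rows = [base + rng.normal(0, sd, 12) for sd in (0.05, 0.3, 1.0, 2.0)]
        cq = cq_frame(rows)
        dct_order = delta_ct_stability(cq).sort_values(kind="stable").index.tolist()
        gn = genorm(relative_quantities(cq, 2.0))
        assert dct_order[-1] == gn.ranking[-1]
        assert set(dct_order[:2]) == set(gn.ranking[:2])


class TestCompositeRanking:
    def _ranks(self, rows, genes):
        return pd.DataFrame(rows, index=genes,
                            columns=["rank_genorm", "rank_normfinder",
                                     "rank_bestkeeper"])

    def test_printed_worked_examples(self):
        # (1, 1, 5) -> 2.33 and (1, 6, 2) -> 3.00
        table = composite_rank(self._ranks([[1, 1, 5], [1, 6, 2]], ["UBQ", "SAND"]))
        assert table.at["UBQ", "ranking_mean"] == pytest.approx(2.33, abs=0.005)
        assert table.at["SAND", "ranking_mean"] == pytest.approx(3.00, abs=0.005)
        assert table.at["UBQ", "final_rank"] == 1
        assert table.at["SAND", "final_rank"] == 2

    def test_unanimous_ranks_give_that_mean_and_geomean(self):
        table = composite_rank(self._ranks([[2, 2, 2], [1, 1, 1]], ["a", "b"]))
        assert table.at["a", "ranking_mean"] == 2.0
        assert table.at["a", "ranking_geomean"] == pytest.approx(2.0)

    def test_gene_input_order_irrelevant(self):
        rng = np.random.default_rng(13)
        meta = make_sample_metadata(3, 3, 3)
        cq, eff, _ = generate_cq_table(5, 0, meta, [0.1, 0.3, 0.5, 0.8, 1.2],
                                       [], seed=3)
        groups = pd.Series([g for g in
                            meta.set_index("sample_id")["group"]],
                           index=meta["sample_id"])
        fwd = stability_report(cq, eff, groups=groups).table
        rev = stability_report(cq.iloc[::-1], eff.iloc[::-1], groups=groups).table
        assert fwd.index.tolist() == rev.index.tolist()
        np.testing.assert_allclose(fwd["ranking_mean"], rev["ranking_mean"])

    def test_missing_method_rank_rejected(self):
        bad = pd.DataFrame({"rank_genorm": [1, 2]}, index=["a", "b"])
        with pytest.raises(ValueError):
            composite_rank(bad)

    def test_planted_stability_order_recovered(self):
        """Composite rank recovers the generating SD order for separated SDs."""
        sds = [0.05, 0.2, 0.7, 2.0]
        hits = 0
        for seed in range(20):
            meta = make_sample_metadata(4, 3, 3)
            cq, eff, truth = generate_cq_table(4, 0, meta, sds, [], seed=seed)
            groups = meta.set_index("sample_id")["group"].reindex(cq.columns)
            table = stability_report(cq, eff, groups=groups).table
            if table.index.tolist() == truth.gene_stability_order:
                hits += 1
        assert hits >= 18

    def test_genorm_sd_order_recovery_small_instance(self):
        meta = make_sample_metadata(5, 5, 3)
        cq, eff, truth = generate_cq_table(3, 0, meta, [0.1, 0.5, 1.5], [],
                                           seed=4)
        res = genorm(relative_quantities(cq, eff))
        assert res.ranking[-1] == "REF3"
        assert set(res.ranking[:2]) == {"REF1", "REF2"}


class TestGoi:
    def test_goi_equal_to_reference_geomean_normalizes_to_zero(self):
        refs = cq_frame([[20.0, 22.0], [20.0, 22.0]], genes=["r1", "r2"])
        goi = cq_frame([[20.0, 22.0]], genes=["x"])
        out = normalize_goi(goi, refs)
        np.testing.assert_allclose(out.to_numpy(), 0.0, atol=1e-12)

    def test_per_sample_shift_cancels(self):
        rng = np.random.default_rng(14)
        refs = cq_frame(rng.uniform(18, 25, (3, 5)))
        goi = cq_frame(rng.uniform(22, 30, (2, 5)), genes=["x", "y"])
        base = normalize_goi(goi, refs)
        shifted = normalize_goi(goi + 1.0, refs + 1.0)
        np.testing.assert_allclose(base.to_numpy(), shifted.to_numpy(),
                                   atol=1e-10)

    def test_simple_arithmetic(self):
        refs = cq_frame([[20.0], [20.0], [20.0]], genes=["r1", "r2", "r3"])
        goi = cq_frame([[25.0]], genes=["x"])
        assert normalize_goi(goi, refs).iloc[0, 0] == pytest.approx(5.0)

    def test_exact_wilcoxon_small_instance(self):
        # (1,2,3) vs (4,5,6): most extreme of C(6,3)=20 arrangements -> p = 0.1
        normalized = cq_frame([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]], genes=["x"])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=normalized.columns)
        out = goi_group_tests(normalized, groups)
        assert out.at["x", "wilcoxon_p"] == pytest.approx(0.1)

    def test_null_rarely_flagged_reliable(self):
        rng = np.random.default_rng(15)
        flags = 0
        for _ in range(100):
            normalized = cq_frame(rng.normal(0, 1, (1, 20)), genes=["x"])
            groups = pd.Series(["A"] * 10 + ["B"] * 10,
                               index=normalized.columns)
            out = goi_group_tests(normalized, groups)
            flags += int(out.at["x", "reliable"])
        assert flags <= 10

    def test_planted_shift_detected_with_power(self):
        rng = np.random.default_rng(16)
        detected = 0
        for _ in range(40):
            a = rng.normal(0, 0.5, 18)
            b = rng.normal(3, 0.5, 12)
            normalized = cq_frame([np.concatenate([a, b])], genes=["x"])
            groups = pd.Series(["A"] * 18 + ["B"] * 12,
                               index=normalized.columns)
            out = goi_group_tests(normalized, groups)
            detected += int(out.at["x", "wilcoxon_p_adjusted"] <= 0.05)
        assert detected >= 38

    def test_degenerate_gene_reported_missing(self):
        normalized = cq_frame([[2.0] * 6, [1, 2, 3, 4, 5, 6]], genes=["flat", "x"])
        groups = pd.Series(["A"] * 3 + ["B"] * 3, index=normalized.columns)
        out = goi_group_tests(normalized, groups)
        assert np.isnan(out.at["flat", "bartlett_p"])
        assert out.at["flat", "wilcoxon_p"] == 1.0
        assert not out.at["flat", "reliable"]
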