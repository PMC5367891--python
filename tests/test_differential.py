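import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

import isousage as iu
from isousage.differential import _interaction_fit, detected_rows


def matrix_from(values, columns, scale_tag="log2p1", rows=None):
    arr = np.asarray(values, dtype=float)
    rows = rows or [f"T{i}" for i in range(arr.shape[0])]
    return iu.ExpressionMatrix(
        pd.DataFrame(arr, index=rows, columns=columns), scale_tag=scale_tag
    )


def annotations_for(er_ids, tn_ids):
    return [iu.SampleAnnotation(s, "ERpos") for s in er_ids] + [
        iu.SampleAnnotation(s, "TN") for s in tn_ids
    ]


class TestWilcoxon:
    def test_disjoint_groups_exact_p(self):
        """{1,2,3} vs {4,5,6}: W=0 for the first group and exact two-sided
        p = 2 * 1/C(6,3) = 0.1."""
        mat = matrix_from([[1, 2, 3, 4, 5, 6]], list("abcdef"), scale_tag="raw")
        ann = annotations_for(list("abc"), list("def"))
        res = iu.wilcoxon_de(mat, ann)[0]
        assert res.statistic == 0
        assert res.p == pytest.approx(0.1)

    def test_constant_row_p_one(self):
        mat = matrix_from([[5, 5, 5, 5]], list("abcd"), scale_tag="raw")
        res = iu.wilcoxon_de(mat, annotations_for(["a", "b"], ["c", "d"]))[0]
        assert res.p == 1.0

    def test_missing_subtype_rejected(self):
        mat = matrix_from([[1, 2]], ["a", "b"], scale_tag="raw")
        ann = [iu.SampleAnnotation(s, "ERpos") for s in "ab"]
        with pytest.raises(ValueError):
            iu.wilcoxon_de(mat, ann)

    def test_null_type_one_error(self):
        """On constant-free null data the rejection rate at alpha=0.05 stays
        near 0.05."""
        rng = np.random.default_rng(10)
        X = rng.normal(size=(5000, 25))
        mat = matrix_from(np.abs(X), [f"s{i}" for i in range(25)], scale_tag="raw")
        ann = annotations_for([f"s{i}" for i in range(11)], [f"s{i}" for i in range(11, 25)])
        p = np.array([r.p for r in iu.wilcoxon_de(mat, ann)])
        assert 0.035 < (p < 0.05).mean() < 0.065


class TestLmSubtype:
    def test_matches_equal_variance_t_test(self):
        rng = np.random.default_rng(3)
        X = rng.normal(5, 1, (50, 25))
        cols = [f"s{i}" for i in range(25)]
        mat = matrix_from(X, cols)
        ann = annotations_for(cols[:11], cols[11:])
        results = iu.lm_subtype_de(mat, ann)
        for i, r in enumerate(results[:20]):
            t, p = scipy.stats.ttest_ind(X[i, 11:], X[i, :11], equal_var=True)
            assert r.p == pytest.approx(p)
            assert r.statistic == pytest.approx(t)

    def test_beta_sign_positive_iff_tn_higher(self):
        mat = matrix_from([[1, 1, 3, 3], [3, 3, 1, 1]], list("abcd"))
        results = iu.lm_subtype_de(mat, annotations_for(["a", "b"], ["c", "d"]))
        assert results[0].betas["subtype[TN]"] > 0
        assert results[1].betas["subtype[TN]"] < 0

    def test_recovers_planted_effect_within_two_se(self, small_sim):
        """On the exact generative scale (log2 without pseudocount — all
        simulated abundances are positive) the subtype beta recovers the
        planted effect within sampling error."""
        cfg, models, matrix, annotations, truth = small_sim
        log_mat = iu.ExpressionMatrix(np.log2(matrix.data), scale_tag="log2p1")
        results = {r.gene_id: r for r in iu.lm_subtype_de(log_mat, annotations)}
        genes = iu.group_by_gene(models)
        checked = 0
        for gene_id, sign in truth.gene_de.items():
            if sign == 0 or gene_id in truth.switched_genes:
                continue
            for tx in genes[gene_id]:
                r = results[tx.transcript_id]
                beta = r.betas["subtype[TN]"]
                se = abs(beta / r.statistic) if r.statistic != 0 else np.inf
                assert abs(beta - sign * cfg.gene_de_effect) < 2.5 * se
                checked += 1
        assert checked > 5


class TestInteraction:
    def test_saturated_cell_means_beta(self):
        """Cell means [[1,1],[1,3]] (iso x subtype, noise 0) give interaction
        beta 2 and a degenerate (0) F."""
        cols = ["e1", "e2", "t1", "t2"]
        mat = matrix_from([[1, 1, 1, 1], [1, 1, 3, 3]], cols)
        res = iu.isoform_interaction_test(
            mat, annotations_for(["e1", "e2"], ["t1", "t2"]), gene_id="G"
        )
        assert res.betas["subtype[TN]:isoform[T1]"] == pytest.approx(2.0)
        assert res.statistic == 0.0 and res.p == 1.0

    def test_single_isoform_rejected(self):
        mat = matrix_from([[1, 2]], ["a", "b"])
        with pytest.raises(ValueError, match="single isoform"):
            iu.isoform_interaction_test(
                mat, annotations_for(["a"], ["b"]), gene_id="G"
            )

    def test_interaction_beta_equals_ratio_mean_difference(self):
        """The L=2 interaction estimate equals the TN-minus-ER difference of
        per-sample isoform log-ratios exactly; F approximates the squared
        ratio t statistic."""
        rng = np.random.default_rng(4)
        for _ in range(5):
            Y = rng.normal(5, 1, (2, 25))
            is_tn = np.array([0.0] * 11 + [1.0] * 14)
            F, p, _, _, beta = _interaction_fit(Y, is_tn)
            d = Y[1] - Y[0]
            delta = d[11:].mean() - d[:11].mean()
            assert beta[-1] == pytest.approx(delta)
            t, _ = scipy.stats.ttest_ind(d[11:], d[:11], equal_var=True)
            assert F == pytest.approx(t**2, rel=0.25)

    def test_null_interaction_p_uniform(self, null_pair_pvalues):
        p = null_pair_pvalues
        stat, ks_p = scipy.stats.kstest(p, "uniform")
        assert ks_p > 0.01

    def test_pairs_per_gene_combinatorics(self):
        cfg = iu.SimulationConfig(
            n_genes=6, isoform_count_distribution={3: 1.0}, seed=12
        )
        models = iu.simulate_gene_models(cfg)
        matrix, annotations, _ = iu.simulate_cohort(models, cfg)
        pairs = iu.pairwise_interaction_tests(matrix, models, annotations)
        per_gene = pd.Series([r.gene_id for r in pairs]).value_counts()
        assert (per_gene == 3).all()

    def test_two_isoform_pair_equals_whole_gene_test(self):
        cfg = iu.SimulationConfig(
            n_genes=5, isoform_count_distribution={2: 1.0}, seed=13
        )
        models = iu.simulate_gene_models(cfg)
        matrix, annotations, _ = iu.simulate_cohort(models, cfg)
        pairs = iu.pairwise_interaction_tests(matrix, models, annotations)
        genes = iu.group_by_gene(models)
        for pr in pairs:
            block = matrix.subset_rows([pr.iso_a, pr.iso_b])
            whole = iu.isoform_interaction_test(
                block, annotations, gene_id=pr.gene_id
            )
            assert pr.F == pytest.approx(whole.statistic)

    def test_planted_switch_recall_and_direction(self, power_sim):
        """Switched pairs at effect 2, noise 0.5, n=25 reach q<0.05 with high
        recall and the interaction beta sign matches the planted direction."""
        cfg, models, matrix, annotations, truth, results = power_sim
        by_pair = {(r.iso_a, r.iso_b): r for r in results}
        hits = 0
        planted = list(truth.switch_pair.values())
        for iso_a, iso_b in planted:
            r = by_pair[(iso_a, iso_b)]
            if r.q < 0.05:
                hits += 1
                # beta>0 favors iso_b in TN
                expected = iso_b if truth.isoform_direction[iso_b] > 0 else iso_a
                assert r.tn_favored_isoform == expected
        assert hits / len(planted) >= 0.90


class TestStoreyQvalues:
    def test_equals_bh_when_pi0_is_one(self):
        rng = np.random.default_rng(5)
        p = rng.uniform(size=200)
        q = iu.storey_qvalues(p, pi0=1.0).qvalues
        bh = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(q, bh)

    def test_all_equal_pvalues(self):
        q = iu.storey_qvalues(np.full(100, 0.01), pi0=1.0).qvalues
        assert np.allclose(q, 0.01)

    def test_pi0_near_one_on_uniform(self):
        rng = np.random.default_rng(6)
        res = iu.storey_qvalues(rng.uniform(size=10_000))
        assert 0.9 <= res.pi0 <= 1.0

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            iu.storey_qvalues([0.5, 1.5])

    def test_small_m_falls_back_to_bh_with_warning(self):
        p = np.linspace(0.01, 0.9, 10)
        with pytest.warns(UserWarning, match="pi0 = 1"):
            res = iu.storey_qvalues(p)
        assert res.pi0 == 1.0

    @given(st.lists(st.floats(0, 1), min_size=25, max_size=60))
    def test_monotone_in_p_and_bounded(self, pvals):
        res = iu.storey_qvalues(np.array(pvals))
        order = np.argsort(res.pvalues)
        assert np.all(np.diff(res.qvalues[order]) >= -1e-12)
        assert np.all((res.qvalues >= 0) & (res.qvalues <= 1))
        # ties share a q
        ps = res.pvalues
        for i in range(len(ps)):
            for j in range(len(ps)):
                if ps[i] == ps[j]:
                    assert res.qvalues[i] == res.qvalues[j]


class TestFacade:
    def test_model_fit_summary(self, small_sim):
        _, models, matrix, annotations, _ = small_sim
        results = iu.IsoformUsageModel(matrix, annotations, models).fit()
        text = results.summary()
        assert "isoform pairs tested" in text
        frame = results.pairs_frame
        assert {"gene_id", "iso_a", "iso_b", "F", "p", "q", "beta"} <= set(
            frame.columns
        )
        assert len(frame) == len(results.pair_results)

    def test_detection_filter(self):
        cols = list("abcd")
        mat = matrix_from(
            [[0, 0, 0, 1], [2, 2, 2, 2]], cols, scale_tag="raw"
        )
        assert detected_rows(mat, 2) == ["T1"]
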