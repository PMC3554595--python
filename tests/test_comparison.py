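"""Permutation tests, AUC and the ranking table."""

import itertools

import numpy as np
import pytest
from scipy import stats

from glmmscore import (auc_discrimination, permutation_test_paired_ls,
                       rank_models)
from glmmscore.criteria import Assessment, DICResult


def _mk_assessment(ls, model="M", dic=(100.0, 90.0), checksum=1,
                   family="nb", dic_comparable=True, mean_ls=None):
    ls = np.asarray(ls, dtype=float)
    d_bar, d_hat = dic
    p_d = d_bar - d_hat
    return Assessment(
        model=model, family=family, cpo=np.exp(-ls), ls=ls, pit=None,
        flags=np.zeros(len(ls), dtype=bool),
        dic=DICResult(d_bar, d_hat, p_d, d_bar + p_d),
        mean_ls=float(ls.mean()) if mean_ls is None else mean_ls,
        scale="original", dic_comparable=dic_comparable,
        data_checksum=checksum)


class TestPermutationTest:
    def test_identical_scores_give_p_one(self):
        ls = np.linspace(1.0, 2.0, 40)
        res = permutation_test_paired_ls(ls, ls, n_perm=999, seed=1)
        assert res.p_value == 1.0
        assert res.observed_diff == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            permutation_test_paired_ls(np.ones(5), np.ones(4))

    def test_matches_exhaustive_enumeration_at_n8(self):
        rng = np.random.default_rng(7)
        d = rng.normal(0.4, 1.0, size=8)
        a = d
        b = np.zeros(8)
        obs = d.mean()
        exact_stats = np.array([
            (np.array(signs) * d).mean()
            for signs in itertools.product((-1, 1), repeat=8)])
        lo = (1 + np.sum(exact_stats <= obs)) / (len(exact_stats) + 1)
        hi = (1 + np.sum(exact_stats >= obs)) / (len(exact_stats) + 1)
        exact_p = min(1.0, 2 * min(lo, hi))
        mc = permutation_test_paired_ls(a, b, n_perm=9999, seed=3)
        assert abs(mc.p_value - exact_p) < 0.02

    def test_type_i_error_and_super_uniformity(self):
        # both score vectors from the same distribution: 5%-level rejection
        # rate stays near 5%, and p-values are (super-)uniform
        rng = np.random.default_rng(11)
        pvals = []
        for _ in range(400):
            a = rng.normal(2.0, 0.5, size=30)
            b = rng.normal(2.0, 0.5, size=30)
            pvals.append(permutation_test_paired_ls(
                a, b, n_perm=199, seed=int(rng.integers(2 ** 30))).p_value)
        pvals = np.asarray(pvals)
        rate = (pvals <= 0.05).mean()
        assert 0.03 <= rate <= 0.07
        for alpha in (0.1, 0.25, 0.5):
            se = np.sqrt(alpha * (1 - alpha) / 400)
            assert (pvals <= alpha).mean() <= alpha + 3 * se

    def test_block_flips_respect_subject_clustering(self):
        rng = np.random.default_rng(5)
        subj = np.repeat(np.arange(10), 4)
        d = rng.normal(0.0, 1.0, size=10)[subj]  # perfectly clustered diffs
        res = permutation_test_paired_ls(d, np.zeros_like(d), n_perm=499,
                                         seed=2, blocks=subj)
        assert 0.0 < res.p_value <= 1.0
        with pytest.raises(ValueError):
            permutation_test_paired_ls(d, np.zeros_like(d),
                                       blocks=subj[:-1])


class TestAUC:
    def test_identical_constant_vectors_give_half(self):
        res = auc_discrimination(np.ones(10), np.ones(10))
        assert res.auc == 0.5
        assert res.tie_count == 100

    def test_complete_separation_gives_one(self):
        res = auc_discrimination(np.full(6, 5.0), np.full(8, 1.0))
        assert res.auc == 1.0

    def test_matches_rank_sum_oracle(self):
        rng = np.random.default_rng(3)
        w = rng.normal(0.3, 1.0, 100)
        t = rng.normal(0.0, 1.0, 100)
        ours = auc_discrimination(w, t).auc
        u = stats.mannwhitneyu(w, t, alternative="two-sided").statistic
        assert ours == pytest.approx(u / (100 * 100), abs=1e-12)

    @pytest.mark.parametrize("transform", [np.exp, np.tanh,
                                           lambda x: 3 * x + 1])
    def test_invariant_under_increasing_transforms(self, transform):
        rng = np.random.default_rng(4)
        w = rng.normal(0.5, 1.0, 40)
        t = rng.normal(0.0, 1.0, 35)
        assert auc_discrimination(transform(w), transform(t)).auc == \
            auc_discrimination(w, t).auc

    def test_same_distribution_near_half(self):
        rng = np.random.default_rng(9)
        w = rng.normal(0.0, 1.0, 200)
        t = rng.normal(0.0, 1.0, 200)
        assert abs(auc_discrimination(w, t).auc - 0.5) < 0.1

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            auc_discrimination(np.array([]), np.ones(3))


class TestRankModels:
    def test_identical_assessments_tie_at_delta_zero(self):
        a = _mk_assessment(np.full(20, 1.5), model="A")
        b = _mk_assessment(np.full(20, 1.5), model="B")
        tab = rank_models([a, b], n_perm=199)
        assert np.allclose(tab["delta_LS"], 0.0)
        assert np.allclose(tab["delta_DIC"], 0.0)
        assert tab.iloc[0]["p_vs_best"] == "ref."
        assert tab.iloc[1]["p_vs_best"] == "1.0000"

    def test_best_model_has_zero_delta_by_construction(self):
        rng = np.random.default_rng(2)
        tab = rank_models([
            _mk_assessment(rng.normal(2.0, 0.1, 30), model="worse",
                           dic=(120.0, 100.0)),
            _mk_assessment(rng.normal(1.0, 0.1, 30), model="better",
                           dic=(100.0, 90.0)),
        ], n_perm=199)
        assert tab.iloc[0]["model"] == "better"
        assert tab.iloc[0]["delta_LS"] == 0.0
        assert tab.iloc[1]["dic_noteworthy"]

    def test_different_datasets_rejected(self):
        a = _mk_assessment(np.ones(5), checksum=1)
        b = _mk_assessment(np.ones(5), checksum=2)
        with pytest.raises(ValueError, match="different datasets"):
            rank_models([a, b])

    def test_menu_of_one_rejected(self):
        with pytest.raises(ValueError):
            rank_models([_mk_assessment(np.ones(5))])

    def test_transformed_outcome_rows_masked(self):
        a = _mk_assessment(np.full(10, 1.2), model="NB(I)")
        nmm = _mk_assessment(np.full(10, 1.1), model="arcsinh(I)",
                             family="nmm_arcsinh", dic=(50.0, 40.0),
                             dic_comparable=False)
        tab = rank_models([a, nmm], n_perm=99)
        row = tab[tab["model"] == "arcsinh(I)"].iloc[0]
        assert not row["dic_comparable"]
        assert np.isnan(row["delta_DIC"])
        other = tab[tab["model"] == "NB(I)"].iloc[0]
        assert other["p_vs_best"] == "n.a."  # best model is the NMM here

    def test_ordering_invariant_to_loglik_constants(self):
        # adding a constant per observation to every model's log-likelihood
        # shifts all mean scores equally and preserves the ranking
        rng = np.random.default_rng(6)
        base = [rng.normal(1.0, 0.1, 25), rng.normal(1.4, 0.1, 25),
                rng.normal(1.2, 0.1, 25)]
        tab0 = rank_models([
            _mk_assessment(ls, model=f"M{i}") for i, ls in enumerate(base)],
            permutation=False)
        tab1 = rank_models([
            _mk_assessment(ls + 0.7, model=f"M{i}")
            for i, ls in enumerate(base)], permutation=False)
        assert list(tab0["model"]) == list(tab1["model"])
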