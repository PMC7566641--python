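"""Beta-binomial differential test, DMR chaining, signatures, clustering."""

import numpy as np
import pytest

import imprintmeth as im
from imprintmeth.diffmeth import call_dmrs, direction_signature_association, \
    group_signature, sample_distance_cluster
from imprintmeth.diffmeth import test_cpgs as run_cpg_test
from .conftest import make_toy_table


def _two_cohort_table(rng, n_sites=60, p_beta=0.6, p_ins=None, depth=22):
    p_ins = p_beta if p_ins is None else p_ins
    n_b, n_i = 5, 19
    total = rng.poisson(depth, size=(n_b + n_i, n_sites)) + 1
    p = np.concatenate([np.full(n_b, p_beta), np.full(n_i, p_ins)])
    meth = rng.binomial(total, p[:, None])
    return make_toy_table(meth, total, ["beta"] * n_b + ["insulinoma"] * n_i)


class TestTestCpgs:
    def test_identical_cohorts_null_identity(self):
        meth = np.tile([[3, 7, 1]], (8, 1))
        total = np.tile([[10, 10, 10]], (8, 1))
        table = make_toy_table(meth, total, ["beta"] * 4 + ["insulinoma"] * 4)
        res = run_cpg_test(table)
        np.testing.assert_allclose(res["delta"], 0.0, atol=1e-12)
        np.testing.assert_allclose(res["p"], 1.0, atol=1e-6)
        assert not res["significant"].any()

    def test_label_swap_symmetry(self):
        rng = np.random.default_rng(2)
        table = _two_cohort_table(rng, p_beta=0.5, p_ins=0.7)
        fwd = run_cpg_test(table, case="insulinoma", control="beta")
        rev = run_cpg_test(table, case="beta", control="insulinoma")
        np.testing.assert_allclose(fwd["delta"], -rev["delta"], atol=1e-12)
        np.testing.assert_allclose(fwd["p"], rev["p"], rtol=1e-6)

    def test_planted_large_effect_is_detected(self):
        rng = np.random.default_rng(3)
        table = _two_cohort_table(rng, n_sites=100, p_beta=0.3, p_ins=0.7)
        res = run_cpg_test(table)
        assert res["significant"].mean() > 0.95
        assert (res.loc[res["significant"], "direction"] == "hyper").all()

    def test_untestable_sites_reported_untested_not_p1(self):
        meth = np.array([[1, 1], [0, 2], [0, 3], [2, 1], [1, 1], [1, 2]])
        total = np.array([[5, 5], [0, 5], [0, 5], [5, 5], [5, 5], [5, 5]])
        table = make_toy_table(meth, total,
                               ["beta"] * 3 + ["insulinoma"] * 3)
        res = run_cpg_test(table)
        assert not res["tested"].iloc[0]      # only 1 covered beta sample
        assert np.isnan(res["p"].iloc[0])
        assert res["tested"].iloc[1]

    def test_bh_fdr_monotone_in_sorted_pvalues(self, diff_results):
        tested = diff_results[diff_results["tested"]].sort_values("p")
        assert (np.diff(tested["fdr"].cummin()[::-1]) <= 1e-12).all() or \
            (tested["fdr"].to_numpy()[np.argsort(tested["p"].to_numpy(),
                                                 kind="stable")] ==
             tested["fdr"].to_numpy()).all()
        # classic check: q-values sorted by p are non-decreasing
        q = tested["fdr"].to_numpy()
        assert (np.diff(q) >= -1e-12).all()

    def test_dispersion_shrinkage_bounds(self, diff_results):
        rho = diff_results["dispersion"]
        assert (rho > 0).all() and (rho <= 0.5).all()


class TestCallDmrs:
    def _results(self, pos, sig=None, direction="hyper", fdr=1e-4):
        import pandas as pd
        n = len(pos)
        sig = [True] * n if sig is None else sig
        return pd.DataFrame({
            "chrom": "chr11", "pos": pos,
            "delta": [0.3 if direction == "hyper" else -0.3] * n,
            "fdr": [fdr] * n, "significant": sig,
            "direction": [direction if s else "" for s in sig],
        })

    def test_chaining_by_hand(self):
        dmrs = call_dmrs(self._results([100, 500, 900]), bandwidth=1000)
        assert len(dmrs) == 1
        assert (dmrs["start"].iloc[0], dmrs["end"].iloc[0]) == (100, 901)
        assert dmrs["n_cpgs"].iloc[0] == 3

    def test_two_distant_cpgs_no_dmr(self):
        dmrs = call_dmrs(self._results([100, 5100]), min_cpgs=3)
        assert len(dmrs) == 0

    def test_direction_purity_of_chains(self):
        import pandas as pd
        hypo = self._results([100, 400, 700], direction="hypo")
        hyper = self._results([250, 550, 850], direction="hyper")
        res = pd.concat([hypo, hyper]).sort_values("pos").reset_index(drop=True)
        dmrs = call_dmrs(res)
        assert len(dmrs) == 2
        assert set(dmrs["direction"]) == {"hypo", "hyper"}

    def test_never_contains_nonsignificant_constituent(self, diff_results):
        dmrs = call_dmrs(diff_results)
        assert len(dmrs) > 0
        for ids in dmrs["site_ids"]:
            assert diff_results.loc[ids, "significant"].all()
            assert diff_results.loc[ids, "fdr"].max() < 0.005

    def test_planted_block_recovery(self, sim_bundle, diff_results):
        from .conftest import jaccard
        dmrs = call_dmrs(diff_results)
        for block in (sim_bundle["truth"].hyper_blocks
                      + sim_bundle["truth"].hypo_blocks):
            best = max(jaccard((block.start, block.end), (r.start, r.end))
                       for r in dmrs.itertuples())
            assert best >= 0.8


class TestGroupSignature:
    def test_planted_signature_recovered(self, sim_bundle, filtered_table):
        sig = group_signature(filtered_table)
        planted = set().union(*map(set,
                                   sim_bundle["truth"].signature_sites.values()))
        sens = len(planted & set(sig.signature_ids)) / len(planted)
        assert sens >= 0.8

    def test_signature_is_about_five_percent_of_eligible(self, filtered_table):
        sig = group_signature(filtered_table)
        frac = len(sig.signature_ids) / len(sig.measurable)
        assert 0.03 <= frac <= 0.07

    def test_cpg_missing_in_one_group_excluded(self):
        rng = np.random.default_rng(4)
        n_b, groups = 3, ["G1"] * 3 + ["G2"] * 3 + ["G3"] * 3
        total = rng.poisson(20, size=(n_b + 9, 30)) + 5
        meth = rng.binomial(total, 0.5)
        total[[3, 4, 5], 0] = 0   # site 0 unmeasurable in all of G2
        meth[[3, 4, 5], 0] = 0
        table = make_toy_table(meth, total, ["beta"] * n_b + ["insulinoma"] * 9,
                               groups=[""] * n_b + groups)
        sig = group_signature(table)
        assert 0 not in sig.measurable
        assert 0 not in sig.signature_ids

    def test_group_with_single_sample_rejected(self):
        table = make_toy_table(np.ones((5, 4), int), np.full((5, 4), 10),
                               ["beta", "beta", "insulinoma", "insulinoma",
                                "insulinoma"],
                               groups=["", "", "G1", "G2", "G2"])
        with pytest.raises(ValueError, match="fewer than two"):
            group_signature(table)


class TestDirectionSignatureAssociation:
    def _results(self, hypo_flags):
        import pandas as pd
        n = len(hypo_flags)
        return pd.DataFrame({
            "pos": np.arange(n), "significant": [True] * n,
            "direction": ["hypo" if h else "hyper" for h in hypo_flags],
        })

    def test_independent_table_gives_zero(self):
        res = self._results([True] * 20 + [False] * 20)
        signature = np.concatenate([np.arange(10), np.arange(20, 30)])
        chi2, df, p = direction_signature_association(res, signature)
        assert chi2 == pytest.approx(0.0)
        assert df == 1

    def test_perfect_association_equals_n(self):
        res = self._results([True] * 20 + [False] * 20)
        chi2, df, p = direction_signature_association(res, np.arange(20))
        assert chi2 == pytest.approx(40.0)  # [[20,0],[0,20]] -> chi2 = N

    def test_empty_margin_rejected(self):
        res = self._results([True] * 10)
        with pytest.raises(ValueError, match="margin"):
            direction_signature_association(res, np.arange(5))

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(5)
        pvals = []
        for _ in range(200):
            res = self._results(rng.random(60) < 0.5)
            signature = rng.choice(60, size=20, replace=False)
            try:
                pvals.append(direction_signature_association(res, signature)[2])
            except ValueError:
                continue
        assert 0.35 <= np.mean(np.array(pvals) < 0.5) <= 0.65

    def test_strong_association_on_synthetic_study(self, diff_results,
                                                   filtered_table):
        sig = group_signature(filtered_table)
        chi2, df, p = direction_signature_association(diff_results,
                                                      sig.signature_ids)
        assert df == 1 and chi2 > 10 and p < 1e-3


class TestClustering:
    def test_duplicate_samples_merge_first_at_zero(self):
        rng = np.random.default_rng(6)
        total = rng.poisson(20, size=(3, 50)) + 5
        meth = rng.binomial(total, 0.5)
        meth = np.vstack([meth, meth[0]])
        total = np.vstack([total, total[0]])
        table = make_toy_table(meth, total, ["beta"] * 4)
        z, _ = sample_distance_cluster(table)
        assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert {int(z[0, 0]), int(z[0, 1])} == {0, 3}

    def test_two_planted_cohorts_recovered_at_k2(self, filtered_table):
        z, labels = sample_distance_cluster(filtered_table, k=2)
        cohorts = filtered_table.samples["cohort"]
        # cluster labels must be a bijection onto cohorts
        tab = labels.groupby(cohorts).nunique()
        assert (tab == 1).all()
        assert labels[cohorts == "beta"].iloc[0] != \
            labels[cohorts == "insulinoma"].iloc[0]

    def test_merge_heights_invariant_to_sample_order(self):
        rng = np.random.default_rng(7)
        total = rng.poisson(20, size=(6, 80)) + 5
        meth = rng.binomial(total, rng.uniform(0.2, 0.8, size=(6, 1)))
        table = make_toy_table(meth, total, ["beta"] * 6)
        z1, _ = sample_distance_cluster(table)
        perm = rng.permutation(6)
        table2 = make_toy_table(meth[perm], total[perm], ["beta"] * 6)
        z2, _ = sample_distance_cluster(table2)
        np.testing.assert_allclose(np.sort(z1[:, 2]), np.sort(z2[:, 2]),
                                   atol=1e-10)

    def test_fewer_than_three_samples_rejected(self):
        table = make_toy_table([[1], [2]], [[5], [5]], ["beta", "beta"])
        with pytest.raises(ValueError):
            sample_distance_cluster(table)
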