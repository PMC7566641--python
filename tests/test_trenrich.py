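"""Binding-site CpG coverage, rank change, cumulative methylation, classes."""

import numpy as np
import pandas as pd
import pytest

from imprintmeth.profiles import make_windows
from imprintmeth.core import Interval
from imprintmeth.trenrich import (
    classify_trs,
    map_tr_sites,
    overlay_loop_scores,
    rank_change,
    site_cpg_coverage,
    tr_cumulative_methylation,
    tr_enrichment_table,
    tr_scores,
)
from imprintmeth.elements import label_sites


class TestSiteCoverage:
    def test_interior_cpg_two_bases(self):
        assert site_cpg_coverage(0, 10, np.array([4])) == pytest.approx(0.2)

    def test_boundary_cpg_clipped_to_one_base(self):
        # CpG at pos -1 covers [-1, 1): only base 0 is inside the site
        assert site_cpg_coverage(0, 10, np.array([-1])) == pytest.approx(0.1)

    def test_adjacent_cpgs_union_no_double_count(self):
        assert site_cpg_coverage(0, 10, np.array([2, 4])) == pytest.approx(0.4)
        # overlapping footprints cannot happen for CG but union handles it
        assert site_cpg_coverage(0, 10, np.array([2, 3])) == pytest.approx(0.3)

    def test_no_cpgs_zero(self):
        assert site_cpg_coverage(0, 10, np.array([50])) == 0.0

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_per_base_oracle(self, seed):
        rng = np.random.default_rng(seed)
        pos = np.sort(rng.choice(200, 30, replace=False))
        s, e = 37, 161
        mask = np.zeros(400, dtype=bool)
        for p in pos:
            mask[p:p + 2] = True
        expected = mask[s:e].sum() / (e - s)
        assert site_cpg_coverage(s, e, pos) == pytest.approx(expected)


def _sites(rows):
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])


class TestTrScores:
    def test_zero_score_regulator_excluded(self):
        sites = _sites([("c", 0, 10, "A"), ("c", 100, 110, "B")])
        out = tr_scores(sites, np.array([4]))
        assert list(out["tr"]) == ["A"]
        assert out["n_ranked"].iloc[0] == 1

    def test_descending_ranks(self):
        sites = _sites([("c", 0, 10, "A"), ("c", 100, 110, "B")])
        cpgs = np.array([2, 102, 104, 106])
        out = tr_scores(sites, cpgs).set_index("tr")
        assert out.at["B", "rank"] == 1 and out.at["A", "rank"] == 2

    def test_expressed_filter_applied(self):
        sites = _sites([("c", 0, 10, "A"), ("c", 100, 110, "B")])
        out = tr_scores(sites, np.array([2, 102]), expressed={"A"})
        assert list(out["tr"]) == ["A"]

    @pytest.mark.parametrize("seed", range(3))
    def test_ranks_match_brute_force_sort(self, seed):
        rng = np.random.default_rng(seed)
        rows = []
        for t in range(20):
            for _ in range(rng.integers(1, 6)):
                s = int(rng.integers(0, 5_000))
                rows.append(("c", s, s + int(rng.integers(10, 100)), f"T{t}"))
        cpgs = np.sort(rng.choice(5_100, 300, replace=False))
        out = tr_scores(_sites(rows), cpgs)
        # brute force: recompute scores and rank by descending score
        df = pd.DataFrame(rows, columns=["chrom", "start", "end", "name"])
        scores = {}
        for _, r in df.iterrows():
            scores[r["name"]] = scores.get(r["name"], 0) + site_cpg_coverage(
                r["start"], r["end"], cpgs)
        scores = {k: v for k, v in scores.items() if v > 0}
        from scipy.stats import rankdata
        expected = dict(zip(sorted(scores),
                            rankdata([-scores[k] for k in sorted(scores)],
                                     method="average")))
        got = dict(zip(out["tr"], out["rank"]))
        assert got == pytest.approx(expected)


class TestRankChange:
    def _ranking(self, pairs, n):
        df = pd.DataFrame(pairs, columns=["tr", "rank"])
        df["score"] = 1.0 / df["rank"]
        df["n_ranked"] = n
        return df

    def test_stated_formula_by_hand(self):
        base = self._ranking([("X", 10)] + [(f"b{i}", i) for i in range(1, 10)]
                             + [(f"c{i}", i) for i in range(11, 101)], 100)
        sig = self._ranking([("X", 1)] + [(f"b{i}", i + 1) for i in range(1, 50)],
                            50)
        out = rank_change(base, sig).set_index("tr")
        assert out.at["X", "delta_r"] == pytest.approx(10 / 100 - 1 / 50)

    def test_identical_lists_all_zero(self):
        base = self._ranking([(f"t{i}", i) for i in range(1, 6)], 5)
        out = rank_change(base, base.copy())
        np.testing.assert_allclose(out["delta_r"], 0.0)

    def test_reversed_list_antisymmetric_about_middle(self):
        base = self._ranking([("a", 1), ("b", 2), ("c", 3)], 3)
        rev = self._ranking([("a", 3), ("b", 2), ("c", 1)], 3)
        out = rank_change(base, rev).set_index("tr")
        assert out.at["b", "delta_r"] == pytest.approx(0.0)
        assert out.at["a", "delta_r"] == pytest.approx(-out.at["c", "delta_r"])

    def test_absent_regulator_flagged_not_scored(self):
        base = self._ranking([("a", 1), ("b", 2)], 2)
        sig = self._ranking([("a", 1)], 1)
        out = rank_change(base, sig).set_index("tr")
        assert bool(out.at["b", "dropped_out"])
        assert np.isnan(out.at["b", "delta_r"])


class TestCumulativeMethylation:
    def _results(self, pos, deltas):
        return pd.DataFrame({"pos": pos, "delta": deltas,
                             "significant": [True] * len(pos),
                             "direction": ["hyper" if d > 0 else "hypo"
                                           for d in deltas]})

    def test_single_site_mean(self):
        sites = _sites([("c", 0, 100, "T")])
        res = self._results([10, 50], [0.2, 0.4])
        out = tr_cumulative_methylation(sites, res).set_index("tr")
        assert out.at["T", "delta_m"] == pytest.approx(0.3)

    def test_mean_of_site_means_not_pooled(self):
        sites = _sites([("c", 0, 100, "T"), ("c", 200, 300, "T")])
        # site A: three CpGs at +0.3; site B: one CpG at -0.1
        res = self._results([10, 20, 30, 250], [0.3, 0.3, 0.3, -0.1])
        out = tr_cumulative_methylation(sites, res).set_index("tr")
        assert out.at["T", "delta_m"] == pytest.approx((0.3 - 0.1) / 2)
        pooled = (0.3 * 3 - 0.1) / 4
        assert out.at["T", "delta_m"] != pytest.approx(pooled)

    def test_regulator_without_qualifying_sites_nan(self):
        sites = _sites([("c", 0, 100, "T")])
        res = self._results([500], [0.2])
        out = tr_cumulative_methylation(sites, res).set_index("tr")
        assert np.isnan(out.at["T", "delta_m"])
        assert out.at["T", "n_sig_sites"] == 0


class TestClassify:
    def test_all_equal_records_unclassified(self):
        rec = pd.DataFrame({"tr": [f"t{i}" for i in range(25)],
                            "delta_r": 0.1, "delta_m": -0.2,
                            "dropped_out": False})
        out = classify_trs(rec)
        assert (out["tr_class"] == "unclassified").all()

    def test_minimum_record_count_enforced(self):
        rec = pd.DataFrame({"tr": ["a"], "delta_r": [0.1], "delta_m": [0.1]})
        with pytest.raises(ValueError, match="20"):
            classify_trs(rec)

    def test_planted_regulators_recovered(self, sim_bundle, diff_results):
        expressed = set(sim_bundle["expression"]["gene"])
        rec = tr_enrichment_table(sim_bundle["annotations"]["tr_site"].df,
                                  sim_bundle["sites"]["pos"].to_numpy(),
                                  diff_results, expressed)
        out = classify_trs(rec).set_index("tr")
        for tr, cls in sim_bundle["truth"].tr_classes.items():
            assert out.at[tr, "tr_class"] == cls

    def test_rank_change_zero_when_significant_is_everything(self, sim_bundle,
                                                             diff_results):
        sites = sim_bundle["annotations"]["tr_site"].df
        pos = sim_bundle["sites"]["pos"].to_numpy()
        base = tr_scores(sites, pos)
        out = rank_change(base, tr_scores(sites, pos))
        np.testing.assert_allclose(out["delta_r"].dropna(), 0.0, atol=1e-12)


class TestMapSites:
    def test_planted_hyper_regulator_all_hyper(self, sim_bundle, diff_results):
        labeled = label_sites(sim_bundle["annotations"]["tr_site"].df,
                              diff_results)
        own = labeled[labeled["name"] == "PDX1L"]
        dm = own[own["meth_label"] != ""]
        assert len(dm) > 0
        assert (dm["meth_label"] == "hyper").all()

    def test_counts_against_brute_force(self, sim_bundle, diff_results):
        labeled = label_sites(sim_bundle["annotations"]["tr_site"].df,
                              diff_results)
        targets = pd.DataFrame({
            "start": [b.start for b in sim_bundle["truth"].hyper_blocks],
            "end": [b.end for b in sim_bundle["truth"].hyper_blocks],
            "direction": "hyper",
        })
        out = map_tr_sites(labeled, targets)
        pd1 = out[out["tr"] == "PDX1L"]
        assert pd1["n_sites"].sum() == 10   # all planted sites in hyper blocks
        assert (pd1["n_dm_hypo"] == 0).all()

    def test_regulator_with_no_sites_in_targets_zero_row(self):
        labeled = pd.DataFrame({"name": ["T"], "start": [0], "end": [10],
                                "meth_label": [""]})
        targets = pd.DataFrame({"start": [100], "end": [200],
                                "direction": ["hypo"]})
        out = map_tr_sites(labeled, targets)
        assert out["n_sites"].iloc[0] == 0


class TestLoopOverlay:
    def _grid(self):
        return make_windows(Interval("chr11", 0, 30_000), 10_000)

    def _counts(self, grid):
        c = grid.windows.copy()
        c["n_hypo"] = [1, 2, 3]
        c["n_hyper"] = [4, 5, 6]
        return c

    def test_out_of_region_scores_dropped_with_count(self):
        grid = self._grid()
        track = pd.DataFrame({"pos": [5, 15_000, 40_000], "score": [1.0, 2.0, 3.0]})
        joined, dropped = overlay_loop_scores(track, self._counts(grid), grid)
        assert dropped == 1
        assert len(joined) == 2

    def test_scores_kept_at_native_coordinates(self):
        grid = self._grid()
        track = pd.DataFrame({"pos": [5, 15_000], "score": [1.5, 2.5]})
        joined, _ = overlay_loop_scores(track, self._counts(grid), grid)
        assert list(joined["pos"]) == [5, 15_000]
        assert list(joined["score"]) == [1.5, 2.5]
        assert list(joined["window"]) == [0, 1]
        assert list(joined["n_hyper"]) == [4, 5]

    def test_negative_scores_rejected(self):
        grid = self._grid()
        track = pd.DataFrame({"pos": [5], "score": [-1.0]})
        with pytest.raises(ValueError):
            overlay_loop_scores(track, self._counts(grid), grid)
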