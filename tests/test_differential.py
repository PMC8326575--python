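import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from amfpipe import ConfigError, build_taxon_tree, heat_tree_compare, lefse
from amfpipe.io_and_design import TaxonomyLineage


def lineages(names):
    return {
        name: TaxonomyLineage("Glomeraceae", "Glomus", "", "uncultured")
        for name in names
    }


def frame(data):
    return pd.DataFrame(data).T


class TestTaxonTree:
    def test_hierarchy_and_aggregation(self):
        taxonomy = {
            "sp1": TaxonomyLineage("Glomeraceae", "Glomus", "", "uncultured"),
            "sp2": TaxonomyLineage("Glomeraceae", "Rhizophagus", "", "uncultured"),
            "sp3": TaxonomyLineage("Archaeosporaceae", "Archaeospora", "", "uncultured"),
        }
        tree = build_taxon_tree(taxonomy)
        assert tree.rank == "root"
        assert sorted(tree.member_taxa()) == ["sp1", "sp2", "sp3"]
        families = {c.name for c in tree.children}
        assert families == {"Glomeraceae", "Archaeosporaceae"}


class TestHeatTree:
    def test_identical_tables_no_flags(self):
        a = frame({"sp1": [5, 6, 7, 8, 9], "sp2": [1, 1, 2, 2, 3]})
        result = heat_tree_compare(a, a.copy(), lineages(a.index))
        assert np.allclose(result["effect"], 0.0)
        assert (result["flag"] == 0).all()

    def test_complete_separation_exact_p(self):
        a = frame({"sp1": [100] * 5})
        b = frame({"sp1": [0] * 5})
        result = heat_tree_compare(a, b, lineages(["sp1"]))
        leaf = result[result["node"] == "sp1"].iloc[0]
        assert leaf["p"] == pytest.approx(2 / 252)
        assert leaf["flag"] == 1
        assert leaf["effect"] == pytest.approx(np.log2(100.5 / 0.5))

    def test_median_robust_to_single_replicate(self):
        a = frame({"sp1": [10, 10, 10, 10, 500]})
        b = frame({"sp1": [10, 10, 10, 10, 10]})
        result = heat_tree_compare(a, b, lineages(["sp1"]))
        assert result.iloc[0]["effect"] == pytest.approx(0.0)

    def test_antisymmetry(self):
        rng = np.random.default_rng(60)
        a = frame({f"sp{i}": rng.poisson(20, 5) for i in range(4)})
        b = frame({f"sp{i}": rng.poisson(30, 5) for i in range(4)})
        tax = lineages(a.index)
        fwd = heat_tree_compare(a, b, tax).set_index("node")
        rev = heat_tree_compare(b, a, tax).set_index("node")
        assert np.allclose(fwd["effect"], -rev.loc[fwd.index, "effect"])

    def test_too_few_replicates_rejected(self):
        a = frame({"sp1": [1]})
        with pytest.raises(ConfigError):
            heat_tree_compare(a, a, lineages(["sp1"]))


class TestLefse:
    def _table(self, rows, n_per_group=5):
        return pd.DataFrame(
            rows, columns=[f"s{i}" for i in range(2 * n_per_group)]
        )

    def test_flat_feature_not_reported(self):
        table = pd.DataFrame(
            {f"s{i}": [100, 100] for i in range(10)}, index=["sp1", "sp2"]
        )
        features = lefse(table, ["a"] * 5 + ["b"] * 5, seed=1)
        assert features == []

    def test_large_gap_scores_near_five(self):
        # ~1e5 CPM difference between groups, tiny noise -> score close to 5
        rng = np.random.default_rng(61)
        high = 2e5 + rng.normal(0, 500, 5)
        low = 1e5 + rng.normal(0, 500, 5)
        other_a = 8e5 - high
        other_b = 9e5 - low
        table = pd.DataFrame(
            np.vstack(
                [
                    np.concatenate([high, low]),
                    np.concatenate([other_a, other_b]),
                    np.full(10, 2e5),
                ]
            ),
            index=["target", "filler", "flat"],
            columns=[f"s{i}" for i in range(10)],
        )
        features = lefse(table, ["a"] * 5 + ["b"] * 5, seed=2)
        by_name = {f.taxon: f for f in features}
        assert "target" in by_name
        assert by_name["target"].lda_score == pytest.approx(5.0, abs=0.2)
        assert by_name["target"].top_group == "a"

    def test_largest_separation_gets_highest_score(self):
        rng = np.random.default_rng(62)
        n = 6
        labels = ["a"] * n + ["b"] * n
        gaps = {"sp_small": 2e4, "sp_mid": 8e4, "sp_big": 3e5}
        rows = {}
        for name, gap in gaps.items():
            a_vals = 5e4 + gap + rng.normal(0, 2e3, n)
            b_vals = 5e4 + rng.normal(0, 2e3, n)
            rows[name] = np.concatenate([a_vals, b_vals])
        rows["rest"] = 2e6 - np.sum(list(rows.values()), axis=0)
        table = pd.DataFrame(rows).T
        table.columns = [f"s{i}" for i in range(2 * n)]
        features = lefse(table, labels, seed=3)
        scores = {f.taxon: f.lda_score for f in features}
        planted = {t: scores[t] for t in gaps if t in scores}
        assert planted["sp_big"] == max(planted.values())
        ordered = sorted(planted, key=gaps.get)
        assert [planted[t] for t in ordered] == sorted(planted.values())

    def test_monotone_in_group_separation(self):
        rng = np.random.default_rng(63)
        n = 5
        noise = rng.normal(0, 1e3, 2 * n)
        labels = ["a"] * n + ["b"] * n
        scores = []
        for gap in (5e4, 1e5, 3e5):
            target = np.concatenate([np.full(n, 1e5 + gap), np.full(n, 1e5)]) + noise
            rest = 1.5e6 - target
            table = pd.DataFrame(
                [target, rest], index=["target", "rest"],
                columns=[f"s{i}" for i in range(2 * n)],
            )
            features = lefse(table, labels, seed=4)
            scores.append({f.taxon: f.lda_score for f in features}["target"])
        assert scores == sorted(scores)

    def test_groups_need_three_replicates(self):
        table = pd.DataFrame({"s0": [1], "s1": [2], "s2": [3], "s3": [4]}, index=["sp"]).astype(float)
        with pytest.raises(ConfigError):
            lefse(table, ["a", "a", "b", "b"])


class TestBenjaminiHochberg:
    def test_hand_computed_toy_set(self):
        # p (sorted): .005 .01 .03 .04 .05 with m=5:
        # adj_i = min over j>=i of p_j * m / j, from the right:
        # .05*5/5=.05; .04*5/4=.05; .03*5/3=.05; .01*5/2=.025; .005*5/1=.025
        p = [0.005, 0.01, 0.03, 0.04, 0.05]
        adjusted = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(adjusted, [0.025, 0.025, 0.05, 0.05, 0.05])
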