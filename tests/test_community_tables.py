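import numpy as np
import pandas as pd
import pytest

from amfpipe import (
    AbundanceTable,
    ConfigError,
    all_sample_keys,
    median_filter,
    present_taxa,
    rarefy,
    rollup,
    venn,
)
from amfpipe.io_and_design import TaxonomyLineage


def make_table(counts: dict[str, list[int]], samples=None) -> AbundanceTable:
    samples = samples or all_sample_keys()
    frame = pd.DataFrame(
        counts, index=[k.sample_id for k in samples[: len(next(iter(counts.values())))]]
    ).T
    taxonomy = {
        name: (TaxonomyLineage("Glomeraceae", "Glomus", "", "uncultured"), "de_novo")
        for name in counts
    }
    return AbundanceTable(frame.astype(int), taxonomy, samples)


class TestRarefy:
    def test_exact_depth_column_unchanged(self):
        table = make_table({"t1": [8000], "t2": [0]}, samples=all_sample_keys()[:1])
        out = rarefy(table, depth=8000, seed=1)
        assert out.counts["Bs1S_1"].tolist() == [8000, 0]
        assert out.below_depth == set()

    def test_below_depth_column_flagged_unchanged(self):
        # mirrors the survey's 2,492-read replicate retained un-normalized
        table = make_table({"t1": [2000], "t2": [492]}, samples=all_sample_keys()[:1])
        out = rarefy(table, depth=8000, seed=1)
        assert out.counts["Bs1S_1"].tolist() == [2000, 492]
        assert out.below_depth == {"Bs1S_1"}

    def test_single_taxon_column(self):
        table = make_table(
            {"t1": [16000], "t2": [0], "t3": [0]}, samples=all_sample_keys()[:1]
        )
        out = rarefy(table, depth=8000, seed=2)
        assert out.counts["Bs1S_1"].tolist() == [8000, 0, 0]

    def test_depth_must_be_positive(self):
        table = make_table({"t1": [10]}, samples=all_sample_keys()[:1])
        with pytest.raises(ConfigError):
            rarefy(table, depth=0, seed=1)

    def test_zero_counts_stay_zero_and_expectation(self):
        counts = np.array([5000, 3000, 2000, 0])
        table = make_table(
            {f"t{i}": [int(c)] for i, c in enumerate(counts)},
            samples=all_sample_keys()[:1],
        )
        depth = 1000
        total = counts.sum()
        draws = np.array(
            [
                rarefy(table, depth=depth, seed=s).counts["Bs1S_1"].to_numpy()
                for s in range(200)
            ]
        )
        assert (draws[:, 3] == 0).all()
        assert (draws.sum(axis=1) == depth).all()
        expected = depth * counts / total
        # hypergeometric variance; sample mean within 3 sigma of expectation
        var = (
            depth
            * (counts / total)
            * (1 - counts / total)
            * (total - depth)
            / (total - 1)
        )
        se = np.sqrt(var / 200)
        observed = draws.mean(axis=0)
        assert np.all(np.abs(observed[:3] - expected[:3]) < 3 * se[:3])


class TestPresence:
    def test_single_replicate_over_threshold(self):
        table = make_table({"t1": [12, 0, 0, 0, 0], "t2": [9, 9, 9, 9, 9]})
        present = present_taxa(table, "Bs", "1S")
        assert present == {"t1"}

    def test_counted_once_across_replicates(self):
        table = make_table({"t1": [10, 10, 0, 0, 0]})
        assert present_taxa(table, "Bs", "1S") == {"t1"}

    def test_monotone_in_counts(self):
        base = make_table({"t1": [9, 0, 0, 0, 0]})
        more = make_table({"t1": [19, 0, 0, 0, 0]})
        assert present_taxa(base, "Bs", "1S") <= present_taxa(more, "Bs", "1S")


class TestVenn:
    def test_two_sets(self):
        regions = venn({"A": {"x", "y"}, "B": {"y", "z"}})
        assert regions[("A",)] == {"x"}
        assert regions[("B",)] == {"z"}
        assert regions[("A", "B")] == {"y"}

    def test_four_identical_sets(self):
        s = {f"t{i}" for i in range(20)}
        regions = venn({k: set(s) for k in "ABCD"})
        assert regions[("A", "B", "C", "D")] == s
        assert all(v == set() for k, v in regions.items() if len(k) < 4)

    def test_matches_bruteforce_membership(self):
        rng = np.random.default_rng(12)
        universe = [f"s{i}" for i in range(300)]
        sets = {
            name: set(rng.choice(universe, size=100, replace=False))
            for name in "ABCD"
        }
        regions = venn(sets)
        sizes = {k: len(v) for k, v in regions.items()}
        brute = {k: 0 for k in regions}
        for item in universe:
            inside = tuple(n for n in "ABCD" if item in sets[n])
            if inside:
                brute[inside] += 1
        assert sizes == brute
        assert sum(sizes.values()) == len(set.union(*sets.values()))

    def test_more_than_four_unsupported(self):
        with pytest.raises(ConfigError):
            venn({k: set() for k in "ABCDE"})


class TestMedianFilter:
    @pytest.mark.parametrize(
        "counts,kept",
        [([0, 0, 1, 2, 3], True), ([0, 0, 0, 5, 9], False), ([7, 7, 7, 7, 7], True)],
    )
    def test_third_order_statistic(self, counts, kept):
        table = make_table({"t1": counts})
        assert (("t1" in median_filter(table, "Bs", "1S"))) is kept


class TestRollup:
    def test_known_and_denovo_tallied_jointly(self):
        glomus = TaxonomyLineage("Glomeraceae", "Glomus", "", "uncultured")
        known = {"Bs1S": [(f"k{i}", glomus) for i in range(3)]}
        denovo = {"Bs1S": [(f"d{i}", glomus) for i in range(2)]}
        joint, separate = rollup(known, denovo)
        assert joint.loc["Glomus", "Bs1S"] == 5
        assert separate.loc[("known", "Glomus"), "Bs1S"] == 3
        assert separate.loc[("de_novo", "Glomus"), "Bs1S"] == 2

    def test_denovo_only_genus_appears(self):
        # a genus found only among annotated de novo taxa still gets a bin
        arch = TaxonomyLineage("Archaeosporaceae", "Archaeospora", "", "uncultured")
        joint, separate = rollup({}, {"Rs2S": [("d1", arch)]})
        assert joint.loc["Archaeospora", "Rs2S"] == 1
        assert ("known", "Archaeospora") not in separate.index

    def test_empty_input(self):
        joint, separate = rollup({}, {})
        assert joint.empty and separate.empty

    def test_lineage_less_taxon_binned_unresolved(self):
        bare = TaxonomyLineage(status="uncultured")
        joint, _ = rollup({}, {"Bs1S": [("d1", bare)]})
        assert joint.loc["Glomeromycota (unresolved)", "Bs1S"] == 1
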