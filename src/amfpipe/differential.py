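"""Differential abundance: heat-tree node comparison and single-level LEfSe.

The heat-tree comparison aggregates counts over a taxonomy tree (root ->
family -> genus -> species/cluster) and, per node, reports a median-based
log2 effect, log2((median_A + eps) / (median_B + eps)) with eps = 0.5, and
an exact two-sided Wilcoxon rank-sum p over the replicate counts.

LEfSe is re-implemented in its single-level form: counts are converted to
relative abundance x 10^6, features are screened by Kruskal-Wallis with
Benjamini-Hochberg adjustment, and survivors are scored by an LDA-based
effect size: over stratified 2/3 bootstrap subsamples a linear discriminant
is fitted on the single feature, the feature is projected on the
unit-normalized discriminant axis, and the effect is the mean absolute
difference between the two extreme group means on that axis (so the effect
stays in relative-abundance units); lda_score = log10(max(effect, 1)).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from statsmodels.stats.multitest import multipletests

from .errors import ConfigError
from .io_and_design import TaxonomyLineage

_EPS = 0.5


@dataclass
class TaxonTreeNode:
    name: str
    rank: str  # root | family | genus | species/cluster
    children: list["TaxonTreeNode"] = field(default_factory=list)
    leaf_taxa: list[str] = field(default_factory=list)

    def member_taxa(self) -> list[str]:
        taxa = list(self.leaf_taxa)
        for child in self.children:
            taxa.extend(child.member_taxa())
        return taxa

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class LefseFeature:
    taxon: str
    kw_p: float
    kw_p_adj: float
    lda_score: float
    top_group: str


def build_taxon_tree(taxonomy: dict[str, TaxonomyLineage]) -> TaxonTreeNode:
    """Assemble the root/family/genus/leaf hierarchy from per-taxon lineages."""
    root = TaxonTreeNode("Glomeromycota", "root")
    families: dict[str, TaxonTreeNode] = {}
    genera: dict[tuple[str, str], TaxonTreeNode] = {}
    for name, lineage in taxonomy.items():
        family = lineage.family or "Glomeromycota (unresolved)"
        if family not in families:
            families[family] = TaxonTreeNode(family, "family")
            root.children.append(families[family])
        parent = families[family]
        if lineage.genus:
            gkey = (family, lineage.genus)
            if gkey not in genera:
                genera[gkey] = TaxonTreeNode(lineage.genus, "genus")
                parent.children.append(genera[gkey])
            parent = genera[gkey]
        leaf = TaxonTreeNode(name, "species/cluster", leaf_taxa=[name])
        parent.children.append(leaf)
    return root


def heat_tree_compare(
    tableA: pd.DataFrame,
    tableB: pd.DataFrame,
    taxonomy: dict[str, TaxonomyLineage],
) -> pd.DataFrame:
    """Per-node effect and Wilcoxon p between two replicate groups.

    ``tableA``/``tableB``: taxa x replicate count frames sharing an index.
    Returns a frame with columns node, rank, effect, p, flag where flag is
    the sign of the effect for nodes with p < 0.05 and 0 otherwise.
    """
    if tableA.shape[1] < 2 or tableB.shape[1] < 2:
        raise ConfigError("heat-tree comparison needs >= 2 replicates per side")
    if not tableA.index.equals(tableB.index):
        raise ConfigError("the two tables must share a taxonomy")
    tree = build_taxon_tree({t: taxonomy[t] for t in tableA.index})
    rows = []
    for node in tree.walk():
        members = [t for t in node.member_taxa() if t in tableA.index]
        if not members:
            continue
        a = tableA.loc[members].sum(axis=0).to_numpy(dtype=float)
        b = tableB.loc[members].sum(axis=0).to_numpy(dtype=float)
        effect = float(np.log2((np.median(a) + _EPS) / (np.median(b) + _EPS)))
        if np.all(a == a[0]) and np.all(b == b[0]) and a[0] == b[0]:
            p = 1.0
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p = float(
                    stats.mannwhitneyu(
                        a, b, alternative="two-sided", method="exact"
                    ).pvalue
                )
        flag = int(np.sign(effect)) if p < 0.05 else 0
        rows.append((node.name, node.rank, effect, p, flag))
    return pd.DataFrame(rows, columns=["node", "rank", "effect", "p", "flag"])


def _lda_effect(
    x: np.ndarray, labels: np.ndarray, n_boot: int, rng: np.random.Generator
) -> float:
    """Mean over bootstraps of the extreme-group-mean gap on the LDA axis."""
    unique = np.unique(labels)
    effects = []
    for _ in range(n_boot):
        idx: list[int] = []
        for g in unique:
            members = np.flatnonzero(labels == g)
            take = max(2, int(np.ceil(len(members) * 2 / 3)))
            idx.extend(rng.choice(members, size=min(take, len(members)), replace=False))
        xs = x[idx]
        ys = labels[idx]
        projected = xs
        if len(np.unique(xs)) > 1:
            try:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    lda = LinearDiscriminantAnalysis(n_components=1)
                    lda.fit(xs.reshape(-1, 1), ys)
                    w = lda.scalings_[:, 0]
                    projected = xs * (w[0] / abs(w[0]))  # unit axis, feature units
            except Exception:
                projected = xs
        means = [projected[ys == g].mean() for g in np.unique(ys)]
        effects.append(max(means) - min(means))
    return float(np.mean(effects))


def lefse(
    table: pd.DataFrame,
    group_labels: list[str],
    p_cutoff: float = 0.05,
    lda_cutoff: float = 1.0,
    n_boot: int = 30,
    seed: int = 0,
) -> list[LefseFeature]:
    """Single-level LEfSe over a taxa x sample count frame.

    ``group_labels`` assigns a class to each column.  Returns the features
    passing both cutoffs, sorted by decreasing lda_score.
    """
    if len(group_labels) != table.shape[1]:
        raise ConfigError("one group label per sample column required")
    labels = np.asarray(group_labels)
    unique = np.unique(labels)
    if len(unique) < 2:
        raise ConfigError("LEfSe needs at least two groups")
    if any((labels == g).sum() < 3 for g in unique):
        raise ConfigError("every group needs at least three replicates")
    totals = table.sum(axis=0).to_numpy(dtype=float)
    if (totals == 0).any():
        raise ConfigError("all-zero sample column")
    rel = table.to_numpy(dtype=float) / totals * 1e6  # LEfSe CPM convention
    taxa = list(table.index)
    kw_p = np.ones(len(taxa))
    testable = np.zeros(len(taxa), dtype=bool)
    for i in range(len(taxa)):
        x = rel[i]
        if np.all(x == x[0]):
            continue  # degenerate feature: excluded, kw_p stays 1
        testable[i] = True
        groups_values = [x[labels == g] for g in unique]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            kw_p[i] = stats.kruskal(*groups_values).pvalue
    kw_adj = np.ones(len(taxa))
    if testable.any():
        kw_adj[testable] = multipletests(kw_p[testable], method="fdr_bh")[1]
    rng = np.random.default_rng(seed)
    features: list[LefseFeature] = []
    for i in np.argsort(kw_p):
        if not testable[i] or kw_adj[i] > p_cutoff:
            continue
        effect = _lda_effect(rel[i], labels, n_boot, rng)
        score = float(np.log10(max(effect, 1.0)))
        if score < lda_cutoff:
            continue
        means = {g: rel[i][labels == g].mean() for g in unique}
        top = max(sorted(means), key=lambda g: means[g])
        features.append(
            LefseFeature(taxa[i], float(kw_p[i]), float(kw_adj[i]), score, top)
        )
    features.sort(key=lambda f: -f.lda_score)
    return features


def lefse_to_tsv(features: list[LefseFeature]) -> str:
    lines = ["taxon\tkw_p\tkw_p_adj\tlda_score\tgroup"]
    for f in features:
        lines.append(
            f"{f.taxon}\t{f.kw_p:.6g}\t{f.kw_p_adj:.6g}\t{f.lda_score:.3f}\t{f.top_group}"
        )
    return "\n".join(lines) + "\n"
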