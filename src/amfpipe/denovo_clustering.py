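"""Greedy de novo clustering of reads that failed reference assignment.

Unassigned reads are dereplicated and processed in a content-based order
(decreasing multiplicity, then decreasing length, then lexicographic
sequence), so the clustering is invariant to input read order.  Each unique
sequence joins the first existing centroid it satisfies the dual criterion
against (query = member, subject = centroid); otherwise it founds a new
centroid.  Clusters are named ``de novo_<k>`` in founding order.  An
optional transitive (single-linkage) mode is provided behind a switch;
greedy centroid is the default because every member then provably satisfies
the criterion against its centroid.

Cluster centroids can afterwards be annotated against a local labeled
database (a stand-in for a BLAST search of a public nucleotide database) at
laxer genus-level thresholds; centroids with no passing hit keep the
fallback label "uncultured Glomeromycota".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .errors import ConfigError
from .io_and_design import (
    ReferenceSequence,
    SampleKey,
    SequencingRead,
    TaxonomyLineage,
    UNRESOLVED_LINEAGE,
)
from .pairwise_alignment import (
    DEFAULT_SCORING,
    Scoring,
    align,
    could_pass_criteria,
    passes_criteria,
)


@dataclass
class UniqueSequence:
    """An exact-dereplicated sequence with its multiplicity."""

    sequence: str
    multiplicity: int
    read_ids: list[str]


@dataclass
class DeNovoCluster:
    name: str
    centroid_read_id: str
    centroid_sequence: str
    member_read_ids: list[str] = field(default_factory=list)
    label: TaxonomyLineage | None = None

    @property
    def size(self) -> int:
        return len(self.member_read_ids)

    @property
    def label_text(self) -> str:
        if self.label is None:
            return UNRESOLVED_LINEAGE.label
        return self.label.label


def dereplicate(pool: list[SequencingRead]) -> list[UniqueSequence]:
    """Collapse exact duplicates (case-folded); multiplicities sum to |pool|."""
    table: dict[str, UniqueSequence] = {}
    for read in pool:
        seq = read.bases.upper()
        entry = table.get(seq)
        if entry is None:
            table[seq] = UniqueSequence(seq, 1, [read.read_id])
        else:
            entry.multiplicity += 1
            entry.read_ids.append(read.read_id)
    return list(table.values())


def _processing_order(uniques: list[UniqueSequence]) -> list[UniqueSequence]:
    return sorted(
        uniques, key=lambda u: (-u.multiplicity, -len(u.sequence), u.sequence)
    )


def cluster_denovo(
    uniques: list[UniqueSequence],
    scoring: Scoring = DEFAULT_SCORING,
    min_cov: float = 80.0,
    min_id: float = 97.0,
    prefilter: bool = True,
    linkage: str = "centroid",
) -> list[DeNovoCluster]:
    """Group dereplicated sequences under the dual criterion.

    ``linkage='centroid'`` (default): greedy, first-passing-centroid.
    ``linkage='single'``: transitive closure of the pairwise pass relation
    (connected components), centroids being each component's first sequence
    in processing order.
    """
    if linkage not in ("centroid", "single"):
        raise ConfigError(f"unknown linkage {linkage!r}")
    ordered = _processing_order(uniques)
    clusters: list[DeNovoCluster] = []
    if linkage == "centroid":
        for unique in ordered:
            home = None
            for cluster in clusters:
                if prefilter and not could_pass_criteria(
                    unique.sequence, cluster.centroid_sequence, min_cov, min_id
                ):
                    continue
                hit = align(unique.sequence, cluster.centroid_sequence, scoring)
                if passes_criteria(hit, min_cov, min_id):
                    home = cluster
                    break
            if home is None:
                home = DeNovoCluster(
                    name=f"de novo_{len(clusters) + 1}",
                    centroid_read_id=min(unique.read_ids),
                    centroid_sequence=unique.sequence,
                )
                clusters.append(home)
            home.member_read_ids.extend(unique.read_ids)
    else:
        n = len(ordered)
        parent = list(range(n))

        def find(x: int) -> int:
            while parent[x] != x:
                parent[x] = parent[parent[x]]
                x = parent[x]
            return x

        for i in range(n):
            for j in range(i + 1, n):
                a, b = ordered[i], ordered[j]
                if find(i) == find(j):
                    continue
                if prefilter and not could_pass_criteria(
                    b.sequence, a.sequence, min_cov, min_id
                ):
                    continue
                hit = align(b.sequence, a.sequence, scoring)
                if passes_criteria(hit, min_cov, min_id):
                    parent[find(j)] = find(i)
        components: dict[int, DeNovoCluster] = {}
        for i, unique in enumerate(ordered):
            root = find(i)
            if root not in components:
                components[root] = DeNovoCluster(
                    name=f"de novo_{len(components) + 1}",
                    centroid_read_id=min(ordered[root].read_ids),
                    centroid_sequence=ordered[root].sequence,
                )
                clusters.append(components[root])
            components[root].member_read_ids.extend(unique.read_ids)
    return clusters


def annotate_denovo(
    clusters: list[DeNovoCluster],
    labeled_db: list[ReferenceSequence],
    scoring: Scoring = DEFAULT_SCORING,
    min_cov: float = 80.0,
    min_id: float = 90.0,
    prefilter: bool = True,
) -> list[DeNovoCluster]:
    """Label each centroid by its best passing hit in a local annotated db.

    Thresholds default to genus-level naming (coverage >= 80, identity >=
    90); centroids without a passing hit get the unresolved fallback
    lineage ("uncultured Glomeromycota").  Clusters are modified in place
    and returned.
    """
    refs = sorted(labeled_db, key=lambda r: r.accession)
    for cluster in clusters:
        best_key = None
        best_lineage = None
        for ref in refs:
            if prefilter and not could_pass_criteria(
                cluster.centroid_sequence, ref.bases, min_cov, min_id
            ):
                continue
            hit = align(cluster.centroid_sequence, ref.bases, scoring)
            if not passes_criteria(hit, min_cov, min_id):
                continue
            key = (-hit.score, -hit.identity, ref.accession)
            if best_key is None or key < best_key:
                best_key = key
                best_lineage = ref.lineage
        cluster.label = best_lineage if best_lineage is not None else UNRESOLVED_LINEAGE
    return clusters


def denovo_count_table(
    clusters: list[DeNovoCluster], read_samples: dict[str, SampleKey]
) -> pd.DataFrame:
    """Cluster x sample count matrix from member read ids."""
    sample_ids = sorted({key.sample_id for key in read_samples.values()})
    rows = []
    for cluster in clusters:
        row = {sid: 0 for sid in sample_ids}
        for read_id in cluster.member_read_ids:
            key = read_samples.get(read_id)
            if key is not None:
                row[key.sample_id] += 1
        rows.append(row)
    return pd.DataFrame(
        rows, index=[c.name for c in clusters], columns=sample_ids, dtype=int
    )
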