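"""Count-table normalization, presence/median filters, Venn sets, rollup.

Counts are normalized by rarefaction: each replicate column is subsampled
without replacement (multivariate hypergeometric) to a common depth of
8,000 reads.  Columns whose total is below the depth are kept unchanged and
flagged, mirroring the survey's retention of a 2,492-read replicate.
Presence of a taxon in a (soil, time) cell requires at least 10 reads in at
least one of its five replicates; the taxonomic-group rollup keeps only
taxa whose within-cell median count exceeds zero.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AmfPipeError, ConfigError
from .io_and_design import SampleKey, TaxonomyLineage


@dataclass
class AbundanceTable:
    """Taxon x sample count matrix with per-taxon lineage and origin.

    ``counts``: integer DataFrame, index = taxon names, columns = sample ids.
    ``taxonomy``: taxon name -> (lineage, origin), origin in {known, de_novo}.
    ``below_depth``: sample ids left un-rarefied because of a short column.
    """

    counts: pd.DataFrame
    taxonomy: dict[str, tuple[TaxonomyLineage, str]]
    samples: list[SampleKey]
    below_depth: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ConfigError("counts must be non-negative")
        if self.counts.index.has_duplicates:
            raise ConfigError("taxon names must be unique")

    def replicate_columns(self, soil: str, time: str) -> list[str]:
        cols = [
            k.sample_id
            for k in self.samples
            if k.soil == soil and k.time == time and k.sample_id in self.counts
        ]
        if not cols:
            raise AmfPipeError(f"no replicates for group {soil}{time}")
        return cols


def rarefy(table: AbundanceTable, depth: int = 8000, seed: int = 0) -> AbundanceTable:
    """Subsample every column without replacement to exactly ``depth`` reads.

    Columns with fewer than ``depth`` total reads are left unchanged and
    recorded in ``below_depth``.  Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ConfigError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    out = table.counts.copy()
    flagged = set(table.below_depth)
    for col in out.columns:
        column = out[col].to_numpy()
        total = int(column.sum())
        if total < depth:
            flagged.add(col)
        elif total > depth:
            out[col] = rng.multivariate_hypergeometric(column, depth)
    return AbundanceTable(out, dict(table.taxonomy), list(table.samples), flagged)


def present_taxa(
    table: AbundanceTable, soil: str, time: str, min_reads: int = 10
) -> set[str]:
    """Taxa with >= min_reads in at least one replicate of the (soil, time) cell.

    A taxon present in several replicates of the cell still counts once.
    """
    cols = table.replicate_columns(soil, time)
    sub = table.counts[cols]
    return set(sub.index[(sub >= min_reads).any(axis=1)])


def venn(sets: dict[str, set[str]]) -> dict[tuple[str, ...], set[str]]:
    """All exclusive regions of 2-4 named sets.

    Keys are tuples of the set names a region belongs to; region contents
    are disjoint and their union is the union of the inputs.
    """
    if not 2 <= len(sets) <= 4:
        raise ConfigError("venn supports between 2 and 4 sets")
    names = list(sets)
    regions: dict[tuple[str, ...], set[str]] = {}
    for r in range(1, len(names) + 1):
        for inside in itertools.combinations(names, r):
            outside = [n for n in names if n not in inside]
            region = set.intersection(*(sets[n] for n in inside))
            for n in outside:
                region -= sets[n]
            regions[inside] = region
    return regions


def median_filter(table: AbundanceTable, soil: str, time: str) -> set[str]:
    """Taxa whose median count over the cell's replicates exceeds zero."""
    cols = table.replicate_columns(soil, time)
    medians = table.counts[cols].median(axis=1)
    return set(medians.index[medians > 0])


def rollup(
    known_sets: dict[str, list[tuple[str, TaxonomyLineage]]],
    labeled_denovo_sets: dict[str, list[tuple[str, TaxonomyLineage]]],
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tally taxa per taxonomic group for each (soil, time) sample.

    Inputs map sample-group name (e.g. ``Bs1S``) to the retained taxa of
    that group as (taxon name, lineage) pairs, separately for known and de
    novo taxa.  Returns (joint, separate): ``joint`` counts known and de
    novo together per taxonomic bin; ``separate`` keeps a (origin, bin)
    MultiIndex.  Lineage-less taxa fall in "Glomeromycota (unresolved)".
    """
    groups = sorted(set(known_sets) | set(labeled_denovo_sets))
    joint: dict[str, dict[str, int]] = {}
    separate: dict[tuple[str, str], dict[str, int]] = {}
    for origin, sets in (("known", known_sets), ("de_novo", labeled_denovo_sets)):
        for group in groups:
            for _name, lineage in sets.get(group, []):
                bin_key = lineage.rollup_key
                joint.setdefault(bin_key, {}).setdefault(group, 0)
                joint[bin_key][group] += 1
                separate.setdefault((origin, bin_key), {}).setdefault(group, 0)
                separate[(origin, bin_key)][group] += 1
    joint_df = pd.DataFrame(
        [[joint[b].get(g, 0) for g in groups] for b in sorted(joint)],
        index=sorted(joint),
        columns=groups,
        dtype=int,
    )
    sep_index = pd.MultiIndex.from_tuples(
        sorted(separate), names=["origin", "group_bin"]
    )
    separate_df = pd.DataFrame(
        [[separate[k].get(g, 0) for g in groups] for k in sorted(separate)],
        index=sep_index,
        columns=groups,
        dtype=int,
    )
    return joint_df, separate_df


def venn_to_json(regions: dict[tuple[str, ...], set[str]]) -> dict[str, list[str]]:
    """JSON-friendly Venn regions: '&'-joined names -> sorted members."""
    return {"&".join(k): sorted(v) for k, v in regions.items()}
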