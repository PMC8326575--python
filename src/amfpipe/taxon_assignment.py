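"""Assignment of QC-passed reads to known reference taxa.

A read is "known" when its best local alignment against the reference
database satisfies the dual criterion (coverage >= 80%, identity >= 97%).
Among passing hits the winner is chosen by highest score, then highest
identity, then lexicographically smallest accession.  Reads with no passing
hit go to the de novo pool.  Assignment granularity is the reference
lineage label, so multiple accessions sharing a label pool into one taxon.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .errors import ConfigError
from .io_and_design import ReferenceSequence, SequencingRead
from .pairwise_alignment import (
    DEFAULT_SCORING,
    PairwiseHit,
    Scoring,
    align,
    align_score,
    could_pass_criteria,
    passes_criteria,
)

KNOWN = "known"
DE_NOVO_POOL = "de_novo_pool"


@dataclass
class TaxonAssignment:
    read_id: str
    kind: str  # KNOWN or DE_NOVO_POOL
    taxon_label: str = ""
    best_hit: PairwiseHit | None = None

    def to_tsv(self) -> str:
        if self.best_hit is None:
            return f"{self.read_id}\t{self.kind}\t\t\t\t"
        h = self.best_hit
        return (
            f"{self.read_id}\t{self.kind}\t{self.taxon_label}\t"
            f"{h.identity:.2f}\t{h.coverage:.2f}\t{h.score}"
        )


def assign_known(
    read: SequencingRead,
    reference_db: list[ReferenceSequence],
    scoring: Scoring = DEFAULT_SCORING,
    min_cov: float = 80.0,
    min_id: float = 97.0,
    prefilter: bool = True,
) -> TaxonAssignment:
    """Assign one read by best passing hit, or route it to the de novo pool.

    References are screened with a sound edit-distance prefilter (it can
    only discard pairs that provably fail the criterion), scored cheaply,
    and fully aligned in descending score order until the best passing hit
    is certain.
    """
    if not reference_db:
        raise ConfigError("reference database is empty")
    candidates: list[tuple[int, str, ReferenceSequence]] = []
    for ref in sorted(reference_db, key=lambda r: r.accession):
        if prefilter and not could_pass_criteria(
            read.bases, ref.bases, min_cov, min_id
        ):
            continue
        score = align_score(read.bases, ref.bases, scoring)
        candidates.append((score, ref.accession, ref))
    # Descending score, ascending accession: the first passing hit can only
    # be displaced by an equal-score hit with higher identity.
    candidates.sort(key=lambda t: (-t[0], t[1]))
    best: tuple[int, float, str] | None = None  # (score, -identity proxy, acc)
    best_hit: PairwiseHit | None = None
    best_label = ""
    for score, accession, ref in candidates:
        if best is not None and score < best[0]:
            break
        hit = align(
            read.bases,
            ref.bases,
            scoring,
            query_id=read.read_id,
            subject_id=accession,
        )
        if not passes_criteria(hit, min_cov, min_id):
            continue
        key = (-hit.score, -hit.identity, accession)
        if best is None or key < (-best[0], best[1], best[2]):
            best = (hit.score, -hit.identity, accession)
            best_hit = hit
            best_label = ref.label
    if best_hit is None:
        return TaxonAssignment(read.read_id, DE_NOVO_POOL)
    return TaxonAssignment(read.read_id, KNOWN, best_label, best_hit)


def assign_all(
    reads: list[SequencingRead],
    reference_db: list[ReferenceSequence],
    scoring: Scoring = DEFAULT_SCORING,
    min_cov: float = 80.0,
    min_id: float = 97.0,
    prefilter: bool = True,
) -> tuple[list[TaxonAssignment], pd.DataFrame, list[SequencingRead]]:
    """Assign every read; tabulate known-taxon counts per sample.

    Returns (assignments, counts DataFrame taxa x sample_ids, de novo pool
    reads).  Assignments partition the input: every read is either counted
    under a known taxon or present in the pool.
    """
    assignments: list[TaxonAssignment] = []
    pool: list[SequencingRead] = []
    counts: dict[str, dict[str, int]] = {}
    sample_ids = sorted({r.sample.sample_id for r in reads if r.sample is not None})
    for read in reads:
        assignment = assign_known(
            read, reference_db, scoring, min_cov, min_id, prefilter
        )
        assignments.append(assignment)
        if assignment.kind == KNOWN:
            if read.sample is not None:
                row = counts.setdefault(assignment.taxon_label, {})
                row[read.sample.sample_id] = row.get(read.sample.sample_id, 0) + 1
        else:
            pool.append(read)
    table = pd.DataFrame(
        [
            [counts[taxon].get(sid, 0) for sid in sample_ids]
            for taxon in sorted(counts)
        ],
        index=sorted(counts),
        columns=sample_ids,
        dtype=int,
    )
    return assignments, table, pool
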