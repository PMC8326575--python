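"""Local pairwise alignment: the coverage/identity contract.

Both reference assignment and de novo clustering decide "same taxon" through
one contract: the optimal Smith-Waterman local alignment under BLASTN-like
affine scoring (match +2, mismatch -3, gap open -5, gap extend -2; a gap of
length k costs open + k*extend), from which

* identity  = 100 * matches / alignment_columns  (columns include gaps), and
* coverage  = 100 * aligned query span / query length  (query-coverage,
  span = q_end - q_start + 1),

are compared against the dual criterion coverage >= 80% and identity >= 97%
(inclusive).  Ties between equal-score alignments are broken deterministically:
traceback prefers diagonal (match state) over vertical over horizontal
continuation and prefers extending over terminating, and among co-optimal
endpoints the alignment with the smallest (q_start, s_start) wins.

Only the single best local alignment is used per pair; a chimeric read whose
halves match two distant parents therefore fails the identity criterion and
is routed to the de novo pool, which is what removes chimeras downstream.
"""

from __future__ import annotations

from dataclasses import dataclass

import edlib
import numpy as np
from numba import njit

from .errors import ConfigError

_NEG = -(2**30)


@dataclass(frozen=True)
class Scoring:
    """Affine local-alignment scoring; gap of length k costs open + k*extend."""

    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch >= 0 or self.gap_extend >= 0:
            raise ConfigError("scoring must reward matches and penalize edits")


DEFAULT_SCORING = Scoring()


@dataclass(frozen=True)
class PairwiseHit:
    """Best local alignment between a query and a subject."""

    query_id: str
    subject_id: str
    coverage: float
    identity: float
    score: int
    alignment_columns: int = 0
    matches: int = 0
    q_start: int = 0  # 1-based, inclusive; 0 when no positive-score alignment
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def to_blast6(self) -> str:
        """BLAST outfmt-6-like TSV row: qseqid sseqid pident qcovs score."""
        return (
            f"{self.query_id}\t{self.subject_id}\t{self.identity:.2f}\t"
            f"{self.coverage:.2f}\t{self.score}"
        )


def passes_criteria(
    hit: PairwiseHit, min_cov: float = 80.0, min_id: float = 97.0
) -> bool:
    """The dual criterion, inclusive on both bounds."""
    return hit.coverage >= min_cov and hit.identity >= min_id


# ---------------------------------------------------------------------------
# Numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _fill(q, s, ma, mi, go, ge):  # pragma: no cover - exercised via align()
    n, m = len(q), len(s)
    M = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Ix = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    Iy = np.full((n + 1, m + 1), _NEG, dtype=np.int64)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            sub = ma if q[i - 1] == s[j - 1] else mi
            pred = 0
            if M[i - 1, j - 1] > pred:
                pred = M[i - 1, j - 1]
            if Ix[i - 1, j - 1] > pred:
                pred = Ix[i - 1, j - 1]
            if Iy[i - 1, j - 1] > pred:
                pred = Iy[i - 1, j - 1]
            M[i, j] = pred + sub
            a = M[i - 1, j] + go + ge
            b = Ix[i - 1, j] + ge
            Ix[i, j] = a if a > b else b
            a = M[i, j - 1] + go + ge
            b = Iy[i, j - 1] + ge
            Iy[i, j] = a if a > b else b
    return M, Ix, Iy


@njit(cache=True)
def _score_only(q, s, ma, mi, go, ge):  # pragma: no cover
    """Best local score with O(m) memory (rolling rows)."""
    m = len(s)
    Mp = np.full(m + 1, _NEG, dtype=np.int64)
    Ixp = np.full(m + 1, _NEG, dtype=np.int64)
    Iyp = np.full(m + 1, _NEG, dtype=np.int64)
    Mc = np.full(m + 1, _NEG, dtype=np.int64)
    Ixc = np.full(m + 1, _NEG, dtype=np.int64)
    Iyc = np.full(m + 1, _NEG, dtype=np.int64)
    best = 0
    for i in range(1, len(q) + 1):
        Mc[0] = _NEG
        Ixc[0] = _NEG
        Iyc[0] = _NEG
        for j in range(1, m + 1):
            sub = ma if q[i - 1] == s[j - 1] else mi
            pred = 0
            if Mp[j - 1] > pred:
                pred = Mp[j - 1]
            if Ixp[j - 1] > pred:
                pred = Ixp[j - 1]
            if Iyp[j - 1] > pred:
                pred = Iyp[j - 1]
            Mc[j] = pred + sub
            if Mc[j] > best:
                best = Mc[j]
            a = Mp[j] + go + ge
            b = Ixp[j] + ge
            Ixc[j] = a if a > b else b
            a = Mc[j - 1] + go + ge
            b = Iyc[j - 1] + ge
            Iyc[j] = a if a > b else b
        Mp, Mc = Mc, Mp
        Ixp, Ixc = Ixc, Ixp
        Iyp, Iyc = Iyc, Iyp
    return best


@njit(cache=True)
def _traceback(M, Ix, Iy, q, s, ei, ej, ma, mi, go, ge):  # pragma: no cover
    """Walk back from endpoint (ei, ej) in match state.

    Tie preference at every step: continue in match state, then vertical
    gap, then horizontal gap, then terminate.  Returns
    (q_start, s_start, matches, columns), starts 1-based.
    """
    i, j = ei, ej
    state = 0  # 0 = M, 1 = Ix (gap in subject), 2 = Iy (gap in query)
    matches = 0
    columns = 0
    while True:
        if state == 0:
            sub = ma if q[i - 1] == s[j - 1] else mi
            if q[i - 1] == s[j - 1]:
                matches += 1
            columns += 1
            target = M[i, j] - sub
            i -= 1
            j -= 1
            if i > 0 and j > 0 and M[i, j] == target:
                state = 0
            elif i > 0 and j > 0 and Ix[i, j] == target:
                state = 1
            elif i > 0 and j > 0 and Iy[i, j] == target:
                state = 2
            else:
                break  # target == 0: local alignment starts here
        elif state == 1:
            columns += 1
            if M[i - 1, j] + go + ge == Ix[i, j]:
                state = 0
            i -= 1
        else:
            columns += 1
            if M[i, j - 1] + go + ge == Iy[i, j]:
                state = 0
            j -= 1
    return i + 1, j + 1, matches, columns


def _encode(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)


# ---------------------------------------------------------------------------
# Public operations
# ---------------------------------------------------------------------------

def align(
    query: str,
    subject: str,
    scoring: Scoring = DEFAULT_SCORING,
    query_id: str = "query",
    subject_id: str = "subject",
) -> PairwiseHit:
    """Optimal local alignment of ``query`` against ``subject``."""
    if not query or not subject:
        raise ConfigError("cannot align empty sequences")
    q, s = _encode(query), _encode(subject)
    ma, mi, go, ge = (
        scoring.match,
        scoring.mismatch,
        scoring.gap_open,
        scoring.gap_extend,
    )
    M, Ix, Iy = _fill(q, s, ma, mi, go, ge)
    best = int(M.max())
    if best <= 0:
        return PairwiseHit(query_id, subject_id, 0.0, 0.0, 0)
    ends = np.argwhere(M == best)  # row-major: ascending i, then j
    chosen = None
    for ei, ej in ends:
        qs, ss, matches, columns = _traceback(
            M, Ix, Iy, q, s, int(ei), int(ej), ma, mi, go, ge
        )
        key = (qs, ss, int(ei), int(ej))
        if chosen is None or key < chosen[0]:
            chosen = (key, qs, ss, matches, columns, int(ei), int(ej))
    _, qs, ss, matches, columns, ei, ej = chosen
    coverage = 100.0 * (ei - qs + 1) / len(query)
    identity = 100.0 * matches / columns
    return PairwiseHit(
        query_id,
        subject_id,
        coverage=coverage,
        identity=identity,
        score=best,
        alignment_columns=columns,
        matches=matches,
        q_start=qs,
        q_end=ei,
        s_start=ss,
        s_end=ej,
    )


def align_score(
    query: str, subject: str, scoring: Scoring = DEFAULT_SCORING
) -> int:
    """Best local alignment score only (cheaper than :func:`align`)."""
    if not query or not subject:
        raise ConfigError("cannot align empty sequences")
    return int(
        _score_only(
            _encode(query),
            _encode(subject),
            scoring.match,
            scoring.mismatch,
            scoring.gap_open,
            scoring.gap_extend,
        )
    )


def could_pass_criteria(
    query: str, subject: str, min_cov: float = 80.0, min_id: float = 97.0
) -> bool:
    """Sound prefilter for the dual criterion via banded infix edit distance.

    A local alignment with coverage >= min_cov and identity >= min_id implies
    the whole query fits into the subject (edlib "HW" infix mode) within

        k = L * [(1 - min_cov/100) + (1 - min_id/100) / (min_id/100)]

    edit operations (unaligned flanks plus within-alignment edits).  If even
    the infix edit distance exceeds k, no alignment can satisfy the
    criterion, so ``False`` is a proof of failure; ``True`` is inconclusive
    and must be confirmed by :func:`align`.
    """
    L = len(query)
    frac = (1.0 - min_cov / 100.0) + (1.0 - min_id / 100.0) / (min_id / 100.0)
    k = int(np.ceil(L * frac)) + 1
    result = edlib.align(query.upper(), subject.upper(), mode="HW", task="distance", k=k)
    return result["editDistance"] != -1


def warm_up() -> None:
    """Trigger numba compilation of the alignment kernels."""
    align("ACGTACGT", "ACGTACGT")
    align_score("ACGTACGT", "ACGTACGT")
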