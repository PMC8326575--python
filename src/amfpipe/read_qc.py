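"""Read quality control.

Three discard rules, applied in fixed order with first-failing attribution:

1. length below ``min_len`` nucleotides (default 200);
2. arithmetic mean Phred quality below ``min_mean_q`` (default 25);
3. at least one ambiguous base (any character outside A/C/G/T, case-folded).

Thresholds are strict "less than" for discarding, so a 200 nt read with mean
quality exactly 25.0 passes.  No trimming is performed.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from typing import Iterable

from .errors import ConfigError
from .io_and_design import SequencingRead

_ACGT = frozenset("ACGT")


@dataclass
class QcReport:
    """Per-reason discard tally; n_input = n_passed + the three discard bins."""

    n_input: int = 0
    n_passed: int = 0
    n_short: int = 0
    n_lowq: int = 0
    n_ambiguous: int = 0

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)


def filter_reads(
    reads: Iterable[SequencingRead],
    min_len: int = 200,
    min_mean_q: float = 25.0,
) -> tuple[list[SequencingRead], QcReport]:
    """Apply the three discard rules; return surviving reads and the tally."""
    if min_len < 0 or min_mean_q < 0:
        raise ConfigError("QC thresholds must be non-negative")
    passed: list[SequencingRead] = []
    report = QcReport()
    for read in reads:
        report.n_input += 1
        if len(read) < min_len:
            report.n_short += 1
        elif read.mean_quality() < min_mean_q:
            report.n_lowq += 1
        elif not _ACGT.issuperset(read.bases.upper()):
            report.n_ambiguous += 1
        else:
            report.n_passed += 1
            passed.append(read)
    return passed, report
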