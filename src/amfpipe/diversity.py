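"""Alpha diversity: rarefaction curves, observed/Shannon/Simpson, group tests.

Shannon entropy is reported in nats and the Simpson index as the
Gini-Simpson form 1 - sum(p_i^2), matching the phyloseq conventions the
field's interactive tools use.  The rarefaction curve is the analytic
expectation of richness under subsampling without replacement,

    E[S_m] = sum_i 1 - C(N - N_i, m) / C(N, m),

evaluated in log space for numerical stability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.special import gammaln

from .errors import AmfPipeError, ConfigError
from .community_tables import AbundanceTable
from .io_and_design import SampleKey


@dataclass
class AlphaResult:
    sample: SampleKey | str
    observed: int
    shannon: float
    simpson: float


def rarefaction_curve(
    counts: np.ndarray | list[int], depths: list[int]
) -> list[tuple[int, float]]:
    """Expected richness at each subsampling depth (without replacement)."""
    counts = np.asarray(counts, dtype=np.int64)
    counts = counts[counts > 0]
    N = int(counts.sum())
    if N == 0:
        raise AmfPipeError("cannot rarefy an all-zero composition")
    curve = []
    for m in depths:
        if m > N:
            raise ConfigError(f"depth {m} exceeds total count {N}")
        if m < 0:
            raise ConfigError("depth must be non-negative")
        # log C(N - N_i, m) - log C(N, m); C(N - N_i, m) = 0 when m > N - N_i
        rest = N - counts
        with np.errstate(invalid="ignore"):
            log_num = gammaln(rest + 1) - gammaln(m + 1) - gammaln(rest - m + 1)
        log_den = gammaln(N + 1) - gammaln(m + 1) - gammaln(N - m + 1)
        absent_prob = np.where(rest >= m, np.exp(log_num - log_den), 0.0)
        curve.append((m, float(np.sum(1.0 - absent_prob))))
    return curve


def _alpha_from_counts(counts: np.ndarray) -> tuple[int, float, float]:
    total = counts.sum()
    if total == 0:
        raise AmfPipeError("all-zero sample column")
    positive = counts[counts > 0]
    p = positive / total
    observed = int(len(positive))
    shannon = float(-np.sum(p * np.log(p)))
    simpson = float(1.0 - np.sum(p**2))
    return observed, shannon, simpson


def alpha(table: AbundanceTable) -> list[AlphaResult]:
    """Observed richness, Shannon (nats), Gini-Simpson per replicate column."""
    results = []
    key_by_id = {k.sample_id: k for k in table.samples}
    for col in table.counts.columns:
        observed, shannon, simpson = _alpha_from_counts(
            table.counts[col].to_numpy(dtype=float)
        )
        results.append(
            AlphaResult(key_by_id.get(col, col), observed, shannon, simpson)
        )
    return results


def alpha_group_test(
    values: list[float], groups: list[str], mode: str = "parametric"
) -> tuple[float, float]:
    """Compare an alpha index across groups.

    ``parametric`` runs a one-way ANOVA F-test, ``nonparametric`` a
    tie-corrected Kruskal-Wallis test.  Returns (statistic, p).
    """
    if len(values) != len(groups):
        raise ConfigError("values and groups must have the same length")
    by_group: dict[str, list[float]] = {}
    for v, g in zip(values, groups):
        by_group.setdefault(g, []).append(v)
    if len(by_group) < 2:
        raise ConfigError("need at least two groups")
    if any(len(v) < 2 for v in by_group.values()):
        raise ConfigError("every group needs at least two values")
    samples = list(by_group.values())
    if mode == "parametric":
        result = stats.f_oneway(*samples)
    elif mode == "nonparametric":
        result = stats.kruskal(*samples)
    else:
        raise ConfigError(f"unknown test mode {mode!r}")
    return float(result.statistic), float(result.pvalue)
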