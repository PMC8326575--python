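"""Trouvelot scoring of arbuscular mycorrhizal root colonization.

Thirty (or any number of) 1-cm root fragments per plant are scored under
the microscope into a colonization class 0-5 (0 = no colonization, 5 =
more than 90% of the cortex colonized) and arbuscule / vesicle richness
classes 0-3.  The class weights of the Trouvelot system are fixed here as
the contract: intensity weights 0/1/5/30/70/95 per colonization class and
arbuscule weights 10/50/100 per arbuscule class.  Derived indices:

    F%  frequency of colonized fragments          100 (N - n0) / N
    M%  colonization intensity of the root system sum(w[class]) / N
    m%  intensity restricted to colonized parts   M N / (N - n0)
    a%  arbuscule richness in colonized parts     (100 mA3 + 50 mA2 + 10 mA1)/100
    A%  arbuscule abundance of the root system    a M / 100

where mA_j is the percentage of colonized-part intensity contributed by
fragments of arbuscule class j.  Vesicles (v%, V%) use the same machinery.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ConfigError, ValidationError

MYC_WEIGHTS = (0.0, 1.0, 5.0, 30.0, 70.0, 95.0)
RICHNESS_WEIGHTS = (0.0, 10.0, 50.0, 100.0)  # arbuscule / vesicle class weights


@dataclass(frozen=True)
class RootFragmentScore:
    myc_class: int
    arb_class: int = 0
    ves_class: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.myc_class <= 5:
            raise ValidationError("myc_class must be 0-5")
        if not 0 <= self.arb_class <= 3 or not 0 <= self.ves_class <= 3:
            raise ValidationError("arbuscule/vesicle classes must be 0-3")
        if self.myc_class == 0 and (self.arb_class or self.ves_class):
            raise ValidationError(
                "an uncolonized fragment cannot carry arbuscules or vesicles"
            )


@dataclass(frozen=True)
class ColonizationResult:
    F_pct: float
    M_pct: float
    m_pct: float
    a_pct: float
    A_pct: float
    v_pct: float
    V_pct: float


def _richness_indices(
    fragments: Sequence[RootFragmentScore],
    attr: str,
    M: float,
    n_colonized: int,
    N: int,
) -> tuple[float, float]:
    """(a%, A%) style pair for arbuscules or vesicles."""
    if M == 0.0:
        return 0.0, 0.0
    # Intensity contribution (as % of root system) from fragments in each
    # richness class; mA_j normalizes it to the colonized-part intensity m,
    # which reduces to a share of M.
    contrib = [0.0, 0.0, 0.0, 0.0]
    for frag in fragments:
        contrib[getattr(frag, attr)] += MYC_WEIGHTS[frag.myc_class] / N
    share = [100.0 * c / M for c in contrib]  # mA_j, % of colonized intensity
    a = sum(w * s for w, s in zip(RICHNESS_WEIGHTS, share)) / 100.0
    a = min(a, 100.0)  # guard against floating-point spill past 100
    A = a * M / 100.0
    return a, A


def colonization_indices(
    fragments: Iterable[RootFragmentScore],
) -> ColonizationResult:
    """Trouvelot indices for one plant's scored fragments."""
    fragments = list(fragments)
    if not fragments:
        raise ConfigError("no fragments scored")
    N = len(fragments)
    n0 = sum(1 for f in fragments if f.myc_class == 0)
    F = 100.0 * (N - n0) / N
    M = sum(MYC_WEIGHTS[f.myc_class] for f in fragments) / N
    m = M * N / (N - n0) if N > n0 else 0.0
    a, A = _richness_indices(fragments, "arb_class", M, N - n0, N)
    v, V = _richness_indices(fragments, "ves_class", M, N - n0, N)
    return ColonizationResult(F, M, m, a, A, v, V)


_INDICES = ("F_pct", "M_pct", "A_pct", "V_pct")


def compare_groups(
    resultsA: Sequence[ColonizationResult],
    resultsB: Sequence[ColonizationResult],
) -> pd.DataFrame:
    """One-way ANOVA per index (F, M, A, V) between two plant groups.

    Returns a frame indexed by index name with group means, SDs, the ANOVA
    F statistic and p-value.
    """
    if len(resultsA) < 2 or len(resultsB) < 2:
        raise ConfigError("need at least two plants per group")
    rows = []
    for name in _INDICES:
        a = np.array([getattr(r, name) for r in resultsA], dtype=float)
        b = np.array([getattr(r, name) for r in resultsB], dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            f_stat, p = 0.0, 1.0
        else:
            res = stats.f_oneway(a, b)
            f_stat, p = float(res.statistic), float(res.pvalue)
        rows.append(
            (
                name.removesuffix("_pct"),
                a.mean(),
                a.std(ddof=1),
                b.mean(),
                b.std(ddof=1),
                f_stat,
                p,
            )
        )
    return pd.DataFrame(
        rows,
        columns=["index", "mean_a", "sd_a", "mean_b", "sd_b", "F_stat", "p"],
    ).set_index("index")


def read_scorecards(path: str) -> dict[str, list[RootFragmentScore]]:
    """Read a fragment score TSV: plant_id, myc_class, arb_class, ves_class."""
    frame = pd.read_csv(path, sep="\t")
    required = {"plant_id", "myc_class", "arb_class", "ves_class"}
    if not required <= set(frame.columns):
        raise ConfigError(f"scorecard must have columns {sorted(required)}")
    cards: dict[str, list[RootFragmentScore]] = {}
    for row in frame.itertuples(index=False):
        cards.setdefault(str(row.plant_id), []).append(
            RootFragmentScore(
                int(row.myc_class), int(row.arb_class), int(row.ves_class)
            )
        )
    return cards
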