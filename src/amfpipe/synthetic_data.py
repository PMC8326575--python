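"""Ground-truthed simulation of the vineyard amplicon survey.

The generator emulates the structure of a 454-style LSU rDNA amplicon run
over the 2 soils x 2 times x 5 replicates design: a mock reference
database of mutually divergent (>= 10%) taxa, per-replicate community
compositions drawn from a Dirichlet model with multiplicative soil and
time effects on selected taxa, and error-bearing ~700 bp reads with
quality strings, plus injected chimeras, off-target sequences, and reads
engineered to fail each of the three QC rules.  Every emitted read is
covered exactly once by the returned ground truth.

What it emulates: amplicon length variation, per-base substitution/indel
noise, two-parent chimeras, depth spread across replicates (the survey's
2,000-12,000 reads per replicate), and compositional group effects.  What
it does not: 454 homopolymer-specific miscalls, flowgram-level artifacts,
primer sequence context, and phylogenetically structured divergence, so
passing recovery tests here shows algorithmic correctness, not robustness
to every real-data pathology.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError
from .io_and_design import (
    MidMap,
    ReferenceSequence,
    SampleKey,
    SequencingRead,
    TaxonomyLineage,
    all_sample_keys,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# Species pool used for "known" (species-level) reference taxa; the mock
# community is dominated by Glomeraceae with Archaeosporaceae as the only
# other family, as in field surveys of conventionally managed vineyards.
_KNOWN_POOL = [
    ("Glomeraceae", "Rhizophagus", "Rhizophagus irregularis"),
    ("Glomeraceae", "Rhizophagus", "Rhizophagus intraradices"),
    ("Glomeraceae", "Glomus", "Glomus macrocarpum"),
    ("Glomeraceae", "Septoglomus", "Septoglomus viscosum"),
    ("Glomeraceae", "Glomus", "Glomus mosseae"),
    ("Glomeraceae", "Rhizophagus", "Rhizophagus diaphanum"),
    ("Glomeraceae", "Glomus", "Glomus aggregatum"),
    ("Glomeraceae", "Glomus", "Glomus etunicatum"),
]
_UNCULTURED_POOL = [
    ("Glomeraceae", "Glomus", ""),
    ("Archaeosporaceae", "Archaeospora", ""),
    ("Glomeraceae", "Rhizophagus", ""),
    ("Archaeosporaceae", "Archaeospora", ""),
    ("Glomeraceae", "Glomus", ""),
]


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the mock survey.

    Defaults mirror the survey scale: ~700 bp amplicons from 600-800 bp
    reference sequences and 2,000-12,000 reads per replicate, with mild
    pyrosequencing-era noise.
    """

    seed: int
    n_ref_taxa: int = 12
    ref_length: tuple[int, int] = (600, 800)
    reads_per_replicate: tuple[int, int] = (2000, 12000)
    read_length_mean: float = 700.0
    read_length_sd: float = 40.0
    min_read_length: int = 250
    substitution_rate: float = 0.005
    indel_rate: float = 0.0005
    chimera_fraction: float = 0.02
    off_target_fraction: float = 0.02
    frac_short: float = 0.01
    frac_lowq: float = 0.01
    frac_ambiguous: float = 0.01
    known_fraction: float = 0.6
    dirichlet_concentration: float = 120.0
    n_soil_effect_taxa: int = 3
    soil_effect_fold: float = 4.0
    n_time_effect_taxa: int = 1
    time_effect_fold: float = 4.0
    min_divergence: float = 0.10

    def __post_init__(self) -> None:
        fractions = (
            self.chimera_fraction,
            self.off_target_fraction,
            self.frac_short,
            self.frac_lowq,
            self.frac_ambiguous,
            self.known_fraction,
        )
        if any(not 0.0 <= f <= 1.0 for f in fractions):
            raise ConfigError("all fractions must lie in [0, 1]")
        if self.substitution_rate < 0 or self.indel_rate < 0:
            raise ConfigError("error rates must be non-negative")
        if self.n_ref_taxa <= 0:
            raise ConfigError("n_ref_taxa must be positive")
        if self.chimera_fraction + self.off_target_fraction > 1.0:
            raise ConfigError("chimera + off-target fractions exceed 1")


@dataclass
class GroundTruth:
    """Per-read provenance and per-replicate truth for one simulation."""

    # read_id -> source accession; chimeras/off-target reads map to None
    read_taxon: dict[str, str | None] = field(default_factory=dict)
    chimera_ids: set[str] = field(default_factory=set)
    off_target_ids: set[str] = field(default_factory=set)
    # sample_id -> rule -> injected defect read ids
    defect_ids: dict[str, dict[str, set[str]]] = field(default_factory=dict)
    # sample_id -> accession -> count over clean (QC-survivable) reads
    true_composition: dict[str, dict[str, int]] = field(default_factory=dict)
    # accession -> fold applied in Rs relative to Bs (resp. 2S relative to 1S)
    soil_effects: dict[str, float] = field(default_factory=dict)
    time_effects: dict[str, float] = field(default_factory=dict)


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _divergence(a: str, b: str) -> float:
    import edlib

    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


def simulate_reference_db(
    config: SimulationConfig,
) -> tuple[list[ReferenceSequence], list[ReferenceSequence]]:
    """Generate (known reference db, full labeled annotation db).

    All ``n_ref_taxa`` taxa carry lineages and appear in the annotation
    database; the ``known_fraction`` of them (species-level entries) form
    the reference database used for read assignment.  Pairwise divergence
    of taxa is at least ``min_divergence`` (enforced by rejection).
    """
    rng = np.random.default_rng(config.seed)
    n_known = int(round(config.n_ref_taxa * config.known_fraction))
    sequences: list[str] = []
    attempts = 0
    while len(sequences) < config.n_ref_taxa:
        attempts += 1
        if attempts > 50 * config.n_ref_taxa:
            raise ConfigError(
                "could not satisfy the pairwise divergence constraint"
            )
        length = int(rng.integers(config.ref_length[0], config.ref_length[1] + 1))
        candidate = _random_sequence(rng, length)
        if all(
            _divergence(candidate, other) >= config.min_divergence
            for other in sequences
        ):
            sequences.append(candidate)
    labeled: list[ReferenceSequence] = []
    known: list[ReferenceSequence] = []
    for i, seq in enumerate(sequences):
        accession = f"SYN{i + 1:04d}"
        if i < n_known:
            family, genus, species = _KNOWN_POOL[i % len(_KNOWN_POOL)]
            if i >= len(_KNOWN_POOL):
                species = f"{species} {i // len(_KNOWN_POOL) + 1}"
            lineage = TaxonomyLineage(family, genus, species, "known")
            ref = ReferenceSequence(accession, seq, lineage)
            known.append(ref)
        else:
            j = i - n_known
            family, genus, _ = _UNCULTURED_POOL[j % len(_UNCULTURED_POOL)]
            lineage = TaxonomyLineage(family, genus, "", "uncultured")
            ref = ReferenceSequence(accession, seq, lineage)
        labeled.append(ref)
    return known, labeled


def _mutate(rng: np.random.Generator, seq: str, sub_rate: float, indel_rate: float) -> str:
    if sub_rate == 0 and indel_rate == 0:
        return seq
    arr = np.frombuffer(seq.encode("ascii"), dtype=np.uint8).copy()
    out = []
    for base in arr:
        r = rng.random()
        if r < indel_rate / 2:
            continue  # deletion
        if r < indel_rate:
            out.append(_BASES[rng.integers(4)])  # insertion before the base
        if rng.random() < sub_rate:
            current = base
            repl = current
            while repl == current:
                repl = _BASES[rng.integers(4)]
            out.append(repl)
        else:
            out.append(base)
    return np.array(out, dtype=np.uint8).tobytes().decode("ascii")


def _draw_length(rng: np.random.Generator, config: SimulationConfig) -> int:
    length = int(round(rng.normal(config.read_length_mean, config.read_length_sd)))
    return max(config.min_read_length, length)


def _good_quals(rng: np.random.Generator, n: int) -> list[int]:
    return list(rng.integers(30, 41, size=n))


def _low_quals(rng: np.random.Generator, n: int) -> list[int]:
    return list(rng.integers(15, 25, size=n))


def simulate_reads(
    config: SimulationConfig,
    db: list[ReferenceSequence],
) -> tuple[dict[SampleKey, list[SequencingRead]], GroundTruth]:
    """Draw per-replicate communities and emit error-bearing reads.

    ``db`` is the full labeled taxon list from
    :func:`simulate_reference_db`.  Returns demultiplexed reads keyed by
    sample and the complete ground truth.
    """
    if not db:
        raise ConfigError("empty taxon database")
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n_taxa = len(db)
    base_weights = 1.0 / np.arange(1, n_taxa + 1)  # rank-abundance profile
    truth = GroundTruth()

    # Planted group effects: soil-effect taxa alternate direction (up in Rs,
    # up in Bs, ...); time-effect taxa act between 1S and 2S.
    soil_idx = list(range(1, min(1 + 2 * config.n_soil_effect_taxa, n_taxa), 2))[
        : config.n_soil_effect_taxa
    ]
    time_idx = [
        i
        for i in range(2, n_taxa, 2)
        if i not in soil_idx
    ][: config.n_time_effect_taxa]
    for rank, i in enumerate(soil_idx):
        fold = config.soil_effect_fold if rank % 2 == 0 else 1.0 / config.soil_effect_fold
        truth.soil_effects[db[i].accession] = fold
    for rank, i in enumerate(time_idx):
        fold = config.time_effect_fold if rank % 2 == 0 else 1.0 / config.time_effect_fold
        truth.time_effects[db[i].accession] = fold

    reads_by_sample: dict[SampleKey, list[SequencingRead]] = {}
    for key in all_sample_keys():
        weights = base_weights.copy()
        for i in soil_idx:
            fold = truth.soil_effects[db[i].accession]
            if key.soil == "Rs":
                weights[i] *= fold
        for i in time_idx:
            fold = truth.time_effects[db[i].accession]
            if key.time == "2S":
                weights[i] *= fold
        target = weights / weights.sum()
        composition = rng.dirichlet(config.dirichlet_concentration * target)
        n_reads = int(
            rng.integers(
                config.reads_per_replicate[0], config.reads_per_replicate[1] + 1
            )
        )
        sample_reads: list[SequencingRead] = []
        sid = key.sample_id
        truth.defect_ids[sid] = {"short": set(), "lowq": set(), "ambiguous": set()}
        truth.true_composition[sid] = {}
        for r in range(n_reads):
            read_id = f"{sid}_r{r + 1:05d}"
            kind_draw = rng.random()
            taxon: str | None
            if kind_draw < config.off_target_fraction:
                taxon = None
                truth.off_target_ids.add(read_id)
                bases = _random_sequence(rng, _draw_length(rng, config))
            elif kind_draw < config.off_target_fraction + config.chimera_fraction:
                taxon = None
                truth.chimera_ids.add(read_id)
                pa, pb = rng.choice(n_taxa, size=2, replace=False)
                length = _draw_length(rng, config)
                breakpoint_ = int(length * rng.uniform(0.3, 0.7))
                left = db[pa].bases[:breakpoint_]
                right = db[pb].bases[breakpoint_:length]
                bases = _mutate(
                    rng, left + right, config.substitution_rate, config.indel_rate
                )
            else:
                i = int(rng.choice(n_taxa, p=composition))
                taxon = db[i].accession
                length = min(_draw_length(rng, config), len(db[i].bases))
                bases = _mutate(
                    rng,
                    db[i].bases[:length],
                    config.substitution_rate,
                    config.indel_rate,
                )
            truth.read_taxon[read_id] = taxon

            defect_draw = rng.random()
            quals = _good_quals(rng, len(bases))
            if defect_draw < config.frac_short:
                cut = int(rng.integers(80, 200))
                bases, quals = bases[:cut], quals[:cut]
                truth.defect_ids[sid]["short"].add(read_id)
            elif defect_draw < config.frac_short + config.frac_lowq:
                quals = _low_quals(rng, len(bases))
                truth.defect_ids[sid]["lowq"].add(read_id)
            elif defect_draw < (
                config.frac_short + config.frac_lowq + config.frac_ambiguous
            ):
                pos = int(rng.integers(len(bases)))
                bases = bases[:pos] + "N" + bases[pos + 1 :]
                truth.defect_ids[sid]["ambiguous"].add(read_id)
            elif taxon is not None:
                comp = truth.true_composition[sid]
                comp[taxon] = comp.get(taxon, 0) + 1
            sample_reads.append(SequencingRead(read_id, bases, quals, sample=key))
        reads_by_sample[key] = sample_reads
    return reads_by_sample, truth


def make_mid_map(seed: int, tag_length: int = 8) -> MidMap:
    """Twenty distinct equal-length MID tags (same length => non-prefix)."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2]))
    tags: list[str] = []
    while len(tags) < 20:
        tag = _random_sequence(rng, tag_length)
        if tag not in tags:
            tags.append(tag)
    return MidMap(dict(zip(tags, all_sample_keys())))


def multiplex(
    reads_by_sample: dict[SampleKey, list[SequencingRead]], mid_map: MidMap
) -> list[SequencingRead]:
    """Prepend each sample's MID tag to its reads (inverse of demultiplexing)."""
    tag_by_key = {key: tag for tag, key in mid_map.items()}
    combined: list[SequencingRead] = []
    for key in sorted(reads_by_sample):
        tag = tag_by_key[key]
        for read in reads_by_sample[key]:
            combined.append(
                SequencingRead(
                    read.read_id,
                    tag + read.bases,
                    [40] * len(tag) + read.quals,
                    sample=None,
                )
            )
    return combined
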