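"""File formats and experimental design.

The pipeline exchanges reads as Sanger-encoded FASTQ (Phred+33) and reference
taxa as FASTA whose headers carry a lineage in the dialect
``accession|family;genus;species|status``.  The survey design is a fixed
2 x 2 x 5 factorial: soil compartment (``Bs`` = bulk soil away from the vines,
``Rs`` = soil associated with grapevine roots), sampling time (``1S`` =
flowering, ``2S`` = early fruit development), and five field replicates.
"""

from __future__ import annotations

import csv
import io as _io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from Bio.SeqIO.FastaIO import SimpleFastaParser
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from .errors import ParseError, ValidationError

PHRED_OFFSET = 33
MAX_PHRED = 62

SOILS = ("Bs", "Rs")
TIMES = ("1S", "2S")
REPLICATES = (1, 2, 3, 4, 5)

#: Per-replicate pyrosequencing depths of the vineyard survey (reads per
#: replicate before normalization), by soil compartment and sampling time.
#: Replicates are listed in order 1..5.
VINEYARD_READ_DEPTHS: dict[tuple[str, str], tuple[int, ...]] = {
    ("Bs", "1S"): (2492, 10949, 6252, 9685, 11600),
    ("Bs", "2S"): (9670, 9730, 11639, 12169, 7145),
    ("Rs", "1S"): (6286, 13603, 9910, 10229, 9641),
    ("Rs", "2S"): (8153, 6405, 6623, 12570, 8816),
}


@dataclass(frozen=True, order=True)
class SampleKey:
    """One cell of the survey design: (soil, time, replicate)."""

    soil: str
    time: str
    replicate: int

    def __post_init__(self) -> None:
        if self.soil not in SOILS:
            raise ValidationError(f"soil must be one of {SOILS}, got {self.soil!r}")
        if self.time not in TIMES:
            raise ValidationError(f"time must be one of {TIMES}, got {self.time!r}")
        if self.replicate not in REPLICATES:
            raise ValidationError(
                f"replicate must be in {REPLICATES}, got {self.replicate!r}"
            )

    @property
    def sample_id(self) -> str:
        return f"{self.soil}{self.time}_{self.replicate}"

    @property
    def group(self) -> str:
        """The (soil, time) cell this replicate belongs to, e.g. ``Bs1S``."""
        return f"{self.soil}{self.time}"

    @classmethod
    def from_sample_id(cls, sample_id: str) -> "SampleKey":
        try:
            cell, rep = sample_id.split("_")
            return cls(soil=cell[:2], time=cell[2:], replicate=int(rep))
        except (ValueError, IndexError) as exc:
            raise ParseError(f"cannot parse sample id {sample_id!r}") from exc


def all_sample_keys() -> list[SampleKey]:
    """The 20 design cells in canonical (soil, time, replicate) order."""
    return [
        SampleKey(s, t, r) for s in SOILS for t in TIMES for r in REPLICATES
    ]


@dataclass
class SequencingRead:
    """A single amplicon read with per-base Phred qualities."""

    read_id: str
    bases: str
    quals: list[int]
    sample: SampleKey | None = None

    def __post_init__(self) -> None:
        if len(self.quals) != len(self.bases):
            raise ValidationError(
                f"read {self.read_id!r}: {len(self.bases)} bases but "
                f"{len(self.quals)} quality values"
            )
        if any(q < 0 for q in self.quals):
            raise ValidationError(f"read {self.read_id!r}: negative Phred score")

    def __len__(self) -> int:
        return len(self.bases)

    def mean_quality(self) -> float:
        return sum(self.quals) / len(self.quals) if self.quals else 0.0


@dataclass(frozen=True)
class TaxonomyLineage:
    """A (possibly partial) lineage: family / genus / species plus a status.

    ``status`` distinguishes reference entries resolved to a described
    species (``known``), environmental sequences (``uncultured``), and
    clusters created by the pipeline itself (``de_novo``).
    """

    family: str = ""
    genus: str = ""
    species: str = ""
    status: str = "known"

    _STATUSES = ("known", "uncultured", "de_novo")

    def __post_init__(self) -> None:
        if self.status not in self._STATUSES:
            raise ValidationError(f"bad lineage status {self.status!r}")
        if self.species and not self.genus:
            raise ValidationError(
                f"species {self.species!r} given without a genus"
            )

    @property
    def label(self) -> str:
        """Human-readable taxon label at the most specific resolved rank."""
        if self.species:
            return self.species
        if self.genus:
            if self.status == "uncultured":
                return f"uncultured {self.genus}"
            return f"{self.genus} sp."
        if self.family:
            if self.status == "uncultured":
                return f"uncultured {self.family}"
            return self.family
        return "uncultured Glomeromycota"

    @property
    def rollup_key(self) -> str:
        """Taxonomic-group bin: most specific non-empty rank, else unresolved."""
        if self.species:
            return self.species
        if self.genus:
            return self.genus
        if self.family:
            return self.family
        return "Glomeromycota (unresolved)"


UNRESOLVED_LINEAGE = TaxonomyLineage(status="uncultured")


@dataclass(frozen=True)
class ReferenceSequence:
    """A database entry: accession, bases, and its lineage annotation."""

    accession: str
    bases: str
    lineage: TaxonomyLineage

    def __post_init__(self) -> None:
        if not self.bases:
            raise ValidationError(f"reference {self.accession!r} has empty bases")

    @property
    def label(self) -> str:
        return self.lineage.label


class MidMap:
    """Multiplex Identifier (MID) tag -> sample mapping.

    Tags must be mutually non-prefix so that prefix matching of a read
    against the tag set is unambiguous.
    """

    def __init__(self, mapping: Mapping[str, SampleKey]):
        tags = sorted(mapping)
        for i, a in enumerate(tags):
            for b in tags[i + 1 :]:
                if b.startswith(a):
                    raise ValidationError(f"MID tag {a!r} is a prefix of {b!r}")
        self._mapping = dict(mapping)

    def __len__(self) -> int:
        return len(self._mapping)

    def items(self):
        return self._mapping.items()

    def match(self, bases: str) -> tuple[str, SampleKey] | None:
        """Return the unique (tag, sample) whose tag prefixes ``bases``."""
        for tag, key in self._mapping.items():
            if bases.startswith(tag):
                return tag, key
        return None


# ---------------------------------------------------------------------------
# FASTQ
# ---------------------------------------------------------------------------

def read_fastq(path: str | Path) -> list[SequencingRead]:
    """Parse a Sanger-encoded (Phred+33) FASTQ file.

    Raises :class:`ParseError` naming the 1-based record index on a
    bases/quality length mismatch, and on quality characters below ``'!'``.
    """
    reads: list[SequencingRead] = []
    with open(path) as handle:
        iterator = FastqGeneralIterator(handle)
        index = 0
        while True:
            index += 1
            try:
                title, seq, qual = next(iterator)
            except StopIteration:
                break
            except ValueError as exc:
                raise ParseError(f"malformed FASTQ record {index}: {exc}") from exc
            quals = []
            for ch in qual:
                q = ord(ch) - PHRED_OFFSET
                if q < 0:
                    raise ParseError(
                        f"FASTQ record {index} ({title.split()[0]!r}): quality "
                        f"character {ch!r} below '!' is not Sanger-encoded"
                    )
                quals.append(q)
            read_id = title.split()[0] if title else f"record{index}"
            try:
                reads.append(SequencingRead(read_id, seq, quals))
            except ValidationError as exc:
                raise ParseError(f"malformed FASTQ record {index}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[SequencingRead], path: str | Path) -> None:
    with open(path, "w") as handle:
        for read in reads:
            qual = "".join(
                chr(min(q, MAX_PHRED) + PHRED_OFFSET) for q in read.quals
            )
            handle.write(f"@{read.read_id}\n{read.bases}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# Demultiplexing
# ---------------------------------------------------------------------------

def demultiplex(
    reads: Iterable[SequencingRead], mid_map: MidMap
) -> tuple[dict[SampleKey, list[SequencingRead]], list[SequencingRead]]:
    """Partition reads by exact-prefix MID tag match and strip the tag.

    Returns (per-sample reads with tag removed from bases and qualities,
    reads matching no tag).  Every input read appears in exactly one output.
    """
    by_sample: dict[SampleKey, list[SequencingRead]] = {
        key: [] for _, key in mid_map.items()
    }
    unmatched: list[SequencingRead] = []
    for read in reads:
        hit = mid_map.match(read.bases)
        if hit is None:
            unmatched.append(read)
            continue
        tag, key = hit
        stripped = SequencingRead(
            read.read_id,
            read.bases[len(tag) :],
            read.quals[len(tag) :],
            sample=key,
        )
        by_sample[key].append(stripped)
    return by_sample, unmatched


# ---------------------------------------------------------------------------
# Reference FASTA
# ---------------------------------------------------------------------------

def _parse_reference_header(header: str, line_no: int) -> tuple[str, TaxonomyLineage]:
    parts = header.strip().split("|")
    if len(parts) != 3:
        raise ParseError(
            f"line {line_no}: reference header {header!r} is not "
            "'accession|family;genus;species|status'"
        )
    accession, lineage_str, status = (p.strip() for p in parts)
    ranks = lineage_str.split(";")
    if len(ranks) != 3 or not accession:
        raise ParseError(
            f"line {line_no}: reference header {header!r} is not "
            "'accession|family;genus;species|status'"
        )
    family, genus, species = (r.strip() for r in ranks)
    try:
        lineage = TaxonomyLineage(family, genus, species, status)
    except ValidationError as exc:
        raise ParseError(f"line {line_no}: {exc}") from exc
    return accession, lineage


def read_reference_fasta(path: str | Path) -> list[ReferenceSequence]:
    """Parse a lineage-annotated reference FASTA.

    Header dialect: ``>accession|family;genus;species|status``.  Duplicate
    accessions and unparseable headers are rejected.
    """
    text = Path(path).read_text()
    header_lines = [
        i + 1 for i, line in enumerate(text.splitlines()) if line.startswith(">")
    ]
    refs: list[ReferenceSequence] = []
    seen: set[str] = set()
    for k, (title, seq) in enumerate(SimpleFastaParser(_io.StringIO(text))):
        line_no = header_lines[k]
        accession, lineage = _parse_reference_header(title, line_no)
        if accession in seen:
            raise ParseError(
                f"line {line_no}: duplicate accession {accession!r}"
            )
        seen.add(accession)
        try:
            refs.append(ReferenceSequence(accession, seq.upper(), lineage))
        except ValidationError as exc:
            raise ParseError(f"line {line_no}: {exc}") from exc
    return refs


def write_reference_fasta(
    refs: Iterable[ReferenceSequence], path: str | Path
) -> None:
    with open(path, "w") as handle:
        for ref in refs:
            lin = ref.lineage
            handle.write(
                f">{ref.accession}|{lin.family};{lin.genus};{lin.species}|"
                f"{lin.status}\n{ref.bases}\n"
            )


# ---------------------------------------------------------------------------
# Design and MID tables
# ---------------------------------------------------------------------------

def read_design(path: str | Path) -> list[SampleKey]:
    """Read a design TSV with columns sample_id, soil, time, replicate."""
    keys: list[SampleKey] = []
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        required = {"sample_id", "soil", "time", "replicate"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ParseError(f"design table must have columns {sorted(required)}")
        for row in reader:
            key = SampleKey(row["soil"], row["time"], int(row["replicate"]))
            if key.sample_id != row["sample_id"]:
                raise ParseError(
                    f"sample_id {row['sample_id']!r} does not match "
                    f"soil/time/replicate {key.sample_id!r}"
                )
            keys.append(key)
    return keys


def write_design(keys: Iterable[SampleKey], path: str | Path) -> None:
    with open(path, "w") as handle:
        handle.write("sample_id\tsoil\ttime\treplicate\n")
        for key in keys:
            handle.write(
                f"{key.sample_id}\t{key.soil}\t{key.time}\t{key.replicate}\n"
            )


def read_mid_map(path: str | Path) -> MidMap:
    """Read a MID map TSV with columns tag, sample_id."""
    mapping: dict[str, SampleKey] = {}
    with open(path) as handle:
        reader = csv.DictReader(handle, delimiter="\t")
        if reader.fieldnames is None or not {"tag", "sample_id"} <= set(
            reader.fieldnames
        ):
            raise ParseError("MID map must have columns tag, sample_id")
        for row in reader:
            tag = row["tag"].strip().upper()
            if tag in mapping:
                raise ParseError(f"duplicate MID tag {tag!r}")
            mapping[tag] = SampleKey.from_sample_id(row["sample_id"])
    return MidMap(mapping)
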