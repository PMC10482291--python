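"""On-disk formats and core domain records.

Everything the toolkit reads or writes lives here: the reference barcode
FASTA (pipe-delimited taxonomy headers), sample reads as FASTA/FASTQ
(Phred+33), and the tab-separated metadata, phenology and results tables.

Reference FASTA header dialect::

    >refID|Genus_species|Common name|Order|Family|Group|region

with ``Group`` one of Terrestrial/Songbird/Waterbird and ``region`` one of
amplicon1/amplicon2/full.  The dialect is pipe-delimited with a fixed field
order so databases stay greppable and diff-friendly.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "ParseError",
    "EcoGroup",
    "RegionLabel",
    "PrimerSet",
    "Direction",
    "Technology",
    "SampleType",
    "PhenologyStatus",
    "BarcodeReference",
    "SampleRead",
    "SampleMetadata",
    "PhenologyWindow",
    "PhenologyTable",
    "day_of_year",
    "read_reference_fasta",
    "write_reference_fasta",
    "read_sample_reads",
    "write_sample_reads",
    "read_metadata_tsv",
    "write_metadata_tsv",
    "read_phenology_tsv",
    "write_phenology_tsv",
    "write_results_table",
    "read_results_table",
]

REFERENCE_ALPHABET = frozenset("ACGTN")
MAX_PHRED = 93


class ParseError(ValueError):
    """A record violated the format contract (never silently coerced)."""


class EcoGroup(str, enum.Enum):
    TERRESTRIAL = "Terrestrial"
    SONGBIRD = "Songbird"
    WATERBIRD = "Waterbird"


class RegionLabel(str, enum.Enum):
    AMPLICON1 = "amplicon1"
    AMPLICON2 = "amplicon2"
    FULL = "full"


class PrimerSet(str, enum.Enum):
    SET1 = "set1"
    SET2 = "set2"
    UNKNOWN = "unknown"


class Direction(str, enum.Enum):
    FORWARD = "forward"
    REVERSE = "reverse"
    MERGED = "merged"


class Technology(str, enum.Enum):
    PV = "PV"    # photovoltaic
    CST = "CST"  # concentrated solar parabolic trough
    PT = "PT"    # concentrated solar power tower


class SampleType(str, enum.Enum):
    INTACT = "intact"
    PARTIAL = "partial"
    FEATHER_SPOT = "feather_spot"


class PhenologyStatus(str, enum.Enum):
    CONSISTENT = "consistent"
    UNLIKELY = "unlikely"
    INCONSISTENT = "inconsistent"
    UNKNOWN = "unknown"


UNKNOWN_MORPHOLOGY = "unknown"


@dataclass(frozen=True)
class BarcodeReference:
    """One reference barcode with full taxonomy and ecological group."""

    ref_id: str
    species: str
    common_name: str
    order_name: str
    family_name: str
    eco_group: EcoGroup
    region_label: RegionLabel
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ParseError(f"reference {self.ref_id!r}: empty sequence")
        bad = set(self.sequence) - REFERENCE_ALPHABET
        if bad:
            raise ParseError(
                f"reference {self.ref_id!r}: invalid bases {sorted(bad)!r} "
                "(alphabet is A/C/G/T/N)"
            )


@dataclass(frozen=True)
class SampleRead:
    """A quality-annotated sequence from one field sample.

    ``qualities`` is ``None`` for FASTA input (no quality information).
    """

    sample_id: str
    read_id: str
    sequence: str
    qualities: Optional[tuple[int, ...]] = None
    primer_set: PrimerSet = PrimerSet.UNKNOWN
    direction: Direction = Direction.MERGED

    def __post_init__(self) -> None:
        if self.qualities is not None:
            if len(self.qualities) != len(self.sequence):
                raise ParseError(
                    f"read {self.read_id!r}: {len(self.qualities)} quality "
                    f"values for {len(self.sequence)} bases"
                )
            if any(q < 0 or q > MAX_PHRED for q in self.qualities):
                raise ParseError(
                    f"read {self.read_id!r}: quality outside [0, {MAX_PHRED}]"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, start: int, stop: int) -> "SampleRead":
        quals = None if self.qualities is None else self.qualities[start:stop]
        return replace(self, sequence=self.sequence[start:stop], qualities=quals)


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    collection_date: _dt.date
    site_id: str
    technology: Technology
    sample_type: SampleType
    morphological_id: str = UNKNOWN_MORPHOLOGY
    site_region: str = "default"
    latitude: Optional[float] = None
    longitude: Optional[float] = None


@dataclass(frozen=True)
class PhenologyWindow:
    """Seasonal occurrence window for one species in one site region.

    Windows are in day-of-year units and may wrap the year boundary
    (``start > end`` is read modularly, e.g. [300, 60] covers Oct-Feb).
    """

    species: str
    site_region: str
    start_day: int
    end_day: int
    status: str  # "expected" or "marginal"

    def __post_init__(self) -> None:
        for d in (self.start_day, self.end_day):
            if not 1 <= d <= 366:
                raise ParseError(
                    f"phenology window for {self.species!r}: day {d} outside [1, 366]"
                )
        if self.status not in ("expected", "marginal"):
            raise ParseError(
                f"phenology window for {self.species!r}: status {self.status!r}"
            )

    def contains(self, day: int) -> bool:
        if self.start_day <= self.end_day:
            return self.start_day <= day <= self.end_day
        return day >= self.start_day or day <= self.end_day


@dataclass
class PhenologyTable:
    windows: list[PhenologyWindow] = field(default_factory=list)

    def rows_for(self, species: str, site_region: str) -> list[PhenologyWindow]:
        return [
            w
            for w in self.windows
            if w.species == species and w.site_region == site_region
        ]

    def species(self) -> set[str]:
        return {w.species for w in self.windows}


_DAYS_BEFORE_MONTH = (0, 0, 31, 59, 90, 120, 151, 181, 212, 243, 273, 304, 334)


def day_of_year(date: _dt.date) -> int:
    """Day of year on a fixed non-leap calendar (Feb 29 maps to day 60).

    Using a single calendar for every year keeps phenology windows
    comparable across leap and non-leap years.
    """
    if date.month == 2 and date.day == 29:
        return 60
    return _DAYS_BEFORE_MONTH[date.month] + date.day


# ---------------------------------------------------------------------------
# Reference FASTA


def _reference_from_header(header: str, sequence: str) -> BarcodeReference:
    fields = header.split("|")
    if len(fields) != 7:
        raise ParseError(
            f"reference header {header!r}: expected 7 pipe-delimited fields, "
            f"got {len(fields)}"
        )
    ref_id, species, common, order, family, group, region = fields
    try:
        eco = EcoGroup(group)
    except ValueError:
        raise ParseError(f"reference {ref_id!r}: unknown group {group!r}") from None
    try:
        reg = RegionLabel(region)
    except ValueError:
        raise ParseError(f"reference {ref_id!r}: unknown region {region!r}") from None
    return BarcodeReference(
        ref_id=ref_id,
        species=species,
        common_name=common,
        order_name=order,
        family_name=family,
        eco_group=eco,
        region_label=reg,
        sequence=sequence.upper().replace("U", "T"),
    )


def read_reference_fasta(path: str | Path) -> list[BarcodeReference]:
    refs: list[BarcodeReference] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        ref = _reference_from_header(record.description, str(record.seq))
        if ref.ref_id in seen:
            raise ParseError(f"duplicate ref_id {ref.ref_id!r} in {path}")
        seen.add(ref.ref_id)
        refs.append(ref)
    return refs


def write_reference_fasta(refs: Iterable[BarcodeReference], path: str | Path) -> None:
    records = []
    for r in refs:
        header = "|".join(
            [
                r.ref_id,
                r.species,
                r.common_name,
                r.order_name,
                r.family_name,
                r.eco_group.value,
                r.region_label.value,
            ]
        )
        records.append(SeqRecord(Seq(r.sequence), id=header, description=""))
    SeqIO.write(records, str(path), "fasta")


# ---------------------------------------------------------------------------
# Sample reads
#
# Read id dialect: "sample_id|primer_set|direction".  Plain ids (no pipes)
# are accepted: the whole id becomes the sample id, primer set unknown.


def _read_from_record(record, qualities: Optional[Sequence[int]]) -> SampleRead:
    parts = record.id.split("|")
    if len(parts) == 3:
        sample_id, pset_s, direction_s = parts
        try:
            pset = PrimerSet(pset_s)
            direction = Direction(direction_s)
        except ValueError as exc:
            raise ParseError(f"read {record.id!r}: {exc}") from None
    else:
        sample_id, pset, direction = record.id, PrimerSet.UNKNOWN, Direction.MERGED
    return SampleRead(
        sample_id=sample_id,
        read_id=record.id,
        sequence=str(record.seq).upper().replace("U", "T"),
        qualities=None if qualities is None else tuple(int(q) for q in qualities),
        primer_set=pset,
        direction=direction,
    )


def read_sample_reads(path: str | Path, fmt: str = "fastq") -> list[SampleRead]:
    fmt = fmt.lower()
    if fmt not in ("fasta", "fastq"):
        raise ValueError(f"format must be 'fasta' or 'fastq', got {fmt!r}")
    reads: list[SampleRead] = []
    try:
        for record in SeqIO.parse(str(path), fmt):
            quals = (
                record.letter_annotations.get("phred_quality")
                if fmt == "fastq"
                else None
            )
            reads.append(_read_from_record(record, quals))
    except ValueError as exc:  # Biopython raises on seq/quality length mismatch
        raise ParseError(f"{path}: {exc}") from exc
    return reads


def write_sample_reads(
    reads: Iterable[SampleRead], path: str | Path, fmt: str = "fastq"
) -> None:
    fmt = fmt.lower()
    records = []
    for r in reads:
        rid = (
            r.read_id
            if "|" in r.read_id
            else "|".join([r.sample_id, r.primer_set.value, r.direction.value])
        )
        rec = SeqRecord(Seq(r.sequence), id=rid, description="")
        if fmt == "fastq":
            if r.qualities is None:
                raise ValueError(f"read {r.read_id!r} has no qualities; use FASTA")
            rec.letter_annotations["phred_quality"] = list(r.qualities)
        records.append(rec)
    SeqIO.write(records, str(path), fmt)


# ---------------------------------------------------------------------------
# Metadata TSV

_METADATA_COLUMNS = [
    "sample_id",
    "collection_date",
    "site_id",
    "site_region",
    "technology",
    "sample_type",
    "morphological_id",
    "latitude",
    "longitude",
]


def read_metadata_tsv(path: str | Path) -> list[SampleMetadata]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_METADATA_COLUMNS[:7]) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing metadata columns {sorted(missing)}")
    rows = []
    for rec in df.to_dict("records"):
        try:
            date = _dt.date.fromisoformat(rec["collection_date"])
            tech = Technology(rec["technology"])
            stype = SampleType(rec["sample_type"])
        except ValueError as exc:
            raise ParseError(f"metadata row {rec['sample_id']!r}: {exc}") from None
        lat = rec.get("latitude", "")
        lon = rec.get("longitude", "")
        rows.append(
            SampleMetadata(
                sample_id=rec["sample_id"],
                collection_date=date,
                site_id=rec["site_id"],
                site_region=rec.get("site_region") or "default",
                technology=tech,
                sample_type=stype,
                morphological_id=rec["morphological_id"] or UNKNOWN_MORPHOLOGY,
                latitude=float(lat) if lat else None,
                longitude=float(lon) if lon else None,
            )
        )
    return rows


def write_metadata_tsv(rows: Iterable[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "sample_id": m.sample_id,
                "collection_date": m.collection_date.isoformat(),
                "site_id": m.site_id,
                "site_region": m.site_region,
                "technology": m.technology.value,
                "sample_type": m.sample_type.value,
                "morphological_id": m.morphological_id,
                "latitude": "" if m.latitude is None else repr(m.latitude),
                "longitude": "" if m.longitude is None else repr(m.longitude),
            }
            for m in rows
        ],
        columns=_METADATA_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Phenology TSV

_PHENOLOGY_COLUMNS = ["species", "site_region", "start_day", "end_day", "status"]


def read_phenology_tsv(path: str | Path) -> PhenologyTable:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(_PHENOLOGY_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing phenology columns {sorted(missing)}")
    windows = [
        PhenologyWindow(
            species=rec["species"],
            site_region=rec["site_region"],
            start_day=int(rec["start_day"]),
            end_day=int(rec["end_day"]),
            status=rec["status"],
        )
        for rec in df.to_dict("records")
    ]
    return PhenologyTable(windows)


def write_phenology_tsv(table: PhenologyTable, path: str | Path) -> None:
    df = pd.DataFrame(
        [
            {
                "species": w.species,
                "site_region": w.site_region,
                "start_day": w.start_day,
                "end_day": w.end_day,
                "status": w.status,
            }
            for w in table.windows
        ],
        columns=_PHENOLOGY_COLUMNS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Results TSV (BLAST-like column names pident/qcovs for familiarity)

_RESULTS_COLUMNS = [
    "sample_id",
    "category",
    "candidates",
    "pident",
    "qcovs",
    "hq_percent",
    "phenology",
    "primer_set",
]


def write_results_table(results: Iterable, path: str | Path) -> None:
    """Write IdentificationResult records as a TSV, one row per sample.

    Sister-taxon ties are written as a single semicolon-joined candidates
    cell so both co-reported species stay attached to one sample.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "sample_id": r.sample_id,
                "category": r.category.value,
                "candidates": ";".join(r.candidates),
                "pident": "" if r.identity_percent is None else f"{r.identity_percent:.2f}",
                "qcovs": "" if r.coverage_percent is None else f"{r.coverage_percent:.2f}",
                "hq_percent": "" if r.hq_percent is None else f"{r.hq_percent:.2f}",
                "phenology": r.phenology.value,
                "primer_set": r.primer_set_used,
            }
        )
    pd.DataFrame(rows, columns=_RESULTS_COLUMNS).to_csv(path, sep="\t", index=False)


def read_results_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
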