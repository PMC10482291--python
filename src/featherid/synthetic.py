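"""Synthetic reference databases and degraded survey reads with ground truth.

The generator emulates the study system end to end so every downstream
stage is testable without any downloads: CO1-like reference templates
carrying both degenerate-primer cassettes (a 512 bp and an adjacent 596 bp
amplicon), interspecies divergence from a common ancestor, occasional
sister pairs with byte-identical barcodes, field degradation
(substitutions, end truncation, decaying quality), per-sample PCR failure
for primer set 1, and same-individual duplicate feather spots.

Every emitted read has exactly one truth-ledger row, and all output is
deterministic under the config seed: each operation draws from its own RNG
stream derived from the master seed by a stable label, so results do not
depend on call order.
"""

from __future__ import annotations

import datetime as _dt
import logging
import math
import zlib
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .amplicon import PRIMER_PAIRS, PRIMERS, DegeneratePrimer, IUPAC_EXPANSION, in_silico_pcr, reverse_complement
from .formats_io import (
    BarcodeReference,
    Direction,
    EcoGroup,
    PhenologyTable,
    PhenologyWindow,
    PrimerSet,
    RegionLabel,
    SampleMetadata,
    SampleRead,
    SampleType,
    Technology,
    write_metadata_tsv,
    write_phenology_tsv,
    write_sample_reads,
)

__all__ = [
    "SimulationConfig",
    "SpeciesTruth",
    "ReferenceTruth",
    "TruthRow",
    "TruthLedger",
    "Survey",
    "DegradationSummary",
    "generate_reference_db",
    "degrade_read",
    "simulate_survey",
    "write_survey",
]

logger = logging.getLogger("featherid")

BASES = "ACGT"
_SITE_REGION = "desert_sw"
# eight facilities: five photovoltaic, two parabolic trough, one power tower
SITES: tuple[tuple[str, Technology], ...] = (
    ("SITE1", Technology.PV),
    ("SITE2", Technology.PV),
    ("SITE3", Technology.PV),
    ("SITE4", Technology.PV),
    ("SITE5", Technology.PV),
    ("SITE6", Technology.CST),
    ("SITE7", Technology.CST),
    ("SITE8", Technology.PT),
)

_GROUP_TAXA = {
    EcoGroup.SONGBIRD: (
        ("Passeriformes", "Passerellidae"),
        ("Passeriformes", "Turdidae"),
        ("Passeriformes", "Icteridae"),
    ),
    EcoGroup.WATERBIRD: (
        ("Anseriformes", "Anatidae"),
        ("Charadriiformes", "Laridae"),
        ("Podicipediformes", "Podicipedidae"),
        ("Pelecaniformes", "Ardeidae"),
    ),
    EcoGroup.TERRESTRIAL: (
        ("Galliformes", "Odontophoridae"),
        ("Apodiformes", "Trochilidae"),
        ("Accipitriformes", "Accipitridae"),
        ("Columbiformes", "Columbidae"),
        ("Strigiformes", "Strigidae"),
        ("Falconiformes", "Falconidae"),
    ),
}

_GROUP_GENUS = {
    EcoGroup.SONGBIRD: "Cantavis",
    EcoGroup.WATERBIRD: "Aquavis",
    EcoGroup.TERRESTRIAL: "Terravis",
}


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic survey.

    ``composition`` mirrors the genetic group proportions of the study
    system (Songbird 0.7 / Waterbird 0.2 / Terrestrial 0.1); amplicon
    lengths are the two primer-set target regions.
    """

    n_species: int = 20
    sister_pair_fraction: float = 0.1
    divergence: float = 0.08
    amplicon1_len: int = 512
    amplicon2_len: int = 596
    n_samples: int = 300
    substitution_rate: float = 0.01
    truncation_rate: float = 0.2
    max_truncation_fraction: float = 0.2
    quality_decay: float = 0.05
    duplicate_rate: float = 0.05
    pcr_failure_rate: float = 0.1
    out_of_window_fraction: float = 0.0
    morph_id_fraction: float = 0.5
    composition: tuple[tuple[EcoGroup, float], ...] = (
        (EcoGroup.SONGBIRD, 0.7),
        (EcoGroup.WATERBIRD, 0.2),
        (EcoGroup.TERRESTRIAL, 0.1),
    )
    flank_len: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "sister_pair_fraction",
            "divergence",
            "substitution_rate",
            "truncation_rate",
            "max_truncation_fraction",
            "duplicate_rate",
            "pcr_failure_rate",
            "out_of_window_fraction",
            "morph_id_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2")


def _rng(seed: int, label: str) -> np.random.Generator:
    """One RNG stream per operation, derived from the seed by a stable label."""
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(zlib.crc32(label.encode()),))
    )


@dataclass
class SpeciesTruth:
    species: str
    common_name: str
    order_name: str
    family_name: str
    eco_group: EcoGroup
    template: str
    amp1_span: tuple[int, int]
    amp2_span: tuple[int, int]
    sister_partner: Optional[str] = None

    def amplicon(self, primer_set: PrimerSet) -> str:
        a, b = self.amp1_span if primer_set == PrimerSet.SET1 else self.amp2_span
        return self.template[a:b]


@dataclass
class ReferenceTruth:
    species: list[SpeciesTruth]
    config: SimulationConfig

    def by_name(self) -> dict[str, SpeciesTruth]:
        return {s.species: s for s in self.species}


@dataclass(frozen=True)
class DegradationSummary:
    n_substitutions: int
    n_truncated: int
    truncated_end: Optional[str]  # "5p", "3p" or None


@dataclass(frozen=True)
class TruthRow:
    sample_id: str
    species: str
    individual_id: str
    eco_group: EcoGroup
    primer_set: PrimerSet
    site_id: str
    collection_date: _dt.date
    n_substitutions: int
    n_truncated: int
    duplicate_of: Optional[str]
    is_sister: bool
    out_of_window: bool


@dataclass
class TruthLedger:
    rows: list[TruthRow] = field(default_factory=list)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {
                    "sample_id": r.sample_id,
                    "species": r.species,
                    "individual_id": r.individual_id,
                    "eco_group": r.eco_group.value,
                    "primer_set": r.primer_set.value,
                    "site_id": r.site_id,
                    "collection_date": r.collection_date.isoformat(),
                    "n_substitutions": r.n_substitutions,
                    "n_truncated": r.n_truncated,
                    "duplicate_of": r.duplicate_of or "",
                    "is_sister": r.is_sister,
                    "out_of_window": r.out_of_window,
                }
                for r in self.rows
            ]
        )


@dataclass
class Survey:
    reads: list[SampleRead]
    metadata: list[SampleMetadata]
    phenology: PhenologyTable
    ledger: TruthLedger


# ---------------------------------------------------------------------------
# Reference database


def _expand_primer(primer: DegeneratePrimer, rng: np.random.Generator) -> str:
    """One concrete expansion of a degenerate primer."""
    return "".join(
        sorted(IUPAC_EXPANSION[c])[rng.integers(len(IUPAC_EXPANSION[c]))]
        for c in primer.iupac_sequence
    )


def _per_species_rate(divergence: float) -> float:
    """Per-species substitution rate giving the requested expected pairwise
    divergence when two lineages mutate independently from one ancestor.

    Sites differ with probability 2r(1-r) + (2/3)r^2; solve for r.
    """
    if divergence == 0:
        return 0.0
    # (4/3) r^2 - 2 r + d = 0, smaller root
    return (2 - math.sqrt(4 - (16.0 / 3.0) * divergence)) / (8.0 / 3.0)


def _allocate_groups(config: SimulationConfig) -> list[EcoGroup]:
    """Largest-remainder allocation of species to ecological groups."""
    weights = dict(config.composition)
    n = config.n_species
    raw = {g: n * w for g, w in weights.items() if w > 0}
    counts = {g: int(math.floor(v)) for g, v in raw.items()}
    # every represented group gets at least one species when room allows
    for g in counts:
        if counts[g] == 0 and n >= len(counts):
            counts[g] = 1
    while sum(counts.values()) < n:
        g = max(raw, key=lambda g: raw[g] - counts[g])
        counts[g] += 1
    while sum(counts.values()) > n:
        g = max(counts, key=lambda g: counts[g] - raw[g])
        counts[g] -= 1
    groups: list[EcoGroup] = []
    for g, c in counts.items():
        groups.extend([g] * c)
    return groups


def generate_reference_db(
    config: SimulationConfig,
) -> tuple[list[BarcodeReference], ReferenceTruth]:
    """Build a species reference database with known amplicon structure.

    Each species template is, in order: 5' flank, primer-set-1 amplicon
    (L7036 cassette / filler / reverse-complemented H7548 cassette), the
    adjacent primer-set-2 amplicon (L7525 / filler / reverse-complemented
    H8121), 3' flank.  Sister pairs share byte-identical amplicon regions
    only; non-sister amplicons are checked for accidental identity and the
    offending species redrawn (bounded retries).
    """
    rng = _rng(config.seed, "refdb")
    fwd1, rev1 = PRIMER_PAIRS[PrimerSet.SET1]
    fwd2, rev2 = PRIMER_PAIRS[PrimerSet.SET2]
    inner1 = config.amplicon1_len - len(fwd1) - len(rev1)
    inner2 = config.amplicon2_len - len(fwd2) - len(rev2)
    if inner1 < 0 or inner2 < 0:
        raise ValueError("amplicon lengths shorter than the primer cassettes")

    cass_f1 = _expand_primer(fwd1, rng)
    cass_r1 = reverse_complement(_expand_primer(rev1, rng))
    cass_f2 = _expand_primer(fwd2, rng)
    cass_r2 = reverse_complement(_expand_primer(rev2, rng))

    def rand_bases(k: int) -> str:
        return "".join(BASES[i] for i in rng.integers(0, 4, size=k))

    flank5 = rand_bases(config.flank_len)
    flank3 = rand_bases(config.flank_len)
    ancestor = (
        flank5 + cass_f1 + rand_bases(inner1) + cass_r1
        + cass_f2 + rand_bases(inner2) + cass_r2 + flank3
    )
    amp1_span = (config.flank_len, config.flank_len + config.amplicon1_len)
    amp2_span = (amp1_span[1], amp1_span[1] + config.amplicon2_len)

    # positions free to mutate: flanks and the two inner fillers
    mutable = np.zeros(len(ancestor), dtype=bool)
    mutable[: config.flank_len] = True
    mutable[amp1_span[0] + len(fwd1) : amp1_span[1] - len(rev1)] = True
    mutable[amp2_span[0] + len(fwd2) : amp2_span[1] - len(rev2)] = True
    mutable[amp2_span[1] :] = True
    mutable_idx = np.nonzero(mutable)[0]

    rate = _per_species_rate(config.divergence)
    groups = _allocate_groups(config)
    n_sister_pairs = int(round(config.sister_pair_fraction * config.n_species)) // 2

    ancestor_arr = np.frombuffer(ancestor.encode(), dtype="S1").copy()

    def mutate() -> str:
        arr = ancestor_arr.copy()
        hit = mutable_idx[rng.random(mutable_idx.size) < rate]
        for pos in hit:
            cur = arr[pos].decode()
            alts = [b for b in BASES if b != cur]
            arr[pos] = alts[rng.integers(3)].encode()
        return arr.tobytes().decode()

    def check_template(template: str) -> bool:
        for pset, want in ((PrimerSet.SET1, config.amplicon1_len), (PrimerSet.SET2, config.amplicon2_len)):
            prods = in_silico_pcr(template, PRIMER_PAIRS[pset], max_mismatch=0)
            if len(prods) != 1 or len(prods[0]) != want:
                return False
        return True

    species_list: list[SpeciesTruth] = []
    seen_barcodes: dict[str, str] = {}  # amplicon-region sequence -> species
    # sister pairing: consecutive species, preferring same-group neighbours;
    # a cross-group partner adopts its mate's group (sisters are congeners)
    sister_of: dict[int, int] = {}
    paired = 0
    i = 0
    while paired < n_sister_pairs and i + 1 < len(groups):
        if groups[i] == groups[i + 1]:
            sister_of[i + 1] = i
            sister_of[i] = i + 1
            paired += 1
            i += 2
        else:
            i += 1
    i = 0
    while paired < n_sister_pairs and i + 1 < len(groups):
        if i not in sister_of and (i + 1) not in sister_of:
            groups[i + 1] = groups[i]
            sister_of[i + 1] = i
            sister_of[i] = i + 1
            paired += 1
            i += 2
        else:
            i += 1

    for idx, group in enumerate(groups):
        genus = _GROUP_GENUS[group]
        order_name, family_name = _GROUP_TAXA[group][idx % len(_GROUP_TAXA[group])]
        name = f"{genus}_sp{idx + 1:03d}"
        mate = sister_of.get(idx)
        if mate is not None and mate < idx:
            # partner already built: share the amplicon region byte for byte
            partner = species_list[mate]
            a, b = amp1_span[0], amp2_span[1]
            template = mutate()
            template = template[:a] + partner.template[a:b] + template[b:]
            # sisters share a genus-level name stem
            name = f"{genus}_sp{mate + 1:03d}b"
            species_list.append(
                SpeciesTruth(
                    name, f"Synthetic bird {idx + 1}", order_name, family_name,
                    group, template, amp1_span, amp2_span, sister_partner=partner.species,
                )
            )
            partner.sister_partner = name
            continue
        for attempt in range(25):
            template = mutate()
            barcode = template[amp1_span[0] : amp2_span[1]]
            if barcode in seen_barcodes:
                logger.warning(
                    "species %s collided with %s (attempt %d); redrawing",
                    name, seen_barcodes[barcode], attempt + 1,
                )
                continue
            if not check_template(template):
                logger.warning("species %s produced spurious priming; redrawing", name)
                continue
            break
        else:
            raise RuntimeError(
                "could not generate a distinct template; divergence too low"
            )
        seen_barcodes[barcode] = name
        species_list.append(
            SpeciesTruth(
                name, f"Synthetic bird {idx + 1}", order_name, family_name,
                group, template, amp1_span, amp2_span,
            )
        )

    refs = [
        BarcodeReference(
            ref_id=f"ref{i + 1:03d}",
            species=s.species,
            common_name=s.common_name,
            order_name=s.order_name,
            family_name=s.family_name,
            eco_group=s.eco_group,
            region_label=RegionLabel.FULL,
            sequence=s.template,
        )
        for i, s in enumerate(species_list)
    ]
    return refs, ReferenceTruth(species_list, config)


# ---------------------------------------------------------------------------
# Degradation


def degrade_read(
    sequence: str,
    config: SimulationConfig,
    rng: np.random.Generator,
    qualities: Optional[Sequence[int]] = None,
    sample_id: str = "sample",
    read_id: str = "read",
    primer_set: PrimerSet = PrimerSet.UNKNOWN,
) -> tuple[SampleRead, DegradationSummary]:
    """Apply field degradation to a pristine amplicon sequence.

    i.i.d. substitutions at ``substitution_rate``; with probability
    ``truncation_rate`` a uniform fraction up to ``max_truncation_fraction``
    is removed from one end; qualities decline from Q40 at
    ``quality_decay`` per base (plus noise) unless provided.
    """
    if not sequence:
        raise ValueError("cannot degrade an empty sequence")
    arr = list(sequence)
    hit = np.nonzero(rng.random(len(arr)) < config.substitution_rate)[0]
    for pos in hit:
        alts = [b for b in BASES if b != arr[pos]]
        arr[pos] = alts[rng.integers(3)]
    n_subs = int(hit.size)

    n_trunc = 0
    trunc_end: Optional[str] = None
    if config.truncation_rate > 0 and rng.random() < config.truncation_rate:
        frac = rng.uniform(0.0, config.max_truncation_fraction)
        n_trunc = int(frac * len(arr))
        if n_trunc > 0:
            if rng.random() < 0.5:
                arr = arr[n_trunc:]
                trunc_end = "5p"
            else:
                arr = arr[: len(arr) - n_trunc]
                trunc_end = "3p"

    n = len(arr)
    if qualities is not None:
        quals = tuple(int(q) for q in qualities[:n])
    else:
        noise = rng.normal(0.0, 2.0, size=n)
        q = 40.0 - config.quality_decay * np.arange(n) + noise
        quals = tuple(int(v) for v in np.clip(np.rint(q), 2, 40))
    read = SampleRead(
        sample_id=sample_id,
        read_id=read_id,
        sequence="".join(arr),
        qualities=quals,
        primer_set=primer_set,
        direction=Direction.MERGED,
    )
    return read, DegradationSummary(n_subs, n_trunc, trunc_end)


# ---------------------------------------------------------------------------
# Survey simulation


def simulate_survey(truth: ReferenceTruth, config: SimulationConfig) -> Survey:
    """Draw a field survey from the reference database.

    Species are sampled by the configured group composition; PCR failure
    switches a sample to the primer-set-2 amplicon; duplicate feather spots
    re-emit an already-sampled individual's read byte-identically at the
    same site on the same or next day.
    """
    comp = dict(config.composition)
    if abs(sum(comp.values()) - 1.0) > 1e-9:
        raise ValueError(f"composition sums to {sum(comp.values())}, not 1")
    if not truth.species:
        raise ValueError("reference database is empty")
    rng = _rng(config.seed, "survey")
    drng = _rng(config.seed, "degrade")

    by_group: dict[EcoGroup, list[SpeciesTruth]] = {}
    for s in truth.species:
        by_group.setdefault(s.eco_group, []).append(s)
    groups = [g for g in comp if comp[g] > 0 and by_group.get(g)]
    probs = np.array([comp[g] for g in groups])
    probs = probs / probs.sum()

    reads: list[SampleRead] = []
    metadata: list[SampleMetadata] = []
    rows: list[TruthRow] = []
    base_samples: list[tuple[str, SpeciesTruth, SampleRead, SampleMetadata, TruthRow]] = []

    year_start = _dt.date(2021, 1, 1)
    counter = 0
    for _ in range(config.n_samples):
        counter += 1
        sample_id = f"S{counter:04d}"
        group = groups[rng.choice(len(groups), p=probs)]
        sp = by_group[group][rng.integers(len(by_group[group]))]
        site_id, tech = SITES[rng.integers(len(SITES))]
        date = year_start + _dt.timedelta(days=int(rng.integers(0, 365)))
        pcr_failed = rng.random() < config.pcr_failure_rate
        pset = PrimerSet.SET2 if pcr_failed else PrimerSet.SET1
        read_id = f"{sample_id}|{pset.value}|merged"
        read, summary = degrade_read(
            sp.amplicon(pset), config, drng,
            sample_id=sample_id, read_id=read_id, primer_set=pset,
        )
        stype = (SampleType.INTACT, SampleType.PARTIAL, SampleType.FEATHER_SPOT)[
            rng.choice(3, p=[0.15, 0.15, 0.7])
        ]
        morph = sp.species if rng.random() < config.morph_id_fraction else "unknown"
        meta = SampleMetadata(
            sample_id=sample_id,
            collection_date=date,
            site_id=site_id,
            site_region=_SITE_REGION,
            technology=tech,
            sample_type=stype,
            morphological_id=morph,
        )
        row = TruthRow(
            sample_id=sample_id,
            species=sp.species,
            individual_id=f"IND{counter:04d}",
            eco_group=sp.eco_group,
            primer_set=pset,
            site_id=site_id,
            collection_date=date,
            n_substitutions=summary.n_substitutions,
            n_truncated=summary.n_truncated,
            duplicate_of=None,
            is_sister=sp.sister_partner is not None,
            out_of_window=False,
        )
        reads.append(read)
        metadata.append(meta)
        rows.append(row)
        base_samples.append((sample_id, sp, read, meta, row))

    # duplicate feather spots: same individual, same site, same/next day,
    # byte-identical sequence
    for base_id, sp, base_read, base_meta, base_row in list(base_samples):
        if rng.random() >= config.duplicate_rate:
            continue
        counter += 1
        dup_id = f"S{counter:04d}"
        date = base_meta.collection_date + _dt.timedelta(days=int(rng.integers(0, 2)))
        read = replace(
            base_read,
            sample_id=dup_id,
            read_id=f"{dup_id}|{base_read.primer_set.value}|merged",
        )
        reads.append(read)
        metadata.append(
            replace(
                base_meta,
                sample_id=dup_id,
                collection_date=date,
                sample_type=SampleType.FEATHER_SPOT,
                morphological_id="unknown",
            )
        )
        rows.append(
            replace(
                base_row,
                sample_id=dup_id,
                collection_date=date,
                duplicate_of=base_id,
            )
        )

    # phenology: every species expected year-round unless a sample was
    # planted out of window, in which case its species gets a 60-day window
    # far from that sample's date
    prng = _rng(config.seed, "phenology")
    windows: dict[str, PhenologyWindow] = {
        s.species: PhenologyWindow(s.species, _SITE_REGION, 1, 366, "expected")
        for s in truth.species
    }
    n_out = int(round(config.out_of_window_fraction * config.n_samples))
    if n_out > 0:
        chosen = prng.choice(len(base_samples), size=min(n_out, len(base_samples)), replace=False)
        from .formats_io import day_of_year as _doy

        for k in chosen:
            _, sp, _, meta, _ = base_samples[k]
            day = _doy(meta.collection_date)
            start = (day + 150) % 366 + 1
            end = (start + 59) % 366 + 1 if (start + 59) > 366 else start + 59
            windows[sp.species] = PhenologyWindow(
                sp.species, _SITE_REGION, start, end, "expected"
            )
    table = PhenologyTable(list(windows.values()))

    # recompute the actual in/out-of-window status for the ledger
    from .formats_io import day_of_year as _doy

    for i, row in enumerate(rows):
        w = windows[row.species]
        if not w.contains(_doy(row.collection_date)):
            rows[i] = replace(row, out_of_window=True)

    ledger = TruthLedger(rows)
    assert len(ledger.rows) == len(reads)
    return Survey(reads=reads, metadata=metadata, phenology=table, ledger=ledger)


def write_survey(survey: Survey, outdir: str | Path) -> dict[str, Path]:
    """Write a survey in the standard on-disk dialects."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reads": outdir / "reads.fastq",
        "metadata": outdir / "metadata.tsv",
        "phenology": outdir / "phenology.tsv",
        "ledger": outdir / "truth_ledger.tsv",
    }
    write_sample_reads(survey.reads, paths["reads"], "fastq")
    write_metadata_tsv(survey.metadata, paths["metadata"])
    write_phenology_tsv(survey.phenology, paths["phenology"])
    survey.ledger.to_dataframe().to_csv(paths["ledger"], sep="\t", index=False)
    return paths
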