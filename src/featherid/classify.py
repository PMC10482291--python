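"""Three-tier identification logic, phenology checks and the primer fallback.

A sample is categorized from four criteria — sequence HQ%, query coverage,
percent identity, phenology — each of which maps to a tier:

======================  =============  ==================  ===============
criterion               positive tier  questionable tier   no-id tier
======================  =============  ==================  ===============
HQ%                     > 20           <= 20 or missing    (never fatal)
coverage %              > 50           [30, 50]            < 30
identity %              > 97           [95, 97]            < 95
phenology               consistent     unlikely            inconsistent
======================  =============  ==================  ===============

The tiers do not form a clean partition on their own (a sample can sit in
different tiers on different criteria), so worst-tier-wins: any criterion
in the no-id tier sinks the sample; *positive* requires every criterion in
the positive tier; everything else is questionable.  Boundary values (95,
97, 30, 50, 20) fall in the questionable tier because the positive tiers
are strict inequalities.  A species missing from the phenology table is
``unknown`` — phenology is a verification, not a prerequisite, so unknown
does not block a positive call.

The two-primer fallback: a sample is first identified from its primer-set-1
read; only if that attempt ends in *no identification* (no amplicon, no hit
at >= 95% identity, inconsistent phenology) is the set-2 read tried, and
the better outcome kept (positive > questionable > no identification, ties
keeping set 1).
"""

from __future__ import annotations

import datetime as _dt
import enum
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence, Union

from .formats_io import (
    BarcodeReference,
    PhenologyStatus,
    PhenologyTable,
    PrimerSet,
    SampleMetadata,
    SampleRead,
    day_of_year,
)
from .read_quality import hq_percent as _hq_percent, trim_ends
from .similarity import CandidateSet, ScoringScheme, search_database, top_candidates

__all__ = [
    "Category",
    "ClassifierConfig",
    "IdentificationResult",
    "ConcordanceReport",
    "CategorySummary",
    "round_percent",
    "phenology_status",
    "categorize",
    "identify_sample",
    "summarize_categories",
    "rescue_rate",
    "blind_test_compare",
]

logger = logging.getLogger("featherid")

YEAR_DAYS = 366  # phenology arithmetic is on the fixed day-of-year circle


class Category(str, enum.Enum):
    POSITIVE = "positive"
    QUESTIONABLE = "questionable"
    NO_IDENTIFICATION = "no_identification"


# fallback preference: positive beats questionable beats no identification
_CATEGORY_RANK = {
    Category.POSITIVE: 2,
    Category.QUESTIONABLE: 1,
    Category.NO_IDENTIFICATION: 0,
}

BOTH_FAILED = "both_failed"


@dataclass(frozen=True)
class ClassifierConfig:
    """Thresholds of the tier table plus search/trim settings."""

    hq_threshold_q: int = 20          # Phred cutoff defining a high-quality base
    hq_positive_percent: float = 20.0
    identity_positive: float = 97.0
    identity_min: float = 95.0        # the general species-assignment criterion
    coverage_positive: float = 50.0
    coverage_min: float = 30.0
    tie_epsilon: float = 0.5          # identity pp window for coverage tie-break
    buffer_days: int = 14             # 'unlikely' halo around phenology windows
    min_report_identity: float = 90.0
    trim_window: int = 10
    trim_mean_q: float = 20.0
    scoring: ScoringScheme = field(default_factory=ScoringScheme)

    def __post_init__(self) -> None:
        for name in (
            "hq_positive_percent",
            "identity_positive",
            "identity_min",
            "coverage_positive",
            "coverage_min",
            "min_report_identity",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 100.0:
                raise ValueError(f"{name}={v} outside [0, 100]")
        if self.identity_min > self.identity_positive:
            raise ValueError("identity_min must not exceed identity_positive")
        if self.coverage_min > self.coverage_positive:
            raise ValueError("coverage_min must not exceed coverage_positive")


@dataclass(frozen=True)
class IdentificationResult:
    sample_id: str
    category: Category
    candidates: tuple[str, ...]  # >= 2 only for metric-identical sister ties
    identity_percent: Optional[float]
    coverage_percent: Optional[float]
    hq_percent: Optional[float]  # None = not assessable (no qualities)
    phenology: PhenologyStatus
    primer_set_used: str  # "set1", "set2" or "both_failed"


@dataclass(frozen=True)
class ConcordanceReport:
    """Blind-test agreement between morphological and genetic calls.

    ``mismatch_percent`` is the headline discrepancy rate and counts
    ambiguous sister-taxon ties together with clean mismatches, so the
    partition n_match + n_mismatch + n_ambiguous == n_specimens holds while
    the rate reflects every sample whose single-species call disagreed.
    """

    n_specimens: int
    n_match: int
    n_mismatch: int
    n_ambiguous: int
    mismatch_percent: float


def round_percent(numerator: float, denominator: float, decimals: int = 1) -> float:
    """100 * numerator / denominator, rounded half-up to ``decimals``."""
    if denominator == 0:
        raise ValueError("denominator is zero")
    value = Decimal(100) * Decimal(str(numerator)) / Decimal(str(denominator))
    quantum = Decimal(1).scaleb(-decimals)
    return float(value.quantize(quantum, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# Phenology


def _circular_distance(a: int, b: int) -> int:
    d = abs(a - b) % YEAR_DAYS
    return min(d, YEAR_DAYS - d)


def phenology_status(
    species: str,
    date: _dt.date,
    site_region: str,
    table: PhenologyTable,
    buffer_days: int = 14,
) -> PhenologyStatus:
    """Seasonal plausibility of a species at a site on a date.

    Inside an 'expected' window -> consistent; inside a 'marginal' window,
    or within ``buffer_days`` of an expected-window boundary -> unlikely;
    otherwise inconsistent.  A species with no window rows is unknown.
    """
    rows = table.rows_for(species, site_region)
    if not rows:
        logger.debug("phenology: no window for %s at %s", species, site_region)
        return PhenologyStatus.UNKNOWN
    day = day_of_year(date)
    status = PhenologyStatus.INCONSISTENT
    for w in rows:
        if w.contains(day):
            if w.status == "expected":
                return PhenologyStatus.CONSISTENT
            status = PhenologyStatus.UNLIKELY
        elif w.status == "expected":
            near = min(
                _circular_distance(day, w.start_day),
                _circular_distance(day, w.end_day),
            )
            if near <= buffer_days:
                status = PhenologyStatus.UNLIKELY
    return status


_PHENOLOGY_PREFERENCE = {
    PhenologyStatus.CONSISTENT: 3,
    PhenologyStatus.UNKNOWN: 2,
    PhenologyStatus.UNLIKELY: 1,
    PhenologyStatus.INCONSISTENT: 0,
}


# ---------------------------------------------------------------------------
# Categorization


def categorize(
    identity: Optional[float],
    coverage: Optional[float],
    hq: Optional[float],
    phenology: PhenologyStatus,
    config: ClassifierConfig = ClassifierConfig(),
) -> Category:
    """Map the four criteria to a category, worst tier winning.

    ``identity=None`` means no reportable hit (or no amplicon) and is
    immediately no-identification.  ``hq=None`` means not assessable: the
    sample cannot reach the positive tier, but HQ alone never sinks it.
    """
    if identity is None or coverage is None:
        return Category.NO_IDENTIFICATION
    if (
        identity < config.identity_min
        or coverage < config.coverage_min
        or phenology == PhenologyStatus.INCONSISTENT
    ):
        return Category.NO_IDENTIFICATION
    positive = (
        identity > config.identity_positive
        and coverage > config.coverage_positive
        and hq is not None
        and hq > config.hq_positive_percent
        and phenology in (PhenologyStatus.CONSISTENT, PhenologyStatus.UNKNOWN)
    )
    return Category.POSITIVE if positive else Category.QUESTIONABLE


# ---------------------------------------------------------------------------
# Per-sample identification with primer fallback


def _attempt(
    sample_id: str,
    reads: Sequence[SampleRead],
    references: Sequence[BarcodeReference],
    phenology_table: Optional[PhenologyTable],
    metadata: Optional[SampleMetadata],
    config: ClassifierConfig,
    primer_label: str,
) -> IdentificationResult:
    # Longest read carries the most signal; the generator emits one per set.
    read = max(reads, key=len)
    trimmed = trim_ends(read, config.trim_window, config.trim_mean_q)
    if len(trimmed.sequence) == 0:
        trimmed = read  # qualities uniformly poor: fall back to the raw read
    hq = _hq_percent(trimmed, config.hq_threshold_q).hq_percent
    hits = search_database(
        trimmed.sequence,
        references,
        scoring=config.scoring,
        min_report_identity=config.min_report_identity,
    )
    cands: CandidateSet = top_candidates(hits, references, config.tie_epsilon)
    if not cands:
        return IdentificationResult(
            sample_id,
            Category.NO_IDENTIFICATION,
            (),
            None,
            None,
            hq,
            PhenologyStatus.UNKNOWN,
            primer_label,
        )
    if phenology_table is not None and metadata is not None:
        phen = max(
            (
                phenology_status(
                    sp,
                    metadata.collection_date,
                    metadata.site_region,
                    phenology_table,
                    config.buffer_days,
                )
                for sp in cands.species
            ),
            key=_PHENOLOGY_PREFERENCE.__getitem__,
        )
    else:
        phen = PhenologyStatus.UNKNOWN
    assert cands.best is not None
    category = categorize(
        cands.best.identity_percent,
        cands.best.coverage_percent,
        hq,
        phen,
        config,
    )
    return IdentificationResult(
        sample_id,
        category,
        cands.species,
        cands.best.identity_percent,
        cands.best.coverage_percent,
        hq,
        phen,
        primer_label,
    )


def identify_sample(
    sample_id: str,
    reads_by_set: Mapping[PrimerSet, Sequence[SampleRead]],
    references: Sequence[BarcodeReference],
    phenology_table: Optional[PhenologyTable] = None,
    metadata: Optional[SampleMetadata] = None,
    config: ClassifierConfig = ClassifierConfig(),
    amplification_failed: bool = False,
) -> IdentificationResult:
    """Identify one sample, trying primer set 1 then falling back to set 2.

    A sample with no reads at all must carry an explicit amplification
    failure record (``amplification_failed=True``); silent empties raise.
    """
    set1 = [r for r in reads_by_set.get(PrimerSet.SET1, ()) if r.sequence]
    set2 = [r for r in reads_by_set.get(PrimerSet.SET2, ()) if r.sequence]
    if not set1 and not set2:
        if not amplification_failed:
            raise ValueError(
                f"sample {sample_id!r} has no reads and no amplification-failure record"
            )
        return IdentificationResult(
            sample_id,
            Category.NO_IDENTIFICATION,
            (),
            None,
            None,
            None,
            PhenologyStatus.UNKNOWN,
            BOTH_FAILED,
        )
    res1 = (
        _attempt(sample_id, set1, references, phenology_table, metadata, config, PrimerSet.SET1.value)
        if set1
        else None
    )
    if res1 is not None and res1.category != Category.NO_IDENTIFICATION:
        return res1
    res2 = (
        _attempt(sample_id, set2, references, phenology_table, metadata, config, PrimerSet.SET2.value)
        if set2
        else None
    )
    # keep the better outcome; ties keep set 1
    best = None
    for res in (res1, res2):
        if res is None:
            continue
        if best is None or _CATEGORY_RANK[res.category] > _CATEGORY_RANK[best.category]:
            best = res
    assert best is not None
    if best.category == Category.NO_IDENTIFICATION:
        best = IdentificationResult(
            best.sample_id,
            best.category,
            best.candidates,
            best.identity_percent,
            best.coverage_percent,
            best.hq_percent,
            best.phenology,
            BOTH_FAILED,
        )
    return best


# ---------------------------------------------------------------------------
# Summaries


@dataclass(frozen=True)
class CategorySummary:
    counts: dict
    percentages: dict            # per category, half-up to one decimal
    identified_percent: float    # positive + questionable combined
    n_total: int


def summarize_categories(
    results: Union[Sequence[IdentificationResult], Mapping[Category, int]],
) -> CategorySummary:
    """Per-category counts and percentages (half-up, one decimal)."""
    if isinstance(results, Mapping):
        counts = {c: int(results.get(c, 0)) for c in Category}
    else:
        if len(results) == 0:
            raise ValueError("no results to summarize")
        counts = {c: 0 for c in Category}
        for r in results:
            counts[r.category] += 1
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no results to summarize")
    percentages = {c: round_percent(counts[c], total) for c in Category}
    identified = counts[Category.POSITIVE] + counts[Category.QUESTIONABLE]
    return CategorySummary(
        counts=counts,
        percentages=percentages,
        identified_percent=round_percent(identified, total),
        n_total=total,
    )


def rescue_rate(n_rescued: int, n_primary_failures: int) -> float:
    """Percent of set-1 failures recovered by the set-2 fallback (one decimal)."""
    return round_percent(n_rescued, n_primary_failures)


def blind_test_compare(
    morph_ids: Mapping[str, str],
    results: Sequence[IdentificationResult],
) -> ConcordanceReport:
    """Compare genetic identifications with withheld morphological calls.

    match: the single genetic candidate equals the morphological species;
    ambiguous: a multi-candidate (sister) tie contains it; mismatch:
    anything else.  The headline ``mismatch_percent`` counts ambiguous
    cases together with clean mismatches.
    """
    by_id = {r.sample_id: r for r in results}
    missing = set(morph_ids) - set(by_id)
    if missing:
        raise ValueError(f"specimens without genetic results: {sorted(missing)}")
    n_match = n_mismatch = n_ambiguous = 0
    for sample_id, morph_species in morph_ids.items():
        cands = by_id[sample_id].candidates
        if len(cands) == 1 and cands[0] == morph_species:
            n_match += 1
        elif len(cands) >= 2 and morph_species in cands:
            n_ambiguous += 1
        else:
            n_mismatch += 1
    n = len(morph_ids)
    if n == 0:
        raise ValueError("no specimens to compare")
    return ConcordanceReport(
        n_specimens=n,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_ambiguous=n_ambiguous,
        mismatch_percent=round_percent(n_mismatch + n_ambiguous, n),
    )
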