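"""End-to-end orchestration: identify -> dedup -> community stats.

``run_pipeline`` wires the file formats to the library stages and writes
the full results bundle (results TSV, category tally JSON, dedup TSV,
stats TSV, plain-text log).  Identical config and inputs produce
byte-identical outputs: the log carries no timestamps and all JSON is
written with sorted keys.  Per-stage record counts are logged, including
every excluded sample and why, so sample conservation is auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import community
from .classify import (
    BOTH_FAILED,
    Category,
    ClassifierConfig,
    IdentificationResult,
    identify_sample,
    rescue_rate,
    summarize_categories,
)
from .dedup import DedupRecord, cluster_duplicates, duplicate_fraction
from .formats_io import (
    BarcodeReference,
    PhenologyTable,
    PrimerSet,
    SampleMetadata,
    SampleRead,
    read_metadata_tsv,
    read_phenology_tsv,
    read_reference_fasta,
    read_sample_reads,
    write_results_table,
)

__all__ = ["PipelineConfig", "PipelineError", "identify_survey", "run_pipeline"]

logger = logging.getLogger("featherid")


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    references: Path
    reads: Path
    metadata: Path
    phenology: Optional[Path]
    outdir: Path
    reads_format: str = "fastq"
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    dedup_min_overlap: int = 400
    primer_set_policy: str = "auto"  # "auto", "1" (set1 only) or "2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.primer_set_policy not in ("auto", "1", "2"):
            raise ValueError("primer_set_policy must be 'auto', '1' or '2'")


def _group_reads(reads: Sequence[SampleRead]) -> dict[str, dict[PrimerSet, list[SampleRead]]]:
    grouped: dict[str, dict[PrimerSet, list[SampleRead]]] = {}
    for r in reads:
        grouped.setdefault(r.sample_id, {}).setdefault(r.primer_set, []).append(r)
    return grouped


def identify_survey(
    reads: Sequence[SampleRead],
    metadata: Sequence[SampleMetadata],
    references: Sequence[BarcodeReference],
    phenology: Optional[PhenologyTable] = None,
    config: ClassifierConfig = ClassifierConfig(),
    primer_set_policy: str = "auto",
) -> list[IdentificationResult]:
    """Identify every sample appearing in the read set, in sample-id order.

    Metadata rows without reads are treated as recorded amplification
    failures (they were processed but yielded no product) and come back as
    no-identification / both_failed.
    """
    grouped = _group_reads(reads)
    meta_by_id = {m.sample_id: m for m in metadata}
    if primer_set_policy == "1":
        grouped = {
            sid: {PrimerSet.SET1: by_set[PrimerSet.SET1]}
            for sid, by_set in grouped.items()
            if PrimerSet.SET1 in by_set
        }
    elif primer_set_policy == "2":
        grouped = {
            sid: {PrimerSet.SET2: by_set[PrimerSet.SET2]}
            for sid, by_set in grouped.items()
            if PrimerSet.SET2 in by_set
        }
    results = []
    sample_ids = sorted(set(grouped) | set(meta_by_id))
    for sid in sample_ids:
        by_set = grouped.get(sid, {})
        results.append(
            identify_sample(
                sid,
                by_set,
                references,
                phenology_table=phenology,
                metadata=meta_by_id.get(sid),
                config=config,
                amplification_failed=not by_set,
            )
        )
    return results


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Execute identify -> dedup -> stats and write the results bundle."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    log_lines: list[str] = []

    def log(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    def stage(name: str):
        class _Ctx:
            def __enter__(self):
                log(f"stage {name}: start")
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise PipelineError(f"stage {name} failed: {exc}") from exc
                log(f"stage {name}: done")

        return _Ctx()

    with stage("load"):
        references = read_reference_fasta(config.references)
        reads = read_sample_reads(config.reads, config.reads_format)
        metadata = read_metadata_tsv(config.metadata)
        phenology = (
            read_phenology_tsv(config.phenology) if config.phenology else None
        )
        log(
            f"loaded {len(references)} references, {len(reads)} reads, "
            f"{len(metadata)} metadata rows"
        )

    with stage("identify"):
        results = identify_survey(
            reads, metadata, references, phenology, config.classifier,
            config.primer_set_policy,
        )
        summary = summarize_categories(results)
        n_set1 = len({r.sample_id for r in reads if r.primer_set == PrimerSet.SET1})
        n_samples = len(results)
        set1_failures = [
            r for r in results
            if r.sample_id not in {x.sample_id for x in reads if x.primer_set == PrimerSet.SET1}
        ]
        rescued = [
            r for r in set1_failures if r.category != Category.NO_IDENTIFICATION
        ]
        for r in results:
            if r.category == Category.NO_IDENTIFICATION:
                log(f"sample {r.sample_id}: no identification (primer={r.primer_set_used})")
        log(f"identified {summary.identified_percent}% of {n_samples} samples")

    results_path = outdir / "results.tsv"
    tally_path = outdir / "tally.json"
    with stage("write-results"):
        write_results_table(results, results_path)
        tally = {
            "counts": {c.value: summary.counts[c] for c in Category},
            "percentages": {c.value: summary.percentages[c] for c in Category},
            "identified_percent": summary.identified_percent,
            "n_samples": summary.n_total,
            "sar_set1_percent": round(100.0 * n_set1 / n_samples, 1) if n_samples else None,
            "n_set1_failures": len(set1_failures),
            "n_rescued_by_set2": len(rescued),
            "set2_rescue_percent": (
                rescue_rate(len(rescued), len(set1_failures)) if set1_failures else None
            ),
        }
        tally_path.write_text(json.dumps(tally, indent=2, sort_keys=True) + "\n")

    dedup_path = outdir / "dedup.tsv"
    with stage("dedup"):
        meta_by_id = {m.sample_id: m for m in metadata}
        by_id = {r.sample_id: r for r in results}
        records = []
        best_read: dict[str, SampleRead] = {}
        for r in reads:
            cur = best_read.get(r.sample_id)
            if cur is None or len(r) > len(cur):
                best_read[r.sample_id] = r
        for sid, res in by_id.items():
            if not res.candidates or sid not in meta_by_id or sid not in best_read:
                continue
            m = meta_by_id[sid]
            records.append(
                DedupRecord(
                    sample_id=sid,
                    site_id=m.site_id,
                    collection_date=m.collection_date,
                    species=res.candidates[0],
                    sequence=best_read[sid].sequence,
                )
            )
        dedup_rows = []
        fractions = {}
        for window in ("same_week", "same_day"):
            clusters = cluster_duplicates(records, window, config.dedup_min_overlap)
            fractions[window] = duplicate_fraction(clusters, len(results))
            for c in clusters:
                dedup_rows.append(
                    {
                        "window": window,
                        "site_id": c.site_id,
                        "n_members": len(c),
                        "members": ";".join(c.members),
                        "hash": c.representative_hash,
                    }
                )
            log(f"dedup {window}: {len(clusters)} clusters, "
                f"{fractions[window]:.2f}% of samples")
        pd.DataFrame(
            dedup_rows, columns=["window", "site_id", "n_members", "members", "hash"]
        ).to_csv(dedup_path, sep="\t", index=False)

    stats_path = outdir / "stats.tsv"
    stats_json_path = outdir / "stats.json"
    with stage("stats"):
        stats_rows = []
        stats_json: dict = {"duplicate_fraction_percent": fractions}
        for facet in ("method", "technology"):
            try:
                tally_f = community.proportions_report(results, metadata, references, facet)
            except ValueError as exc:
                log(f"stats facet {facet}: skipped ({exc})")
                continue
            for row in tally_f.counts.index:
                for col in tally_f.counts.columns:
                    stats_rows.append(
                        {
                            "facet": facet,
                            "level": row,
                            "group": col,
                            "count": int(tally_f.counts.loc[row, col]),
                            "percent": int(tally_f.percentages.loc[row, col]),
                        }
                    )
            if tally_f.chi2 is not None:
                stats_json[facet] = {
                    "chi2": tally_f.chi2.statistic,
                    "df": tally_f.chi2.df,
                    "p_value": tally_f.chi2.p_value,
                    "n": tally_f.chi2.n,
                }
                log(
                    f"stats {facet}: chi2={tally_f.chi2.statistic:.2f} "
                    f"df={tally_f.chi2.df} n={tally_f.chi2.n}"
                )
            else:
                stats_json[facet] = None
                log(f"stats {facet}: table below 2x2 after dropping empty levels")
        pd.DataFrame(
            stats_rows, columns=["facet", "level", "group", "count", "percent"]
        ).to_csv(stats_path, sep="\t", index=False)
        stats_json_path.write_text(json.dumps(stats_json, indent=2, sort_keys=True) + "\n")

    log_path.write_text("\n".join(log_lines) + "\n")
    return {
        "results": results_path,
        "tally": tally_path,
        "dedup": dedup_path,
        "stats": stats_path,
        "stats_json": stats_json_path,
        "log": log_path,
    }
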