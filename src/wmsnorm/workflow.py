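"""Pipeline orchestration: load -> filter -> weight -> quantify -> report.

Island filtration runs per reference sequence (strain) before the
strain-to-species collapse, because islands belong to a specific
reference; species records then aggregate only the surviving
references.  GC weighting is applied after filtration so weighted
counts never include island reads.
"""

from __future__ import annotations

import json
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from wmsnorm.abundance import (
    LoadContext,
    aggregate,
    apply_load,
    resolve_multireads,
    write_report,
)
from wmsnorm.alignment_io import TaxonomyMap, gc_count_table, load_alignments, load_references
from wmsnorm.gc_model import GcBiasModel
from wmsnorm.island_filter import (
    CLASS_FILTERED,
    CLASS_UNCERTAIN,
    FilterConfig,
    evaluate_reference,
)

logger = logging.getLogger("wmsnorm")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class PipelineConfig:
    alignments: str
    references: str
    taxonomy: str
    model: str | None = None
    out_dir: str = "."
    window_size: int = 100
    min_mapq: int = 0
    filter_enabled: bool = True
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    human_read_count: int | None = None
    diploid_genome_mb: float = 6191.39
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        fc = raw.pop("filter_config", None)
        config = cls(**raw)
        if fc:
            config.filter_config = FilterConfig(**fc)
        return config

    def validate(self) -> None:
        for name in ("alignments", "references", "taxonomy"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} file not found: {p}")
        if self.model is not None and not Path(self.model).exists():
            raise FileNotFoundError(f"model file not found: {self.model}")


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return wrapper

    return deco


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full pipeline and write report TSV + summary JSON.

    Returns the summary dictionary (also written to summary.json).
    """
    logging.basicConfig(level=config.log_level)
    config.validate()
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    genomes = _stage("load_references")(load_references)(config.references, config.window_size)
    assignments = _stage("load_alignments")(load_alignments)(
        config.alignments, config.min_mapq, genomes
    )
    taxonomy = _stage("load_taxonomy")(TaxonomyMap.from_tsv)(config.taxonomy)
    _stage("load_taxonomy")(taxonomy.validate)(a.ref_id for a in assignments)
    total_records = len(assignments)
    total_reads = len({a.read_id for a in assignments})
    logger.info("loaded %d records (%d reads) on %d references", total_records, total_reads, len(genomes))

    by_len = {g.ref_id: g.length for g in genomes}
    island_results = []
    filtered_refs: set[str] = set()
    uncertain = []
    if config.filter_enabled:
        starts_by_ref = defaultdict(list)
        for a in assignments:
            starts_by_ref[a.ref_id].append(a.start)
        for ref_id, starts in sorted(starts_by_ref.items()):
            res = _stage("island_filter")(evaluate_reference)(
                ref_id, starts, by_len[ref_id], config.filter_config
            )
            island_results.append(res)
            if res.classification == CLASS_FILTERED:
                filtered_refs.add(ref_id)
            elif res.classification == CLASS_UNCERTAIN:
                uncertain.append(res)
    else:
        logger.warning("island filtration disabled by configuration")

    surviving = [a for a in assignments if a.ref_id not in filtered_refs]
    reads_after_filter = {a.read_id for a in surviving}
    removed_with_hits = total_reads - len(reads_after_filter)

    resolved, discarded = _stage("resolve_multireads")(resolve_multireads)(surviving, taxonomy)

    model = None
    if config.model is not None:
        model = _stage("load_model")(GcBiasModel.from_json)(config.model)
    records = _stage("aggregate")(aggregate)(resolved, genomes, model, taxonomy)

    ctx = None
    if config.human_read_count is not None:
        ctx = LoadContext(config.human_read_count, config.diploid_genome_mb)
        _stage("bacterial_load")(apply_load)(records, ctx)

    table = gc_count_table(surviving, genomes)
    ledger = {
        "input_reads": total_reads,
        "assigned": len(resolved),
        "discarded_multispecies": discarded,
        "removed_with_filtered_hits": removed_with_hits,
        "gc_tail_window_remainder": sum(table.remainder.values()),
    }

    report_path = out_dir / "report.tsv"
    filtered_results = [r for r in island_results if r.classification == CLASS_FILTERED]
    _stage("write_report")(write_report)(
        records,
        report_path,
        island_results=filtered_results,
        uncertain_hits=uncertain,
        ledger=ledger,
    )
    summary = {
        "n_references": len(genomes),
        "n_species_reported": len(records),
        "filtered_hits": sorted(filtered_refs),
        "uncertain_hits": [r.ref_id for r in uncertain],
        "ledger": ledger,
        "gc_model": config.model,
        "per_species": {
            r.species_key: {
                "raw_count": r.raw_count,
                "weighted_count": r.weighted_count,
                "weighted_per_mb": r.weighted_per_mb,
                "relative_percent": r.relative_percent,
                "per_human_cell": r.per_human_cell,
            }
            for r in records
        },
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    logger.info("report written to %s", report_path)
    return summary
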