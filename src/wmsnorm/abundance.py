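"""Species-level quantification: multireads, weighting, per-Mb counts.

A multiread (one query aligned to several references) is usable at
species level only if it is counted once: reads whose hits span more
than one species are discarded, and hits to multiple strains of the
same species collapse to a single representative strain.  Retained
reads are weighted by the reciprocal of their predicted normalized
coverage and summed; dividing by the reference length in Mb removes
the higher sampling likelihood of longer genomes.  Per-Mb weighted
counts can finally be calibrated to the host background: with C_H
human reads, the absolute abundance of a species per human cell is

    A = 6191.39 * C_GCperMbR / C_H

where 6191.39 Mb is the length of a diploid human genome.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from wmsnorm.alignment_io import ReadAssignment, ReferenceGenome, TaxonomyMap
from wmsnorm.gc_model import GcBiasModel, read_weight
from wmsnorm.island_filter import IslandTestResult

DIPLOID_HUMAN_GENOME_MB = 6191.39


@dataclass
class AbundanceRecord:
    species_key: str
    raw_count: int
    weighted_count: float
    weighted_per_mb: float
    relative_percent: float
    genome_length_mb: float
    per_human_cell: float | None = None


@dataclass
class LoadContext:
    """Host background used to convert per-Mb counts to absolute load."""

    human_read_count: int
    diploid_genome_mb: float = DIPLOID_HUMAN_GENOME_MB

    def __post_init__(self) -> None:
        if self.human_read_count < 0:
            raise ValueError("human read count cannot be negative")


def resolve_multireads(
    assignments: list[ReadAssignment],
    taxonomy: TaxonomyMap,
) -> tuple[list[ReadAssignment], int]:
    """Assign every read to at most one species.

    Returns the retained assignments (one per read) and the number of
    reads discarded because their hits span multiple species.  The
    representative strain for a multi-strain read is the strain with
    the highest raw read count in the sample, ties broken by
    lexicographic ref_id.
    """
    taxonomy.validate(a.ref_id for a in assignments)
    ref_counts = Counter(a.ref_id for a in assignments)
    by_read: dict[str, list[ReadAssignment]] = defaultdict(list)
    for a in assignments:
        by_read[a.read_id].append(a)
    retained: list[ReadAssignment] = []
    discarded = 0
    for hits in by_read.values():
        species = {taxonomy.species(h.ref_id) for h in hits}
        if len(species) > 1:
            discarded += 1
            continue
        best = min(hits, key=lambda h: (-ref_counts[h.ref_id], h.ref_id))
        best.species_key = species.pop()
        retained.append(best)
    return retained, discarded


def aggregate(
    assignments: list[ReadAssignment],
    genomes: list[ReferenceGenome],
    model: GcBiasModel | None = None,
    taxonomy: TaxonomyMap | None = None,
) -> list[AbundanceRecord]:
    """Aggregate resolved assignments into per-species abundance records.

    With ``model=None`` every read has weight 1 (raw counting).  The
    species genome length is that of its reference with the most
    assigned reads, so per-Mb values stay well defined when several
    strains of a species survive.
    """
    by_ref = {g.ref_id: g for g in genomes}
    per_species_refs: dict[str, Counter] = defaultdict(Counter)
    raw: Counter = Counter()
    weighted: dict[str, float] = defaultdict(float)
    for a in assignments:
        genome = by_ref.get(a.ref_id)
        if genome is None:
            raise KeyError(f"assignment to unknown reference {a.ref_id!r}")
        key = a.species_key
        if key is None:
            key = taxonomy.species(a.ref_id) if taxonomy else a.ref_id
        if model is not None:
            a.weight = float(read_weight(a.read_gc, genome.gc_percent, model))
        raw[key] += 1
        weighted[key] += a.weight
        per_species_refs[key][a.ref_id] += 1
    records: list[AbundanceRecord] = []
    for key in sorted(raw):
        rep_ref, _ = min(per_species_refs[key].items(), key=lambda kv: (-kv[1], kv[0]))
        length_mb = by_ref[rep_ref].length_mb
        if length_mb <= 0:
            raise ValueError(f"zero genome length for species {key!r}")
        records.append(
            AbundanceRecord(
                species_key=key,
                raw_count=raw[key],
                weighted_count=weighted[key],
                weighted_per_mb=weighted[key] / length_mb,
                relative_percent=0.0,
                genome_length_mb=length_mb,
            )
        )
    total = sum(r.weighted_per_mb for r in records)
    if total > 0:
        for r in records:
            r.relative_percent = 100.0 * r.weighted_per_mb / total
    records.sort(key=lambda r: -r.weighted_per_mb)
    return records


def rmse(estimated_percent, actual_percent) -> float:
    """Root-mean-square error between estimated and true percentages."""
    est = np.asarray(estimated_percent, dtype=np.float64)
    act = np.asarray(actual_percent, dtype=np.float64)
    if est.shape != act.shape or est.size == 0:
        raise ValueError("need two equal-length, non-empty vectors")
    return float(np.sqrt(np.mean((est - act) ** 2)))


def bacterial_load(weighted_per_mb: float, ctx: LoadContext) -> float:
    """Absolute abundance per host cell from a per-Mb weighted count."""
    if ctx.human_read_count == 0:
        raise ValueError("bacterial load undefined without host background reads")
    return ctx.diploid_genome_mb * weighted_per_mb / ctx.human_read_count


def apply_load(records: list[AbundanceRecord], ctx: LoadContext) -> None:
    for r in records:
        r.per_human_cell = bacterial_load(r.weighted_per_mb, ctx)


def write_report(
    records: list[AbundanceRecord],
    out_path: str | Path,
    island_results: list[IslandTestResult] | None = None,
    uncertain_hits: list[IslandTestResult] | None = None,
    ledger: dict[str, int] | None = None,
    histogram_edges=(0, 10, 100, 1000, 10000),
) -> None:
    """Write the main abundance table plus diagnostic sections.

    The main table is sorted by weighted count per Mb, descending.
    Uncertain hits get their t-test statistics and a spacing histogram
    so a reviewer with domain knowledge about the sample can decide
    them manually.  A footer ledger reconciles every input read.
    """
    from wmsnorm.island_filter import distance_histogram

    if not records:
        raise ValueError("no abundance records to report")
    with_load = any(r.per_human_cell is not None for r in records)
    lines: list[str] = []
    header = [
        "species",
        "raw_reads",
        "gc_weighted_reads",
        "gc_weighted_per_mb",
        "relative_percent",
        "genome_mb",
    ]
    if with_load:
        header.append("per_human_cell")
    lines.append("\t".join(header))
    for r in sorted(records, key=lambda r: -r.weighted_per_mb):
        row = [
            r.species_key,
            str(r.raw_count),
            f"{r.weighted_count:.10g}",
            f"{r.weighted_per_mb:.10g}",
            f"{r.relative_percent:.2f}",
            f"{r.genome_length_mb:.6g}",
        ]
        if with_load:
            row.append("" if r.per_human_cell is None else f"{r.per_human_cell:.6g}")
        lines.append("\t".join(row))

    for title, results in (
        ("uncertain bacterial hits", uncertain_hits or []),
        ("filtered bacterial hits", island_results or []),
    ):
        if not results:
            continue
        lines.append("")
        lines.append(f"# {title}")
        lines.append(
            "ref_id\tn_reads\tmean_distance\tnull_mean\tt_stat\tp_value\t"
            "genome_size_estimate\tgenome_size_upper_bound\tclassification"
        )
        for res in results:
            lines.append(
                f"{res.ref_id}\t{res.n_reads}\t{res.mean_distance:.6g}\t"
                f"{res.null_mean:.6g}\t{res.t_stat:.6g}\t{res.p_value:.3g}\t"
                f"{res.genome_size_estimate:.6g}\t{res.genome_size_upper_bound:.6g}\t"
                f"{res.classification}"
            )
            if res.distances.size:
                for label, count in distance_histogram(res.distances, histogram_edges):
                    lines.append(f"#   spacing {label}\t{count}")

    if ledger:
        lines.append("")
        lines.append("# read ledger")
        for k, v in ledger.items():
            lines.append(f"#   {k}\t{v}")
    Path(out_path).write_text("\n".join(lines) + "\n")
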