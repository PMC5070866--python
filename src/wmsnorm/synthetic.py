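"""Synthetic genomes, GC-biased read sets and pooled samples.

Generates the inputs the rest of the package consumes — FASTA
references, SAM alignments, a taxonomy map and a truth table of known
DNA proportions — so filtration and normalization can be exercised
against ground truth.  Read starts are drawn window-wise: the chance
of a 100 bp window emitting a read is proportional to the bias
surface evaluated at (window GC, genome GC), which makes the
recomputed normalized-coverage curves reproduce the planted surface
up to a global constant.  A genome's overall representation in a pool
is its DNA proportion times its mean per-window bias, so GC-poor
genomes end up overrepresented exactly as a biased sequencer would
leave them.

Reads are single-end, fixed length (default 75 bp), error-free; the
package consumes alignments, not raw reads, so base-call noise and
mapping ambiguity are out of scope here.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam

from wmsnorm.alignment_io import _window_gc_points
from wmsnorm.gc_model import GcBiasModel, predict_normcov

#: Genome GC ladder emulating seven individually sequenced calibration
#: bacteria spanning the 32.8-70.8% GC range.
GC_LADDER = (32.8, 39.7, 50.5, 57.3, 64.9, 66.7, 70.8)

_BASES = np.frombuffer(b"GCAT", dtype=np.uint8)


def planted_bias_model(floor: float = 0.01) -> GcBiasModel:
    """A bell-shaped bias surface of realistic magnitude.

    Peak near 45% read GC, several-fold drop in representation from
    the lowest- to the highest-GC genomes via the negative log term —
    the shape a fragment-library short-read platform produces.
    """
    return GcBiasModel(theta=(2.0, 45.0, 12.0, 3.6, 0.01, -1e-4, 0.0, -0.8), floor=floor)


@dataclass
class SimulationSpec:
    """Recipe for one pooled sample with known composition.

    ``genomes`` are (length bp, target GC%) pairs; ``islands`` are
    (host genome index, island length bp, island start bp, read count)
    tuples describing clustered decoy reads.
    """

    genomes: list[tuple[int, float]]
    pool_proportions: list[float]
    total_reads: int
    read_length: int = 75
    window_size: int = 100
    bias: GcBiasModel | None = None
    islands: list[tuple[int, int, int, int]] = field(default_factory=list)
    seed: int = 0
    names: list[str] | None = None

    def __post_init__(self) -> None:
        if len(self.genomes) != len(self.pool_proportions):
            raise ValueError("one proportion per genome required")
        if abs(sum(self.pool_proportions) - 1.0) > 1e-9:
            raise ValueError("pool proportions must sum to 1")
        if self.read_length > min(length for length, _ in self.genomes):
            raise ValueError("read length exceeds shortest genome")
        if self.names is None:
            self.names = [f"genome{i:02d}" for i in range(len(self.genomes))]


def make_genome(length: int, gc_percent: float, seed: int | np.random.Generator = 0) -> str:
    """I.i.d. nucleotide sequence with the requested expected GC%."""
    if not 0 <= gc_percent <= 100:
        raise ValueError("gc_percent must be within [0, 100]")
    if length <= 0:
        raise ValueError("length must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    p_gc = gc_percent / 200.0
    p_at = (100.0 - gc_percent) / 200.0
    idx = rng.choice(4, size=length, p=[p_gc, p_gc, p_at, p_at])
    return _BASES[idx].tobytes().decode("ascii")


def implant_island(host: str, donor_segment: str, position: int) -> tuple[str, tuple[int, int]]:
    """Substitute a donor segment into a host sequence in place.

    Length-preserving; returns the modified sequence and the island's
    (start, end) half-open coordinates for truth tracking.
    """
    if position < 0 or position + len(donor_segment) > len(host):
        raise ValueError("island does not fit in host at that position")
    end = position + len(donor_segment)
    return host[:position] + donor_segment + host[end:], (position, end)


def _window_probs(
    sequence: str,
    genome_gc: float,
    bias: GcBiasModel | None,
    window_size: int,
) -> np.ndarray:
    window_gc = _window_gc_points(sequence.encode("ascii"), window_size)
    probs = np.zeros(window_gc.size, dtype=np.float64)
    valid = window_gc >= 0
    if bias is None:
        probs[valid] = 1.0
    else:
        probs[valid] = predict_normcov(window_gc[valid].astype(float), genome_gc, bias)
    total = probs.sum()
    if total <= 0:
        raise ValueError("no usable windows to sample reads from")
    return probs / total


def sample_read_starts(
    sequence: str,
    n: int,
    genome_gc: float,
    bias: GcBiasModel | None,
    rng: np.random.Generator,
    read_length: int = 75,
    window_size: int = 100,
) -> np.ndarray:
    """Draw ``n`` read starts window-wise under the bias surface."""
    if n < 1:
        raise ValueError("need n >= 1 reads")
    if n > len(sequence) - read_length + 1:
        raise ValueError("more reads requested than available start positions")
    probs = _window_probs(sequence, genome_gc, bias, window_size)
    windows = rng.choice(probs.size, size=n, p=probs)
    offsets = rng.integers(0, window_size, size=n)
    starts = windows * window_size + offsets
    return np.minimum(starts, len(sequence) - read_length)


def sample_reads(
    ref_id: str,
    sequence: str,
    n: int,
    genome_gc: float,
    bias: GcBiasModel | None,
    rng: np.random.Generator,
    read_length: int = 75,
    window_size: int = 100,
    id_prefix: str = "r",
) -> list[tuple[str, str, int, str]]:
    """Sampled reads as (read_id, ref_id, start, sequence) tuples."""
    starts = sample_read_starts(
        sequence, n, genome_gc, bias, rng, read_length=read_length, window_size=window_size
    )
    return [
        (f"{id_prefix}{k:07d}", ref_id, int(s), sequence[s : s + read_length])
        for k, s in enumerate(starts)
    ]


def write_sam(path: str | Path, references: list[tuple[str, int]], reads) -> None:
    """Write single-end forward-strand records as plain-text SAM."""
    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": name, "LN": length} for name, length in references],
    }
    tid = {name: i for i, (name, _) in enumerate(references)}
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for read_id, ref_id, start, seq in reads:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = read_id
            rec.query_sequence = seq
            rec.flag = 0
            rec.reference_id = tid[ref_id]
            rec.reference_start = start
            rec.mapping_quality = 60
            rec.cigarstring = f"{len(seq)}M"
            rec.query_qualities = pysam.qualitystring_to_array("I" * len(seq))
            out.write(rec)


def write_fasta(path: str | Path, sequences: list[tuple[str, str]], width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def make_pool(spec: SimulationSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate a pooled sample: SAM + FASTA + taxonomy + truth table.

    Background reads are allocated across genomes by a multinomial
    whose weights are DNA proportion times mean window bias; island
    reads are added on top, uniformly placed inside their island.
    The truth table records exact DNA proportions and realized read
    counts per genome.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(spec.seed)

    sequences: list[str] = []
    island_coords: dict[int, list[tuple[int, int]]] = {}
    for gi, (length, gc) in enumerate(spec.genomes):
        sequences.append(make_genome(length, gc, rng))
    for gi, island_len, position, _count in spec.islands:
        donor = make_genome(island_len, 50.0, rng)
        sequences[gi], coords = implant_island(sequences[gi], donor, position)
        island_coords.setdefault(gi, []).append(coords)

    # Representation weight: DNA amount times the genome's mean bias.
    weights = []
    for gi, seq in enumerate(sequences):
        probs = _window_probs(seq, spec.genomes[gi][1], spec.bias, spec.window_size)
        window_gc = _window_gc_points(seq.encode("ascii"), spec.window_size)
        valid = window_gc >= 0
        if spec.bias is None:
            mean_bias = 1.0
        else:
            mean_bias = float(
                np.mean(predict_normcov(window_gc[valid].astype(float), spec.genomes[gi][1], spec.bias))
            )
        weights.append(spec.pool_proportions[gi] * mean_bias)
    weights = np.asarray(weights)
    alloc = rng.multinomial(spec.total_reads, weights / weights.sum())

    reads = []
    counts = np.zeros(len(sequences), dtype=np.int64)
    for gi, n in enumerate(alloc):
        if n == 0:
            continue
        counts[gi] += n
        reads.extend(
            sample_reads(
                spec.names[gi],
                sequences[gi],
                int(n),
                spec.genomes[gi][1],
                spec.bias,
                rng,
                read_length=spec.read_length,
                window_size=spec.window_size,
                id_prefix=f"g{gi}_",
            )
        )
    for ii, (gi, island_len, position, count) in enumerate(spec.islands):
        starts = rng.integers(position, position + island_len - spec.read_length + 1, size=count)
        for k, s in enumerate(np.sort(starts)):
            reads.append(
                (
                    f"isl{ii}_{k:05d}",
                    spec.names[gi],
                    int(s),
                    sequences[gi][s : s + spec.read_length],
                )
            )
        counts[gi] += count

    paths = {
        "sam": out / "pool.sam",
        "fasta": out / "references.fasta",
        "taxonomy": out / "taxonomy.tsv",
        "truth": out / "truth.tsv",
    }
    refs = [(spec.names[gi], len(sequences[gi])) for gi in range(len(sequences))]
    write_sam(paths["sam"], refs, reads)
    write_fasta(paths["fasta"], list(zip(spec.names, sequences)))
    with open(paths["taxonomy"], "w") as fh:
        for name in spec.names:
            fh.write(f"{name}\t{name}_sp\t{name}_strain1\n")
    with open(paths["truth"], "w") as fh:
        fh.write("ref_id\tspecies_key\tdna_proportion\treads_generated\tgenome_length\tislands\n")
        for gi, name in enumerate(spec.names):
            coords = ";".join(f"{a}-{b}" for a, b in island_coords.get(gi, []))
            fh.write(
                f"{name}\t{name}_sp\t{spec.pool_proportions[gi]:.10g}\t"
                f"{int(counts[gi])}\t{len(sequences[gi])}\t{coords}\n"
            )
    return paths


def gc_ladder_spec(
    total_reads: int = 70_000,
    genome_length: int = 500_000,
    bias: GcBiasModel | None = None,
    seed: int = 0,
) -> SimulationSpec:
    """Equal-DNA calibration pool over the seven-genome GC ladder.

    Mirrors the calibration design for bias-model fitting: equal DNA
    amounts of genomes spanning a wide GC range, so pooled
    normalized-coverage curves expose the bias surface directly.
    """
    n = len(GC_LADDER)
    return SimulationSpec(
        genomes=[(genome_length, gc) for gc in GC_LADDER],
        pool_proportions=[1.0 / n] * n,
        total_reads=total_reads,
        bias=bias,
        seed=seed,
    )
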