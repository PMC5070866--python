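"""Readers and count structures for alignments, references and taxonomy.

Everything downstream works from two aggregates produced here: the
per-genome histogram of 100 bp window GC content (``W_i``) and the
per-genome counts of read starts falling in windows of each GC
percentage point (``Rst_i``).  Windows are consecutive, non-overlapping
and fixed-length; a tail shorter than the window size is dropped, and
reads starting in a dropped tail are excluded from GC counting but kept
for abundance counting.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pysam
from Bio import SeqIO

IUPAC_CODES = set(b"ACGTRYSWKMBDVHN")

#: GC points are integers on the 0..100 percent scale.
N_GC_BINS = 101


def _round_half_up(x: float) -> int:
    return int(np.floor(x + 0.5))


@dataclass
class ReferenceGenome:
    """One reference sequence with its GC window decomposition.

    ``window_gc`` holds the integer GC point of every full window in
    genome order; dropped windows (more than half ambiguous bases) are
    recorded as -1 so read starts can still be located.
    """

    ref_id: str
    length: int
    gc_percent: float
    window_gc_histogram: dict[int, int]
    window_size: int = 100
    window_gc: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=np.int16), repr=False)

    @property
    def n_windows(self) -> int:
        return self.length // self.window_size

    @property
    def w_total(self) -> int:
        """Count of retained windows (W_Total for this genome)."""
        return sum(self.window_gc_histogram.values())

    @property
    def length_mb(self) -> float:
        return self.length / 1e6


@dataclass
class ReadAssignment:
    """A classified read: where it mapped and its own GC content."""

    read_id: str
    ref_id: str
    start: int  # 0-based
    read_gc: float
    n_best_hits: int = 1
    species_key: str | None = None
    weight: float = 1.0


@dataclass
class TaxonomyMap:
    """ref_id -> (species_key, strain_key) lookup."""

    entries: dict[str, tuple[str, str]]

    def species(self, ref_id: str) -> str:
        try:
            return self.entries[ref_id][0]
        except KeyError:
            raise KeyError(f"reference {ref_id!r} missing from taxonomy map") from None

    def strain(self, ref_id: str) -> str:
        return self.entries[ref_id][1]

    def validate(self, ref_ids) -> None:
        missing = sorted({r for r in ref_ids if r not in self.entries})
        if missing:
            raise ValueError(f"taxonomy map lacks entries for: {', '.join(missing)}")

    @classmethod
    def from_tsv(cls, path: str | Path) -> "TaxonomyMap":
        entries: dict[str, tuple[str, str]] = {}
        with open(path, newline="") as fh:
            for row in csv.reader(fh, delimiter="\t"):
                if not row or row[0].startswith("#"):
                    continue
                if len(row) < 3:
                    raise ValueError(f"taxonomy rows need 3 columns, got: {row}")
                entries[row[0]] = (row[1], row[2])
        return cls(entries)

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            for ref_id, (sp, st) in sorted(self.entries.items()):
                w.writerow([ref_id, sp, st])


@dataclass
class GcCountTable:
    """Read-start counts per (reference, GC point) with exclusion ledger.

    ``remainder`` counts reads whose start fell in a dropped tail or in
    an ambiguous window — excluded from GC counting, not lost.
    """

    counts: dict[str, np.ndarray]
    remainder: dict[str, int]

    @property
    def rst_total(self) -> int:
        return int(sum(int(c.sum()) for c in self.counts.values()))

    def rst(self, ref_id: str) -> np.ndarray:
        return self.counts[ref_id]

    def to_tsv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["ref_id", "gc_point", "read_starts"])
            for ref_id in sorted(self.counts):
                arr = self.counts[ref_id]
                for i in np.nonzero(arr)[0]:
                    w.writerow([ref_id, int(i), int(arr[i])])


def _window_gc_points(seq: bytes, window_size: int) -> np.ndarray:
    """Integer GC point per full window; -1 where >50% bases ambiguous.

    Ambiguous bases are excluded from both numerator and denominator,
    so a window's GC resolution reflects only its unambiguous bases.
    """
    arr = np.frombuffer(seq, dtype=np.uint8)
    n_windows = len(arr) // window_size
    if n_windows == 0:
        return np.empty(0, dtype=np.int16)
    arr = arr[: n_windows * window_size].reshape(n_windows, window_size)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    counted = is_acgt.sum(axis=1)
    gc = is_gc.sum(axis=1)
    points = np.full(n_windows, -1, dtype=np.int16)
    ok = counted > window_size // 2
    points[ok] = np.floor(100.0 * gc[ok] / counted[ok] + 0.5).astype(np.int16)
    return points


def load_references(fasta_path: str | Path, window_size: int = 100) -> list[ReferenceGenome]:
    """Load reference genomes and compute their GC window histograms.

    Raises on missing files, empty sequences, and characters outside
    the IUPAC nucleotide alphabet.
    """
    path = Path(fasta_path)
    if not path.exists():
        raise FileNotFoundError(path)
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    genomes: list[ReferenceGenome] = []
    for record in SeqIO.parse(str(path), "fasta"):
        seq = bytes(str(record.seq).upper(), "ascii")
        if not seq:
            raise ValueError(f"empty sequence for reference {record.id!r}")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ValueError(
                f"non-IUPAC characters in {record.id!r}: "
                + ", ".join(chr(b) for b in sorted(bad))
            )
        arr = np.frombuffer(seq, dtype=np.uint8)
        is_gc = (arr == ord("G")) | (arr == ord("C"))
        is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
        counted = int(is_acgt.sum())
        gc_percent = 100.0 * int(is_gc.sum()) / counted if counted else 0.0
        window_gc = _window_gc_points(seq, window_size)
        hist_vals, hist_counts = np.unique(window_gc[window_gc >= 0], return_counts=True)
        genomes.append(
            ReferenceGenome(
                ref_id=record.id,
                length=len(seq),
                gc_percent=gc_percent,
                window_gc_histogram={int(v): int(c) for v, c in zip(hist_vals, hist_counts)},
                window_size=window_size,
                window_gc=window_gc,
            )
        )
    if not genomes:
        raise ValueError(f"no sequences found in {path}")
    return genomes


def _read_gc(seq: str | None) -> float:
    if not seq:
        return 0.0
    arr = np.frombuffer(bytes(seq.upper(), "ascii"), dtype=np.uint8)
    is_gc = (arr == ord("G")) | (arr == ord("C"))
    is_acgt = is_gc | (arr == ord("A")) | (arr == ord("T"))
    counted = int(is_acgt.sum())
    return 100.0 * int(is_gc.sum()) / counted if counted else 0.0


def load_alignments(
    sam_path: str | Path,
    min_mapq: int = 0,
    genomes: list[ReferenceGenome] | None = None,
) -> list[ReadAssignment]:
    """Load mapped records from SAM/BAM as :class:`ReadAssignment`.

    Unmapped and secondary-duplicate-free records are kept as-is;
    ``n_best_hits`` is the number of records sharing the query name
    (the upstream aligner's reporting mode decides what appears here).
    SAM POS is 1-based; internal starts are 0-based.
    """
    path = Path(sam_path)
    if not path.exists():
        raise FileNotFoundError(path)
    known = {g.ref_id: g.length for g in genomes} if genomes is not None else None
    assignments: list[ReadAssignment] = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        unknown: set[str] = set()
        for i, rec in enumerate(fh):
            if rec.is_unmapped:
                continue
            if rec.mapping_quality < min_mapq:
                continue
            if rec.reference_name is None or rec.query_name is None:
                raise ValueError(f"malformed alignment record at line {i + 1}")
            if known is not None and rec.reference_name not in known:
                unknown.add(rec.reference_name)
                continue
            assignments.append(
                ReadAssignment(
                    read_id=rec.query_name,
                    ref_id=rec.reference_name,
                    start=rec.reference_start,
                    read_gc=_read_gc(rec.query_sequence),
                )
            )
        if known is not None and unknown:
            raise ValueError(
                "alignment references absent from loaded genomes: "
                + ", ".join(sorted(unknown))
            )
    counts: dict[str, int] = {}
    for a in assignments:
        counts[a.read_id] = counts.get(a.read_id, 0) + 1
    for a in assignments:
        a.n_best_hits = counts[a.read_id]
    return assignments


def gc_count_table(
    assignments: list[ReadAssignment],
    genomes: list[ReferenceGenome],
) -> GcCountTable:
    """Count read starts per (reference, window GC point).

    Reads starting past the last full window, or in a window dropped
    for ambiguity, go to the per-reference ``remainder`` ledger.
    """
    by_ref = {g.ref_id: g for g in genomes}
    counts = {g.ref_id: np.zeros(N_GC_BINS, dtype=np.int64) for g in genomes}
    remainder = {g.ref_id: 0 for g in genomes}
    for a in assignments:
        genome = by_ref.get(a.ref_id)
        if genome is None:
            raise KeyError(f"assignment to unknown reference {a.ref_id!r}")
        if not 0 <= a.start < genome.length:
            raise ValueError(
                f"read {a.read_id!r} start {a.start} outside reference "
                f"{a.ref_id!r} of length {genome.length}"
            )
        w = a.start // genome.window_size
        if w >= genome.n_windows or genome.window_gc[w] < 0:
            remainder[a.ref_id] += 1
        else:
            counts[a.ref_id][genome.window_gc[w]] += 1
    return GcCountTable(counts=counts, remainder=remainder)
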