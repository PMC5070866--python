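"""Detection of bacterial hits whose reads cluster in genomic islands.

Reads mapping to a horizontally transferred island really originate
from the island's donor, so a reference hit supported only by a few
tight read clusters is a false positive.  Under genuine presence reads
fall roughly uniformly over the genome and the mean spacing between
neighboring read starts is close to G/N; clustering pushes it far
below.  Two complementary checks exploit this:

* a one-sample t-test of the observed mean neighbor spacing against
  the uniform null mean G/N (one-sided, alternative "smaller");
* a uniform-model genome-size estimate from the read-start range —
  if even its upper confidence bound is a small fraction of the real
  genome length, the reads cannot be genome-wide.

A short-spacing heuristic (fraction of spacings below a few bp) is
available as an optional extra filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

CLASS_KEEP = "keep"
CLASS_UNCERTAIN = "uncertain"
CLASS_FILTERED = "filtered"
CLASS_TOO_FEW = "too_few_reads"


class TooFewReadsError(ValueError):
    """Raised when a per-reference statistic needs more reads."""


@dataclass
class FilterConfig:
    """Thresholds controlling hit classification.

    ``short_fraction_limit`` is off by default; the 10 bp spacing
    threshold is only a suggested operating point.  The uncertain band
    flags hits whose genome-size upper bound is 10–50% of the actual
    size for manual review rather than automatic filtration.
    """

    p_threshold: float = 1e-3
    short_distance_bp: int = 10
    short_fraction_limit: float | None = None
    uncertain_band: tuple[float, float] = (0.10, 0.50)
    min_reads: int = 3
    size_confidence: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.p_threshold < 1:
            raise ValueError("p_threshold must be in (0, 1)")
        lo, hi = self.uncertain_band
        if not 0 < lo < hi <= 1:
            raise ValueError("uncertain_band must satisfy 0 < lo < hi <= 1")


@dataclass
class IslandTestResult:
    """Per-reference clustering diagnostics and classification."""

    ref_id: str
    n_reads: int
    distances: np.ndarray = field(repr=False)
    mean_distance: float = float("nan")
    null_mean: float = float("nan")
    t_stat: float = float("nan")
    p_value: float = float("nan")
    short_distance_fraction: float = float("nan")
    genome_size_estimate: float = float("nan")
    genome_size_upper_bound: float = float("nan")
    classification: str = CLASS_TOO_FEW


def neighbor_distances(starts) -> np.ndarray:
    """Spacings between consecutive sorted read starts (N-1 values).

    No wraparound gap between the last and first read is added: the
    N-1 forward differences are exactly what the G/N null describes.
    """
    starts = np.asarray(starts, dtype=np.int64)
    if starts.size < 2:
        raise TooFewReadsError("need at least 2 read starts for spacings")
    return np.diff(np.sort(starts))


def island_ttest(distances, G: int, N: int) -> tuple[float, float]:
    """One-sample t-test of mean neighbor spacing against G/N.

    One-sided with alternative mean < G/N, since island clustering can
    only shrink the mean spacing.  A zero-variance sample (reads in a
    perfect stack or ladder) has no t-statistic; by convention p = 0
    when the mean is below the null and p = 1 otherwise, so degenerate
    clusters are still filtered.
    """
    d = np.asarray(distances, dtype=np.float64)
    if d.size < 2:
        raise TooFewReadsError("need at least 2 spacings (3 reads) for the t-test")
    null_mean = G / N
    sd = d.std(ddof=1)
    if sd == 0.0:
        mean = d.mean()
        if mean < null_mean:
            return -np.inf, 0.0
        return np.inf if mean > null_mean else 0.0, 1.0
    t, p = stats.ttest_1samp(d, popmean=null_mean, alternative="less")
    return float(t), float(p)


def short_distance_fraction(distances, threshold_bp: int = 10) -> float:
    """Fraction of spacings strictly below ``threshold_bp``."""
    d = np.asarray(distances)
    if d.size == 0:
        raise TooFewReadsError("no spacings to evaluate")
    return float((d < threshold_bp).mean())


def estimate_genome_size(starts, confidence: float = 0.95) -> tuple[float, float]:
    """Genome size from the read-start range under a uniform model.

    For N uniform points on (0, G) the range R has E[R] = G(N-1)/(N+1),
    giving the unbiased-style point estimate R(N+1)/(N-1).  R/G follows
    a Beta(N-1, 2) distribution, so an upper confidence bound at level
    ``confidence`` is R / q with q the (1-confidence) quantile of that
    Beta: P(G <= R/q) = P(R/G >= q) = confidence.
    """
    starts = np.asarray(starts, dtype=np.float64)
    N = starts.size
    if N < 3:
        raise TooFewReadsError("need at least 3 reads for a genome-size estimate")
    span = float(starts.max() - starts.min())
    estimate = span * (N + 1) / (N - 1)
    q = stats.beta.ppf(1.0 - confidence, N - 1, 2)
    upper = span / q if q > 0 else float("inf")
    return estimate, upper


def classify_hit(result: IslandTestResult, G: int, config: FilterConfig) -> str:
    """Keep / uncertain / filtered decision for one reference hit."""
    if result.n_reads < config.min_reads:
        return CLASS_TOO_FEW
    lo, hi = config.uncertain_band
    if result.p_value < config.p_threshold:
        return CLASS_FILTERED
    if result.genome_size_upper_bound < lo * G:
        return CLASS_FILTERED
    if (
        config.short_fraction_limit is not None
        and result.short_distance_fraction > config.short_fraction_limit
    ):
        return CLASS_FILTERED
    if lo * G <= result.genome_size_upper_bound < hi * G:
        return CLASS_UNCERTAIN
    return CLASS_KEEP


def distance_histogram(distances, bin_edges) -> list[tuple[str, int]]:
    """Spacing counts per bin, with a final open bin covering the tail.

    Returned labels are half-open interval strings; counts always sum
    to the number of spacings.
    """
    d = np.asarray(distances)
    edges = list(bin_edges)
    if not edges:
        return [("[0, inf)", int(d.size))]
    rows: list[tuple[str, int]] = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        rows.append((f"[{lo}, {hi})", int(((d >= lo) & (d < hi)).sum())))
    rows.append((f"[{edges[-1]}, inf)", int((d >= edges[-1]).sum())))
    rows.insert(0, (f"(-inf, {edges[0]})", int((d < edges[0]).sum())))
    if rows[0][1] == 0:
        rows.pop(0)
    return rows


def evaluate_reference(
    ref_id: str,
    starts,
    G: int,
    config: FilterConfig | None = None,
) -> IslandTestResult:
    """Run every clustering diagnostic for one reference and classify it."""
    config = config or FilterConfig()
    starts = np.asarray(starts, dtype=np.int64)
    N = int(starts.size)
    if N < config.min_reads:
        return IslandTestResult(
            ref_id=ref_id,
            n_reads=N,
            distances=np.empty(0, dtype=np.int64),
            null_mean=G / N if N else float("nan"),
        )
    d = neighbor_distances(starts)
    t, p = island_ttest(d, G, N)
    est, upper = estimate_genome_size(starts, confidence=config.size_confidence)
    result = IslandTestResult(
        ref_id=ref_id,
        n_reads=N,
        distances=d,
        mean_distance=float(d.mean()),
        null_mean=G / N,
        t_stat=t,
        p_value=p,
        short_distance_fraction=short_distance_fraction(d, config.short_distance_bp),
        genome_size_estimate=est,
        genome_size_upper_bound=upper,
        classification=CLASS_KEEP,
    )
    result.classification = classify_hit(result, G, config)
    return result
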