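"""Normalized-coverage curves and the eight-parameter GC-bias model.

The observable is normalized coverage per integer GC point i:

    NormCov_i = (Rst_i / W_i) / (Rst_Total / W_Total)

for a single genome, where Rst_i counts read starts in 100 bp windows
of GC% i and W_i counts such windows.  In a pooled sample of m genomes
the total read starts are attributed equally to every member, so under-
or over-representation caused by GC bias shows up in the curve instead
of being normalized away:

    NormCov_ij = (Rst_ij / W_ij) / ((Rst_Total / m) / W_Totalj)

The bias surface over (read GC, genome GC) is modelled as a Gaussian
peak plus a cubic polynomial in read GC and a logarithmic genome-GC
term:

    NormCov(GC_R, GC_G) = t1*exp(-0.5*((GC_R-t2)/t3)^2) + t4
                          + t5*GC_R + t6*GC_R^2 + t7*GC_R^3
                          + t8*ln(GC_G)

fitted by nonlinear least squares.  Predictions are floored at 0.01 so
reciprocal read weights stay bounded.  The bias is specific to one
sequencing setup: the model is meant to be refitted per platform from
curves of individually sequenced genomes spanning a wide GC range and
shipped as JSON coefficients.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares

DEFAULT_FLOOR = 0.01


@dataclass
class GcCoverageCurve:
    """Normalized coverage per GC point for one genome.

    ``context`` is ``"single"`` or ``"pooled"``; only bins with at
    least one window appear in ``points``.
    """

    ref_id: str
    genome_gc: float
    gc_points: np.ndarray
    normcov: np.ndarray
    read_starts: np.ndarray
    windows: np.ndarray
    context: str = "single"
    pool_size: int = 1


@dataclass
class GcBiasModel:
    """Fitted coefficients t1..t8 plus the prediction floor."""

    theta: tuple[float, ...]
    floor: float = DEFAULT_FLOOR
    residual_se: float | None = None
    dof: int | None = None
    n_iterations: int | None = None
    tolerance: float | None = None
    converged: bool = True

    def __post_init__(self) -> None:
        self.theta = tuple(float(t) for t in self.theta)
        if len(self.theta) != 8:
            raise ValueError("GcBiasModel needs exactly 8 coefficients")
        if self.floor <= 0:
            raise ValueError("prediction floor must be positive")
        if self.theta[2] == 0:
            raise ValueError("Gaussian width coefficient must be nonzero")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "theta": list(self.theta),
            "floor": self.floor,
            "diagnostics": {
                "residual_se": self.residual_se,
                "dof": self.dof,
                "n_iterations": self.n_iterations,
                "tolerance": self.tolerance,
                "converged": self.converged,
            },
        }
        Path(path).write_text(json.dumps(payload, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GcBiasModel":
        payload = json.loads(Path(path).read_text())
        diag = payload.get("diagnostics", {})
        return cls(
            theta=tuple(payload["theta"]),
            floor=payload.get("floor", DEFAULT_FLOOR),
            residual_se=diag.get("residual_se"),
            dof=diag.get("dof"),
            n_iterations=diag.get("n_iterations"),
            tolerance=diag.get("tolerance"),
            converged=diag.get("converged", True),
        )


class FitConvergenceError(RuntimeError):
    """Nonlinear least squares did not converge; diagnostics attached."""

    def __init__(self, message: str, diagnostics: dict):
        super().__init__(message)
        self.diagnostics = diagnostics


def normcov_single(rst, windows, ref_id: str = "", genome_gc: float = float("nan")) -> GcCoverageCurve:
    """Single-genome normalized coverage curve.

    ``rst`` and ``windows`` are aligned per-GC-point arrays (index =
    GC point).  Bins without windows are omitted.
    """
    rst = np.asarray(rst, dtype=np.float64)
    windows = np.asarray(windows, dtype=np.float64)
    if rst.shape != windows.shape:
        raise ValueError("rst and windows must align per GC point")
    w_total = windows.sum()
    rst_total = rst.sum()
    if w_total <= 0 or rst_total <= 0:
        raise ValueError("need positive window and read-start totals")
    occ = windows > 0
    gc_points = np.nonzero(occ)[0]
    normcov = (rst[occ] / windows[occ]) / (rst_total / w_total)
    return GcCoverageCurve(
        ref_id=ref_id,
        genome_gc=genome_gc,
        gc_points=gc_points,
        normcov=normcov,
        read_starts=rst[occ].astype(np.int64),
        windows=windows[occ].astype(np.int64),
        context="single",
    )


def normcov_pooled(
    rst_j,
    windows_j,
    rst_total: int,
    m: int,
    ref_id: str = "",
    genome_gc: float = float("nan"),
) -> GcCoverageCurve:
    """Pooled-sample normalized coverage for one member genome.

    The per-genome expected density is the equal share Rst_Total/m over
    that genome's own retained windows, so a genome whose reads exceed
    its share shows normcov > 1 across its occupied bins.  With m = 1
    this reduces exactly to the single-genome curve.
    """
    if m < 1:
        raise ValueError("pool size m must be >= 1")
    rst_j = np.asarray(rst_j, dtype=np.float64)
    windows_j = np.asarray(windows_j, dtype=np.float64)
    if rst_j.shape != windows_j.shape:
        raise ValueError("rst and windows must align per GC point")
    w_totalj = windows_j.sum()
    if w_totalj <= 0 or rst_total <= 0:
        raise ValueError("need positive window and read-start totals")
    occ = windows_j > 0
    gc_points = np.nonzero(occ)[0]
    expected_per_window = (rst_total / m) / w_totalj
    normcov = (rst_j[occ] / windows_j[occ]) / expected_per_window
    return GcCoverageCurve(
        ref_id=ref_id,
        genome_gc=genome_gc,
        gc_points=gc_points,
        normcov=normcov,
        read_starts=rst_j[occ].astype(np.int64),
        windows=windows_j[occ].astype(np.int64),
        context="pooled" if m > 1 else "single",
        pool_size=m,
    )


def gaussian_term(gc_read, t1: float, t2: float, t3: float, t4: float):
    """Bell-shaped component of the bias surface, peak t1+t4 at t2."""
    if t3 == 0:
        raise ValueError("Gaussian width must be nonzero")
    gc_read = np.asarray(gc_read, dtype=np.float64)
    out = t1 * np.exp(-0.5 * ((gc_read - t2) / t3) ** 2) + t4
    return float(out) if out.ndim == 0 else out


def _raw_surface(gc_read, gc_genome, theta):
    t1, t2, t3, t4, t5, t6, t7, t8 = theta
    gc_read = np.asarray(gc_read, dtype=np.float64)
    gc_genome = np.asarray(gc_genome, dtype=np.float64)
    return (
        gaussian_term(gc_read, t1, t2, t3, t4)
        + t5 * gc_read
        + t6 * gc_read**2
        + t7 * gc_read**3
        + t8 * np.log(gc_genome)
    )


def predict_normcov(gc_read, gc_genome, model: GcBiasModel):
    """Predicted normalized coverage, floored at ``model.floor``."""
    gc_genome = np.asarray(gc_genome, dtype=np.float64)
    if np.any(gc_genome <= 0):
        raise ValueError("genome GC must be positive (log term)")
    raw = _raw_surface(gc_read, gc_genome, model.theta)
    out = np.maximum(raw, model.floor)
    return float(out) if out.ndim == 0 else out


def read_weight(gc_read, gc_genome, model: GcBiasModel):
    """Reciprocal of predicted normalized coverage; capped at 1/floor."""
    return 1.0 / predict_normcov(gc_read, gc_genome, model)


def fit_gc_model(
    curves: list[GcCoverageCurve],
    init: tuple[float, ...] | None = None,
    tol: float = 1e-5,
    max_iter: int = 50,
    min_windows: int = 5,
    floor: float = DEFAULT_FLOOR,
    weight_by_windows: bool = False,
) -> GcBiasModel:
    """Fit the bias surface to observed curves by nonlinear least squares.

    Observations are (bin GC point, genome GC, normcov) triples pooled
    across genomes.  Bins supported by fewer than ``min_windows``
    windows are excluded: their normcov estimates are dominated by
    shot noise.  At least two distinct genome GC values are required,
    otherwise the log(GC_G) term is indistinguishable from the
    intercept.  Non-convergence raises with diagnostics rather than
    returning a silently bad model.
    """
    gc_r, gc_g, y, w = [], [], [], []
    for curve in curves:
        keep = curve.windows >= min_windows
        gc_r.append(curve.gc_points[keep].astype(np.float64))
        gc_g.append(np.full(int(keep.sum()), curve.genome_gc))
        y.append(curve.normcov[keep])
        w.append(curve.windows[keep].astype(np.float64))
    gc_r = np.concatenate(gc_r)
    gc_g = np.concatenate(gc_g)
    y = np.concatenate(y)
    w = np.sqrt(np.concatenate(w)) if weight_by_windows else np.ones_like(y)
    if len({round(g, 6) for g in gc_g}) < 2:
        raise ValueError("need curves from >= 2 distinct genome GC values")
    if y.size < 20:
        raise ValueError(f"need >= 20 data points to fit 8 coefficients, got {y.size}")

    def residuals(theta):
        return w * (_raw_surface(gc_r, gc_g, theta) - y)

    amp = float(y.max() - y.min())
    center = float(gc_r.mean())
    width = float(gc_r.std()) or 1.0
    base = float(y.min())
    if init is not None:
        starts = [tuple(init)]
    else:
        # deterministic multistart over Gaussian center/width: the
        # only nonlinear parameters, and the ones local minima hide in
        starts = [
            (amp, c, s, base, 0.0, 0.0, 0.0, 0.0)
            for c in (center - width, center, center + width)
            for s in (0.5 * width, width)
        ]
    result = None
    for x0 in starts:
        candidate = least_squares(
            residuals,
            x0=np.asarray(x0, dtype=np.float64),
            method="lm",
            xtol=tol * 1e-3,
            ftol=tol * 1e-3,
            gtol=1e-12,
            max_nfev=max_iter * 40,
        )
        if result is None or (candidate.success and candidate.cost < result.cost):
            result = candidate
    dof = y.size - 8
    resid = residuals(result.x)
    residual_se = float(np.sqrt((resid**2).sum() / dof)) if dof > 0 else float("nan")
    diagnostics = {
        "status": int(result.status),
        "message": result.message,
        "n_evaluations": int(result.nfev),
        "residual_se": residual_se,
        "dof": dof,
    }
    if not result.success:
        raise FitConvergenceError(
            f"GC model fit did not converge: {result.message}", diagnostics
        )
    if result.x[2] == 0 or not math.isfinite(residual_se):
        raise FitConvergenceError("degenerate fit (zero Gaussian width)", diagnostics)
    return GcBiasModel(
        theta=tuple(result.x),
        floor=floor,
        residual_se=residual_se,
        dof=dof,
        n_iterations=int(result.nfev),
        tolerance=tol,
        converged=True,
    )


def curves_from_counts(
    table,
    genomes,
    pooled: bool = True,
) -> list[GcCoverageCurve]:
    """Build per-genome curves from a GC count table.

    ``pooled=True`` applies the equal-share pooled normalization (the
    right choice whenever the table comes from one multi-genome
    sample); ``pooled=False`` normalizes each genome by its own read
    total.
    """
    m = len(genomes)
    rst_total = table.rst_total
    curves = []
    for g in genomes:
        rst = table.rst(g.ref_id)
        windows = np.zeros_like(rst, dtype=np.int64)
        for i, c in g.window_gc_histogram.items():
            windows[i] = c
        if rst.sum() == 0:
            continue
        if pooled:
            curve = normcov_pooled(rst, windows, rst_total, m, ref_id=g.ref_id, genome_gc=g.gc_percent)
        else:
            curve = normcov_single(rst, windows, ref_id=g.ref_id, genome_gc=g.gc_percent)
        curves.append(curve)
    return curves


def curves_to_tsv(curves: list[GcCoverageCurve], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("ref_id\tgenome_gc\tgc_point\tnormcov\tread_starts\twindows\tcontext\tpool_size\n")
        for c in curves:
            for i in range(c.gc_points.size):
                fh.write(
                    f"{c.ref_id}\t{c.genome_gc:.6g}\t{int(c.gc_points[i])}\t"
                    f"{c.normcov[i]:.10g}\t{int(c.read_starts[i])}\t"
                    f"{int(c.windows[i])}\t{c.context}\t{c.pool_size}\n"
                )


def curves_from_tsv(path: str | Path) -> list[GcCoverageCurve]:
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    curves = []
    for (ref_id, genome_gc, context, pool_size), grp in df.groupby(
        ["ref_id", "genome_gc", "context", "pool_size"], sort=False
    ):
        curves.append(
            GcCoverageCurve(
                ref_id=str(ref_id),
                genome_gc=float(genome_gc),
                gc_points=grp["gc_point"].to_numpy(),
                normcov=grp["normcov"].to_numpy(dtype=np.float64),
                read_starts=grp["read_starts"].to_numpy(),
                windows=grp["windows"].to_numpy(),
                context=str(context),
                pool_size=int(pool_size),
            )
        )
    return curves
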