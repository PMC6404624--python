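"""Centromere localization from GBS marker density.

Genotyping-by-sequencing libraries built with a methylation-sensitive
restriction enzyme are depleted of markers in highly methylated
heterochromatin, so the centromere of a chromosome shows up as a dip in the
smoothed density of marker positions.  A Gaussian kernel density estimate of
the positions is computed on an even grid, its stationary points are located
as sign changes of the finite-difference derivative, and the second
stationary point from the low-coordinate end (the interior minimum between
the two arm density peaks of a two-armed chromosome) defines the estimated
interval: its start and end are the grid positions flanking that point.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome_model import CentromereTable, MarkerMap

__all__ = [
    "DensityCurve",
    "CentromereEstimate",
    "silverman_bandwidth",
    "kde",
    "stationary_points",
    "estimate_centromere",
    "estimate_for_chromosome",
    "complete_centromere_table",
]


@dataclass
class DensityCurve:
    """Smoothed marker-position density on an even grid (positions in bp)."""

    grid: np.ndarray
    density: np.ndarray
    bandwidth: float

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        self.density = np.asarray(self.density, dtype=float)
        if self.grid.ndim != 1 or self.grid.shape != self.density.shape:
            raise ValueError("grid and density must be matching 1-D arrays")
        if not np.all(np.diff(self.grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(self.density < 0):
            raise ValueError("density must be nonnegative")

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


@dataclass
class CentromereEstimate:
    """Estimated centromere interval with the stationary points seen on the way."""

    chromosome: str
    start: float
    end: float
    n_markers: int
    diagnostics: list[tuple[float, str]] = field(default_factory=list)


def silverman_bandwidth(positions: np.ndarray) -> float:
    """Rule-of-thumb bandwidth 0.9 * min(sd, IQR/1.34) * n^(-1/5).

    Mirrors the common default of KDE routines for univariate data; falls
    back to the non-zero member when sd or IQR degenerates to zero.
    """
    x = np.asarray(positions, dtype=float)
    n = x.size
    sd = float(np.std(x, ddof=1)) if n > 1 else 0.0
    q75, q25 = np.percentile(x, [75, 25])
    iqr = float(q75 - q25) / 1.34
    spread = min(d for d in (sd, iqr) if d > 0) if (sd > 0 or iqr > 0) else 1.0
    return 0.9 * spread * n ** (-1 / 5)


def kde(positions, bandwidth: float | None = None, n_grid: int = 512) -> DensityCurve:
    """Gaussian KDE of marker positions on an even grid over [min-3h, max+3h]."""
    x = np.sort(np.asarray(positions, dtype=float))
    if x.size < 10:
        raise ValueError(
            f"need at least 10 marker positions for a reliable density, got {x.size}"
        )
    h = silverman_bandwidth(x) if bandwidth is None else float(bandwidth)
    if h <= 0:
        raise ValueError("bandwidth must be positive")
    grid = np.linspace(x[0] - 3 * h, x[-1] + 3 * h, int(n_grid))
    # direct kernel sum, chunked over grid to bound memory at large n
    dens = np.empty_like(grid)
    norm = 1.0 / (x.size * h * np.sqrt(2 * np.pi))
    step = max(1, int(2e7) // max(x.size, 1))
    for i in range(0, grid.size, step):
        z = (grid[i : i + step, None] - x[None, :]) / h
        dens[i : i + step] = np.exp(-0.5 * z * z).sum(axis=1) * norm
    return DensityCurve(grid=grid, density=dens, bandwidth=h)


def stationary_points(curve: DensityCurve) -> list[tuple[int, str]]:
    """Stationary points of the density as (grid index, kind) from low to high.

    A sign change of the first differences marks a maximum (+ to -) or a
    minimum (- to +); a run of exactly-zero differences (a plateau) collapses
    to its midpoint grid index.
    """
    d = np.diff(curve.density)
    signs = np.sign(d)
    # run-length encode the sign sequence
    runs: list[tuple[int, int, int]] = []  # (sign, first diff index, last diff index)
    start = 0
    for i in range(1, len(signs) + 1):
        if i == len(signs) or signs[i] != signs[start]:
            runs.append((int(signs[start]), start, i - 1))
            start = i
    points: list[tuple[int, str]] = []
    prev_sign = 0
    for sign, lo, hi in runs:
        if sign == 0:
            # density flat over grid[lo .. hi+1]
            points.append(((lo + hi + 1) // 2, "plateau"))
            prev_sign = 0
        else:
            if prev_sign == 1 and sign == -1:
                points.append((lo, "max"))
            elif prev_sign == -1 and sign == 1:
                points.append((lo, "min"))
            prev_sign = sign
    return points


def estimate_centromere(curve: DensityCurve, chromosome: str = "NA", n_markers: int = 0) -> CentromereEstimate:
    """Estimate the centromere interval from a marker-density curve.

    The second stationary point from the low-coordinate end — for a
    two-armed chromosome the interior density minimum between the two arm
    peaks — is taken as the centromere location, and the grid positions
    flanking it as the interval.
    """
    pts = stationary_points(curve)
    if len(pts) < 3:
        raise ValueError(
            "no interior density minimum: need at least 3 stationary points "
            f"(found {len(pts)}); the marker density may be unimodal or monotone"
        )
    j, _kind = pts[1]
    lo = max(j - 1, 0)
    hi = min(j + 1, curve.grid.size - 1)
    diagnostics = [(float(curve.grid[i]), kind) for i, kind in pts]
    return CentromereEstimate(
        chromosome=chromosome,
        start=float(curve.grid[lo]),
        end=float(curve.grid[hi]),
        n_markers=n_markers,
        diagnostics=diagnostics,
    )


def estimate_for_chromosome(
    marker_map: MarkerMap,
    chromosome: str,
    bandwidth: float | None = None,
    n_grid: int = 512,
) -> CentromereEstimate:
    """KDE + interior-minimum estimate for one chromosome of a marker map."""
    pos = marker_map.positions(chromosome)
    curve = kde(pos, bandwidth=bandwidth, n_grid=n_grid)
    return estimate_centromere(curve, chromosome=chromosome, n_markers=pos.size)


def complete_centromere_table(
    marker_map: MarkerMap,
    centromeres: CentromereTable,
    bandwidth: float | None = None,
    n_grid: int = 512,
) -> CentromereTable:
    """Fill in missing centromere rows by density estimation.

    Annotated rows are kept untouched; estimation is applied only to
    chromosomes of the marker map that lack an interval.
    """
    have = set(centromeres.table["chromosome"])
    out = centromeres
    for chrom in marker_map.chromosomes:
        if chrom not in have:
            est = estimate_for_chromosome(marker_map, chrom, bandwidth=bandwidth, n_grid=n_grid)
            out = out.with_row(chrom, int(round(est.start)), int(round(est.end)), source="estimated")
    return out
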