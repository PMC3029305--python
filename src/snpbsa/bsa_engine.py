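"""Bulk-difference genome scans: pool differences, loess smoothing, extremes.

The bulk segregant signal at each marker is the difference between the
two pools' mean allele-difference intensities.  Each chromosome's raw
trace is smoothed by locally weighted polynomial regression (loess,
span expressed as a fraction of the chromosome's markers) and the
per-chromosome extremes of the smoothed trace — candidate QTL peaks —
are extracted.

Loess dialect: degree-2 local polynomial fitted by weighted least
squares over the ``ceil(span * m)`` nearest markers with tricube
weights ``w = (1 - (|dx| / max|dx|)^3)^3``, evaluated at each marker,
no robustness iterations.  For fixed marker positions and span the
smoother is a linear operator; :class:`LoessOperator` precomputes its
hat matrix once per map so that replicate simulations smooth by a
single matrix-vector product.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .array_signal import PoolSignalMatrix
from .genetic_models import GeneticMap

__all__ = [
    "ChromosomeTrace",
    "SmoothedTrace",
    "ChromosomeExtremes",
    "ExtremeRecord",
    "pool_difference",
    "loess_hat_matrix",
    "loess_smooth",
    "LoessOperator",
    "chromosome_extremes",
]


@dataclass(frozen=True)
class ChromosomeTrace:
    """Sorted marker positions with raw and smoothed values on one chromosome."""

    positions: np.ndarray
    raw: np.ndarray
    smoothed: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        raw = np.asarray(self.raw, dtype=float)
        smoothed = np.asarray(self.smoothed, dtype=float)
        if not (pos.size == raw.size == smoothed.size):
            raise ValueError("positions, raw, smoothed must have equal length")
        if np.any(np.diff(pos) < 0):
            raise ValueError("positions must be sorted")
        for arr in (pos, raw, smoothed):
            arr.setflags(write=False)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "raw", raw)
        object.__setattr__(self, "smoothed", smoothed)


@dataclass(frozen=True)
class SmoothedTrace:
    """Per-chromosome raw and loess-smoothed pool-difference traces.

    ``units`` records the position scale: cM for simulations, bp for
    real array data.  The two are never mixed within one trace.
    """

    chromosomes: dict[str, ChromosomeTrace]
    span: float
    units: str = "cM"

    def to_frame(self):
        import pandas as pd

        rows = [
            pd.DataFrame(
                {
                    "chrom": name,
                    "pos": tr.positions,
                    "raw": tr.raw,
                    "smoothed": tr.smoothed,
                }
            )
            for name, tr in self.chromosomes.items()
        ]
        return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class ChromosomeExtremes:
    max_value: float
    max_position: float
    min_value: float
    min_position: float


@dataclass(frozen=True)
class ExtremeRecord:
    """Smoothed-trace extremes (value and position) per chromosome."""

    chromosomes: dict[str, ChromosomeExtremes]


def pool_difference(high: PoolSignalMatrix, low: PoolSignalMatrix) -> np.ndarray:
    """Per-marker difference of pool mean signals (high minus low)."""
    if high.values.shape[1] != low.values.shape[1]:
        raise ValueError("pools do not share a marker set")
    if high.map is not low.map and high.map != low.map:
        raise ValueError("pools were generated on different maps")
    if high.values.shape[0] == 0 or low.values.shape[0] == 0:
        raise ValueError("empty pool")
    return high.values.mean(axis=0) - low.values.mean(axis=0)


def _neighborhood_size(n_points: int, span: float, degree: int) -> int:
    if not 0 < span <= 1:
        raise ValueError("span must be in (0, 1]")
    k = math.ceil(span * n_points)
    # the furthest neighbour gets tricube weight 0, so keep degree + 2
    # points for a solvable local fit
    return min(n_points, max(k, degree + 2))


def loess_hat_matrix(positions: np.ndarray, span: float, degree: int = 2) -> np.ndarray:
    """Linear smoother matrix L with ``smoothed = L @ values``.

    Row i holds the weighted-least-squares coefficients that evaluate
    the local degree-``degree`` fit at marker i from its
    ``ceil(span * m)`` nearest markers with tricube weights.
    """
    x = np.asarray(positions, dtype=float)
    m = x.size
    if m < max(4, degree + 2):
        raise ValueError(f"need >= {max(4, degree + 2)} points to smooth, got {m}")
    if np.any(np.diff(x) <= 0):
        raise ValueError("positions must be strictly increasing")
    k = _neighborhood_size(m, span, degree)
    L = np.zeros((m, m))
    for i in range(m):
        dist = np.abs(x - x[i])
        nbr = np.argpartition(dist, k - 1)[:k]
        d = dist[nbr]
        dmax = d.max()
        w = (1.0 - (d / dmax) ** 3) ** 3
        dx = x[nbr] - x[i]
        X = np.vander(dx, degree + 1, increasing=True)
        XtW = X.T * w
        try:
            coef = np.linalg.solve(XtW @ X, XtW)
        except np.linalg.LinAlgError:
            coef = np.linalg.pinv(XtW @ X) @ XtW
        L[i, nbr] = coef[0]
    return L


def loess_smooth(
    positions: np.ndarray, values: np.ndarray, span: float, degree: int = 2
) -> np.ndarray:
    """Loess-smooth ``values`` observed at ``positions`` (one chromosome)."""
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    if values.size != np.asarray(positions).size:
        raise ValueError("positions and values must have equal length")
    return loess_hat_matrix(positions, span, degree) @ values


class LoessOperator:
    """Precomputed per-chromosome loess smoother for a fixed map.

    Building the hat matrices is the expensive step; once built, each
    replicate's genome-wide raw vector is smoothed with one
    matrix-vector product per chromosome.
    """

    def __init__(self, gmap: GeneticMap, span: float = 0.25, degree: int = 2):
        self.map = gmap
        self.span = span
        self.degree = degree
        self._slices = gmap.chrom_slices()
        self._hats = {
            chrom: loess_hat_matrix(gmap.markers[chrom], span, degree)
            for chrom in gmap.chromosome_names
        }

    def smooth(self, raw: np.ndarray) -> np.ndarray:
        """Smooth a concatenated genome-wide raw vector, per chromosome."""
        raw = np.asarray(raw, dtype=float)
        out = np.empty_like(raw)
        for chrom, sl in self._slices.items():
            out[sl] = self._hats[chrom] @ raw[sl]
        return out

    def trace(self, raw: np.ndarray) -> SmoothedTrace:
        smoothed = self.smooth(raw)
        chroms = {
            chrom: ChromosomeTrace(self.map.markers[chrom], raw[sl], smoothed[sl])
            for chrom, sl in self._slices.items()
        }
        return SmoothedTrace(chromosomes=chroms, span=self.span, units="cM")


def chromosome_extremes(trace: SmoothedTrace) -> ExtremeRecord:
    """Max/min smoothed value and position per chromosome.

    Ties resolve to the smallest position (first occurrence along the
    sorted trace).
    """
    if not trace.chromosomes:
        raise ValueError("empty trace")
    out = {}
    for name, tr in trace.chromosomes.items():
        if tr.smoothed.size == 0:
            raise ValueError(f"chromosome {name!r} has no markers")
        imax = int(np.argmax(tr.smoothed))
        imin = int(np.argmin(tr.smoothed))
        out[name] = ChromosomeExtremes(
            max_value=float(tr.smoothed[imax]),
            max_position=float(tr.positions[imax]),
            min_value=float(tr.smoothed[imin]),
            min_position=float(tr.positions[imin]),
        )
    return ExtremeRecord(chromosomes=out)
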