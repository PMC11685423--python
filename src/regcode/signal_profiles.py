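"""Metaprofiles (reference-point and scaled-region) and the boundary
enrichment statistic.

``scale_regions`` rescales each interval body to a fixed number of bins
and appends fixed-width flank bins on either side, the layout used for
metaplots over regions of heterogeneous length; ``reference_point``
centres fixed-width bins on the interval midpoint. Bin values are means
of per-bp coverage, computed by exact fractional-overlap integration, so
bodies shorter than one bin are handled by weighting rather than error.
Flank bins extending beyond a chromosome end are missing values and are
excluded from column means (zero-filling would fabricate boundary dips).

The boundary statistic quantifies signal piling up at region borders
(e.g. 24nt siRNA / RdDM at enhancer edges): the mean over bins straddling
each boundary (``edge_bp`` inside plus ``edge_bp`` outside) divided by the
mean over interior body bins, with bins partially covering the edge zone
left out of both terms.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .genome_io import IntervalSet, StrandedSignal


@dataclass
class ProfileMatrix:
    """Rows = intervals, columns = bins; NaN marks missing flank bins."""

    values: np.ndarray
    mode: str  # reference_point | scale_regions
    flank_bp: int
    bin_bp: int
    body_bins: int
    row_lengths: np.ndarray  # interval lengths, bp

    @property
    def n_flank_bins(self) -> int:
        return self.flank_bp // self.bin_bp

    def metaplot(self) -> np.ndarray:
        """Per-column mean over rows, ignoring missing values."""
        return np.nanmean(self.values, axis=0)


def metaprofile(
    signal: StrandedSignal,
    intervals: IntervalSet,
    mode: str = "scale_regions",
    flank_bp: int = 5000,
    bin_bp: int = 50,
    body_bins: int = 100,
    strand: str = "both",
) -> ProfileMatrix:
    """Per-interval binned mean coverage in metaplot layout."""
    if bin_bp < 1:
        raise ValueError("bin_bp must be >= 1")
    if flank_bp % bin_bp != 0:
        raise ValueError("flank_bp must be a multiple of bin_bp")
    if mode not in ("scale_regions", "reference_point"):
        raise ValueError(f"unknown mode {mode!r}")
    nf = flank_bp // bin_bp
    ncols = 2 * nf + (body_bins if mode == "scale_regions" else 0)
    out = np.full((len(intervals), ncols), np.nan)
    for i, iv in enumerate(intervals):
        chrom_len = signal.chrom_lengths.get(iv.chrom)
        if mode == "scale_regions":
            edges = np.concatenate(
                [
                    iv.start - flank_bp + bin_bp * np.arange(nf + 1, dtype=float),
                    iv.start + iv.length * np.arange(1, body_bins + 1) / body_bins,
                    iv.end + bin_bp * np.arange(1, nf + 1, dtype=float),
                ]
            )
        else:
            center = (iv.start + iv.end) / 2
            edges = center - flank_bp + bin_bp * np.arange(2 * nf + 1, dtype=float)
        lo, hi = edges[:-1], edges[1:]
        areas = signal.integral(iv.chrom, lo, hi, strand=strand)
        vals = areas / (hi - lo)
        missing = lo < 0
        if chrom_len is not None:
            missing |= hi > chrom_len
        vals[missing] = np.nan
        out[i] = vals
    return ProfileMatrix(
        out,
        mode,
        flank_bp,
        bin_bp,
        body_bins if mode == "scale_regions" else 0,
        np.array([iv.length for iv in intervals], dtype=np.int64),
    )


@dataclass
class BoundaryEnrichment:
    ratio: float
    ratio_left: float
    ratio_right: float
    boundary_mean: float
    interior_mean: float
    note: str = ""


def boundary_enrichment(matrix: ProfileMatrix, edge_bp: int = 500) -> BoundaryEnrichment:
    """Boundary-over-interior signal ratio on a scale_regions matrix.

    Per row, the boundary zone at each side comprises the flank bins
    covering ``edge_bp`` outside the region plus the body bins falling
    entirely within ``edge_bp`` inside it (the count depends on the row's
    own length); the interior is the body bins entirely beyond the edge
    zone on both sides. Bins partially inside the edge zone belong to
    neither term. An interior mean of zero yields a +inf ratio.
    """
    if matrix.mode != "scale_regions":
        raise ValueError("boundary_enrichment requires a scale_regions matrix")
    if matrix.flank_bp < edge_bp:
        raise ValueError("flanks must be at least edge_bp wide")
    nf, B = matrix.n_flank_bins, matrix.body_bins
    ne_flank = edge_bp // matrix.bin_bp
    left_vals, right_vals, interior_vals = [], [], []
    for row, L in zip(matrix.values, matrix.row_lengths):
        n_in = int(edge_bp * B // L)  # body bins fully inside the edge zone
        n_in = min(n_in, B // 2)
        n_guard = min(int(math.ceil(edge_bp * B / L)), B // 2)
        body = row[nf : nf + B]
        left = np.concatenate([row[nf - ne_flank : nf], body[:n_in]])
        right = np.concatenate([body[B - n_in :] if n_in else body[:0], row[nf + B : nf + B + ne_flank]])
        inner = body[n_guard : B - n_guard]
        left_vals.append(left)
        right_vals.append(right)
        interior_vals.append(inner)
    left_mean = float(np.nanmean(np.concatenate(left_vals)))
    right_mean = float(np.nanmean(np.concatenate(right_vals)))
    boundary_mean = float(
        np.nanmean(np.concatenate([np.concatenate(left_vals), np.concatenate(right_vals)]))
    )
    interior_all = np.concatenate(interior_vals)
    interior_mean = float(np.nanmean(interior_all)) if interior_all.size else float("nan")
    note = ""
    if interior_mean == 0:
        ratio = ratio_l = ratio_r = math.inf
        note = "interior mean is zero; ratio undefined (+inf)"
    else:
        ratio = boundary_mean / interior_mean
        ratio_l = left_mean / interior_mean
        ratio_r = right_mean / interior_mean
    return BoundaryEnrichment(ratio, ratio_l, ratio_r, boundary_mean, interior_mean, note)
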