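"""Linkage-disequilibrium decay from unphased genotypes.

r^2 is the squared Pearson correlation of dosage vectors on pairwise-complete
samples (composite LD; no phasing). The decay curve bins every qualifying
intra-chromosome pair by physical distance; the half-decay distance is where
the binned curve first drops to half of its maximum.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from popdiv.variant_io import MISSING, GenotypeMatrix

logger = logging.getLogger(__name__)


@dataclass
class LDCurve:
    """Distance-binned mean r^2. Bin i covers [bin_edges[i], bin_edges[i+1])."""

    bin_edges: np.ndarray
    mean_r2: np.ndarray  # NaN for empty bins
    pair_count: np.ndarray

    @property
    def midpoints(self) -> np.ndarray:
        return (self.bin_edges[:-1] + self.bin_edges[1:]) / 2.0

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "bin_start": self.bin_edges[:-1].astype(int),
                "bin_end": self.bin_edges[1:].astype(int),
                "mean_r2": self.mean_r2,
                "n_pairs": self.pair_count.astype(int),
            }
        )


def genotype_r2(dosages_i: np.ndarray, dosages_j: np.ndarray) -> float:
    """Squared dosage correlation on pairwise-complete samples.

    Returns NaN when fewer than 3 shared non-missing samples remain or when
    either vector is constant on the shared set.
    """
    x = np.asarray(dosages_i, dtype=float)
    y = np.asarray(dosages_j, dtype=float)
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 3:
        return math.nan
    x = x[ok]
    y = y[ok]
    sx = x.std()
    sy = y.std()
    if sx == 0.0 or sy == 0.0:
        return math.nan
    r = ((x - x.mean()) * (y - y.mean())).mean() / (sx * sy)
    return float(r * r)


def ld_decay_curve(
    matrix: GenotypeMatrix,
    samples: list[str] | None = None,
    max_dist: int = 300_000,
    bin_width: int = 1_000,
) -> LDCurve:
    """Mean r^2 per distance bin over all same-chromosome pairs <= max_dist."""
    idx = matrix.sample_indices(samples)
    edges = np.arange(0, max_dist + bin_width, bin_width, dtype=np.int64)
    n_bins = len(edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)

    var_cols = np.flatnonzero(matrix.is_variant)
    dos = matrix.dosages[np.ix_(idx, var_cols)].astype(float)
    chrom = matrix.chrom[var_cols]
    pos = matrix.pos[var_cols]

    for c in dict.fromkeys(chrom.tolist()):
        sel = np.flatnonzero(chrom == c)
        p = pos[sel]
        d = dos[:, sel]
        called = d != MISSING
        m = len(sel)
        for i in range(m - 1):
            # positions are sorted: stop once beyond max_dist
            hi = int(np.searchsorted(p, p[i] + max_dist, side="right"))
            if hi <= i + 1:
                continue
            # vectorised pairwise-complete correlation of site i vs i+1..hi-1
            x = d[:, i]
            y = d[:, i + 1 : hi]
            v = called[:, i, None] & called[:, i + 1 : hi]
            n_ok = v.sum(axis=0)
            xm = np.where(v, x[:, None], 0.0)
            ym = np.where(v, y, 0.0)
            sx = xm.sum(axis=0)
            sy = ym.sum(axis=0)
            sxx = (xm * xm).sum(axis=0)
            syy = (ym * ym).sum(axis=0)
            sxy = (xm * ym).sum(axis=0)
            with np.errstate(invalid="ignore", divide="ignore"):
                var_x = n_ok * sxx - sx * sx
                var_y = n_ok * syy - sy * sy
                cov = n_ok * sxy - sx * sy
                r2 = (cov * cov) / (var_x * var_y)
            ok = (n_ok >= 3) & (var_x > 0) & (var_y > 0)
            if not ok.any():
                continue
            dist = (p[i + 1 : hi] - p[i]).astype(np.int64)
            bins = np.minimum(dist // bin_width, n_bins - 1)
            np.add.at(sums, bins[ok], r2[ok])
            np.add.at(counts, bins[ok], 1)

    with np.errstate(invalid="ignore"):
        mean = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    logger.info("ld_decay_curve: %d pairs binned", int(counts.sum()))
    return LDCurve(bin_edges=edges, mean_r2=mean, pair_count=counts)


def half_decay_distance(curve: LDCurve, smooth: int = 0) -> float:
    """Distance at which mean r^2 first falls to half of its maximum.

    Scans non-empty bins from the maximum outward with linear interpolation
    between bin midpoints; returns +inf when the curve never reaches half of
    its maximum within range. ``smooth`` > 1 applies a centered moving
    average over that many non-empty bins first.
    """
    filled = curve.pair_count > 0
    if not filled.any():
        raise ValueError("half_decay_distance: curve has no non-empty bins")
    x = curve.midpoints[filled].astype(float)
    y = curve.mean_r2[filled].astype(float)
    if len(x) < 2:
        raise ValueError("half_decay_distance: need >= 2 non-empty bins")
    if smooth and smooth > 1:
        kernel = np.ones(smooth) / smooth
        pad = smooth // 2
        ypad = np.pad(y, pad, mode="edge")
        y = np.convolve(ypad, kernel, mode="valid")[: len(x)]

    imax = int(np.argmax(y))
    target = y[imax] / 2.0
    for i in range(imax, len(x) - 1):
        if y[i] > target >= y[i + 1]:
            frac = (y[i] - target) / (y[i] - y[i + 1])
            return float(x[i] + frac * (x[i + 1] - x[i]))
    if y[imax] <= target:  # flat-zero curve degenerate case
        return float(x[imax])
    return math.inf
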