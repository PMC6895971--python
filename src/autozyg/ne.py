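"""Historical effective population size from LD decay (Sved's relation).

Within-chromosome marker pairs are binned by genetic distance c (Morgans);
each bin's mean squared dosage correlation r², corrected for sample size
(r²_adj = r² - 1/(2n), composite LD on unphased dosages), is inverted through

    E(r²) = 1 / (1 + 4 Ne c)   =>   Ne = (1/r²_adj - 1) / (4 c)

at the bin midpoint, and the bin is dated T = 1/(2c) generations ago: long-range
LD reflects recent Ne, short-range LD ancient Ne.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")


@dataclass
class NeBin:
    c_lo: float
    c_hi: float
    c_mid: float
    n_pairs: int
    mean_r2: float
    r2_adj: float
    ne: float          # NaN when r2_adj >= 1 or <= 0
    generations: float  # T = 1/(2c)


def default_bins(n_bins: int = 20, c_min: float = 0.0005, c_max: float = 0.25) -> np.ndarray:
    """Log-spaced genetic-distance bin edges in Morgans."""
    return np.logspace(np.log10(c_min), np.log10(c_max), n_bins + 1)


def pairwise_r2(g: GenotypeMatrix, i: int, j: int) -> float:
    """Squared Pearson correlation of dosages at markers i, j over complete pairs."""
    a, b = g.codes[:, i].astype(float), g.codes[:, j].astype(float)
    ok = (g.codes[:, i] != MISSING) & (g.codes[:, j] != MISSING)
    if ok.sum() < 2:
        raise ValueError("fewer than 2 complete genotype pairs")
    a, b = a[ok], b[ok]
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance at one marker")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_matrix(codes: np.ndarray) -> np.ndarray:
    """Pairwise-complete r² between all marker columns (NaN where undefined)."""
    X = codes.astype(float)
    obs = (codes != MISSING).astype(float)
    X = np.where(codes == MISSING, 0.0, X)
    n = obs.T @ obs                                 # complete-pair counts
    sx = X.T @ obs
    sy = sx.T
    sxy = X.T @ X
    sxx = (X * X).T @ obs
    syy = sxx.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = sxy - sx * sy / n
        vx = sxx - sx * sx / n
        vy = syy - sy * sy / n
        r2 = cov * cov / (vx * vy)
    r2[(n < 2) | ~np.isfinite(r2)] = np.nan
    return r2


def estimate_ne(g: GenotypeMatrix, bin_edges: np.ndarray | None = None,
                adjust: str = "1/(2n)", min_maf: float = 0.05,
                alpha: float = 1.0) -> list[NeBin]:
    """Bin within-chromosome LD by genetic distance and invert Sved's relation.

    ``adjust``: ``"none"`` or ``"1/(2n)"`` (chromosome-sample-size correction of
    the squared correlation).  ``alpha`` multiplies the 4 Ne c term (default 1,
    i.e. the relation used verbatim).
    """
    if bin_edges is None:
        bin_edges = default_bins()
    freq = g.allele_frequency()
    maf_ok = np.isfinite(freq) & (np.minimum(freq, 1 - freq) >= min_maf)

    n_bins = len(bin_edges) - 1
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, dtype=np.int64)
    n_samples = g.n_samples

    for c in g.markers.chromosomes():
        idx = g.markers.chrom_index(c)
        idx = idx[maf_ok[idx]]
        if len(idx) < 2:
            continue
        r2 = _r2_matrix(g.codes[:, idx])
        cm = g.markers.cm[idx]
        d = np.abs(cm[:, None] - cm[None, :]) / 100.0   # Morgans
        iu = np.triu_indices(len(idx), k=1)
        dist, vals = d[iu], r2[iu]
        ok = np.isfinite(vals)
        which = np.digitize(dist[ok], bin_edges) - 1
        inside = (which >= 0) & (which < n_bins)
        np.add.at(sums, which[inside], vals[ok][inside])
        np.add.at(counts, which[inside], 1)

    out: list[NeBin] = []
    correction = 1.0 / (2 * n_samples) if adjust == "1/(2n)" else 0.0
    for b in range(n_bins):
        if counts[b] == 0:
            continue
        c_lo, c_hi = bin_edges[b], bin_edges[b + 1]
        c_mid = (c_lo + c_hi) / 2.0
        mean_r2 = sums[b] / counts[b]
        r2_adj = mean_r2 - correction
        if 0.0 < r2_adj < 1.0:
            ne = (1.0 / r2_adj - 1.0) / (4.0 * alpha * c_mid)
        else:
            ne = float("nan")
            logger.info("bin [%.4g, %.4g): adjusted r²=%.3g outside (0,1); Ne undefined",
                        c_lo, c_hi, r2_adj)
        out.append(NeBin(c_lo, c_hi, c_mid, int(counts[b]), float(mean_r2),
                         float(r2_adj), float(ne), 1.0 / (2.0 * c_mid)))
    out.sort(key=lambda nb: nb.generations)
    return out


def sved_ne(r2_adj: float, c: float, alpha: float = 1.0) -> float:
    """Analytic inversion Ne = (1/r² - 1)/(4 alpha c)."""
    if not 0.0 < r2_adj < 1.0:
        raise ValueError("adjusted r² must be in (0, 1)")
    return (1.0 / r2_adj - 1.0) / (4.0 * alpha * c)


def ne_table(bins: list[NeBin]) -> pd.DataFrame:
    return pd.DataFrame([vars(b) for b in bins])
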