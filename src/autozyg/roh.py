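"""Runs of homozygosity: detection, inbreeding coefficients, summaries, islands.

A run is a maximal stretch of consecutive markers on one chromosome of one
individual containing at most ``max_het`` heterozygous and ``max_missing``
missing calls (consecutive-marker method, not a sliding-window heuristic), then
filtered by a minimum SNP count and minimum physical length.  Where two maximal
windows overlap (possible around an allowed heterozygote) the longer one wins,
ties to the leftmost, so the segment set per individual/chromosome is
deterministic and non-overlapping.

F_ROH = L_ROH / L_AUTO with L_AUTO defaulting to the 2399.4 Mb goat autosome;
F_HOM is the excess-homozygosity coefficient (O - E)/(N - E) with the
small-sample-corrected expected heterozygosity 2pq * 2n/(2n - 1) per marker.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")

#: goat autosome length in Mb used to normalize F_ROH
L_AUTO_MB = 2399.4

#: half-open run-length class bounds in Mb
LENGTH_CLASSES = [(0.0, 3.0), (3.0, 5.0), (5.0, 10.0), (10.0, 20.0), (20.0, 30.0),
                  (30.0, float("inf"))]
CLASS_LABELS = ["0-3", "3-5", "5-10", "10-20", "20-30", ">30"]


@dataclass
class ROHParams:
    min_snps: int = 15
    min_length_mb: float = 1.0
    max_het: int = 1
    max_missing: int = 1

    def __post_init__(self) -> None:
        if self.min_snps < 0 or self.max_het < 0 or self.max_missing < 0:
            raise ValueError("ROH parameters must be nonnegative")
        if self.min_length_mb <= 0:
            raise ValueError("minimum run length must be positive")


@dataclass
class ROHSegment:
    sample: str
    chrom: str
    start_bp: int
    end_bp: int
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length_mb(self) -> float:
        return (self.end_bp - self.start_bp) / 1e6

    def length_class(self) -> str:
        for (lo, hi), lab in zip(LENGTH_CLASSES, CLASS_LABELS):
            if lo <= self.length_mb < hi:
                return lab
        raise AssertionError("unreachable")


def _maximal_windows(het: np.ndarray, mis: np.ndarray, max_het: int, max_missing: int):
    """Maximal [i, j] windows with <=max_het het and <=max_missing missing calls.

    Two-pointer sweep: R(i) = furthest valid end for start i is non-decreasing,
    and [i, R(i)] is maximal iff i == 0 or R(i-1) < R(i).
    """
    n = len(het)
    out = []
    j = -1
    h = m = 0
    prev_R = -1
    for i in range(n):
        if j < i - 1:
            j = i - 1
            h = m = 0
        while j + 1 < n:
            nh, nm = h + het[j + 1], m + mis[j + 1]
            if nh > max_het or nm > max_missing:
                break
            j += 1
            h, m = nh, nm
        if j >= i and j > prev_R:
            out.append((i, j))
            prev_R = j
        if j >= i:
            h -= het[i]
            m -= mis[i]
    return out


def _resolve_overlaps(windows, bp):
    """Greedy overlap resolution: keep longer (bp span) first, ties leftmost."""
    order = sorted(windows, key=lambda w: (-(bp[w[1]] - bp[w[0]]), bp[w[0]]))
    kept: list[tuple[int, int]] = []
    for w in order:
        if all(w[1] < k[0] or w[0] > k[1] for k in kept):
            kept.append(w)
    kept.sort()
    return kept


def detect_roh(g: GenotypeMatrix, p: ROHParams | None = None) -> list[ROHSegment]:
    """All runs of homozygosity per sample per chromosome satisfying ``p``."""
    p = p or ROHParams()
    segments: list[ROHSegment] = []
    for c in g.markers.chromosomes():
        idx = g.markers.chrom_index(c)
        bp = g.markers.bp[idx]
        sub = g.codes[:, idx]
        for i in range(g.n_samples):
            row = sub[i]
            het = (row == 1).astype(np.int32)
            mis = (row == MISSING).astype(np.int32)
            wins = _maximal_windows(het, mis, p.max_het, p.max_missing)
            wins = [w for w in wins
                    if (w[1] - w[0] + 1) >= p.min_snps
                    and (bp[w[1]] - bp[w[0]]) / 1e6 >= p.min_length_mb]
            for a, b in _resolve_overlaps(wins, bp):
                segments.append(ROHSegment(
                    sample=str(g.samples[i]), chrom=str(c),
                    start_bp=int(bp[a]), end_bp=int(bp[b]),
                    n_snps=int(b - a + 1),
                    n_het=int(het[a:b + 1].sum()),
                    n_missing=int(mis[a:b + 1].sum()),
                ))
    return segments


def froh(segments: list[ROHSegment], samples: list[str],
         l_auto_mb: float = L_AUTO_MB) -> pd.Series:
    """F_ROH = L_ROH / L_AUTO per sample (samples without runs get 0)."""
    if l_auto_mb <= 0:
        raise ValueError("autosome length must be positive")
    total = {s: 0.0 for s in samples}
    for seg in segments:
        total[seg.sample] = total.get(seg.sample, 0.0) + seg.length_mb
    return pd.Series({s: total[s] / l_auto_mb for s in samples}, name="F_ROH")


def froh_by_class(segments: list[ROHSegment], samples: list[str],
                  l_auto_mb: float = L_AUTO_MB) -> pd.DataFrame:
    """Per-sample F_ROH split by run-length class; rows sum to total F_ROH."""
    tab = pd.DataFrame(0.0, index=list(samples), columns=CLASS_LABELS)
    for seg in segments:
        tab.loc[seg.sample, seg.length_class()] += seg.length_mb / l_auto_mb
    return tab


def fhom(g: GenotypeMatrix) -> pd.Series:
    """Excess-homozygosity inbreeding coefficient per sample.

    O = observed homozygote count over the sample's non-missing markers,
    E = sum of per-marker expected homozygosity 1 - 2pq * 2n/(2n-1) with p and
    n from the marker's non-missing genotypes across all samples,
    F = (O - E)/(N - E).  NaN when every marker is monomorphic (N = E).
    """
    obs = g.codes != MISSING
    n_obs = obs.sum(axis=0)
    freq = g.allele_frequency()
    two_n = 2 * n_obs
    with np.errstate(invalid="ignore", divide="ignore"):
        exp_het = 2 * freq * (1 - freq) * np.where(two_n > 1, two_n / np.maximum(two_n - 1, 1), 0.0)
    exp_hom = 1.0 - exp_het

    values = {}
    for i, s in enumerate(g.samples):
        use = obs[i] & (n_obs > 0) & np.isfinite(exp_hom)
        N = int(use.sum())
        O = int(((g.codes[i] == 0) | (g.codes[i] == 2))[use].sum())
        E = float(exp_hom[use].sum())
        values[s] = (O - E) / (N - E) if abs(N - E) > 1e-12 else float("nan")
    return pd.Series(values, name="F_HOM")


def summarize(segments: list[ROHSegment], g: GenotypeMatrix,
              chrom_lengths_mb: dict[str, float] | None = None) -> dict:
    """Per-breed and per-chromosome ROH summaries.

    Per-chromosome coverage % = mean summed ROH length over individuals that
    carry at least one run on that chromosome, divided by the chromosome length
    (x100).  Per-class per-breed mean length = class length sum / breed size.
    """
    pops = {str(s): str(p) for s, p in zip(g.samples, g.populations)}
    breeds = g.population_labels()
    breed_n = {b: int((g.populations == b).sum()) for b in breeds}

    seg_tab = pd.DataFrame([{
        "sample": s.sample, "breed": pops.get(s.sample, "?"), "chrom": s.chrom,
        "start_bp": s.start_bp, "end_bp": s.end_bp, "n_snps": s.n_snps,
        "length_mb": s.length_mb, "length_class": s.length_class(),
    } for s in segments])

    per_breed = []
    for b in breeds:
        rows = seg_tab[seg_tab["breed"] == b] if len(seg_tab) else seg_tab
        per_ind = rows.groupby("sample").size() if len(rows) else pd.Series(dtype=int)
        counts = {f"class_count_{lab}": int((rows["length_class"] == lab).sum())
                  if len(rows) else 0 for lab in CLASS_LABELS}
        total = len(rows)
        freqs = {f"class_freq_{lab}": counts[f"class_count_{lab}"] / total if total else 0.0
                 for lab in CLASS_LABELS}
        class_mean_len = {f"class_mean_mb_{lab}":
                          float(rows.loc[rows["length_class"] == lab, "length_mb"].sum())
                          / breed_n[b] if len(rows) else 0.0
                          for lab in CLASS_LABELS}
        per_breed.append({
            "breed": b, "n_individuals": breed_n[b], "total_roh": total,
            "mean_roh_per_individual": float(per_ind.mean()) if len(per_ind) else 0.0,
            "min_roh_per_individual": int(per_ind.min()) if len(per_ind) else 0,
            "max_roh_per_individual": int(per_ind.max()) if len(per_ind) else 0,
            "mean_length_mb": float(rows["length_mb"].mean()) if total else 0.0,
            "min_length_mb": float(rows["length_mb"].min()) if total else 0.0,
            "max_length_mb": float(rows["length_mb"].max()) if total else 0.0,
            "mean_sum_length_mb": (float(rows.groupby("sample")["length_mb"].sum().sum())
                                   / breed_n[b]) if total else 0.0,
            **counts, **freqs, **class_mean_len,
        })

    per_chrom = []
    for c in g.markers.chromosomes():
        rows = seg_tab[seg_tab["chrom"] == str(c)] if len(seg_tab) else seg_tab
        count = len(rows)
        if chrom_lengths_mb and str(c) in chrom_lengths_mb and count:
            carriers = rows.groupby("sample")["length_mb"].sum()
            mean_len = float(rows["length_mb"].sum()) / len(carriers)
            coverage = mean_len / chrom_lengths_mb[str(c)] * 100.0
        else:
            coverage = 0.0
            if count == 0:
                logger.info("chromosome %s has no ROH; coverage set to 0", c)
        per_chrom.append({"chrom": str(c), "n_roh": count, "coverage_pct": coverage})

    return {"segments": seg_tab,
            "per_breed": pd.DataFrame(per_breed),
            "per_chromosome": pd.DataFrame(per_chrom)}


def snp_in_roh_percentage(segments: list[ROHSegment], g: GenotypeMatrix) -> pd.DataFrame:
    """Per-SNP share (%) of samples whose runs cover the SNP (Manhattan table)."""
    cover = np.zeros((g.n_samples, g.n_markers), dtype=bool)
    sample_row = {str(s): i for i, s in enumerate(g.samples)}
    for seg in segments:
        idx = g.markers.chrom_index(seg.chrom)
        bp = g.markers.bp[idx]
        inside = idx[(bp >= seg.start_bp) & (bp <= seg.end_bp)]
        cover[sample_row[seg.sample], inside] = True
    pct = cover.mean(axis=0) * 100.0
    return pd.DataFrame({"chrom": g.markers.chrom, "id": g.markers.ids,
                         "bp": g.markers.bp, "pct_in_roh": pct})


def roh_islands(segments: list[ROHSegment], g: GenotypeMatrix,
                threshold: float = 0.45) -> tuple[pd.DataFrame, pd.DataFrame]:
    """ROH islands: maximal runs of consecutive SNPs whose occurrence % exceeds
    ``threshold``; returns (islands table, per-SNP occurrence table)."""
    if not 0.0 < threshold < 1.0:
        raise ValueError("threshold must be in (0, 1)")
    per_snp = snp_in_roh_percentage(segments, g)
    above = per_snp["pct_in_roh"].to_numpy() > threshold * 100.0
    islands = []
    for c in g.markers.chromosomes():
        idx = g.markers.chrom_index(c)
        flags = above[idx]
        j = 0
        while j < len(flags):
            if flags[j]:
                k = j
                while k + 1 < len(flags) and flags[k + 1]:
                    k += 1
                block = idx[j:k + 1]
                islands.append({
                    "chrom": str(c),
                    "start_bp": int(g.markers.bp[block[0]]),
                    "end_bp": int(g.markers.bp[block[-1]]),
                    "n_snps": len(block),
                    "peak_pct": float(per_snp["pct_in_roh"].iloc[block].max()),
                })
                j = k + 1
            else:
                j += 1
    cols = ["chrom", "start_bp", "end_bp", "n_snps", "peak_pct"]
    return pd.DataFrame(islands, columns=cols), per_snp


def region_gene_distance(region_start_bp: int, gene_start_bp: int) -> float:
    """Signed distance (Mb) from a region start to a gene start on one chromosome."""
    return (gene_start_bp - region_start_bp) / 1e6
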