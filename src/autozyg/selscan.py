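"""Three-statistic selection scan contrasting two population groups.

Per SNP: Weir-Cockerham F_ST between the high- and low-fecundity groups and its
genome-wide z-score ZF_ST; nucleotide diversity pi in each group and the ratio
pi_low / pi_high (elevated ratio = diversity loss in the high group); and, when
phased haplotypes are supplied, XP-EHH = ln(I_A / I_B) where I is the trapezoid
integral of EHH over genetic distance away from the core, truncated where the
pooled-population EHH falls below 0.05.  Candidates are empirical-quantile
outliers (top 1% F_ST, top 1% pi-ratio, top 0.1% XP-EHH), intersected, extended
+/-100 kb, merged, and optionally annotated against a gene-interval file.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, HaplotypeSet
from .popdiff import weir_cockerham_fst

logger = logging.getLogger("autozyg")


@dataclass
class ScanParams:
    q_fst: float = 0.01
    q_pi: float = 0.01
    q_xpehh: float = 0.001
    extension_bp: int = 100_000
    ehh_cutoff: float = 0.05
    max_extension_mb: float = 2.5


@dataclass
class CandidateRegion:
    chrom: str
    start_bp: int
    end_bp: int
    statistics: list[str]
    genes: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# per-site statistics
# ---------------------------------------------------------------------------

def site_pi(g: GenotypeMatrix) -> np.ndarray:
    """Unbiased per-site nucleotide diversity 2k(2n-k) / (2n(2n-1)).

    k counts the counted allele among the 2n non-missing allele copies; this is
    the proportion of allelically different pairs among all pairs of copies.
    """
    obs = g.codes != MISSING
    n2 = 2 * obs.sum(axis=0)
    k = np.where(obs, g.codes, 0).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        pi = 2.0 * k * (n2 - k) / (n2 * (n2 - 1.0))
    pi[n2 < 4] = np.nan    # need >= 2 diploid samples
    return pi


def zfst(fst: np.ndarray) -> np.ndarray:
    """Z-transform of per-SNP F_ST (population sd); NaNs are ignored in the
    moments and propagate through."""
    fst = np.asarray(fst, dtype=float)
    mu = np.nanmean(fst)
    sd = np.nanstd(fst)
    if sd == 0:
        raise ValueError("F_ST values are constant; z-score undefined")
    return (fst - mu) / sd


def standardize_xpehh(raw: np.ndarray) -> np.ndarray:
    """Standardize raw XP-EHH scores to mean 0, variance 1 over scanned cores."""
    raw = np.asarray(raw, dtype=float)
    ok = np.isfinite(raw)
    if ok.sum() < 2:
        raise ValueError("need at least two finite scores to standardize")
    mu, sd = raw[ok].mean(), raw[ok].std()
    if sd == 0:
        raise ValueError("scores are constant; standardization undefined")
    return (raw - mu) / sd


# ---------------------------------------------------------------------------
# EHH / XP-EHH
# ---------------------------------------------------------------------------

def ehh(h: HaplotypeSet, core: int, direction: int) -> tuple[np.ndarray, np.ndarray]:
    """EHH from ``core`` outward (direction +1/-1) over one chromosome.

    EHH(x) = probability that two random distinct haplotypes are identical at
    every marker between the core (exclusive, so EHH(core) = 1) and x
    (inclusive); computed jointly over all haplotypes (the unstandardized
    cross-population variant).  Returns (marker indices, EHH values).
    """
    H = h.haplotypes
    if H.shape[0] < 2:
        raise ValueError("need at least two haplotypes")
    chrom = h.markers.chrom[core]
    idx = h.markers.chrom_index(chrom)
    pos_in_chrom = int(np.flatnonzero(idx == core)[0])
    if direction > 0:
        walk = idx[pos_in_chrom:]
    else:
        walk = idx[pos_in_chrom::-1]
    N = H.shape[0]
    group = np.zeros(N, dtype=np.int64)
    out = np.empty(len(walk))
    out[0] = 1.0                       # empty extension: identity is vacuous
    for t, j in enumerate(walk):
        if t == 0:
            continue                   # the core allele itself is not required to match
        # refine the prefix-identity partition with marker j
        key = group * 2 + H[:, j]
        _, group = np.unique(key, return_inverse=True)
        counts = np.bincount(group)
        out[t] = (counts * (counts - 1)).sum() / (N * (N - 1))
    return walk, out


def _partition_ehh(group: np.ndarray, allele: np.ndarray) -> tuple[np.ndarray, float]:
    """Refine a prefix-identity partition with one more marker; return new
    labels and the haplotype homozygosity of the refined partition."""
    key = group * 2 + allele
    _, group = np.unique(key, return_inverse=True)
    counts = np.bincount(group)
    N = len(group)
    return group, float((counts * (counts - 1)).sum() / (N * (N - 1)))


def _integrated_ehh(HA: np.ndarray, HB: np.ndarray, core: int,
                    idx: np.ndarray, cm: np.ndarray, bp: np.ndarray,
                    params: ScanParams) -> tuple[float, float]:
    """Trapezoid integrals (I_A, I_B) of EHH over Morgans, both directions from
    the core, truncated where the pooled-haplotype EHH falls below the cutoff
    or the physical extension exceeds the maximum.  ``idx`` is the marker index
    of the core's chromosome; the walk stops as soon as truncation hits, so the
    cost per core is proportional to the truncated extension."""
    HP = np.vstack([HA, HB])
    pos_in_chrom = int(np.flatnonzero(idx == core)[0])
    IA = IB = 0.0
    for direction in (+1, -1):
        walk = idx[pos_in_chrom:] if direction > 0 else idx[pos_in_chrom::-1]
        gA = np.zeros(HA.shape[0], dtype=np.int64)
        gB = np.zeros(HB.shape[0], dtype=np.int64)
        gP = np.zeros(HP.shape[0], dtype=np.int64)
        eA_prev = eB_prev = 1.0
        x_prev = 0.0
        for t in range(1, len(walk)):
            j = walk[t]
            if abs(bp[j] - bp[core]) / 1e6 > params.max_extension_mb:
                break
            gA, eA = _partition_ehh(gA, HA[:, j])
            gB, eB = _partition_ehh(gB, HB[:, j])
            gP, eP = _partition_ehh(gP, HP[:, j])
            x = abs(cm[j] - cm[core]) / 100.0
            IA += 0.5 * (eA_prev + eA) * (x - x_prev)
            IB += 0.5 * (eB_prev + eB) * (x - x_prev)
            eA_prev, eB_prev, x_prev = eA, eB, x
            if eP < params.ehh_cutoff:
                break
    return IA, IB


def xpehh(hA: HaplotypeSet, hB: HaplotypeSet, core: int,
          params: ScanParams | None = None) -> float:
    """Raw XP-EHH = ln(I_A / I_B) at one core marker (NaN when I_B = 0)."""
    params = params or ScanParams()
    m = hA.markers
    idx = m.chrom_index(m.chrom[core])
    IA, IB = _integrated_ehh(hA.haplotypes, hB.haplotypes, core,
                             idx, m.cm, m.bp, params)
    if IB <= 0 or IA <= 0:
        logger.info("core %s: zero integrated EHH; XP-EHH undefined", m.ids[core])
        return float("nan")
    return float(np.log(IA / IB))


def xpehh_scan(hA: HaplotypeSet, hB: HaplotypeSet,
               params: ScanParams | None = None) -> np.ndarray:
    """Raw XP-EHH at every marker as core."""
    params = params or ScanParams()
    m = hA.markers
    out = np.empty(m.n)
    for c in m.chromosomes():
        idx = m.chrom_index(c)
        for core in idx:
            IA, IB = _integrated_ehh(hA.haplotypes, hB.haplotypes, int(core),
                                     idx, m.cm, m.bp, params)
            out[core] = np.log(IA / IB) if (IA > 0 and IB > 0) else np.nan
    return out


# ---------------------------------------------------------------------------
# scan assembly and candidate calling
# ---------------------------------------------------------------------------

def scan_statistics(g: GenotypeMatrix, high: list[str], low: list[str],
                    haplotypes: tuple[HaplotypeSet, HaplotypeSet] | None = None,
                    params: ScanParams | None = None) -> pd.DataFrame:
    """Per-SNP table of F_ST, ZF_ST, pi in each group, pi_low/pi_high (raw and
    log2) and (when haplotypes are given) raw + standardized XP-EHH."""
    params = params or ScanParams()
    grouped = g.subset(sample_idx=np.flatnonzero(np.isin(g.populations, high + low)))
    group_label = np.where(np.isin(grouped.populations, high), "high", "low")
    flat = GenotypeMatrix(grouped.samples, group_label.astype(object), grouped.codes,
                          grouped.markers, grouped.allele1, grouped.allele2)
    fst = weir_cockerham_fst(flat, ["high", "low"], mode="per-marker").to_numpy()
    z = zfst(fst)
    pi_high = site_pi(flat.by_population("high"))
    pi_low = site_pi(flat.by_population("low"))
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = pi_low / pi_high
        log2_ratio = np.log2(ratio)
    tab = pd.DataFrame({
        "chrom": g.markers.chrom, "id": g.markers.ids, "bp": g.markers.bp,
        "fst": fst, "zfst": z, "pi_high": pi_high, "pi_low": pi_low,
        "pi_ratio": ratio, "log2_pi_ratio": log2_ratio,
    })
    if haplotypes is not None:
        hA, hB = haplotypes
        raw = xpehh_scan(hA, hB, params)
        tab["xpehh_raw"] = raw
        tab["xpehh"] = standardize_xpehh(raw)
    return tab


def top_quantile_mask(values: np.ndarray, q: float) -> np.ndarray:
    """Boolean mask of the ceil(q*n) largest finite values (empirical top-q tail),
    deterministic under ties (earlier index wins)."""
    values = np.asarray(values, dtype=float)
    ok = np.flatnonzero(np.isfinite(values))
    mask = np.zeros(len(values), dtype=bool)
    if len(ok) == 0:
        return mask
    k = int(np.ceil(q * len(ok)))
    order = ok[np.lexsort((ok, -values[ok]))]
    mask[order[:k]] = True
    return mask


def call_candidates(rows: pd.DataFrame, params: ScanParams | None = None,
                    annotation: pd.DataFrame | None = None,
                    chrom_lengths_bp: dict[str, int] | None = None):
    """Outlier flags, Venn intersection counts and merged candidate regions.

    ``annotation``: optional gene intervals with columns chrom/start/end/name
    (1-based inclusive).  Returns (rows with flag columns, venn dict, regions).
    """
    params = params or ScanParams()
    rows = rows.copy()
    rows["outlier_fst"] = top_quantile_mask(rows["fst"].to_numpy(), params.q_fst)
    rows["outlier_pi"] = top_quantile_mask(rows["pi_ratio"].to_numpy(), params.q_pi)
    has_xp = "xpehh" in rows.columns
    rows["outlier_xpehh"] = (top_quantile_mask(rows["xpehh"].to_numpy(), params.q_xpehh)
                             if has_xp else False)

    f, p, x = (rows["outlier_fst"].to_numpy(), rows["outlier_pi"].to_numpy(),
               rows["outlier_xpehh"].to_numpy())
    venn = {
        "fst": int(f.sum()), "pi": int(p.sum()), "xpehh": int(x.sum()),
        "fst_and_pi": int((f & p).sum()),
        "fst_and_xpehh": int((f & x).sum()),
        "pi_and_xpehh": int((p & x).sum()),
        "fst_and_pi_and_xpehh": int((f & p & x).sum()),
    }

    core = rows[f | p | x]
    regions: list[CandidateRegion] = []
    for chrom, sub in core.groupby("chrom", sort=False):
        sub = sub.sort_values("bp")
        limit = chrom_lengths_bp.get(str(chrom)) if chrom_lengths_bp else None
        for _, row in sub.iterrows():
            start = max(1, int(row["bp"]) - params.extension_bp)
            end = int(row["bp"]) + params.extension_bp
            if limit:
                end = min(end, limit)
            stats = [s for s, flag in (("fst", row["outlier_fst"]),
                                       ("pi", row["outlier_pi"]),
                                       ("xpehh", row["outlier_xpehh"])) if flag]
            if regions and regions[-1].chrom == str(chrom) and start <= regions[-1].end_bp:
                regions[-1].end_bp = max(regions[-1].end_bp, end)
                regions[-1].statistics = sorted(set(regions[-1].statistics) | set(stats))
            else:
                regions.append(CandidateRegion(str(chrom), start, end, sorted(set(stats))))

    if annotation is not None and len(annotation):
        for reg in regions:
            hits = annotation[(annotation["chrom"].astype(str) == reg.chrom)
                              & (annotation["end"].astype(int) >= reg.start_bp)
                              & (annotation["start"].astype(int) <= reg.end_bp)]
            reg.genes = list(hits["name"].astype(str))
    return rows, venn, regions


def read_gene_intervals(path) -> pd.DataFrame:
    """Gene intervals from BED (0-based half-open, converted) or GFF/GTF
    (1-based), as a chrom/start/end/name frame with 1-based inclusive bounds."""
    path = str(path)
    if path.endswith((".gff", ".gff3", ".gtf")):
        tab = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["chrom", "source", "feature", "start", "end",
                                 "score", "strand", "frame", "attributes"], dtype=str)
        name = tab["attributes"].str.extract(r"(?:Name|gene_id|ID)[=\s\"]+([^;\"]+)")[0]
        return pd.DataFrame({"chrom": tab["chrom"], "start": tab["start"].astype(int),
                             "end": tab["end"].astype(int),
                             "name": name.fillna("gene")})
    bed = pd.read_csv(path, sep="\t", header=None, comment="#").iloc[:, :4]
    bed.columns = ["chrom", "start", "end", "name"][:bed.shape[1]]
    if "name" not in bed.columns:
        bed["name"] = [f"feature{i}" for i in range(len(bed))]
    bed["start"] = bed["start"].astype(int) + 1      # BED 0-based -> 1-based
    bed["end"] = bed["end"].astype(int)
    return bed
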