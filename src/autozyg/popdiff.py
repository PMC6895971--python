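"""Population structure and differentiation.

Implements the coancestry (theta) estimators behind the two distance matrices
(pairwise theta below the diagonal, Reynolds D_R = -ln(1 - theta) above),
per-marker and global Weir-Cockerham F_ST, a two-level AMOVA with permutation
significance, PLINK-style greedy LD pruning, allele-frequency-scaled PCA, the
1 - IBS allele-sharing distance, and a Saitou-Nei neighbor-joining tree.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.labels),) * 2:
            raise ValueError("distance matrix shape does not match labels")
        if np.max(np.abs(self.values - self.values.T)) > 1e-12:
            raise ValueError("distance matrix must be symmetric")
        np.fill_diagonal(self.values, 0.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class AMOVAResult:
    sigma_among: float
    sigma_within: float
    pct_among: float
    pct_within: float
    phi_st: float
    p_value: float
    n_permutations: int


# ---------------------------------------------------------------------------
# coancestry / F_ST
# ---------------------------------------------------------------------------

def _pop_freq_stats(g: GenotypeMatrix, labels: list[str]):
    """Per-population allele frequency, observed het frequency and sample size."""
    freqs, hets, sizes = [], [], []
    for lab in labels:
        sub = g.by_population(lab)
        obs = sub.codes != MISSING
        n_obs = obs.sum(axis=0)
        if not np.any(n_obs > 0):
            raise ValueError(f"population {lab} has no typed markers")
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(obs, sub.codes, 0).sum(axis=0) / np.maximum(2 * n_obs, 1)
            h = np.where(obs, sub.codes == 1, False).sum(axis=0) / np.maximum(n_obs, 1)
        p[n_obs == 0] = np.nan
        freqs.append(p)
        hets.append(h)
        sizes.append(n_obs)
    return np.array(freqs), np.array(hets), np.array(sizes)


def reynolds_theta(p1: np.ndarray, p2: np.ndarray,
                   n1: np.ndarray, n2: np.ndarray) -> float:
    """Coancestry theta for one population pair, ratio of sums over markers.

    Method-of-moments pure-drift estimator: the numerator unbiasedly estimates
    2*theta*p(1-p) by removing the binomial sampling variance of each sample
    frequency, the denominator estimates 2*p(1-p); both are summed over markers
    before taking the ratio.
    """
    n1 = np.broadcast_to(np.asarray(n1, dtype=float), p1.shape)
    n2 = np.broadcast_to(np.asarray(n2, dtype=float), p2.shape)
    ok = np.isfinite(p1) & np.isfinite(p2) & (n1 > 0) & (n2 > 0)
    p1, p2, n1, n2 = p1[ok], p2[ok], n1[ok], n2[ok]
    s1 = p1 * (1 - p1)
    s2 = p2 * (1 - p2)
    num = (p1 - p2) ** 2 - s1 / (2 * n1 - 1) - s2 / (2 * n2 - 1)
    den = num + (2 * n1) * s1 / (2 * n1 - 1) + (2 * n2) * s2 / (2 * n2 - 1)
    return float(num.sum() / den.sum())


def reynolds_distance(g: GenotypeMatrix) -> tuple[DistanceMatrix, DistanceMatrix]:
    """(Reynolds D_R, pairwise theta) matrices over populations.

    D_R = -ln(1 - theta) with the same aggregated coancestry theta that fills
    the pairwise-difference matrix.
    """
    labels = g.population_labels()
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    freqs, _, sizes = _pop_freq_stats(g, labels)
    r = len(labels)
    theta = np.zeros((r, r))
    for i in range(r):
        for j in range(i + 1, r):
            t = reynolds_theta(freqs[i], freqs[j], sizes[i], sizes[j])
            theta[i, j] = theta[j, i] = t
    with np.errstate(invalid="ignore"):
        dr = -np.log(np.clip(1.0 - theta, 1e-300, None))
    np.fill_diagonal(dr, 0.0)
    return (DistanceMatrix(labels, dr, "reynolds_DR"),
            DistanceMatrix(labels, theta, "pairwise_theta"))


def weir_cockerham_fst(g: GenotypeMatrix, populations: list[str] | None = None,
                       mode: str = "per-marker"):
    """Weir-Cockerham (1984) theta from variance components a, b, c.

    ``per-marker`` returns a Series of a/(a+b+c) per marker (NaN where the
    denominator vanishes, e.g. monomorphic everywhere); ``global`` returns
    the ratio of sums over markers.
    """
    labels = populations or g.population_labels()
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    sub = g.subset(sample_idx=np.flatnonzero(np.isin(g.populations, labels)))
    freqs, hets, sizes = _pop_freq_stats(sub, labels)
    r = len(labels)

    n_i = sizes.astype(float)                    # (r, markers)
    valid = (n_i > 0).all(axis=0)
    nbar = n_i.mean(axis=0)
    n_tot = n_i.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (n_tot - (n_i ** 2).sum(axis=0) / n_tot) / (r - 1)
        pbar = (n_i * freqs).sum(axis=0) / n_tot
        s2 = (n_i * (freqs - pbar) ** 2).sum(axis=0) / ((r - 1) * nbar)
        hbar = (n_i * hets).sum(axis=0) / n_tot
        a = (nbar / nc) * (s2 - (pbar * (1 - pbar) - (r - 1) / r * s2 - hbar / 4) / (nbar - 1))
        b = (nbar / (nbar - 1)) * (pbar * (1 - pbar) - (r - 1) / r * s2
                                   - (2 * nbar - 1) / (4 * nbar) * hbar)
        c = hbar / 2
        denom = a + b + c
    a = np.where(valid, a, np.nan)
    denom = np.where(valid & (np.abs(denom) > 0), denom, np.nan)
    if mode == "per-marker":
        with np.errstate(invalid="ignore", divide="ignore"):
            theta = a / denom
        return pd.Series(theta, index=sub.markers.ids, name="fst")
    if mode == "global":
        ok = np.isfinite(a) & np.isfinite(denom)
        return float(np.nansum(a[ok]) / np.nansum(denom[ok]))
    raise ValueError(f"unknown mode {mode!r}")


# ---------------------------------------------------------------------------
# AMOVA
# ---------------------------------------------------------------------------

def _squared_distance_matrix(codes: np.ndarray) -> np.ndarray:
    """Squared Euclidean dosage distances; missing handled pairwise-complete."""
    X = codes.astype(float)
    obs = (codes != MISSING).astype(float)
    X = np.where(codes == MISSING, 0.0, X)
    xx = (X * X) @ obs.T
    d2 = xx + xx.T - 2 * X @ X.T
    return d2


def amova(g: GenotypeMatrix, n_perm: int = 100, seed: int = 0) -> AMOVAResult:
    """Two-level AMOVA (among / within populations) with a permutation test.

    Sums of squares follow the distance formulation: SS(group) =
    sum_{i<j in group} d²_ij / n_group; Phi_ST = sigma²_a / (sigma²_a +
    sigma²_w); p = (#perm Phi >= observed + 1)/(n_perm + 1) permuting sample
    labels among populations.
    """
    if n_perm < 99:
        raise ValueError("need at least 99 permutations")
    labels = g.population_labels()
    if len(labels) < 2:
        raise ValueError("need at least two populations")
    d2 = _squared_distance_matrix(g.codes)
    pop_idx = np.array([labels.index(p) for p in g.populations])

    def decompose(assign: np.ndarray):
        N = len(assign)
        r = len(labels)
        ss_total = d2[np.triu_indices(N, k=1)].sum() / N
        ss_within = 0.0
        n_g = np.zeros(r)
        for k in range(r):
            members = np.flatnonzero(assign == k)
            n_g[k] = len(members)
            if len(members) > 1:
                sub = d2[np.ix_(members, members)]
                ss_within += sub[np.triu_indices(len(members), k=1)].sum() / len(members)
        ss_among = ss_total - ss_within
        df_among, df_within = r - 1, N - r
        ms_within = ss_within / df_within
        n_prime = (N - (n_g ** 2).sum() / N) / df_among
        sigma_a = (ss_among / df_among - ms_within) / n_prime
        sigma_w = ms_within
        phi = sigma_a / (sigma_a + sigma_w)
        return sigma_a, sigma_w, phi

    sigma_a, sigma_w, phi = decompose(pop_idx)
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pop_idx)
        if decompose(perm)[2] >= phi:
            hits += 1
    total = max(sigma_a, 0.0) + sigma_w
    return AMOVAResult(
        sigma_among=float(sigma_a), sigma_within=float(sigma_w),
        pct_among=float(100 * max(sigma_a, 0.0) / total),
        pct_within=float(100 * sigma_w / total),
        phi_st=float(phi),
        p_value=float((hits + 1) / (n_perm + 1)),
        n_permutations=n_perm,
    )


# ---------------------------------------------------------------------------
# LD pruning, PCA, IBS
# ---------------------------------------------------------------------------

def ld_prune(g: GenotypeMatrix, window: int = 50, step: int = 10,
             r2_threshold: float = 0.1) -> np.ndarray:
    """PLINK-style ``indep-pairwise`` greedy pruning; returns kept marker indices.

    Within each window of ``window`` markers, every pair still present with
    r² > threshold loses one member (the lower-MAF marker; ties drop the later
    one); the window then slides by ``step``.  Deterministic.
    """
    from .ne import _r2_matrix

    freq = g.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    keep = np.ones(g.n_markers, dtype=bool)
    for c in g.markers.chromosomes():
        idx = g.markers.chrom_index(c)
        start = 0
        while start < len(idx):
            w = idx[start:start + window]
            active = [j for j in w if keep[j]]
            if len(active) > 1:
                r2 = _r2_matrix(g.codes[:, active])
                for ai in range(len(active)):
                    for bi in range(ai + 1, len(active)):
                        ja, jb = active[ai], active[bi]
                        if not (keep[ja] and keep[jb]):
                            continue
                        v = r2[ai, bi]
                        if np.isfinite(v) and v > r2_threshold:
                            if np.isnan(maf[ja]) or np.isnan(maf[jb]):
                                keep[jb] = False
                            elif maf[ja] < maf[jb]:
                                keep[ja] = False
                            else:
                                keep[jb] = False
            if start + window >= len(idx):
                break
            start += step
    return np.flatnonzero(keep)


def pca(g: GenotypeMatrix, n_components: int = 10):
    """PCA of mean-imputed genotypes centered per marker and scaled by
    sqrt(p(1-p)); returns (coordinates DataFrame, variance-explained fractions)."""
    X = g.codes.astype(float)
    obs = g.codes != MISSING
    freq = g.allele_frequency()
    col_mean = np.where(obs, X, np.nan)
    col_mean = np.nanmean(col_mean, axis=0)
    X = np.where(obs, X, col_mean)
    with np.errstate(invalid="ignore", divide="ignore"):
        scale = np.sqrt(freq * (1 - freq))
    ok = np.isfinite(scale) & (scale > 0)
    X = (X[:, ok] - col_mean[ok]) / scale[ok]

    cov = X @ X.T / X.shape[1]
    vals, vecs = np.linalg.eigh(cov)
    order = np.argsort(vals)[::-1]
    vals, vecs = np.maximum(vals[order], 0.0), vecs[:, order]
    k = min(n_components, len(vals))
    coords = vecs[:, :k] * np.sqrt(vals[:k])
    frame = pd.DataFrame(coords, index=g.samples,
                         columns=[f"PC{i+1}" for i in range(k)])
    frame.insert(0, "population", g.populations)
    fractions = vals / vals.sum() if vals.sum() > 0 else vals
    return frame, fractions[:k]


def ibs_distance(g: GenotypeMatrix, level: str = "sample") -> DistanceMatrix:
    """1 - IBS allele-sharing distance between samples, optionally averaged to
    population level (the breed-tree input)."""
    X = g.codes.astype(float)
    obs = g.codes != MISSING
    n = g.n_samples
    d = np.zeros((n, n))
    Xm = np.where(obs, X, np.nan)
    for i in range(n):
        diff = np.abs(Xm - Xm[i])          # 0, 1 or 2 allele differences
        share = 1.0 - diff / 2.0
        d[i] = 1.0 - np.nanmean(share, axis=1)
    d = (d + d.T) / 2.0
    np.fill_diagonal(d, 0.0)
    if level == "sample":
        return DistanceMatrix([str(s) for s in g.samples], d, "1-IBS")
    labels = g.population_labels()
    r = len(labels)
    out = np.zeros((r, r))
    groups = [np.flatnonzero(g.populations == lab) for lab in labels]
    for a in range(r):
        for b in range(a + 1, r):
            out[a, b] = out[b, a] = d[np.ix_(groups[a], groups[b])].mean()
    return DistanceMatrix(labels, out, "1-IBS")


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(d: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string.

    Negative branch lengths are clamped to zero with the negative amount
    transferred to the adjacent (sister) branch, preserving path lengths.
    """
    n = len(d.labels)
    if n < 3:
        raise ValueError("need at least three taxa")
    D = d.values.astype(float).copy()
    nodes = [f"{lab}" for lab in d.labels]
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        ai, aj = np.unravel_index(np.argmin(Q), Q.shape)
        if ai > aj:
            ai, aj = aj, ai
        i, j = active[ai], active[aj]
        dij = D[i, j]
        li = 0.5 * dij + (r[ai] - r[aj]) / (2 * (m - 2))
        lj = dij - li
        # clamp negatives, transfer to the sister branch
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        new = f"({nodes[i]}:{li:.10g},{nodes[j]}:{lj:.10g})"
        dnew = 0.5 * (D[i, :] + D[j, :] - dij)
        D = np.vstack([D, dnew])
        D = np.column_stack([D, np.append(dnew, 0.0)])
        nodes.append(new)
        active = [k for k in active if k not in (i, j)] + [len(nodes) - 1]

    i, j, k = active
    li = 0.5 * (D[i, j] + D[i, k] - D[j, k])
    lj = 0.5 * (D[i, j] + D[j, k] - D[i, k])
    lk = 0.5 * (D[i, k] + D[j, k] - D[i, j])
    branches = [[li, i], [lj, j], [lk, k]]
    for b in branches:
        if b[0] < 0:
            deficit = b[0]
            b[0] = 0.0
            for o in branches:
                if o is not b:
                    o[0] += deficit / 2.0
    return (f"({nodes[branches[0][1]]}:{branches[0][0]:.10g},"
            f"{nodes[branches[1][1]]}:{branches[1][0]:.10g},"
            f"{nodes[branches[2][1]]}:{branches[2][0]:.10g});")
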