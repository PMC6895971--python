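"""Homozygosity-by-descent (HBD) mixture hidden-Markov model.

Each individual's genome is modelled as a mosaic of segments drawn from K
classes: K-1 HBD classes whose segment lengths are exponential with fixed
rates R_k = 2^1 ... 2^(K-1) Morgans^-1, plus one non-HBD class sharing the most
ancient rate 2^(K-1).  A rate R roughly equals twice the number of generations
to the segment's common ancestor, so small-R classes capture recent inbreeding
(long segments, mean length 1/R Morgans) and large-R classes ancient
inbreeding.  Only the mixing coefficients M_k are estimated (per individual, by
EM on the scaled forward-backward recursions); rates stay on the fixed grid.

Emissions: an HBD class emits a heterozygote only through genotyping error
(probability eps) and homozygotes in proportion to allele frequency; the
non-HBD class emits Hardy-Weinberg genotype frequencies.  Missing genotypes
are uninformative (emission 1 for every class).

F_G-T sums the genome-averaged posterior HBD probability over classes with
R_k <= T: raising T adds older ancestors, so the curve is non-decreasing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")


@dataclass
class HBDModelSpec:
    """K-class model: rates[k] for k < K-1 are HBD classes, the last is non-HBD."""

    n_classes: int = 10
    rates: np.ndarray | None = None
    epsilon: float = 0.001
    max_iter: int = 1000
    tol: float = 1e-6

    def __post_init__(self) -> None:
        if self.rates is None:
            hbd = 2.0 ** np.arange(1, self.n_classes)
            self.rates = np.append(hbd, hbd[-1])   # non-HBD shares the oldest rate
        self.rates = np.asarray(self.rates, dtype=float)
        if len(self.rates) != self.n_classes:
            raise ValueError("need one rate per class")
        if np.any(self.rates <= 0) or np.any(np.diff(self.rates[:-1]) < 0):
            raise ValueError("rates must be positive and non-decreasing over HBD classes")
        if not 0.0 <= self.epsilon <= 0.1:
            raise ValueError("genotyping error must be in [0, 0.1]")

    @property
    def hbd_rates(self) -> np.ndarray:
        return self.rates[:-1]


@dataclass
class HBDResult:
    samples: list[str]
    spec: HBDModelSpec
    #: per-sample (K,) genome-averaged posterior per class
    class_autozygosity: np.ndarray
    #: per-sample fitted mixing coefficients (K,)
    mixing: np.ndarray
    loglik: np.ndarray
    converged: np.ndarray
    #: optional list of per-sample (n_markers, K) posteriors
    posteriors: list[np.ndarray] | None = None

    def autozygosity_frame(self) -> pd.DataFrame:
        cols = [f"R{int(r)}" for r in self.spec.hbd_rates] + ["nonHBD"]
        return pd.DataFrame(self.class_autozygosity, index=self.samples, columns=cols)


def hbd_emission(code: int, p: float, hbd: bool, eps: float) -> float:
    """Emission probability of one genotype code (0/1/2 copies of the counted
    allele, -1 missing) under an HBD or non-HBD class."""
    if code == MISSING:
        return 1.0
    q = 1.0 - p
    if hbd:
        probs = (q * (1 - eps), eps, p * (1 - eps))
    else:
        probs = (q * q, 2 * p * q, p * p)
    return probs[code]


def _emission_matrix(codes: np.ndarray, freqs: np.ndarray, spec: HBDModelSpec) -> np.ndarray:
    """(n_markers, K) emission matrix for one individual."""
    n, K = len(codes), spec.n_classes
    p = freqs
    q = 1.0 - p
    eps = spec.epsilon
    hbd_em = np.select([codes == 0, codes == 1, codes == 2],
                       [q * (1 - eps), np.full(n, eps), p * (1 - eps)], default=1.0)
    non_em = np.select([codes == 0, codes == 1, codes == 2],
                       [q * q, 2 * p * q, p * p], default=1.0)
    B = np.empty((n, K))
    B[:, :-1] = hbd_em[:, None]
    B[:, -1] = non_em
    return B


def hbd_transition(d_morgans: float, spec: HBDModelSpec,
                   mixing: np.ndarray | None = None) -> np.ndarray:
    """K x K transition matrix across genetic distance ``d``.

    Stay in class k with exp(-R_k d); otherwise the segment ends and the next
    class is drawn from the mixing distribution M (which may return to k).
    """
    if d_morgans < 0:
        raise ValueError("distance must be nonnegative")
    M = np.full(spec.n_classes, 1.0 / spec.n_classes) if mixing is None else mixing
    stay = np.exp(-spec.rates * d_morgans)
    A = stay[:, None] * np.eye(spec.n_classes) + (1 - stay)[:, None] * M[None, :]
    return A


def _forward_backward(B: np.ndarray, d: np.ndarray, rates: np.ndarray, M: np.ndarray):
    """Scaled forward-backward exploiting the diagonal-plus-rank-one transitions.

    ``d[t]`` is the genetic distance (Morgans) between markers t-1 and t.
    Returns (loglik, gamma, jump_into) where jump_into[k] is the expected count
    of segment-change transitions that land in class k (plus the initial draw),
    i.e. the sufficient statistic for the M-step.
    """
    n, K = B.shape
    stay = np.exp(-rates[None, :] * d[:, None])        # (n-1, K)
    alpha = np.empty((n, K))
    c = np.empty(n)
    a = M * B[0]
    c[0] = a.sum()
    alpha[0] = a / c[0]
    for t in range(1, n):
        e = stay[t - 1]
        jump_mass = float((alpha[t - 1] * (1 - e)).sum())
        a = (alpha[t - 1] * e + jump_mass * M) * B[t]
        c[t] = a.sum()
        alpha[t] = a / c[t]
    loglik = float(np.log(c).sum())

    beta = np.empty((n, K))
    beta[-1] = 1.0
    gamma = np.empty((n, K))
    gamma[-1] = alpha[-1] * beta[-1]
    jump_into = np.zeros(K)
    for t in range(n - 2, -1, -1):
        e = stay[t]
        bb = B[t + 1] * beta[t + 1]
        common = float((M * bb).sum())
        beta[t] = (e * bb + (1 - e) * common) / c[t + 1]
        gamma[t] = alpha[t] * beta[t]
        # expected jumps landing in k between t and t+1
        jump_mass = float((alpha[t] * (1 - e)).sum())
        jump_into += jump_mass * M * bb / c[t + 1]
    gamma /= gamma.sum(axis=1, keepdims=True)
    # initial state draw also comes from M
    jump_into = jump_into + gamma[0]
    return loglik, gamma, jump_into


def hbd_loglikelihood(codes: np.ndarray, freqs: np.ndarray, d_morgans: np.ndarray,
                      spec: HBDModelSpec, mixing: np.ndarray) -> float:
    """Log-likelihood of one genotype sequence under the model (forward pass).

    ``d_morgans`` holds the n-1 inter-marker distances; the initial class is
    drawn from ``mixing``.
    """
    B = _emission_matrix(np.asarray(codes), np.asarray(freqs, dtype=float), spec)
    ll, _, _ = _forward_backward(B, np.asarray(d_morgans, dtype=float), spec.rates,
                                 np.asarray(mixing, dtype=float))
    return ll


def fit_hbd(g: GenotypeMatrix, spec: HBDModelSpec | None = None,
            keep_posteriors: bool = False,
            freqs: np.ndarray | None = None) -> HBDResult:
    """Fit per-individual mixing coefficients by EM and decode posteriors.

    Allele frequencies default to the analyzed sample; monomorphic markers are
    dropped (zero information for HBD).  Chromosomes are independent sequences
    re-initialized from M.
    """
    spec = spec or HBDModelSpec()
    if freqs is None:
        freqs = g.allele_frequency()
    poly = np.isfinite(freqs) & (freqs > 0) & (freqs < 1)
    if not poly.all():
        logger.info("HBD: dropping %d monomorphic/uninformative markers", int((~poly).sum()))
    gp = g.subset(marker_idx=np.flatnonzero(poly))
    fr = freqs[poly]
    K = spec.n_classes

    chrom_blocks = []
    for c in gp.markers.chromosomes():
        idx = gp.markers.chrom_index(c)
        d = np.diff(gp.markers.cm[idx]) / 100.0     # cM -> Morgans
        chrom_blocks.append((idx, d))

    n_samples = gp.n_samples
    class_auto = np.zeros((n_samples, K))
    mixing_out = np.zeros((n_samples, K))
    logliks = np.zeros(n_samples)
    converged = np.zeros(n_samples, dtype=bool)
    posts: list[np.ndarray] | None = [] if keep_posteriors else None

    for i in range(n_samples):
        Bs = [(_emission_matrix(gp.codes[i, idx], fr[idx], spec), d)
              for idx, d in chrom_blocks]
        M = np.full(K, 1.0 / K)
        prev_ll = -np.inf
        for it in range(spec.max_iter):
            ll = 0.0
            stat = np.zeros(K)
            for B, d in Bs:
                l, _, jump = _forward_backward(B, d, spec.rates, M)
                ll += l
                stat += jump
            new_M = stat / stat.sum()
            if ll - prev_ll < spec.tol and it > 0:
                converged[i] = True
                break
            prev_ll = ll
            M = new_M
        else:
            logger.warning("HBD EM did not converge for sample %s", gp.samples[i])
        gammas = []
        ll = 0.0
        for B, d in Bs:
            l, gamma, _ = _forward_backward(B, d, spec.rates, M)
            ll += l
            gammas.append(gamma)
        gamma_all = np.vstack(gammas)
        class_auto[i] = gamma_all.mean(axis=0)
        mixing_out[i] = M
        logliks[i] = ll
        if posts is not None:
            posts.append(gamma_all)

    return HBDResult(samples=[str(s) for s in gp.samples], spec=spec,
                     class_autozygosity=class_auto, mixing=mixing_out,
                     loglik=logliks, converged=converged, posteriors=posts)


def fgt_curve(result: HBDResult, thresholds: np.ndarray | list[float]) -> pd.DataFrame:
    """F_G-T per threshold T: cumulative autozygosity of HBD classes with R_k <= T."""
    thresholds = np.asarray(thresholds, dtype=float)
    hbd_rates = result.spec.hbd_rates
    rows = {}
    for t in thresholds:
        use = hbd_rates <= t
        rows[t] = result.class_autozygosity[:, :-1][:, use].sum(axis=1)
    out = pd.DataFrame(rows, index=result.samples)
    out.columns.name = "T"
    return out
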