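"""SNP-array quality control.

Filters mirror the standard PLINK workflow for 50K-chip data: samples with
excess missingness are removed first, then markers are dropped in the fixed
order sex-chromosome -> call rate -> MAF -> Hardy-Weinberg, so that every
marker lands in exactly one exclusion category and the ledger is conservative
(initial = remaining + sum of removals).  The HWE test is the exact
conditional test on heterozygote counts; a marker is removed when p < the
threshold (exclusion reading).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln

from .io import MISSING, GenotypeMatrix

logger = logging.getLogger("autozyg")


@dataclass
class QCParams:
    """Marker/sample filter thresholds (defaults match common 50K-chip practice)."""

    min_call_rate: float = 0.95
    min_maf: float = 0.05
    max_sample_missing: float = 0.10
    hwe_p: float = 1e-5
    drop_sex_chromosomes: bool = True

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "max_sample_missing", "hwe_p"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class QCReport:
    """Exclusion ledger; invariant: remaining = initial - total_removed."""

    initial_markers: int
    removed_call_rate: int = 0
    removed_maf: int = 0
    removed_hwe: int = 0
    removed_sex_chrom: int = 0
    removed_samples: int = 0
    remaining_markers: int = 0
    remaining_samples: int = 0
    genotyping_rate: float = float("nan")

    @property
    def total_removed(self) -> int:
        return (self.removed_call_rate + self.removed_maf
                + self.removed_hwe + self.removed_sex_chrom)

    def validate(self) -> None:
        if self.initial_markers != self.remaining_markers + self.total_removed:
            raise AssertionError("QC ledger does not conserve marker counts")

    def to_rows(self) -> list[tuple[str, int]]:
        return [
            ("total_markers", self.initial_markers),
            ("removed_call_rate", self.removed_call_rate),
            ("removed_maf", self.removed_maf),
            ("removed_hwe", self.removed_hwe),
            ("removed_sex_chromosome", self.removed_sex_chrom),
            ("total_removed", self.total_removed),
            ("remaining_markers", self.remaining_markers),
            ("removed_samples", self.removed_samples),
            ("remaining_samples", self.remaining_samples),
        ]


def hwe_exact_test(n_hom1: int, n_het: int, n_hom2: int) -> float:
    """Exact conditional Hardy-Weinberg test (no mid-p).

    Conditions on the observed allele count and sums the probabilities of all
    heterozygote counts no more likely than the observed one (Wigginton-style
    two-sided exact test).  Monomorphic markers return 1.0.
    """
    if min(n_hom1, n_het, n_hom2) < 0:
        raise ValueError("genotype counts must be nonnegative")
    n = n_hom1 + n_het + n_hom2
    if n < 1:
        raise ValueError("no genotyped samples at marker")
    n_rare = 2 * min(n_hom1, n_hom2) + n_het
    if n_rare == 0 or n_rare == 2 * n:
        return 1.0

    hets = np.arange(n_rare % 2, n_rare + 1, 2)
    hets = hets[(n_rare - hets) // 2 + (2 * n - n_rare - hets) // 2 >= 0]
    hets = hets[(n_rare - hets) >= 0]
    hets = hets[(2 * n - n_rare - hets) >= 0]
    rare_hom = (n_rare - hets) // 2
    common_hom = (2 * n - n_rare - hets) // 2
    # P(het = h | n, n_rare) ∝ n! / (hom_r! h! hom_c!) * 2^h
    logp = (gammaln(n + 1) - gammaln(rare_hom + 1) - gammaln(hets + 1)
            - gammaln(common_hom + 1) + hets * np.log(2.0)
            - gammaln(2 * n + 1) + gammaln(n_rare + 1) + gammaln(2 * n - n_rare + 1))
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs = prob[hets == n_het][0]
    return float(min(1.0, prob[prob <= obs * (1 + 1e-12)].sum()))


def _marker_stats(g: GenotypeMatrix):
    obs = g.codes != MISSING
    n_obs = obs.sum(axis=0)
    call_rate = n_obs / max(g.n_samples, 1)
    freq = g.allele_frequency()
    maf = np.minimum(freq, 1 - freq)
    return obs, n_obs, call_rate, maf


def apply_filters(g: GenotypeMatrix, p: QCParams | None = None) -> tuple[GenotypeMatrix, QCReport]:
    """Apply sample then marker filters; returns survivors and the ledger.

    Order: samples failing missingness -> sex-chromosome markers -> call rate
    -> MAF -> HWE.  Marker statistics are computed on post-sample-removal data.
    """
    p = p or QCParams()
    report = QCReport(initial_markers=g.n_markers)

    sample_missing = g.missing_mask().mean(axis=1) if g.n_markers else np.zeros(g.n_samples)
    keep_samples = sample_missing <= p.max_sample_missing
    report.removed_samples = int((~keep_samples).sum())
    if not keep_samples.any():
        raise ValueError("all samples removed by missingness filter")
    g = g.subset(sample_idx=np.flatnonzero(keep_samples))

    n_markers = g.n_markers
    category = np.zeros(n_markers, dtype=np.int8)  # 0 keep, 1 sex, 2 call, 3 maf, 4 hwe
    if p.drop_sex_chromosomes:
        category[~g.markers.is_autosome()] = 1

    obs, n_obs, call_rate, maf = _marker_stats(g)
    undecided = category == 0
    category[undecided & (call_rate < p.min_call_rate)] = 2
    undecided = category == 0
    category[undecided & ~(maf >= p.min_maf)] = 3  # NaN freq (all missing) also fails

    for j in np.flatnonzero(category == 0):
        col = g.codes[obs[:, j], j]
        n_hom2 = int((col == 0).sum())
        n_het = int((col == 1).sum())
        n_hom1 = int((col == 2).sum())
        if n_hom1 + n_het + n_hom2 == 0:
            logger.warning("marker %s all-missing at HWE stage; skipped", g.markers.ids[j])
            continue
        if hwe_exact_test(n_hom1, n_het, n_hom2) < p.hwe_p:
            category[j] = 4

    report.removed_sex_chrom = int((category == 1).sum())
    report.removed_call_rate = int((category == 2).sum())
    report.removed_maf = int((category == 3).sum())
    report.removed_hwe = int((category == 4).sum())

    out = g.subset(marker_idx=np.flatnonzero(category == 0))
    report.remaining_markers = out.n_markers
    report.remaining_samples = out.n_samples
    report.genotyping_rate = 1.0 - out.missing_fraction()
    report.validate()
    logger.info("QC: %d/%d markers retained, %d samples removed",
                out.n_markers, report.initial_markers, report.removed_samples)
    return out, report
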