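"""Selection scan: pi, ZF_ST, EHH/XP-EHH, outlier and region calling."""

import numpy as np
import pandas as pd
import pytest

import autozyg as az
from autozyg.io import HaplotypeSet
from tests.conftest import make_genotypes, make_map


def pi_all_pairs_oracle(codes):
    """Mean proportion of allelically different pairs of copies, per site,
    by explicit enumeration of all pairs of allele copies."""
    out = []
    for j in range(codes.shape[1]):
        col = codes[:, j]
        col = col[col >= 0]
        alleles = []
        for c in col:
            alleles += [1] * int(c) + [0] * int(2 - c)
        alleles = np.array(alleles)
        n = len(alleles)
        diff = sum(1 for a in range(n) for b in range(a + 1, n)
                   if alleles[a] != alleles[b])
        out.append(diff / (n * (n - 1) / 2))
    return np.array(out)


class TestSitePi:
    def test_fixed_site_is_zero(self):
        g = make_genotypes([[2, 2], [2, 0]])
        assert az.site_pi(g)[0] == 0.0

    def test_half_frequency_four_copies(self):
        """k = 2 of 2n = 4 copies: 2*2*2/(4*3) = 2/3."""
        g = make_genotypes([[1, 1], [1, 0]])
        assert az.site_pi(g)[0] == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_all_pairs_oracle(self, seed):
        rng = np.random.default_rng(seed)
        codes = rng.integers(-1, 3, size=(8, 12)).astype(np.int8)
        codes[0] = 1      # keep >= 2 typed samples everywhere
        codes[1] = 0
        g = make_genotypes(codes)
        np.testing.assert_allclose(az.site_pi(g), pi_all_pairs_oracle(codes), rtol=1e-12)


class TestZFst:
    def test_mean_zero_sd_one(self):
        rng = np.random.default_rng(2)
        z = az.zfst(rng.uniform(0, 0.5, 500))
        assert np.nanmean(z) == pytest.approx(0.0, abs=1e-12)
        assert np.nanstd(z) == pytest.approx(1.0)

    def test_two_value_population_sd(self):
        """{0.1, 0.3} with the population (n-denominator) sd 0.1 gives -1, +1."""
        np.testing.assert_allclose(az.zfst(np.array([0.1, 0.3])), [-1.0, 1.0])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            az.zfst(np.full(10, 0.2))


def _hapset(rows, bps=None, cm=None):
    rows = np.asarray(rows, dtype=np.uint8)
    n = rows.shape[0] // 2
    markers = make_map(bps if bps is not None
                       else (np.arange(rows.shape[1]) + 1) * 100_000, cm=cm)
    samples = np.array([f"s{i}" for i in range(n)], dtype=object)
    return HaplotypeSet(samples, np.full(n, "P", dtype=object), rows, markers)


class TestEHH:
    def test_identical_haplotypes_stay_one(self):
        h = _hapset(np.tile([1, 0, 1, 0], (6, 1)))
        _, e = az.ehh(h, 0, +1)
        np.testing.assert_allclose(e, np.ones(4))

    def test_all_distinct_adjacent_marker_drops_to_zero(self):
        rows = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=np.uint8)
        rows = np.vstack([rows, [[0, 0], [1, 1]]])
        # make all six haplotypes pairwise distinct at marker 1 is impossible
        # with binary alleles; use 2 haplotypes instead
        h = _hapset(np.array([[0, 0], [0, 1]], dtype=np.uint8))
        _, e = az.ehh(h, 0, +1)
        assert e[0] == 1.0 and e[1] == 0.0

    def test_six_haplotype_hand_grouping(self):
        """Hand-derived homozygosity counts: 1, 12/30, 4/30."""
        rows = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 0],
                         [1, 1, 1], [1, 1, 1], [1, 0, 0]], dtype=np.uint8)
        h = _hapset(rows)
        _, e = az.ehh(h, 0, +1)
        np.testing.assert_allclose(e, [1.0, 12 / 30, 4 / 30])

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(7)
        h = _hapset(rng.integers(0, 2, size=(20, 30)).astype(np.uint8))
        _, e = az.ehh(h, 15, -1)
        assert (np.diff(e) <= 1e-12).all()

    def test_fewer_than_two_haplotypes_rejected(self):
        with pytest.raises(ValueError):
            az.ehh(_hapset(np.zeros((0, 3), dtype=np.uint8)), 0, 1)


class TestXPEHH:
    def _pair(self, seed=3, n=40, markers=200):
        rng = np.random.default_rng(seed)
        freqs = rng.uniform(0.2, 0.8, markers)
        hA = _hapset((rng.random((2 * n, markers)) < freqs).astype(np.uint8))
        hB = _hapset((rng.random((2 * n, markers)) < freqs).astype(np.uint8))
        return hA, hB

    def test_identical_sets_score_zero(self):
        hA, _ = self._pair()
        assert az.xpehh(hA, hA, 100) == 0.0

    def test_population_swap_flips_sign(self):
        hA, hB = self._pair()
        assert az.xpehh(hA, hB, 100) == pytest.approx(-az.xpehh(hB, hA, 100))

    def test_standardized_moments(self):
        rng = np.random.default_rng(9)
        raw = rng.normal(0.3, 0.7, 400)
        z = az.standardize_xpehh(raw)
        assert z.mean() == pytest.approx(0.0, abs=1e-12)
        assert z.var() == pytest.approx(1.0)

    def test_standardize_affine_invariance(self):
        rng = np.random.default_rng(10)
        x = rng.normal(size=100)
        np.testing.assert_allclose(az.standardize_xpehh(3.2 * x + 1.1),
                                   az.standardize_xpehh(x), atol=1e-10)

    def test_standardize_constant_rejected(self):
        with pytest.raises(ValueError):
            az.standardize_xpehh(np.full(10, 1.0))

    def test_neutral_background_tail_bounded(self):
        """Without a sweep, |standardized XP-EHH| > 2 at no more than 10% of cores."""
        cfg = az.SimConfig(seed=91, ne=150, generations=80,
                           populations={"A": 30, "B": 30},
                           n_chromosomes=1, chrom_length_cm=50)
        h, _, _ = az.simulate_wright_fisher(cfg, n_sample=60)
        pops = np.array(["A"] * 30 + ["B"] * 30, dtype=object)
        h = HaplotypeSet(h.samples, pops, h.haplotypes, h.markers)
        z = az.standardize_xpehh(az.xpehh_scan(h.by_population("A"),
                                               h.by_population("B")))
        assert np.mean(np.abs(z[np.isfinite(z)]) > 2) <= 0.10


class TestCallCandidates:
    def _rows(self, n=1000, seed=0, with_xp=True):
        rng = np.random.default_rng(seed)
        tab = pd.DataFrame({
            "chrom": "1", "id": [f"m{i}" for i in range(n)],
            "bp": (np.arange(n) + 1) * 100_000,
            "fst": rng.permutation(np.linspace(0.001, 0.5, n)),
            "pi_ratio": rng.permutation(np.linspace(0.5, 3.0, n)),
        })
        if with_xp:
            tab["xpehh"] = rng.permutation(np.linspace(-3, 3, n))
        return tab

    def test_quantile_counts_are_ceil(self):
        rows, venn, _ = az.call_candidates(self._rows(n=1000))
        assert venn["fst"] == 10 and venn["pi"] == 10 and venn["xpehh"] == 1
        rows, venn, _ = az.call_candidates(self._rows(n=999))
        assert venn["fst"] == 10 and venn["xpehh"] == 1

    def test_constructed_rank_intersection_counts(self):
        """Statistics engineered so the same 5 SNPs top both F_ST and pi-ratio."""
        n = 500
        tab = self._rows(n=n, with_xp=False)
        top = np.arange(5)
        fst = np.linspace(0.0, 0.3, n)
        ratio = np.linspace(0.5, 2.0, n)
        fst[top] = 0.9
        ratio[top] = 9.0
        tab["fst"], tab["pi_ratio"] = fst, ratio
        _, venn, _ = az.call_candidates(tab)
        assert venn["fst_and_pi"] == 5
        assert venn["xpehh"] == 0

    def test_regions_extended_and_merged(self):
        tab = self._rows(n=200, with_xp=False)
        tab["fst"] = 0.01
        tab.loc[[50, 51], "fst"] = 0.9     # adjacent outliers 100 kb apart
        tab["pi_ratio"] = 1.0
        tab.loc[100, "pi_ratio"] = 9.0
        _, venn, regions = az.call_candidates(
            tab, az.ScanParams(q_fst=2 / 200, q_pi=1 / 200))
        assert len(regions) == 2
        first = regions[0]
        assert first.end_bp - first.start_bp == 300_000   # merged pair +/- 100 kb
        assert regions[1].statistics == ["pi"]

    def test_no_annotation_empty_genes(self):
        _, _, regions = az.call_candidates(self._rows(n=100))
        assert all(r.genes == [] for r in regions)

    def test_bed_annotation_hits(self, tmp_path):
        tab = self._rows(n=100, with_xp=False)
        tab["fst"] = 0.0
        tab.loc[50, "fst"] = 1.0           # bp 5,100,000
        bed = tmp_path / "genes.bed"
        bed.write_text("1\t5050000\t5080000\tGENE1\n2\t1\t100\tOTHER\n")
        ann = az.read_gene_intervals(bed)
        _, _, regions = az.call_candidates(tab, az.ScanParams(q_fst=1 / 100, q_pi=1e-9),
                                           annotation=ann)
        hit = [r for r in regions if "GENE1" in r.genes]
        assert len(hit) == 1


class TestScanStatistics:
    def test_divergent_marker_tops_fst(self):
        rng = np.random.default_rng(20)
        n = 60
        freqs = rng.uniform(0.3, 0.7, 100)
        codes = rng.binomial(2, freqs, size=(2 * n, 100)).astype(np.int8)
        codes[:n, 0] = 2                    # fixed difference at marker 0
        codes[n:, 0] = 0
        pops = np.array(["H"] * n + ["L"] * n, dtype=object)
        g = make_genotypes(codes, populations=pops)
        tab = az.scan_statistics(g, ["H"], ["L"])
        assert tab["fst"].idxmax() == 0
        assert tab["zfst"].iloc[0] > 3
        np.testing.assert_allclose(np.nanmean(tab["zfst"]), 0, atol=1e-9)

    def test_pi_ratio_orientation_low_over_high(self):
        """Diversity lost in the high group inflates pi_low / pi_high."""
        rng = np.random.default_rng(21)
        n = 40
        codes_h = np.full((n, 50), 2, dtype=np.int8)          # high: monomorphic
        codes_h[:, 25:] = rng.binomial(2, 0.5, size=(n, 25))
        codes_l = rng.binomial(2, 0.5, size=(n, 50)).astype(np.int8)
        g = make_genotypes(np.vstack([codes_h, codes_l]),
                           populations=np.array(["H"] * n + ["L"] * n, dtype=object))
        tab = az.scan_statistics(g, ["H"], ["L"])
        lost = tab["pi_ratio"].iloc[:25]
        keptv = tab["pi_ratio"].iloc[25:]
        assert not np.isfinite(lost).any() or np.nanmin(lost) > np.nanmedian(keptv)
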