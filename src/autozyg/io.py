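"""Genotype and haplotype I/O.

Reads and writes PLINK text (.ped/.map) and binary (.bed/.bim/.fam, SNP-major)
genotype sets, phased VCF and Oxford haps/sample haplotypes, into a shared
in-memory model:

* :class:`MarkerMap` — per-marker chromosome, id, genetic (cM) and physical (bp)
  coordinates;
* :class:`GenotypeMatrix` — samples x markers genotype codes in {0, 1, 2}
  counting copies of the counted allele, ``-1`` for missing;
* :class:`HaplotypeSet` — 2n binary haplotypes for phased data.

Conventions: physical coordinates are 1-based inclusive (PLINK); exported BED
intervals are 0-based half-open via :func:`to_bed_interval`. The counted allele
is the allele-1 column of the .bim/.map companion file; no re-polarization is
ever performed. The family-id column provides the population label.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger("autozyg")

MISSING = -1

#: chromosome labels treated as sex/non-autosomal in goat-style PLINK files
SEX_CHROM_LABELS = {"X", "Y", "XY", "MT", "0"}

# PLINK .bed magic bytes (SNP-major third byte)
_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit .bed codes -> genotype code counting allele-1 copies
# 00 = hom allele-1 (2 copies), 01 = missing, 10 = het, 11 = hom allele-2
_BED_DECODE = np.array([2, MISSING, 1, 0], dtype=np.int8)
_BED_ENCODE = {2: 0b00, MISSING: 0b01, 1: 0b10, 0: 0b11}


class FormatError(ValueError):
    """Raised when an input file violates its declared format."""


# ---------------------------------------------------------------------------
# data model
# ---------------------------------------------------------------------------

@dataclass
class MarkerMap:
    """Marker coordinates: chromosome, id, genetic (cM) and physical (bp) position.

    Physical positions must be strictly increasing within a chromosome and
    marker ids unique.  If the genetic column is absent or all zero it is
    imputed as 1 cM/Mb (bp * 1e-6), which is flagged in the log.
    """

    chrom: np.ndarray          # str labels
    ids: np.ndarray            # str, unique
    cm: np.ndarray             # float64, centiMorgans
    bp: np.ndarray             # int64, 1-based

    cm_imputed: bool = False

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.ids = np.asarray(self.ids, dtype=object)
        self.cm = np.asarray(self.cm, dtype=np.float64)
        self.bp = np.asarray(self.bp, dtype=np.int64)
        if len({len(self.chrom), len(self.ids), len(self.cm), len(self.bp)}) != 1:
            raise ValueError("marker map columns have unequal lengths")
        if len(np.unique(self.ids)) != len(self.ids):
            raise ValueError("marker ids are not unique")
        for c in self.chromosomes():
            pos = self.bp[self.chrom == c]
            if np.any(np.diff(pos) <= 0):
                raise ValueError(f"physical positions not strictly increasing on chromosome {c}")
        if self.n > 0 and not np.any(self.cm != 0.0):
            self.cm = self.bp * 1e-6  # 1 cM/Mb
            self.cm_imputed = True
            logger.info("genetic positions absent; imputed at 1 cM/Mb")

    @property
    def n(self) -> int:
        return len(self.ids)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in file order."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_index(self, c: str) -> np.ndarray:
        return np.flatnonzero(self.chrom == c)

    def is_autosome(self) -> np.ndarray:
        return np.array([c not in SEX_CHROM_LABELS for c in self.chrom], dtype=bool)

    def subset(self, idx: np.ndarray) -> "MarkerMap":
        m = MarkerMap(self.chrom[idx], self.ids[idx], self.cm[idx], self.bp[idx])
        m.cm_imputed = self.cm_imputed
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"chrom": self.chrom, "id": self.ids, "cm": self.cm, "bp": self.bp})


def to_bed_interval(start_bp: int, end_bp: int) -> tuple[int, int]:
    """Convert a 1-based inclusive bp interval to 0-based half-open (BED)."""
    return start_bp - 1, end_bp


@dataclass
class GenotypeMatrix:
    """Diploid genotype codes (samples x markers) with a marker map.

    ``codes[i, j]`` counts copies of the counted allele (allele-1) in sample
    ``i`` at marker ``j``; ``-1`` means missing. ``populations`` carries the
    family-id column of the source file unless overridden.
    """

    samples: np.ndarray        # str sample ids
    populations: np.ndarray    # str population label per sample
    codes: np.ndarray          # int8 (n_samples, n_markers)
    markers: MarkerMap
    allele1: np.ndarray | None = None   # counted allele letter per marker
    allele2: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.shape != (len(self.samples), self.markers.n):
            raise ValueError(
                f"codes shape {self.codes.shape} does not match "
                f"{len(self.samples)} samples x {self.markers.n} markers"
            )
        if self.allele1 is None:
            self.allele1 = np.full(self.markers.n, "A", dtype=object)
        if self.allele2 is None:
            self.allele2 = np.full(self.markers.n, "B", dtype=object)
        self.allele1 = np.asarray(self.allele1, dtype=object)
        self.allele2 = np.asarray(self.allele2, dtype=object)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_markers(self) -> int:
        return self.markers.n

    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def missing_fraction(self) -> float:
        if self.codes.size == 0:
            return 0.0
        return float(self.missing_mask().mean())

    def allele_frequency(self) -> np.ndarray:
        """Counted-allele frequency per marker over non-missing genotypes (NaN if none)."""
        obs = self.codes != MISSING
        counts = np.where(obs, self.codes, 0).sum(axis=0)
        denom = 2 * obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(denom > 0, counts / np.maximum(denom, 1), np.nan)

    def subset(self, sample_idx: np.ndarray | None = None,
               marker_idx: np.ndarray | None = None) -> "GenotypeMatrix":
        si = np.arange(self.n_samples) if sample_idx is None else np.asarray(sample_idx)
        mi = np.arange(self.n_markers) if marker_idx is None else np.asarray(marker_idx)
        return GenotypeMatrix(
            self.samples[si], self.populations[si],
            self.codes[np.ix_(si, mi)], self.markers.subset(mi),
            self.allele1[mi], self.allele2[mi],
        )

    def by_population(self, label: str) -> "GenotypeMatrix":
        return self.subset(sample_idx=np.flatnonzero(self.populations == label))

    def population_labels(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.populations:
            seen.setdefault(p, None)
        return list(seen)

    def set_populations_from_tsv(self, path: str | Path) -> None:
        """Override population labels from a two-column sample<TAB>population file."""
        tab = pd.read_csv(path, sep="\t", header=None, names=["sample", "population"], dtype=str)
        mapping = dict(zip(tab["sample"], tab["population"]))
        self.populations = np.array(
            [mapping.get(s, p) for s, p in zip(self.samples, self.populations)], dtype=object
        )


@dataclass
class HaplotypeSet:
    """Phased binary haplotypes: rows 2i, 2i+1 belong to sample i; no missing."""

    samples: np.ndarray
    populations: np.ndarray
    haplotypes: np.ndarray     # uint8 (2*n_samples, n_markers), values 0/1
    markers: MarkerMap

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=object)
        self.populations = np.asarray(self.populations, dtype=object)
        self.haplotypes = np.asarray(self.haplotypes, dtype=np.uint8)
        if self.haplotypes.shape != (2 * len(self.samples), self.markers.n):
            raise ValueError("haplotype array must have exactly two rows per sample")
        if self.haplotypes.size and self.haplotypes.max() > 1:
            raise ValueError("haplotype values must be binary")

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def to_genotypes(self) -> GenotypeMatrix:
        codes = (self.haplotypes[0::2].astype(np.int8) + self.haplotypes[1::2])
        return GenotypeMatrix(self.samples, self.populations, codes, self.markers,
                              np.full(self.markers.n, "B", dtype=object),
                              np.full(self.markers.n, "A", dtype=object))

    def by_population(self, label: str) -> "HaplotypeSet":
        si = np.flatnonzero(self.populations == label)
        hi = np.ravel(np.column_stack([2 * si, 2 * si + 1]))
        return HaplotypeSet(self.samples[si], self.populations[si],
                            self.haplotypes[hi], self.markers)


# ---------------------------------------------------------------------------
# PLINK text (.ped/.map)
# ---------------------------------------------------------------------------

def _read_map(path: Path) -> tuple[MarkerMap, None]:
    rows = pd.read_csv(path, sep=r"\s+", header=None,
                       names=["chrom", "id", "cm", "bp"], dtype=str)
    return MarkerMap(rows["chrom"].to_numpy(dtype=object),
                     rows["id"].to_numpy(dtype=object),
                     rows["cm"].astype(float).to_numpy(),
                     rows["bp"].astype(np.int64).to_numpy()), None


def _read_ped(path: Path, n_markers: int):
    samples, fids, geno_rows = [], [], []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 6 + 2 * n_markers:
                raise FormatError(
                    f"{path}: line {line_no} has {len(tok)} fields, "
                    f"expected {6 + 2 * n_markers} for {n_markers} markers"
                )
            fids.append(tok[0])
            samples.append(tok[1])
            geno_rows.append(tok[6:])
    return samples, fids, geno_rows


def _decode_ped_genotypes(geno_rows, n_markers):
    """Decode allele-pair text columns to counted-allele codes.

    The .ped format has no allele-designation columns, so the counted allele is
    recovered from the written heterozygote order (this writer emits
    counted-allele-first heterozygotes); for het-free markers it falls back to
    the lexicographically smaller observed allele.  Binary filesets carry the
    designation explicitly and round-trip exactly in all cases.
    """
    n = len(geno_rows)
    codes = np.full((n, n_markers), MISSING, dtype=np.int8)
    first_het = np.full(n_markers, None, dtype=object)
    observed: list[set] = [set() for _ in range(n_markers)]
    for row in geno_rows:
        for j in range(n_markers):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            observed[j].update((a, b))
            if len(observed[j]) > 2:
                raise FormatError(f"marker index {j}: more than two alleles observed")
            if a != b and first_het[j] is None:
                first_het[j] = a
    allele1 = np.empty(n_markers, dtype=object)
    allele2 = np.empty(n_markers, dtype=object)
    for j in range(n_markers):
        obs = sorted(observed[j])
        a1 = first_het[j] if first_het[j] is not None else (obs[0] if obs else "A")
        rest = [al for al in obs if al != a1]
        allele1[j] = a1
        allele2[j] = rest[0] if rest else ("B" if a1 != "B" else "A")
    for i, row in enumerate(geno_rows):
        for j in range(n_markers):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                continue
            codes[i, j] = (a == allele1[j]) + (b == allele1[j])
    return codes, allele1, allele2


def read_plink(path_prefix: str | Path, dialect: str = "binary") -> GenotypeMatrix:
    """Read a PLINK fileset (``text`` = .ped/.map, ``binary`` = .bed/.bim/.fam).

    The .bed must be SNP-major with magic bytes 0x6C 0x1B 0x01. Genotype codes
    count allele-1 copies; family id becomes the population label.
    """
    prefix = Path(path_prefix)
    if dialect == "text":
        markers, _ = _read_map(prefix.with_suffix(".map"))
        samples, fids, geno_rows = _read_ped(prefix.with_suffix(".ped"), markers.n)
        codes, a1, a2 = _decode_ped_genotypes(geno_rows, markers.n)
        return GenotypeMatrix(np.array(samples, dtype=object), np.array(fids, dtype=object),
                              codes, markers, a1, a2)
    if dialect != "binary":
        raise ValueError(f"unknown dialect {dialect!r}")

    def _table(path, names):
        try:
            return pd.read_csv(path, sep=r"\s+", header=None, names=names, dtype=str)
        except pd.errors.EmptyDataError:
            return pd.DataFrame(columns=names, dtype=str)

    bim = _table(prefix.with_suffix(".bim"), ["chrom", "id", "cm", "bp", "a1", "a2"])
    markers = MarkerMap(bim["chrom"].to_numpy(dtype=object), bim["id"].to_numpy(dtype=object),
                        bim["cm"].astype(float).to_numpy(), bim["bp"].astype(np.int64).to_numpy())
    fam = _table(prefix.with_suffix(".fam"), ["fid", "iid", "pat", "mat", "sex", "phe"])
    n_samples = len(fam)

    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise FormatError(f"{prefix}.bed: bad magic bytes {raw[:3].hex()} (want {_BED_MAGIC.hex()})")
    bytes_per_marker = (n_samples + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != bytes_per_marker * markers.n:
        raise FormatError(
            f"{prefix}.bed: {len(body)} data bytes, expected {bytes_per_marker * markers.n}"
        )
    if markers.n == 0 or n_samples == 0:
        codes = np.zeros((n_samples, markers.n), dtype=np.int8)
    else:
        body = body.reshape(markers.n, bytes_per_marker)
        # unpack 2-bit fields, sample-minor within byte (LSB first)
        shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
        two_bit = (body[:, :, None] >> shifts) & 0b11      # (markers, bytes, 4)
        two_bit = two_bit.reshape(markers.n, -1)[:, :n_samples]
        codes = _BED_DECODE[two_bit].T.copy()              # (samples, markers)
    return GenotypeMatrix(fam["iid"].to_numpy(dtype=object), fam["fid"].to_numpy(dtype=object),
                          codes, markers,
                          bim["a1"].to_numpy(dtype=object), bim["a2"].to_numpy(dtype=object))


def write_plink(g: GenotypeMatrix, path_prefix: str | Path, dialect: str = "binary") -> None:
    """Write ``g`` as a PLINK fileset re-readable to an equal matrix."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    mapframe = g.markers.to_frame()
    if dialect == "text":
        mapframe.to_csv(prefix.with_suffix(".map"), sep="\t", header=False, index=False)
        with open(prefix.with_suffix(".ped"), "w") as fh:
            for i in range(g.n_samples):
                fields = [str(g.populations[i]), str(g.samples[i]), "0", "0", "0", "-9"]
                for j in range(g.n_markers):
                    c = g.codes[i, j]
                    if c == MISSING:
                        fields += ["0", "0"]
                    else:
                        a1, a2 = g.allele1[j], g.allele2[j]
                        fields += [a1] * int(c) + [a2] * int(2 - c)
                fh.write(" ".join(fields) + "\n")
        return
    if dialect != "binary":
        raise ValueError(f"unknown dialect {dialect!r}")

    bim = mapframe.copy()
    bim["a1"] = g.allele1
    bim["a2"] = g.allele2
    bim.to_csv(prefix.with_suffix(".bim"), sep="\t", header=False, index=False)
    fam = pd.DataFrame({"fid": g.populations, "iid": g.samples,
                        "pat": "0", "mat": "0", "sex": "0", "phe": "-9"})
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)

    n = g.n_samples
    bytes_per_marker = (n + 3) // 4
    enc = np.zeros((g.n_markers, 4 * bytes_per_marker), dtype=np.uint8)
    lut = np.zeros(4, dtype=np.uint8)
    for code, bits in _BED_ENCODE.items():
        lut[code % 4] = bits                   # -1 -> index 3
    enc[:, :n] = lut[g.codes.T % 4]
    packed = (enc.reshape(g.n_markers, bytes_per_marker, 4)
              << np.array([0, 2, 4, 6], dtype=np.uint8)).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# phased haplotypes
# ---------------------------------------------------------------------------

def _read_phased_vcf(path: Path) -> HaplotypeSet:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples, dtype=object)
    chroms, ids, bps, columns = [], [], [], []
    for var in vcf:
        gt = np.asarray(var.genotypes)          # (n_samples, 3): a, b, phased flag
        if not np.all(gt[:, 2]):
            bad = samples[np.flatnonzero(gt[:, 2] == 0)[0]]
            raise FormatError(
                f"{path}: unphased genotype for sample {bad} at {var.CHROM}:{var.POS}"
            )
        gts = gt[:, :2]
        if np.any(gts < 0):
            raise FormatError(f"{path}: missing genotype at {var.CHROM}:{var.POS}; "
                              "haplotype input must be complete")
        chroms.append(str(var.CHROM))
        ids.append(var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}")
        bps.append(var.POS)
        columns.append(gts.reshape(-1).astype(np.uint8))
    markers = MarkerMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                        np.zeros(len(ids)), np.array(bps, dtype=np.int64))
    hap = np.column_stack(columns) if columns else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    return HaplotypeSet(samples, samples.copy(), hap, markers)


def _read_haps_sample(path: Path) -> HaplotypeSet:
    """Oxford .haps/.sample: one marker per .haps row, two columns per sample."""
    sample_file = path.with_suffix(".sample")
    stab = pd.read_csv(sample_file, sep=r"\s+", dtype=str)
    stab = stab.iloc[1:]  # second header row of type codes
    samples = stab.iloc[:, 1].to_numpy(dtype=object)
    pops = stab.iloc[:, 0].to_numpy(dtype=object)

    chroms, ids, bps, rows = [], [], [], []
    with open(path.with_suffix(".haps")) as fh:
        for line_no, line in enumerate(fh, start=1):
            tok = line.split()
            if not tok:
                continue
            if len(tok) != 5 + 2 * len(samples):
                raise FormatError(f"{path}: haps line {line_no} has {len(tok)} fields, "
                                  f"expected {5 + 2 * len(samples)}")
            chroms.append(tok[0])
            ids.append(tok[1])
            bps.append(int(tok[2]))
            rows.append(np.array(tok[5:], dtype=np.uint8))
    markers = MarkerMap(np.array(chroms, dtype=object), np.array(ids, dtype=object),
                        np.zeros(len(ids)), np.array(bps, dtype=np.int64))
    hap = np.column_stack(rows) if rows else np.zeros((2 * len(samples), 0), dtype=np.uint8)
    return HaplotypeSet(samples, pops, hap, markers)


def read_haplotypes(path: str | Path, format: str = "phased-vcf") -> HaplotypeSet:
    """Read phased haplotypes (``phased-vcf`` or ``haps-sample``).

    Any unphased or missing genotype raises :class:`FormatError` naming the site.
    """
    p = Path(path)
    if format == "phased-vcf":
        return _read_phased_vcf(p)
    if format == "haps-sample":
        return _read_haps_sample(p)
    raise ValueError(f"unknown haplotype format {format!r}")


def write_haps_sample(h: HaplotypeSet, path_prefix: str | Path) -> None:
    """Write Oxford .haps + .sample files (re-readable by :func:`read_haplotypes`)."""
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    with open(prefix.with_suffix(".sample"), "w") as fh:
        fh.write("ID_1 ID_2 missing\n0 0 0\n")
        for p, s in zip(h.populations, h.samples):
            fh.write(f"{p} {s} 0\n")
    with open(prefix.with_suffix(".haps"), "w") as fh:
        for j in range(h.markers.n):
            lead = [str(h.markers.chrom[j]), str(h.markers.ids[j]),
                    str(int(h.markers.bp[j])), "A", "B"]
            fh.write(" ".join(lead + [str(int(v)) for v in h.haplotypes[:, j]]) + "\n")
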