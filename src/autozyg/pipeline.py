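"""End-to-end orchestration: qc -> roh / hbd / ne / structure / scan.

``run_pipeline`` executes the enabled stages in dependency order on one input
genotype set (plus optional phased haplotypes for XP-EHH), writing every table
as TSV into the output directory together with a manifest carrying the tool
version, the config hash and per-stage status.  Identical config + seed yields
byte-identical outputs.  A failing stage aborts its dependents but not
independent stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .hbd import HBDModelSpec, fgt_curve, fit_hbd
from .io import (GenotypeMatrix, HaplotypeSet, read_haplotypes, read_plink,
                 to_bed_interval, write_plink)
from .ne import default_bins, estimate_ne, ne_table
from .popdiff import (amova, ibs_distance, ld_prune, nj_tree, pca,
                      reynolds_distance, weir_cockerham_fst)
from .qc import QCParams, apply_filters
from .roh import (L_AUTO_MB, ROHParams, detect_roh, fhom, froh, froh_by_class,
                  roh_islands, summarize)
from .selscan import ScanParams, call_candidates, read_gene_intervals, scan_statistics

logger = logging.getLogger("autozyg")

_KNOWN_KEYS = {
    "input_prefix", "input_dialect", "haplotypes", "haplotype_format",
    "population_tsv", "annotation", "output_dir", "seed", "stages",
    "qc", "roh", "hbd", "ne", "scan", "l_auto_mb", "chrom_lengths_mb",
    "high_populations", "low_populations", "hbd_thresholds",
    "ld_prune_window", "ld_prune_step", "ld_prune_r2", "amova_permutations",
}
ALL_STAGES = ["qc", "roh", "hbd", "ne", "structure", "scan"]


@dataclass
class RunConfig:
    input_prefix: str
    output_dir: str
    input_dialect: str = "binary"
    haplotypes: str | None = None
    haplotype_format: str = "haps-sample"
    population_tsv: str | None = None
    annotation: str | None = None
    seed: int = 1
    stages: list[str] = field(default_factory=lambda: list(ALL_STAGES))
    qc: QCParams = field(default_factory=QCParams)
    roh: ROHParams = field(default_factory=ROHParams)
    hbd: HBDModelSpec = field(default_factory=HBDModelSpec)
    scan: ScanParams = field(default_factory=ScanParams)
    l_auto_mb: float = L_AUTO_MB
    chrom_lengths_mb: dict[str, float] | None = None
    high_populations: list[str] = field(default_factory=list)
    low_populations: list[str] = field(default_factory=list)
    hbd_thresholds: list[float] = field(default_factory=lambda: [2.0 ** k for k in range(1, 10)])
    ld_prune_window: int = 50
    ld_prune_step: int = 10
    ld_prune_r2: float = 0.1
    amova_permutations: int = 100

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _KNOWN_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key, typ in (("qc", QCParams), ("roh", ROHParams),
                         ("hbd", HBDModelSpec), ("scan", ScanParams)):
            if key in raw and isinstance(raw[key], dict):
                raw[key] = typ(**raw[key])
        cfg = cls(**raw)
        for name in ("input_prefix",):
            probe = Path(getattr(cfg, name))
            candidates = list(probe.parent.glob(probe.name + ".*"))
            if not candidates:
                raise FileNotFoundError(f"no files match input prefix {probe}")
        return cfg

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if isinstance(o, np.ndarray):
                return o.tolist()
            if isinstance(o, dict):
                return {k: enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        payload = dataclasses.asdict(self)
        payload.pop("output_dir", None)     # destination is not analysis identity
        blob = json.dumps(enc(payload), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _write(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=index, float_format="%.6g")


def run_pipeline(cfg: RunConfig, genotypes: GenotypeMatrix | None = None,
                 haplotypes: HaplotypeSet | None = None) -> dict:
    """Run the enabled stages; returns {stage: "ok"|"failed: ..."|"skipped"}.

    ``genotypes``/``haplotypes`` may be passed directly (e.g. from the
    simulator); otherwise they are read from the configured paths.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    status: dict[str, str] = {}

    if genotypes is None:
        genotypes = read_plink(cfg.input_prefix, cfg.input_dialect)
    if cfg.population_tsv:
        genotypes.set_populations_from_tsv(cfg.population_tsv)
    if haplotypes is None and cfg.haplotypes:
        haplotypes = read_haplotypes(cfg.haplotypes, cfg.haplotype_format)

    g = genotypes
    if "qc" in cfg.stages:
        try:
            g, report = apply_filters(genotypes, cfg.qc)
            _write(pd.DataFrame(report.to_rows(), columns=["category", "count"]),
                   out / "qc_ledger.tsv")
            status["qc"] = "ok"
        except Exception as exc:   # noqa: BLE001 - stage isolation is the contract
            logger.error("qc stage failed: %s", exc)
            status["qc"] = f"failed: {exc}"
            for dep in ("roh", "hbd", "ne", "structure", "scan"):
                if dep in cfg.stages:
                    status[dep] = "skipped (qc failed)"
            _finish(cfg, out, status)
            return status

    samples = [str(s) for s in g.samples]
    if "roh" in cfg.stages:
        try:
            segments = detect_roh(g, cfg.roh)
            summary = summarize(segments, g, cfg.chrom_lengths_mb)
            _write(summary["segments"], out / "roh_segments.tsv")
            _write(summary["per_breed"], out / "roh_per_breed.tsv")
            _write(summary["per_chromosome"], out / "roh_per_chromosome.tsv")
            inb = pd.DataFrame({"F_ROH": froh(segments, samples, cfg.l_auto_mb),
                                "F_HOM": fhom(g)})
            inb = inb.join(froh_by_class(segments, samples, cfg.l_auto_mb)
                           .add_prefix("F_ROH_"))
            _write(inb, out / "inbreeding.tsv", index=True)
            islands, per_snp = roh_islands(segments, g)
            _write(per_snp, out / "roh_snp_occurrence.tsv")
            bed = islands.copy()
            if len(bed):
                starts, ends = zip(*[to_bed_interval(s, e) for s, e in
                                     zip(bed["start_bp"], bed["end_bp"])])
                bed["start_bp"], bed["end_bp"] = starts, ends
            bed.to_csv(out / "roh_islands.bed", sep="\t", header=False, index=False)
            status["roh"] = "ok"
        except Exception as exc:   # noqa: BLE001
            logger.error("roh stage failed: %s", exc)
            status["roh"] = f"failed: {exc}"

    if "hbd" in cfg.stages:
        try:
            res = fit_hbd(g, cfg.hbd)
            _write(res.autozygosity_frame(), out / "hbd_class_autozygosity.tsv", index=True)
            _write(fgt_curve(res, cfg.hbd_thresholds), out / "hbd_fgt_curve.tsv", index=True)
            status["hbd"] = "ok"
        except Exception as exc:   # noqa: BLE001
            logger.error("hbd stage failed: %s", exc)
            status["hbd"] = f"failed: {exc}"

    if "ne" in cfg.stages:
        try:
            frames = []
            for pop in g.population_labels():
                bins = estimate_ne(g.by_population(pop), default_bins())
                tab = ne_table(bins)
                tab.insert(0, "population", pop)
                frames.append(tab)
            _write(pd.concat(frames, ignore_index=True), out / "ne_bins.tsv")
            status["ne"] = "ok"
        except Exception as exc:   # noqa: BLE001
            logger.error("ne stage failed: %s", exc)
            status["ne"] = f"failed: {exc}"

    if "structure" in cfg.stages:
        try:
            dr, theta = reynolds_distance(g)
            _write(dr.to_frame(), out / "reynolds_distance.tsv", index=True)
            _write(theta.to_frame(), out / "pairwise_theta.tsv", index=True)
            res = amova(g, cfg.amova_permutations, seed=cfg.seed)
            _write(pd.DataFrame([dataclasses.asdict(res)]), out / "amova.tsv")
            kept = ld_prune(g, cfg.ld_prune_window, cfg.ld_prune_step, cfg.ld_prune_r2)
            pruned = g.subset(marker_idx=kept)
            coords, fractions = pca(pruned)
            _write(coords, out / "pca_coordinates.tsv", index=True)
            _write(pd.DataFrame({"component": np.arange(1, len(fractions) + 1),
                                 "fraction": fractions}), out / "pca_variance.tsv")
            dm = ibs_distance(g, level="population")
            if len(dm.labels) >= 3:
                (out / "nj_tree.nwk").write_text(nj_tree(dm) + "\n")
            else:
                logger.warning("structure: fewer than 3 populations; NJ tree skipped")
            write_plink(pruned, out / "pruned_for_admixture", dialect="binary")
            status["structure"] = "ok"
        except Exception as exc:   # noqa: BLE001
            logger.error("structure stage failed: %s", exc)
            status["structure"] = f"failed: {exc}"

    if "scan" in cfg.stages:
        try:
            high = cfg.high_populations or g.population_labels()[:1]
            low = cfg.low_populations or g.population_labels()[1:2]
            hap_pair = None
            if haplotypes is not None:
                hap_qc = _restrict_haps(haplotypes, g)
                hap_pair = (
                    _merge_haps(hap_qc, high),
                    _merge_haps(hap_qc, low),
                )
            else:
                logger.warning("scan: no haplotype input; XP-EHH skipped")
            rows = scan_statistics(g, high, low, hap_pair, cfg.scan)
            annotation = read_gene_intervals(cfg.annotation) if cfg.annotation else None
            chrom_bp = ({c: int(v * 1e6) for c, v in cfg.chrom_lengths_mb.items()}
                        if cfg.chrom_lengths_mb else None)
            rows, venn, regions = call_candidates(rows, cfg.scan, annotation, chrom_bp)
            _write(rows, out / "scan_rows.tsv")
            _write(pd.DataFrame(sorted(venn.items()), columns=["set", "count"]),
                   out / "scan_venn.tsv")
            reg_rows = []
            for r in regions:
                s0, e0 = to_bed_interval(r.start_bp, r.end_bp)
                reg_rows.append({"chrom": r.chrom, "start": s0, "end": e0,
                                 "statistics": ",".join(r.statistics),
                                 "genes": ",".join(r.genes)})
            pd.DataFrame(reg_rows, columns=["chrom", "start", "end", "statistics", "genes"]) \
                .to_csv(out / "scan_regions.bed", sep="\t", header=False, index=False)
            status["scan"] = "ok" if hap_pair else "ok (xpehh skipped)"
        except Exception as exc:   # noqa: BLE001
            logger.error("scan stage failed: %s", exc)
            status["scan"] = f"failed: {exc}"

    _finish(cfg, out, status)
    return status


def _restrict_haps(h: HaplotypeSet, g: GenotypeMatrix) -> HaplotypeSet:
    """Keep only haplotype markers that survived QC (matched by marker id)."""
    keep_ids = set(g.markers.ids)
    idx = np.flatnonzero([mid in keep_ids for mid in h.markers.ids])
    if len(idx) == h.markers.n:
        return h
    logger.info("scan: restricting haplotypes to %d/%d QC-surviving markers",
                len(idx), h.markers.n)
    return HaplotypeSet(h.samples, h.populations, h.haplotypes[:, idx],
                        h.markers.subset(idx))


def _merge_haps(h: HaplotypeSet, pops: list[str]) -> HaplotypeSet:
    keep = np.flatnonzero(np.isin(h.populations, pops))
    rows = np.ravel(np.column_stack([2 * keep, 2 * keep + 1]))
    return HaplotypeSet(h.samples[keep], h.populations[keep],
                        h.haplotypes[rows], h.markers)


def _finish(cfg: RunConfig, out: Path, status: dict[str, str]) -> None:
    manifest = {"version": __version__, "config_hash": cfg.config_hash(),
                "seed": cfg.seed, "stages": status}
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
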