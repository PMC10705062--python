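"""End-to-end orchestration: qc -> structure -> scan -> gene.

One YAML config drives the whole run; every output TSV carries a header
comment with the tool version, a hash of the resolved config, and the seed,
so a rerun with the same config and seed is byte-identical (no timestamps).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

import pandas as pd
import yaml

from . import __version__
from .genes import characteristic_loci, gene_profile
from .io import (
    read_fai,
    read_gtf_genes,
    read_pop_map,
    read_vcf,
    write_newick,
    write_vcf,
)
from .matrix import GenotypeMatrix
from .qc import QcReport, QcThresholds, apply_qc
from .structure import admixture_cv, admixture_em, ibs_matrix, neighbor_joining, pca
from .sweep import ScanThresholds, genes_in_regions, scan

logger = logging.getLogger(__name__)


def parse_chrom_spec(spec: str | Sequence[str]) -> list[str]:
    """Parse a chromosome spec like ``"1-18"`` or ``"1-18,X"`` or a list."""
    if not isinstance(spec, str):
        return [str(c) for c in spec]
    out: list[str] = []
    for part in spec.split(","):
        part = part.strip()
        if "-" in part and all(s.strip().isdigit() for s in part.split("-", 1)):
            lo, hi = (int(s) for s in part.split("-", 1))
            out.extend(str(c) for c in range(lo, hi + 1))
        elif part:
            out.append(part)
    return out


@dataclass
class PipelineConfig:
    """Resolved configuration for one full run."""

    vcf: Path
    pop_map: Path
    fai: Path
    outdir: Path
    gtf: Path | None = None
    seed: int = 0
    group1_pops: list[str] = field(default_factory=list)
    group2_pops: list[str] = field(default_factory=list)
    group_labels: tuple[str, str] = ("indigenous", "commercial")
    qc: QcThresholds = field(default_factory=QcThresholds)
    qc_chroms: list[str] = field(default_factory=lambda: [str(c) for c in range(1, 19)])
    pca_components: int = 10
    k_range: list[int] = field(default_factory=lambda: list(range(2, 11)))
    cv_folds: int = 5
    em_restarts: int = 5
    scan_window: int = 40_000
    scan_step: int = 20_000
    scan_quantile: float = 0.05
    gene_names: list[str] = field(default_factory=list)
    gene_flank: int = 50_000
    gene_margin: float = 0.5
    run_structure: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw: dict[str, Any] = yaml.safe_load(Path(path).read_text()) or {}
        paths = raw.get("paths", {})
        qc_raw = dict(raw.get("qc", {}))
        chroms = parse_chrom_spec(qc_raw.pop("chroms", "1-18"))
        st = raw.get("structure", {})
        sc = raw.get("scan", {})
        ge = raw.get("gene", {})
        groups = raw.get("groups", {})
        cfg = cls(
            vcf=Path(paths["vcf"]),
            pop_map=Path(paths["pop_map"]),
            fai=Path(paths["fai"]),
            gtf=Path(paths["gtf"]) if paths.get("gtf") else None,
            outdir=Path(raw.get("outdir", "sweepscan_out")),
            seed=int(raw.get("seed", 0)),
            group1_pops=list(groups.get("group1", [])),
            group2_pops=list(groups.get("group2", [])),
            group_labels=tuple(
                raw.get("group_labels", ("indigenous", "commercial"))
            ),
            qc=QcThresholds(**qc_raw),
            qc_chroms=chroms,
            pca_components=int(st.get("pca", 10)),
            k_range=list(
                range(int(st.get("k_min", 2)), int(st.get("k_max", 10)) + 1)
            ),
            cv_folds=int(st.get("folds", 5)),
            em_restarts=int(st.get("restarts", 5)),
            scan_window=int(sc.get("window", 40_000)),
            scan_step=int(sc.get("step", 20_000)),
            scan_quantile=float(sc.get("quantile", 0.05)),
            gene_names=list(ge.get("genes", [])),
            gene_flank=int(ge.get("flank", 50_000)),
            gene_margin=float(ge.get("margin", 0.5)),
            run_structure=bool(st.get("enabled", True)),
        )
        cfg.validate()
        return cfg

    def validate(self) -> None:
        for name in ("vcf", "pop_map", "fai"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name} path does not exist: {p}")
        if self.gene_names and self.gtf is None:
            raise ValueError("gene stage requested but no GTF configured")
        if self.gtf is not None and not Path(self.gtf).exists():
            raise FileNotFoundError(f"gtf path does not exist: {self.gtf}")

    def config_hash(self) -> str:
        payload = {
            k: str(v) for k, v in asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:12]


def output_header(config: PipelineConfig) -> str:
    return (
        f"# sweepscan v{__version__} config={config.config_hash()} "
        f"seed={config.seed}\n"
    )


def write_tsv(df: pd.DataFrame, path: Path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        fh.write(output_header(config))
        df.to_csv(fh, sep="\t", index=False, na_rep="NA", lineterminator="\n")


def run_all(config: PipelineConfig) -> dict[str, Any]:
    """Execute every configured stage; returns a machine-readable report."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "stages": {},
    }

    # ---- load -----------------------------------------------------------
    pops = read_pop_map(config.pop_map)
    gm = read_vcf(config.vcf, pops)
    chrom_lengths = read_fai(config.fai)
    logger.info("loaded %d samples x %d variants", gm.n_samples, gm.n_variants)

    # ---- qc -------------------------------------------------------------
    qc_report = QcReport()
    try:
        gm_qc = apply_qc(gm, config.qc, config.qc_chroms, report=qc_report)
    except Exception as e:
        raise RuntimeError(f"stage qc failed: {e}") from e
    write_tsv(
        pd.DataFrame(qc_report.rows(), columns=["stage", "count"]),
        out / "qc_report.tsv",
        config,
    )
    write_vcf(gm_qc, out / "qc_filtered.vcf", chrom_lengths=chrom_lengths)
    report["stages"]["qc"] = dict(qc_report.rows())

    # ---- structure ------------------------------------------------------
    if config.run_structure:
        try:
            _structure_stage(config, gm_qc, out, report)
        except Exception as e:
            raise RuntimeError(f"stage structure failed: {e}") from e

    # ---- scan -----------------------------------------------------------
    group1 = gm_qc.samples_in_pops(config.group1_pops) if config.group1_pops else []
    group2 = gm_qc.samples_in_pops(config.group2_pops) if config.group2_pops else []
    regions = []
    if group1 and group2:
        try:
            windows, realized, regions = scan(
                gm_qc,
                group1,
                group2,
                chrom_lengths,
                ScanThresholds(
                    fst_quantile=config.scan_quantile,
                    ratio_quantile=config.scan_quantile,
                ),
                size=config.scan_window,
                step=config.scan_step,
                group_labels=config.group_labels,
            )
        except Exception as e:
            raise RuntimeError(f"stage scan failed: {e}") from e
        win_df = pd.DataFrame(
            [
                (w.chrom, w.start, w.end, w.n_sites, w.fst, w.pi_group1,
                 w.pi_group2, w.log2_ratio, w.flag or "none")
                for w in windows
            ],
            columns=["chrom", "start", "end", "n_sites", "fst", "pi_group1",
                     "pi_group2", "log2_ratio", "flag"],
        )
        write_tsv(win_df, out / "scan_windows.tsv", config)
        write_tsv(
            pd.DataFrame(
                {
                    "name": ["fst_cut", "log2_ratio_low_cut", "log2_ratio_high_cut"],
                    "value": [realized.realized_fst_cut,
                              realized.realized_low_cut,
                              realized.realized_high_cut],
                }
            ),
            out / "scan_thresholds.tsv",
            config,
        )
        reg_df = pd.DataFrame(
            [
                (r.chrom, r.start, r.end, r.n_windows, r.direction, r.max_fst,
                 r.extreme_log2_ratio)
                for r in regions
            ],
            columns=["chrom", "start", "end", "n_windows", "direction",
                     "max_fst", "extreme_log2_ratio"],
        )
        write_tsv(reg_df, out / "scan_regions.tsv", config)
        report["stages"]["scan"] = {
            "n_windows": len(windows),
            "n_flagged": int(sum(w.flag is not None for w in windows)),
            "n_regions": len(regions),
            "fst_cut": realized.realized_fst_cut,
            "low_cut": realized.realized_low_cut,
            "high_cut": realized.realized_high_cut,
        }

    # ---- genes ----------------------------------------------------------
    if config.gtf is not None:
        genes = read_gtf_genes(config.gtf)
        if regions:
            per_dir = genes_in_regions(regions, genes)
            rows = [
                (direction, g.gene_id, g.gene_name, g.chrom, g.start, g.end)
                for direction, hits in per_dir.items()
                for g in hits
            ]
            write_tsv(
                pd.DataFrame(
                    rows,
                    columns=["direction", "gene_id", "gene_name", "chrom",
                             "start", "end"],
                ),
                out / "candidate_genes.tsv",
                config,
            )
            report["stages"]["genes_in_regions"] = {
                d: len(h) for d, h in per_dir.items()
            }
        by_name = {g.gene_name: g for g in genes}
        group_map = {
            config.group_labels[0]: gm_qc.samples_in_pops(config.group1_pops)
            if config.group1_pops else [],
            config.group_labels[1]: gm_qc.samples_in_pops(config.group2_pops)
            if config.group2_pops else [],
        }
        for name in config.gene_names:
            if name not in by_name:
                raise RuntimeError(f"stage gene failed: gene {name!r} not in GTF")
            profile = gene_profile(
                gm_qc, by_name[name], flank=config.gene_flank,
                groups={k: v for k, v in group_map.items() if v},
            )
            write_tsv(profile.variant_sites, out / f"gene_{name}_sites.tsv", config)
            classes = profile.genotype_class.reset_index(names="sample")
            write_tsv(classes, out / f"gene_{name}_classes.tsv", config)
            write_tsv(
                pd.DataFrame(
                    profile.pi_by_group.items(), columns=["group", "pi_per_bp"]
                ),
                out / f"gene_{name}_pi.tsv",
                config,
            )
            if group_map[config.group_labels[0]] and group_map[config.group_labels[1]]:
                loci = characteristic_loci(
                    profile,
                    group_map[config.group_labels[0]],
                    group_map[config.group_labels[1]],
                    margin=config.gene_margin,
                )
                write_tsv(loci, out / f"gene_{name}_characteristic_loci.tsv", config)
            report["stages"].setdefault("gene", {})[name] = profile.n_sites

    (out / "run_report.json").write_text(json.dumps(report, indent=2) + "\n")
    return report


def _structure_stage(
    config: PipelineConfig, gm_qc: GenotypeMatrix, out: Path, report: dict
) -> None:
    pca_res = pca(gm_qc, n_components=config.pca_components)
    coords = pd.DataFrame(
        pca_res.coords,
        columns=[f"PC{i + 1}" for i in range(pca_res.coords.shape[1])],
    )
    coords.insert(0, "sample", gm_qc.samples)
    coords.insert(1, "population", gm_qc.pop_labels())
    write_tsv(coords, out / "pca_scores.tsv", config)
    write_tsv(
        pd.DataFrame(
            {
                "component": [f"PC{i + 1}" for i in range(len(pca_res.explained))],
                "explained_fraction": pca_res.explained,
            }
        ),
        out / "pca_explained.tsv",
        config,
    )

    cv_errors, best_k = admixture_cv(
        gm_qc,
        config.k_range,
        folds=config.cv_folds,
        seed=config.seed,
        n_restarts=config.em_restarts,
    )
    write_tsv(
        pd.DataFrame(
            {"K": list(cv_errors), "cv_error": list(cv_errors.values())}
        ),
        out / "admixture_cv.tsv",
        config,
    )
    for K in config.k_range:
        fit = admixture_em(
            gm_qc, K, seed=config.seed, n_restarts=config.em_restarts
        )
        qdf = pd.DataFrame(
            fit.Q, columns=[f"Q{k + 1}" for k in range(K)]
        )
        qdf.insert(0, "sample", gm_qc.samples)
        write_tsv(qdf, out / f"admixture_Q_K{K}.tsv", config)

    dm = ibs_matrix(gm_qc)
    ibs_df = pd.DataFrame(dm.d, columns=dm.labels)
    ibs_df.insert(0, "sample", dm.labels)
    write_tsv(ibs_df, out / "ibs_distances.tsv", config)
    if len(dm.labels) >= 3:
        tree = neighbor_joining(dm)
        write_newick(tree, out / "nj_tree.nwk")

    report["stages"]["structure"] = {
        "pca_components": int(pca_res.coords.shape[1]),
        "cv_errors": {str(k): v for k, v in cv_errors.items()},
        "best_K": int(best_k),
    }
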