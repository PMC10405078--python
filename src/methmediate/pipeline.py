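"""End-to-end orchestration: QC -> association -> methQTL -> CIT -> report.

The pipeline mirrors a two-stage epigenetic mediation study: SNPs pass
genotype QC and case/control association screening; surviving SNPs are
tested against differentially methylated probes (DMPs) for methQTL; the
FDR-significant SNP-CpG pairs enter the causal inference test; pairs
whose composite IUT p-value clears the threshold are reported as
methylation-mediated, alongside the region distribution of the methQTL
CpGs against the array background.

DMPs are an input list by default (their discovery belongs to a separate
differential-methylation analysis); ``dmp_group_difference`` recomputes
case/control summary statistics (Welch t-test) so synthetic studies can
run end-to-end without an external DMP tool.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import ttest_ind

from . import annotation, association, cit, io, methqtl, qc
from .datasets import DMPRecord, GenotypeDataset, MethylationDataset, Phenotype

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """File paths plus every stage's tunables; see the module CLIs for units."""

    genotypes: str = ""
    genotype_format: str = "matrix_tsv"
    methylation: str = ""
    manifest: str = ""
    phenotype: str = ""
    dmp_file: str = ""  # optional: TSV of probe_id (+ delta_beta, p_value, fdr)
    out_dir: str = "results"
    seed: int = 0
    qc_thresholds: qc.QCThresholds = field(default_factory=qc.QCThresholds)
    assoc_test: str = "allelic_chisq"
    select_mode: str = "raw_p"
    select_alpha: float = 0.05
    methqtl_cfg: methqtl.MethQTLConfig = field(default_factory=methqtl.MethQTLConfig)
    cit_alpha: float = 0.05
    n_permutations: int = 1000


@dataclass
class PipelineResult:
    qc_report: qc.QCReport
    association: list[association.AssociationResult]
    selected_snps: set[str]
    methqtl: list[methqtl.MethQTLResult]
    significant_pairs: list[methqtl.MethQTLResult]
    cit: list[cit.CITResult]
    dmps: list[DMPRecord]
    regions: pd.DataFrame | None
    summary: dict[str, int]


def dmp_group_difference(
    m: MethylationDataset, y: Phenotype, probe_ids: Sequence[str]
) -> list[DMPRecord]:
    """Case/control methylation difference per probe.

    delta_beta = mean(case betas) - mean(control betas); p from the
    two-sample unequal-variance (Welch) t-test; BH FDR across the
    supplied probes.  Probes with fewer than two observations in either
    arm are flagged missing.
    """
    if m.sample_ids != y.sample_ids:
        raise ValueError("methylation and phenotype must be sample-aligned")
    if not probe_ids:
        raise ValueError("empty probe list")
    idx = m.probe_index()
    is_case = y.status == 1
    deltas, ps = [], []
    for pid in probe_ids:
        col = m.betas[:, idx[pid]]
        case = col[is_case & ~np.isnan(col)]
        ctrl = col[~is_case & ~np.isnan(col)]
        if case.size < 2 or ctrl.size < 2:
            deltas.append(float("nan"))
            ps.append(float("nan"))
            continue
        deltas.append(float(case.mean() - ctrl.mean()))
        ps.append(float(ttest_ind(case, ctrl, equal_var=False).pvalue))
    fdrs = association.bh_adjust(ps)
    return [
        DMPRecord(pid, d if not np.isnan(d) else 0.0, p, float(q))
        for pid, d, p, q in zip(probe_ids, deltas, ps, fdrs)
    ]


def run_analysis(
    g: GenotypeDataset,
    m: MethylationDataset,
    y: Phenotype,
    dmp_ids: Sequence[str] | None = None,
    cfg: PipelineConfig | None = None,
) -> PipelineResult:
    """Run every stage on aligned in-memory datasets.

    ``dmp_ids`` defaults to all probes (useful for synthetic studies);
    in a real analysis pass the externally discovered DMP list.
    """
    if cfg is None:
        cfg = PipelineConfig()
    t0 = time.perf_counter()
    g, m, y = io.align_samples(g, m, y)
    logger.info("aligned %d samples (%d cases / %d controls)",
                len(y.sample_ids), y.n_cases, y.n_controls)

    g_qc, report = qc.apply_qc(g, y, cfg.qc_thresholds)
    logger.info("qc: %d/%d SNPs retained", report.n_retained, report.n_input)

    assoc = association.associate(g_qc, y, cfg.assoc_test)
    selected = association.select_snps(assoc, cfg.select_mode, cfg.select_alpha)
    logger.info("association: %d SNP(s) selected (%s < %g)",
                len(selected), cfg.select_mode, cfg.select_alpha)

    if dmp_ids is None:
        dmp_ids = [p.probe_id for p in m.probes]
    dmps = dmp_group_difference(m, y, dmp_ids)

    mq: list[methqtl.MethQTLResult] = []
    sig: list[methqtl.MethQTLResult] = []
    cit_results: list[cit.CITResult] = []
    if selected:
        snp_order = [s.snp_id for s in g_qc.snps if s.snp_id in selected]
        mq = methqtl.map_methqtl(g_qc, m, list(dmp_ids), snp_order, cfg.methqtl_cfg)
        sig = methqtl.significant_pairs(mq, cfg.methqtl_cfg.fdr_alpha)
        logger.info("methqtl: %d/%d pairs significant", len(sig), len(mq))
        if sig:
            cit_cfg = cit.CITConfig(
                alpha=cfg.cit_alpha, n_permutations=cfg.n_permutations, seed=cfg.seed
            )
            cit_results = cit.run_cit(
                [(r.snp_id, r.probe_id) for r in sig], g_qc, m, y, cit_cfg
            )

    regions = None
    if sig:
        probe_idx = m.probe_index()
        sub_probes = [m.probes[probe_idx[pid]] for pid in {r.probe_id for r in sig}]
        regions = annotation.enrichment_vs_background(
            annotation.region_distribution(sub_probes),
            annotation.region_distribution(m.probes),
        )

    n_cpg, n_snp = methqtl.unique_counts(sig)
    med = [r for r in cit_results if r.verdict == "mediation"]
    summary = {
        "n_samples": len(y.sample_ids),
        "n_cases": y.n_cases,
        "n_controls": y.n_controls,
        "n_snps_input": report.n_input,
        "n_snps_post_qc": report.n_retained,
        "n_snps_selected": len(selected),
        "n_pairs_tested": len(mq),
        "n_pairs_significant": len(sig),
        "n_unique_cpgs": n_cpg,
        "n_unique_snps": n_snp,
        "n_mediation_pairs": len(med),
        "n_mediation_unique_cpgs": len({r.probe_id for r in med}),
        "n_mediation_unique_snps": len({r.snp_id for r in med}),
    }
    logger.info("pipeline finished in %.1f s: %s", time.perf_counter() - t0, summary)
    return PipelineResult(
        report, assoc, selected, mq, sig, cit_results, dmps, regions, summary
    )


def _report_rows(
    res: PipelineResult, g: GenotypeDataset, m: MethylationDataset
) -> list[dict]:
    probe_idx = m.probe_index()
    snp_meta = {s.snp_id: s for s in g.snps}
    dmp_map = {d.probe_id: d for d in res.dmps}
    rows = []
    for r in sorted(res.cit, key=lambda r: (np.isnan(r.p_cit), r.p_cit)):
        probe = m.probes[probe_idx[r.probe_id]]
        snp = snp_meta[r.snp_id]
        dmp = dmp_map.get(r.probe_id)
        rows.append(
            {
                "probe_id": r.probe_id,
                "gene_context": probe.gene_context,
                "gene_name": probe.gene_name,
                "delta_beta": dmp.delta_beta if dmp else float("nan"),
                "dmp_p": dmp.p_value if dmp else float("nan"),
                "dmp_fdr": dmp.fdr if dmp else float("nan"),
                "snp_id": r.snp_id,
                "snp_gene": "None",
                "chrom": snp.chrom,
                "p_geno_pheno": r.p_geno_pheno,
                "p_meth_pheno_given_geno": r.p_meth_pheno_given_geno,
                "p_geno_meth_given_pheno": r.p_geno_meth_given_pheno,
                "p_independence": r.p_independence,
                "p_cit": r.p_cit,
            }
        )
    return rows


def write_outputs(
    res: PipelineResult,
    g: GenotypeDataset,
    m: MethylationDataset,
    out_dir: str,
) -> None:
    """Persist every stage's TSV plus the summary."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    res.qc_report.write(out / "qc_report.tsv")
    association.results_table(res.association, g).to_csv(
        out / "association.tsv", sep="\t", index=False, float_format="%.6g"
    )
    methqtl.results_table(res.methqtl).to_csv(
        out / "methqtl.tsv", sep="\t", index=False, float_format="%.6g"
    )
    io.write_report(_report_rows(res, g, m), str(out / "cit.tsv"))
    if res.regions is not None:
        res.regions.to_csv(out / "regions.tsv", sep="\t", index=False,
                           float_format="%.6g")
    io.write_dmps(res.dmps, str(out / "dmps.tsv"))
    pd.DataFrame([res.summary]).T.reset_index().rename(
        columns={"index": "stage_count", 0: "value"}
    ).to_csv(out / "summary.tsv", sep="\t", index=False)


def run_pipeline(cfg: PipelineConfig) -> PipelineResult:
    """Read inputs from disk, run every stage, write per-stage TSVs."""
    g = io.read_genotypes(cfg.genotypes, cfg.genotype_format)
    m = io.read_methylation(cfg.methylation, cfg.manifest)
    y = io.read_phenotype(cfg.phenotype)
    dmp_ids = None
    if cfg.dmp_file:
        dmp_ids = [d.probe_id for d in io.read_dmps(cfg.dmp_file)]
    g, m, y = io.align_samples(g, m, y)
    res = run_analysis(g, m, y, dmp_ids, cfg)
    write_outputs(res, g, m, cfg.out_dir)
    return res
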