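"""Readers and writers for the pipeline's external formats.

Formats handled
---------------
* genotypes: VCF 4.x (GT-based dosage extraction, via cyvcf2), a simple
  transposed matrix TSV (``matrix_tsv``), and the plink ``.traw``
  transposed-dosage text export (``plink_text``).  plink binary ``.bed``
  is deliberately not parsed: export with ``plink --recode A-transpose``
  and read the ``.traw``.
* methylation: probes x samples beta matrix TSV plus a manifest TSV with
  columns ``probe_id, chrom, pos, gene, gene_context``.
* phenotype: TSV with columns ``sample_id, status``.
* report: mediation-report TSV whose column order follows the conventional
  per-pair mediation-table layout (DMP columns, SNP columns, four
  component p-values, composite CIT p).

Coordinates are 1-based inclusive throughout; missing data is NaN.
"""

from __future__ import annotations

import logging
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .datasets import (
    GENE_CONTEXTS,
    DMPRecord,
    GenotypeDataset,
    MethylationDataset,
    Phenotype,
    ProbeRecord,
    SNPRecord,
)

logger = logging.getLogger(__name__)

GENOTYPE_FORMATS = ("vcf", "plink_text", "matrix_tsv")

#: Column order of the mediation report, left to right.
REPORT_COLUMNS = [
    "probe_id",
    "gene_context",
    "gene_name",
    "delta_beta",
    "dmp_p",
    "dmp_fdr",
    "snp_id",
    "snp_gene",
    "chrom",
    "p_geno_pheno",
    "p_meth_pheno_given_geno",
    "p_geno_meth_given_pheno",
    "p_independence",
    "p_cit",
]

_P_COLUMNS = {
    "dmp_p",
    "dmp_fdr",
    "p_geno_pheno",
    "p_meth_pheno_given_geno",
    "p_geno_meth_given_pheno",
    "p_independence",
    "p_cit",
}


class ParseError(ValueError):
    """Raised when an input file does not conform to its declared dialect."""


# ---------------------------------------------------------------------------
# genotypes
# ---------------------------------------------------------------------------

def read_genotypes(path: str, format: str = "matrix_tsv") -> GenotypeDataset:
    """Read a genotype dosage matrix.

    Parameters
    ----------
    path
        Input file.
    format
        One of ``vcf``, ``plink_text`` (a plink ``.traw`` export) or
        ``matrix_tsv`` (SNPs as rows: snp_id, chrom, pos, ref, alt, then
        one column per sample; missing as ``NA``).

    Returns
    -------
    GenotypeDataset
        Dosages count alt alleles; genotypes with any missing allele map
        to NaN.  SNP order is preserved from the file; non-biallelic VCF
        sites are skipped with a logged warning.
    """
    if format not in GENOTYPE_FORMATS:
        raise ValueError(f"unknown genotype format {format!r}")
    if format == "vcf":
        return _read_vcf(path)
    if format == "plink_text":
        return _read_traw(path)
    return _read_matrix_tsv(path)


def _read_vcf(path: str) -> GenotypeDataset:
    from cyvcf2 import VCF

    vcf = VCF(path)
    sample_ids = list(vcf.samples)
    if not sample_ids:
        raise ParseError(f"{path}: no samples")
    snps: list[SNPRecord] = []
    cols: list[np.ndarray] = []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        dos = np.full(len(sample_ids), np.nan)
        for i, gt in enumerate(var.genotypes):
            a = gt[:-1]  # drop phasing flag
            if len(a) == 2 and a[0] >= 0 and a[1] >= 0:
                dos[i] = float(a[0] + a[1])
        snp_id = var.ID if var.ID else f"{var.CHROM}:{var.POS}"
        snps.append(SNPRecord(snp_id, str(var.CHROM), int(var.POS), var.REF, var.ALT[0]))
        cols.append(dos)
    vcf.close()
    if n_skipped:
        logger.warning("%s: skipped %d non-biallelic site(s)", path, n_skipped)
    mat = np.column_stack(cols) if cols else np.zeros((len(sample_ids), 0))
    return GenotypeDataset(sample_ids, snps, mat)


def _read_matrix_tsv(path: str) -> GenotypeDataset:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["snp_id", "chrom", "pos", "ref", "alt"]
    if list(df.columns[:5]) != required:
        raise ParseError(f"{path}: expected leading columns {required}")
    sample_ids = [str(c) for c in df.columns[5:]]
    if not sample_ids:
        raise ParseError(f"{path}: no samples")
    snps = [
        SNPRecord(str(r.snp_id), str(r.chrom), int(r.pos), str(r.ref), str(r.alt))
        for r in df.itertuples()
    ]
    mat = df[df.columns[5:]].to_numpy(dtype=float).T
    return GenotypeDataset(sample_ids, snps, mat)


def _read_traw(path: str) -> GenotypeDataset:
    # plink --recode A-transpose: CHR SNP (C)M POS COUNTED ALT <samples...>
    df = pd.read_csv(path, sep="\t", dtype={"CHR": str})
    required = ["CHR", "SNP", "(C)M", "POS", "COUNTED", "ALT"]
    if list(df.columns[:6]) != required:
        raise ParseError(f"{path}: not a plink .traw file (expected columns {required})")
    sample_ids = [str(c) for c in df.columns[6:]]
    if not sample_ids:
        raise ParseError(f"{path}: no samples")
    # the COUNTED allele is what the dosage counts; we store it as alt
    snps = [
        SNPRecord(str(r.SNP), str(r.CHR), int(r.POS), str(r.ALT), str(r.COUNTED))
        for r in df.itertuples()
    ]
    mat = df[df.columns[6:]].to_numpy(dtype=float).T
    return GenotypeDataset(sample_ids, snps, mat)


def write_genotypes(g: GenotypeDataset, path: str, format: str = "matrix_tsv") -> None:
    """Write genotypes as ``matrix_tsv`` or a minimal GT-only VCF."""
    if format == "matrix_tsv":
        df = pd.DataFrame(
            {
                "snp_id": [s.snp_id for s in g.snps],
                "chrom": [s.chrom for s in g.snps],
                "pos": [s.pos for s in g.snps],
                "ref": [s.ref_allele for s in g.snps],
                "alt": [s.alt_allele for s in g.snps],
            }
        )
        for i, sid in enumerate(g.sample_ids):
            col = g.dosages[i, :]
            df[sid] = [("NA" if np.isnan(d) else str(int(d))) for d in col]
        df.to_csv(path, sep="\t", index=False)
    elif format == "vcf":
        _write_vcf(g, path)
    else:
        raise ValueError(f"unsupported genotype output format {format!r}")


_GT = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}


def _write_vcf(g: GenotypeDataset, path: str) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        chroms = dict.fromkeys(s.chrom for s in g.snps)
        for c in chroms:
            fh.write(f"##contig=<ID={c}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(g.sample_ids)
            + "\n"
        )
        for j, s in enumerate(g.snps):
            gts = [
                "./." if np.isnan(d) else _GT[d] for d in g.dosages[:, j]
            ]
            fh.write(
                f"{s.chrom}\t{s.pos}\t{s.snp_id}\t{s.ref_allele}\t{s.alt_allele}"
                f"\t.\t.\t.\tGT\t" + "\t".join(gts) + "\n"
            )


# ---------------------------------------------------------------------------
# methylation
# ---------------------------------------------------------------------------

def read_manifest(path: str) -> dict[str, ProbeRecord]:
    """Read a probe manifest TSV (probe_id, chrom, pos, gene, gene_context)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, keep_default_na=False)
    required = {"probe_id", "chrom", "pos", "gene", "gene_context"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: manifest must have columns {sorted(required)}")
    out: dict[str, ProbeRecord] = {}
    for r in df.itertuples():
        if r.probe_id in out:
            raise ParseError(f"{path}: duplicated probe_id {r.probe_id}")
        ctx = str(r.gene_context)
        if ctx not in GENE_CONTEXTS:
            raise ParseError(f"{path}: unknown gene_context {ctx!r} for {r.probe_id}")
        out[str(r.probe_id)] = ProbeRecord(
            str(r.probe_id), str(r.chrom), int(r.pos), str(r.gene), ctx
        )
    return out


def read_methylation(path: str, manifest_path: str) -> MethylationDataset:
    """Read a probes x samples beta matrix TSV joined to its manifest.

    Probes absent from the manifest are dropped with a logged count; a
    beta value outside [0, 1] or a duplicated probe_id is an error.
    """
    manifest = read_manifest(manifest_path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.index.duplicated().any():
        dups = df.index[df.index.duplicated()].tolist()
        raise ParseError(f"{path}: duplicated probe_id {dups[0]}")
    sample_ids = [str(c) for c in df.columns]
    keep = [pid for pid in df.index if str(pid) in manifest]
    n_dropped = len(df.index) - len(keep)
    if n_dropped:
        logger.warning("%s: dropped %d probe(s) missing from manifest", path, n_dropped)
    if not keep:
        raise ParseError(f"{path}: no probes shared with manifest")
    sub = df.loc[keep]
    mat = sub.to_numpy(dtype=float).T
    vals = mat[~np.isnan(mat)]
    if vals.size and (vals.min() < 0 or vals.max() > 1):
        raise ParseError(f"{path}: beta out of range [0, 1]")
    probes = [manifest[str(pid)] for pid in keep]
    return MethylationDataset(sample_ids, probes, mat)


def write_methylation(m: MethylationDataset, beta_path: str, manifest_path: str) -> None:
    """Write the beta matrix (probes x samples) and its manifest."""
    df = pd.DataFrame(
        m.betas.T, index=[p.probe_id for p in m.probes], columns=m.sample_ids
    )
    df.index.name = "probe_id"
    df.to_csv(beta_path, sep="\t", float_format="%.6g")
    man = pd.DataFrame(
        {
            "probe_id": [p.probe_id for p in m.probes],
            "chrom": [p.chrom for p in m.probes],
            "pos": [p.pos for p in m.probes],
            "gene": [p.gene_name for p in m.probes],
            "gene_context": [p.gene_context for p in m.probes],
        }
    )
    man.to_csv(manifest_path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# phenotype and DMP lists
# ---------------------------------------------------------------------------

def read_phenotype(path: str) -> Phenotype:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if not {"sample_id", "status"}.issubset(df.columns):
        raise ParseError(f"{path}: phenotype needs columns sample_id, status")
    return Phenotype(list(df["sample_id"]), df["status"].to_numpy(dtype=int))


def write_phenotype(y: Phenotype, path: str) -> None:
    pd.DataFrame({"sample_id": y.sample_ids, "status": y.status}).to_csv(
        path, sep="\t", index=False
    )


def read_dmps(path: str) -> list[DMPRecord]:
    """Read a DMP list TSV (probe_id, delta_beta, p_value, fdr)."""
    df = pd.read_csv(path, sep="\t")
    if "probe_id" not in df.columns:
        raise ParseError(f"{path}: DMP list needs a probe_id column")
    recs = []
    for r in df.itertuples():
        recs.append(
            DMPRecord(
                str(r.probe_id),
                float(getattr(r, "delta_beta", np.nan)),
                float(getattr(r, "p_value", np.nan)),
                float(getattr(r, "fdr", np.nan)),
            )
        )
    return recs


def write_dmps(dmps: Sequence[DMPRecord], path: str) -> None:
    pd.DataFrame(
        {
            "probe_id": [d.probe_id for d in dmps],
            "delta_beta": [d.delta_beta for d in dmps],
            "p_value": [d.p_value for d in dmps],
            "fdr": [d.fdr for d in dmps],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# sample alignment
# ---------------------------------------------------------------------------

def align_samples(
    g: GenotypeDataset, m: MethylationDataset, y: Phenotype
) -> tuple[GenotypeDataset, MethylationDataset, Phenotype]:
    """Restrict all three datasets to their common samples, in one order.

    The canonical order is the genotype dataset's sample order restricted
    to the intersection, so the operation is idempotent and invariant to
    the input orders of the other two datasets.  Raises if fewer than two
    cases or two controls remain.
    """
    common = set(g.sample_ids) & set(m.sample_ids) & set(y.sample_ids)
    if not common:
        raise ValueError("no shared samples between genotype/methylation/phenotype")
    order = [sid for sid in g.sample_ids if sid in common]
    y_pos = {sid: i for i, sid in enumerate(y.sample_ids)}
    status = y.status[[y_pos[sid] for sid in order]]
    n_cases = int(status.sum())
    n_controls = len(order) - n_cases
    if n_cases < 2 or n_controls < 2:
        raise ValueError(
            f"aligned samples contain {n_cases} case(s) and {n_controls} "
            "control(s); need at least 2 of each"
        )
    g_pos = {sid: i for i, sid in enumerate(g.sample_ids)}
    m_pos = {sid: i for i, sid in enumerate(m.sample_ids)}
    return (
        g.subset_samples([g_pos[s] for s in order]),
        m.subset_samples([m_pos[s] for s in order]),
        Phenotype(order, status),
    )


# ---------------------------------------------------------------------------
# mediation report
# ---------------------------------------------------------------------------

def _fmt(col: str, v) -> str:
    if v is None or (isinstance(v, float) and np.isnan(v)):
        return "NA"
    if col in _P_COLUMNS:
        return f"{float(v):.2E}"
    if col == "delta_beta":
        return f"{float(v):.4g}"
    return str(v)


def write_report(rows: Iterable[Mapping], path: str) -> None:
    """Write the per-pair mediation report TSV.

    Each row must supply every key in :data:`REPORT_COLUMNS`; p-values are
    rendered in scientific notation with three significant digits.  An
    empty row list yields a header-only file.
    """
    with open(path, "w") as fh:
        fh.write("\t".join(REPORT_COLUMNS) + "\n")
        for row in rows:
            missing = [c for c in REPORT_COLUMNS if c not in row]
            if missing:
                raise ValueError(f"report row missing fields {missing}")
            fh.write("\t".join(_fmt(c, row[c]) for c in REPORT_COLUMNS) + "\n")
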