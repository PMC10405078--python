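"""Per-SNP genotype quality control.

Three filters, applied per SNP on aligned samples:

* call rate (fraction of non-missing genotypes) across **all** samples;
* minor allele frequency (MAF) across **all** samples;
* exact Hardy-Weinberg equilibrium (HWE) test in **controls only** —
  HWE deviation in the unaffected arm flags genotyping artefacts without
  discarding true disease associations.

Boundary convention: a SNP fails when its statistic is strictly below the
threshold (call rate < min_call_rate, MAF < min_maf, HWE p < hwe_alpha);
equality passes.

The HWE test is the exact conditional test: with the total sample size
and allele counts fixed, the probability of each possible heterozygote
count is computed (in log space, by the ratio recurrence between
neighbouring heterozygote counts), and the two-sided p-value sums the
probabilities of all configurations no more likely than the observed
one.  Mid-p is not applied.  An asymptotic 1-df chi-square version is
available as a config switch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from scipy.stats import chi2

from .datasets import GenotypeDataset, Phenotype

#: Relative tolerance for probability ties in the exact-test tail sum.
_TIE_RTOL = 1e-10


@dataclass(frozen=True)
class QCThresholds:
    """Filter thresholds; defaults follow common array-QC practice."""

    min_call_rate: float = 0.98
    min_maf: float = 0.05
    hwe_alpha: float = 1e-4
    hwe_test: str = "exact"  # or "chisq"

    def __post_init__(self) -> None:
        for name in ("min_call_rate", "min_maf", "hwe_alpha"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.hwe_test not in ("exact", "chisq"):
            raise ValueError("hwe_test must be 'exact' or 'chisq'")


@dataclass
class QCReport:
    """Per-SNP statistics, pass flags, and removal bookkeeping."""

    table: pd.DataFrame  # snp_id, call_rate, maf, hwe_p_controls, pass_* flags
    n_input: int = 0
    n_removed_call_rate: int = 0
    n_removed_maf: int = 0
    n_removed_hwe: int = 0
    n_removed: int = 0
    n_retained: int = 0
    thresholds: QCThresholds = field(default_factory=QCThresholds)

    def write(self, path: str) -> None:
        self.table.to_csv(path, sep="\t", index=False, float_format="%.6g")


def call_rate(dosage_column: np.ndarray) -> float:
    """Fraction of non-missing genotypes in a dosage column."""
    col = np.asarray(dosage_column, dtype=float)
    if col.size == 0:
        raise ValueError("empty dosage column")
    return float((~np.isnan(col)).sum() / col.size)


def minor_allele_frequency(dosage_column: np.ndarray) -> float:
    """MAF = min(f, 1-f) with f the alt-allele frequency among called genotypes.

    Returns NaN for an all-missing column (flagged as a filter failure).
    """
    col = np.asarray(dosage_column, dtype=float)
    called = col[~np.isnan(col)]
    if called.size == 0:
        return float("nan")
    f = called.sum() / (2.0 * called.size)
    return float(min(f, 1.0 - f))


@lru_cache(maxsize=100_000)
def _hwe_pvalue_table(n: int, n_minor: int) -> tuple[int, np.ndarray]:
    """Exact-test p-value for every possible heterozygote count.

    Conditional on ``n`` diploid genotypes and ``n_minor`` copies of the
    minor allele, returns ``(het_min, pvals)`` where ``pvals[k]`` is the
    p-value for heterozygote count ``het_min + 2k``.
    """
    het_min = n_minor % 2
    hets = np.arange(het_min, n_minor + 1, 2)
    # log P(het) up to a constant, by the neighbour ratio
    #   P(het+2)/P(het) = 4 * hom_minor * hom_major / ((het+1)(het+2))
    logp = np.zeros(len(hets))
    for k in range(len(hets) - 1):
        het = hets[k]
        hom_minor = (n_minor - het) // 2
        hom_major = n - het - hom_minor
        logp[k + 1] = logp[k] + (
            np.log(4.0 * hom_minor * hom_major) - np.log((het + 1.0) * (het + 2.0))
        )
    logp -= logsumexp(logp)
    probs = np.exp(logp)
    order = np.argsort(probs, kind="stable")
    sorted_probs = probs[order]
    csum = np.cumsum(sorted_probs)
    # p(het) = sum of probabilities <= prob(het), with a relative tie tolerance
    idx = np.searchsorted(sorted_probs, probs * (1.0 + _TIE_RTOL), side="right")
    pvals = np.minimum(csum[idx - 1], 1.0)
    return het_min, pvals


def hwe_exact_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Two-sided exact Hardy-Weinberg test on genotype counts.

    Sums, over all heterozygote counts compatible with the observed
    allele counts, the probabilities of configurations no more probable
    than the observed one.  Symmetric in the two homozygote counts;
    returns 1.0 for monomorphic sites.
    """
    if min(n_hom_ref, n_het, n_hom_alt) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    n_alt = 2 * n_hom_alt + n_het
    n_minor = min(n_alt, 2 * n - n_alt)
    if n_minor == 0:
        return 1.0
    het_min, pvals = _hwe_pvalue_table(n, n_minor)
    return float(pvals[(n_het - het_min) // 2])


def hwe_chisq_test(n_hom_ref: int, n_het: int, n_hom_alt: int) -> float:
    """Asymptotic 1-df chi-square HWE test (no continuity correction)."""
    n = n_hom_ref + n_het + n_hom_alt
    if n < 1:
        raise ValueError("need at least one genotype")
    p = (2 * n_hom_ref + n_het) / (2.0 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    exp = np.array([n * p * p, 2 * n * p * q, n * q * q])
    obs = np.array([n_hom_ref, n_het, n_hom_alt], dtype=float)
    stat = float(((obs - exp) ** 2 / exp).sum())
    return float(chi2.sf(stat, 1))


def _genotype_counts(col: np.ndarray) -> tuple[int, int, int]:
    called = col[~np.isnan(col)]
    return (
        int((called == 0).sum()),
        int((called == 1).sum()),
        int((called == 2).sum()),
    )


def apply_qc(
    g: GenotypeDataset, y: Phenotype, t: QCThresholds | None = None
) -> tuple[GenotypeDataset, QCReport]:
    """Apply the three per-SNP filters and return the surviving panel.

    ``y`` identifies the control subset used for the HWE test; samples
    must already be aligned between ``g`` and ``y``.  Raises if no SNP
    survives (the report is attached to the exception).
    """
    if t is None:
        t = QCThresholds()
    if g.sample_ids != y.sample_ids:
        raise ValueError("genotypes and phenotype must be sample-aligned before QC")
    hwe = hwe_exact_test if t.hwe_test == "exact" else hwe_chisq_test
    control_rows = np.flatnonzero(y.status == 0)

    rows = []
    for j, snp in enumerate(g.snps):
        col = g.dosages[:, j]
        cr = call_rate(col)
        maf = minor_allele_frequency(col)
        ctrl = col[control_rows]
        hp = hwe(*_genotype_counts(ctrl)) if (~np.isnan(ctrl)).any() else float("nan")
        pass_cr = cr >= t.min_call_rate
        pass_maf = bool(maf >= t.min_maf) if not np.isnan(maf) else False
        pass_hwe = bool(hp >= t.hwe_alpha) if not np.isnan(hp) else False
        rows.append(
            {
                "snp_id": snp.snp_id,
                "call_rate": cr,
                "maf": maf,
                "hwe_p_controls": hp,
                "pass_call_rate": pass_cr,
                "pass_maf": pass_maf,
                "pass_hwe": pass_hwe,
                "pass": pass_cr and pass_maf and pass_hwe,
            }
        )
    table = pd.DataFrame(rows)
    keep = table["pass"].to_numpy(dtype=bool) if len(table) else np.zeros(0, bool)
    report = QCReport(
        table=table,
        n_input=g.n_snps,
        n_removed_call_rate=int((~table["pass_call_rate"]).sum()) if len(table) else 0,
        n_removed_maf=int((~table["pass_maf"]).sum()) if len(table) else 0,
        n_removed_hwe=int((~table["pass_hwe"]).sum()) if len(table) else 0,
        n_removed=int((~keep).sum()),
        n_retained=int(keep.sum()),
        thresholds=t,
    )
    if report.n_retained == 0:
        err = ValueError("no SNPs survived quality control")
        err.report = report  # type: ignore[attr-defined]
        raise err
    filtered = g.subset_snps(np.flatnonzero(keep))
    return filtered, report
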