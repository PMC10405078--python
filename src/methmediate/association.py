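"""Case/control SNP association and Benjamini-Hochberg adjustment.

Two per-SNP tests are provided:

* ``allelic_chisq_test`` — the classic allelic test: 1-df Pearson
  chi-square (no continuity correction) on the 2x2 allele-count table
  (alt/ref x case/control), with a Haldane-Anscombe 0.5 cell correction
  applied to the odds ratio only when a cell is zero.
* ``additive_logistic_test`` — likelihood-ratio test of the dosage term
  in a logistic model of status on dosage (log-odds per alt allele).

``bh_adjust`` implements the Benjamini-Hochberg step-up adjustment used
by every module in the pipeline; missing p-values propagate as missing
and are excluded from the correction denominator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from ._glm import fit_logistic
from .datasets import GenotypeDataset, Phenotype

logger = logging.getLogger(__name__)


@dataclass
class AssociationResult:
    snp_id: str
    test_used: str  # "allelic_chisq" or "additive_logistic"
    statistic: float
    p_value: float
    fdr: float = float("nan")
    effect: float = float("nan")  # allelic odds ratio or logistic coefficient


def allelic_chisq_test(
    case_dosages: np.ndarray, control_dosages: np.ndarray
) -> tuple[float, float, float]:
    """Allelic 2x2 chi-square test.

    Returns ``(statistic, p, odds_ratio)``.  Monomorphic in both groups
    gives ``(0, 1, nan)``.  The statistic is invariant under swapping the
    case/control labels and under relabelling ref/alt.
    """
    case = np.asarray(case_dosages, dtype=float)
    ctrl = np.asarray(control_dosages, dtype=float)
    case = case[~np.isnan(case)]
    ctrl = ctrl[~np.isnan(ctrl)]
    if case.size == 0 or ctrl.size == 0:
        raise ValueError("need at least one called genotype per group")
    a = case.sum()  # alt alleles in cases
    b = 2.0 * case.size - a  # ref alleles in cases
    c = ctrl.sum()
    d = 2.0 * ctrl.size - c
    table = np.array([[a, b], [c, d]])
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    total = table.sum()
    if cols[0] == 0 or cols[1] == 0:  # monomorphic overall
        return 0.0, 1.0, float("nan")
    expected = np.outer(rows, cols) / total
    stat = float(((table - expected) ** 2 / expected).sum())
    p = float(chi2.sf(stat, 1))
    if (table == 0).any():
        a, b, c, d = (table + 0.5).ravel()
    odds = float((a * d) / (b * c))
    return stat, p, odds


def additive_logistic_test(
    dosages: np.ndarray, y: Phenotype | np.ndarray
) -> tuple[float, float, float]:
    """Logistic LRT of an additive dosage effect on case status.

    Returns ``(lrt_statistic, p, beta)`` with beta the log-odds per alt
    allele.  Constant dosage gives statistic 0 and p = 1.  Complete
    separation is flagged by a missing p (with a warning).
    """
    status = y.status if isinstance(y, Phenotype) else np.asarray(y)
    g = np.asarray(dosages, dtype=float)
    ok = ~np.isnan(g)
    g, s = g[ok], np.asarray(status, dtype=float)[ok]
    if len(np.unique(s)) < 2:
        raise ValueError("both phenotype classes must be present")
    if np.ptp(g) == 0:
        return 0.0, 1.0, 0.0
    X0 = np.ones((g.size, 1))
    X1 = np.column_stack([np.ones(g.size), g])
    _, ll0, conv0 = fit_logistic(X0, s)
    beta1, ll1, conv1 = fit_logistic(X1, s)
    if not conv1:
        logger.warning("logistic fit did not converge (possible separation)")
        return float("nan"), float("nan"), float(beta1[1])
    if not conv0:
        raise RuntimeError("intercept-only logistic fit failed to converge")
    stat = max(0.0, 2.0 * (ll1 - ll0))
    return float(stat), float(chi2.sf(stat, 1)), float(beta1[1])


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` capped at 1, mapped back to the
    input order.  NaN inputs stay NaN and do not count toward ``m``.
    """
    p = np.asarray(p_values, dtype=float)
    out = np.full(p.shape, np.nan)
    ok = ~np.isnan(p)
    pv = p[ok]
    m = pv.size
    if m == 0:
        return out
    if (pv < 0).any() or (pv > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    order = np.argsort(pv, kind="stable")
    ranked = pv[order] * m / np.arange(1, m + 1)
    q = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.minimum(q, 1.0)
    adj = np.empty(m)
    adj[order] = q
    out[ok] = adj
    return out


def associate(
    g: GenotypeDataset, y: Phenotype, test: str = "allelic_chisq"
) -> list[AssociationResult]:
    """Run the chosen association test on every SNP and attach BH FDR."""
    if g.sample_ids != y.sample_ids:
        raise ValueError("genotypes and phenotype must be sample-aligned")
    if test not in ("allelic_chisq", "additive_logistic"):
        raise ValueError(f"unknown association test {test!r}")
    is_case = y.status == 1
    results: list[AssociationResult] = []
    for j, snp in enumerate(g.snps):
        col = g.dosages[:, j]
        if test == "allelic_chisq":
            stat, p, eff = allelic_chisq_test(col[is_case], col[~is_case])
        else:
            stat, p, eff = additive_logistic_test(col, y)
        results.append(AssociationResult(snp.snp_id, test, stat, p, effect=eff))
    fdrs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def select_snps(
    results: list[AssociationResult], mode: str = "raw_p", alpha: float = 0.05
) -> set[str]:
    """SNP ids passing the selection rule: p < alpha or fdr < alpha (strict)."""
    if not results:
        raise ValueError("no association results to select from")
    if mode not in ("raw_p", "fdr"):
        raise ValueError(f"unknown selection mode {mode!r}")
    key = (lambda r: r.p_value) if mode == "raw_p" else (lambda r: r.fdr)
    chosen = {r.snp_id for r in results if not np.isnan(key(r)) and key(r) < alpha}
    if not chosen:
        logger.warning("association selection is empty (mode=%s, alpha=%g)", mode, alpha)
    return chosen


def results_table(results: list[AssociationResult], g: GenotypeDataset) -> pd.DataFrame:
    pos = {s.snp_id: (s.chrom, s.pos) for s in g.snps}
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "chrom": [pos[r.snp_id][0] for r in results],
            "pos": [pos[r.snp_id][1] for r in results],
            "test": [r.test_used for r in results],
            "statistic": [r.statistic for r in results],
            "p": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "effect": [r.effect for r in results],
        }
    )
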