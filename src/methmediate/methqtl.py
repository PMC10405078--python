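"""Methylation quantitative trait locus (methQTL) mapping.

Each candidate SNP is regressed against each differentially methylated
probe with an additive linear model (beta-value on dosage, ordinary
least squares with intercept), the t-test p-value of the slope is
Benjamini-Hochberg adjusted **once across the full tested Cartesian
product**, and each pair is classified *cis* (same chromosome, distance
strictly less than the window, default 500 kb) or *trans* (beyond the
window or on different chromosomes).

Regression is on the beta-value scale by default; an M-value
(logit2-transformed) scale is available through the config.  No
covariates are fitted by default; a hook exists for a covariate matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist

from .association import bh_adjust
from .datasets import GenotypeDataset, MethylationDataset, ProbeRecord, SNPRecord


@dataclass(frozen=True)
class MethQTLConfig:
    cis_window: int = 500_000
    fdr_alpha: float = 0.05
    value_scale: str = "beta"  # or "m_value"

    def __post_init__(self) -> None:
        if self.cis_window <= 0:
            raise ValueError("cis_window must be positive")
        if not 0.0 < self.fdr_alpha < 1.0:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if self.value_scale not in ("beta", "m_value"):
            raise ValueError("value_scale must be 'beta' or 'm_value'")


@dataclass
class MethQTLResult:
    snp_id: str
    probe_id: str
    slope: float
    t_statistic: float
    p_value: float
    fdr: float
    n_used: int
    relation: str  # "cis" or "trans"
    distance: float  # NaN across chromosomes

    @property
    def testable(self) -> bool:
        return not np.isnan(self.p_value)


def linear_additive_fit(
    dosages: np.ndarray, betas: np.ndarray
) -> tuple[float, float, float, int]:
    """OLS of methylation on dosage with intercept, on complete cases.

    Returns ``(slope, t, p, n_used)``.  Constant dosage among complete
    cases (or fewer than 3 of them) makes the pair untestable: slope and
    p are NaN.  A constant response gives slope 0 with missing p.
    """
    g = np.asarray(dosages, dtype=float)
    b = np.asarray(betas, dtype=float)
    ok = ~np.isnan(g) & ~np.isnan(b)
    g, b = g[ok], b[ok]
    n = g.size
    if n < 3 or np.ptp(g) == 0:
        return float("nan"), float("nan"), float("nan"), n
    gc = g - g.mean()
    bc = b - b.mean()
    sxx = float(gc @ gc)
    sxy = float(gc @ bc)
    syy = float(bc @ bc)
    slope = sxy / sxx
    if syy == 0.0:
        return 0.0, float("nan"), float("nan"), n
    rss = max(syy - sxy * sxy / sxx, 0.0)
    df = n - 2
    se = np.sqrt(rss / df / sxx)
    if se == 0.0:
        return slope, float("inf"), 0.0, n
    t = slope / se
    return float(slope), float(t), float(2.0 * t_dist.sf(abs(t), df)), n


def _fit_probe_vs_snps(G: np.ndarray, b: np.ndarray) -> list[tuple[float, float, float, int]]:
    """Vectorised simple regressions of one probe against many SNPs.

    Pairwise-complete-case equivalent of calling
    :func:`linear_additive_fit` per column, via mask-weighted sums.
    """
    W = ~np.isnan(G) & ~np.isnan(b)[:, None]  # n x S validity
    G0 = np.where(W, np.nan_to_num(G), 0.0)
    b0 = np.where(W, np.nan_to_num(b)[:, None], 0.0)
    n = W.sum(axis=0).astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        sg = G0.sum(axis=0)
        sb = b0.sum(axis=0)
        sxx = (G0 * G0).sum(axis=0) - sg * sg / n
        sxy = (G0 * b0).sum(axis=0) - sg * sb / n
        syy = (b0 * b0).sum(axis=0) - sb * sb / n
        slope = sxy / sxx
        rss = np.maximum(syy - sxy * sxy / sxx, 0.0)
        df = n - 2
        se = np.sqrt(rss / df / sxx)
        t = slope / se
        p = 2.0 * t_dist.sf(np.abs(t), df)
    out = []
    for k in range(G.shape[1]):
        nk = int(n[k])
        if nk < 3 or sxx[k] <= 0:
            out.append((float("nan"), float("nan"), float("nan"), nk))
        elif syy[k] == 0.0:
            out.append((0.0, float("nan"), float("nan"), nk))
        elif se[k] == 0.0:
            out.append((float(slope[k]), float("inf"), 0.0, nk))
        else:
            out.append((float(slope[k]), float(t[k]), float(p[k]), nk))
    return out


def classify_relation(
    snp: SNPRecord, probe: ProbeRecord, cis_window: int = 500_000
) -> tuple[str, float]:
    """cis/trans label and SNP-CpG distance (NaN across chromosomes)."""
    if snp.chrom != probe.chrom:
        return "trans", float("nan")
    d = abs(snp.pos - probe.pos)
    return ("cis" if d < cis_window else "trans"), float(d)


def to_m_values(betas: np.ndarray, eps: float = 1e-3) -> np.ndarray:
    """logit2 transform of beta-values, clipped away from 0/1."""
    b = np.clip(np.asarray(betas, dtype=float), eps, 1.0 - eps)
    return np.log2(b / (1.0 - b))


def map_methqtl(
    g: GenotypeDataset,
    m: MethylationDataset,
    dmp_ids: Sequence[str],
    snp_ids: Sequence[str],
    cfg: MethQTLConfig | None = None,
) -> list[MethQTLResult]:
    """Test every (selected SNP) x (DMP probe) pair.

    BH adjustment is computed once across all testable pairs; untestable
    pairs (constant dosage or too few complete cases) keep missing p and
    FDR and are excluded from the correction denominator.  Output row
    order is (probe-major, SNP-minor) in the order given.
    """
    if cfg is None:
        cfg = MethQTLConfig()
    if g.sample_ids != m.sample_ids:
        raise ValueError("genotypes and methylation must be sample-aligned")
    snp_idx = g.snp_index()
    probe_idx = m.probe_index()
    missing_p = [p for p in dmp_ids if p not in probe_idx]
    missing_s = [s for s in snp_ids if s not in snp_idx]
    if missing_p:
        raise ValueError(f"DMP probes absent from methylation data: {missing_p[:5]}")
    if missing_s:
        raise ValueError(f"selected SNPs absent from genotype data: {missing_s[:5]}")
    if not dmp_ids or not snp_ids:
        raise ValueError("empty SNP x probe product")

    values = m.betas if cfg.value_scale == "beta" else to_m_values(m.betas)
    scols = [snp_idx[s] for s in snp_ids]
    G = g.dosages[:, scols]  # n x S
    results: list[MethQTLResult] = []
    for pid in dmp_ids:
        pj = probe_idx[pid]
        probe = m.probes[pj]
        stats = _fit_probe_vs_snps(G, values[:, pj])
        for k, sid in enumerate(snp_ids):
            snp = g.snps[scols[k]]
            slope, t, p, n_used = stats[k]
            relation, dist = classify_relation(snp, probe, cfg.cis_window)
            results.append(
                MethQTLResult(sid, pid, slope, t, p, float("nan"), n_used, relation, dist)
            )
    fdrs = bh_adjust([r.p_value for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    return results


def significant_pairs(
    results: Sequence[MethQTLResult], fdr_alpha: float = 0.05
) -> list[MethQTLResult]:
    return [r for r in results if r.testable and r.fdr < fdr_alpha]


def unique_counts(results: Sequence[MethQTLResult]) -> tuple[int, int]:
    """(#unique probes, #unique SNPs) in a result set."""
    return len({r.probe_id for r in results}), len({r.snp_id for r in results})


def results_table(results: Sequence[MethQTLResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "snp_id": [r.snp_id for r in results],
            "probe_id": [r.probe_id for r in results],
            "slope": [r.slope for r in results],
            "t": [r.t_statistic for r in results],
            "p": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "n_used": [r.n_used for r in results],
            "relation": [r.relation for r in results],
            "distance": [r.distance for r in results],
        }
    )
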