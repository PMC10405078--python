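"""Independent reference implementations used only to check the package.

Each oracle is written from the definition of the quantity, by a route
different from the implementation under test (closed forms, brute-force
enumeration, or an established library).
"""

from __future__ import annotations

import numpy as np
from scipy.special import gammaln


def hwe_exact_oracle(n_hom_ref: int, n_het: int, n_hom_alt: int, tie_rtol: float = 1e-10) -> float:
    """Exact conditional HWE test by direct gammaln enumeration.

    P(n_het | n, n_alt) = n! / (n_AA! n_Aa! n_aa!) * 2^n_Aa * n_A! n_a! / (2n)!
    summed over all heterozygote counts no more probable than observed.
    """
    n = n_hom_ref + n_het + n_hom_alt
    n_alt = 2 * n_hom_alt + n_het
    n_ref = 2 * n - n_alt
    if min(n_alt, n_ref) == 0:
        return 1.0

    def logprob(het: int) -> float:
        hom_alt = (n_alt - het) // 2
        hom_ref = n - het - hom_alt
        return (
            gammaln(n + 1)
            - gammaln(hom_ref + 1)
            - gammaln(het + 1)
            - gammaln(hom_alt + 1)
            + het * np.log(2.0)
            + gammaln(n_alt + 1)
            + gammaln(n_ref + 1)
            - gammaln(2 * n + 1)
        )

    hets = np.arange(min(n_alt, n_ref) % 2, min(n_alt, n_ref) + 1, 2)
    probs = np.exp([logprob(int(h)) for h in hets])
    probs = probs / probs.sum()
    obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(probs[probs <= obs * (1.0 + tie_rtol)].sum(), 1.0))


def hwe_pvalues_oracle(n: int, n_minor: int, tie_rtol: float = 1e-10) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised oracle: p-value for every possible heterozygote count.

    Returns (het_counts, pvals) for fixed n genotypes and n_minor copies
    of the minor allele.
    """
    n_major = 2 * n - n_minor
    hets = np.arange(n_minor % 2, n_minor + 1, 2)
    hom_minor = (n_minor - hets) // 2
    hom_major = n - hets - hom_minor
    logp = (
        gammaln(n + 1)
        - gammaln(hom_major + 1)
        - gammaln(hets + 1)
        - gammaln(hom_minor + 1)
        + hets * np.log(2.0)
        + gammaln(n_minor + 1)
        + gammaln(n_major + 1)
        - gammaln(2 * n + 1)
    )
    probs = np.exp(logp)
    probs = probs / probs.sum()
    pvals = np.array(
        [probs[probs <= p * (1.0 + tie_rtol)].sum() for p in probs]
    )
    return hets, np.minimum(pvals, 1.0)


def bh_stepup_oracle(pvals) -> np.ndarray:
    """Definitional BH step-up: q_(i) = min_{j>=i} p_(j) * m / j, capped at 1."""
    p = np.asarray(pvals, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    for rank, idx in enumerate(order, start=1):
        tail = [p[order[j]] * m / (j + 1) for j in range(rank - 1, m)]
        q_sorted[rank - 1] = min(1.0, min(tail))
    out = np.empty(m)
    out[order] = q_sorted
    return out


def ols_simple_oracle(x, y):
    """Simple regression slope/SE/t/p via the explicit normal equations."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - intercept - slope * x
    s2 = (resid**2).sum() / (n - 2)
    se = np.sqrt(s2 / sxx)
    t = slope / se
    p = 2 * t_dist.sf(abs(t), n - 2)
    return slope, se, t, p


def logistic_lrt_oracle(x, y):
    """Logistic LRT of a single predictor via statsmodels maximum likelihood."""
    import statsmodels.api as sm

    X = sm.add_constant(np.asarray(x, dtype=float))
    full = sm.Logit(y, X).fit(disp=0, method="newton", maxiter=200)
    null = sm.Logit(y, np.ones((len(y), 1))).fit(disp=0, method="newton", maxiter=200)
    stat = 2.0 * (full.llf - null.llf)
    from scipy.stats import chi2

    return stat, float(chi2.sf(stat, 1)), float(full.params[1])


def pearson_chisq_2x2_oracle(table):
    """1-df Pearson chi-square from the textbook formula (no correction)."""
    from scipy.stats import chi2

    t = np.asarray(table, dtype=float)
    n = t.sum()
    a, b, c, d = t.ravel()
    stat = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return stat, float(chi2.sf(stat, 1))


def welch_oracle(x, y):
    """Welch two-sample t-test from its closed form."""
    from scipy.stats import t as t_dist

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    t = (x.mean() - y.mean()) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    return t, float(2 * t_dist.sf(abs(t), df))


def binom_two_sided_oracle(k: int, n: int, p: float) -> float:
    """Two-sided exact binomial p by summing all outcomes no more likely."""
    from scipy.stats import binom

    probs = binom.pmf(np.arange(n + 1), n, p)
    return float(min(probs[probs <= probs[k] * (1 + 1e-12)].sum(), 1.0))
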