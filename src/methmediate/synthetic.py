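"""Synthetic genotype / methylation / phenotype studies with known truth.

Generates complete case/control studies under four causal topologies for
each planted SNP-CpG-phenotype triad:

* ``mediation``      G -> M -> Y   (no direct G->Y path)
* ``consequential``  G -> Y -> M   (methylation reacts to disease)
* ``independent``    M <- G -> Y   (genotype drives both, no M->Y path)
* ``null``           no effects

Genotypes are drawn in Hardy-Weinberg proportions (two independent
allele draws at the configured MAF).  Methylation is a baseline level
plus additive genotype/phenotype effects plus Gaussian noise, clipped to
[0.01, 0.99].  Case/control status is ascertained from a population pool
by rejection sampling to a fixed arm size (default 44 cases + 44
controls), mirroring a fixed-design study rather than prevalence
sampling.  Everything is deterministic given the config seed, and the
returned truth table is sufficient to score any downstream verdict.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datasets import (
    GENE_CONTEXTS,
    GenotypeDataset,
    MethylationDataset,
    Phenotype,
    ProbeRecord,
    SNPRecord,
)

CAUSAL_MODELS = ("mediation", "consequential", "independent", "null")

#: Gene-context frequencies used to randomise the synthetic manifest;
#: roughly the composition of a genome-wide methylation array.
_CONTEXT_FREQS = {
    "TSS1500": 0.12,
    "TSS200": 0.07,
    "5UTR": 0.09,
    "1stExon": 0.05,
    "Body": 0.36,
    "ExonBnd": 0.02,
    "3UTR": 0.04,
    "IGR": 0.25,
}


@dataclass(frozen=True)
class Effects:
    """Per-triad effect sizes.

    a : G->M slope, beta-units per alt allele (|delta-beta| between the
        homozygote extremes is 2a).
    b : M->Y effect, log-odds per beta-unit.
    c : direct G->Y effect, log-odds per alt allele.
    d : Y->M shift in beta-units (consequential model only).
    """

    a: float = 0.0
    b: float = 0.0
    c: float = 0.0
    d: float = 0.0


def default_effects(model: str, strong: bool = False) -> Effects:
    """Reference effect sizes for each topology.

    The mediation slope a = 0.05 beta/allele puts the between-genotype
    methylation difference on the 0.06-0.24 delta-beta scale typical of
    case/control methylation hits; b is sized so one SD of the mediator
    (~0.04 beta at that slope and noise 0.02) shifts disease odds by
    ~2 log-odds — a strong, clearly detectable mediated signal at
    n = 88.  The strong set concentrates several tag SNPs on one
    mediator CpG (see :func:`planted_study_config`).
    """
    std = {
        "mediation": Effects(a=0.05, b=60.0),
        "consequential": Effects(a=0.05, c=1.2, d=0.06),
        "independent": Effects(a=0.05, c=1.2),
        "null": Effects(),
    }
    big = {
        "mediation": Effects(a=0.11, b=50.0),
        "consequential": Effects(a=0.08, c=0.3, d=0.08),
        "independent": Effects(a=0.08, c=0.3),
        "null": Effects(),
    }
    if model not in CAUSAL_MODELS:
        raise ValueError(f"unknown causal model {model!r}")
    return (big if strong else std)[model]


def _check_effects(model: str, e: Effects) -> None:
    ok = {
        "mediation": e.a != 0 and e.b != 0 and e.c == 0 and e.d == 0,
        "consequential": e.b == 0 and e.d != 0,
        "independent": e.a != 0 and e.c != 0 and e.b == 0 and e.d == 0,
        "null": e.a == e.b == e.c == e.d == 0,
    }
    if model not in ok:
        raise ValueError(f"unknown causal model {model!r}")
    if not ok[model]:
        raise ValueError(f"effects {e} inconsistent with the {model} model")


@dataclass(frozen=True)
class PlantedTriad:
    snp_index: int
    probe_index: int
    model: str
    effects: Effects


@dataclass
class StudyConfig:
    n_cases: int = 44
    n_controls: int = 44
    n_snps: int = 60
    n_probes: int = 30
    maf_range: tuple[float, float] = (0.10, 0.50)
    planted_triads: list[PlantedTriad] = field(default_factory=list)
    noise_sd: float = 0.02
    missing_rate: float = 0.0
    baseline_range: tuple[float, float] = (0.25, 0.75)
    risk_intercept: float = 0.0
    planted_maf_range: tuple[float, float] | None = None
    ld_tau: float = 0.0  # within-group allele-sharing; pairwise dosage corr ~ tau^2
    pool_factor: int = 6
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0.0 <= lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 <= lo <= hi <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        for t in self.planted_triads:
            if not (0 <= t.snp_index < self.n_snps and 0 <= t.probe_index < self.n_probes):
                raise ValueError(f"planted triad indices out of range: {t}")
            _check_effects(t.model, t.effects)


# ---------------------------------------------------------------------------
# primitive simulators
# ---------------------------------------------------------------------------

def _as_rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def simulate_genotypes(n: int, maf: float, seed=0) -> np.ndarray:
    """Dosages from two independent allele draws (HWE by construction)."""
    if not 0.0 <= maf <= 0.5:
        raise ValueError("maf must be in [0, 0.5]")
    rng = _as_rng(seed)
    return rng.binomial(2, maf, size=n).astype(float)


def simulate_triad(
    model: str,
    G: np.ndarray,
    effects: Effects,
    noise_sd: float,
    seed=0,
    baseline: float = 0.5,
    y: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Methylation column and per-sample Y log-odds contribution for a triad.

    Under the consequential model the methylation level depends on the
    realised outcome, so ``y`` (0/1 per sample) must be supplied; the
    other topologies ignore it.  M is clipped to [0.01, 0.99]; effect
    contributions are centred so planted triads do not shift prevalence.
    """
    _check_effects(model, effects)
    rng = _as_rng(seed)
    G = np.asarray(G, dtype=float)
    n = G.size
    eps = rng.normal(0.0, noise_sd, size=n)
    g_centered = G - G.mean()
    if model == "consequential":
        if y is None:
            raise ValueError("the consequential model needs the realised outcome y")
        M = baseline + effects.a * g_centered + effects.d * np.asarray(y, dtype=float) + eps
        contrib = effects.c * g_centered
    elif model == "mediation":
        M = baseline + effects.a * g_centered + eps
        contrib = effects.b * (M - M.mean())
    elif model == "independent":
        M = baseline + effects.a * g_centered + eps
        contrib = effects.c * g_centered
    else:  # null
        M = baseline + eps
        contrib = np.zeros(n)
    return np.clip(M, 0.01, 0.99), contrib


def simulate_phenotype(
    risk_contributions: np.ndarray,
    target_cases: int,
    target_controls: int,
    seed=0,
    max_tries: int = 200,
) -> tuple[np.ndarray, np.ndarray]:
    """Ascertain a fixed case/control design from a population pool.

    Bernoulli outcomes are drawn from the logistic risk; the required
    numbers of cases and controls are then sampled from the realised
    arms, redrawing the pool's outcomes if an arm is short.  Returns
    ``(status, indices)`` into the pool, cases and controls interleaved
    in pool order.
    """
    rng = _as_rng(seed)
    risk = np.asarray(risk_contributions, dtype=float)
    n = risk.size
    if target_cases + target_controls > n:
        raise ValueError("pool smaller than the requested design")
    prob = 1.0 / (1.0 + np.exp(-risk))
    for _ in range(max_tries):
        yy = (rng.random(n) < prob).astype(int)
        case_idx = np.flatnonzero(yy == 1)
        ctrl_idx = np.flatnonzero(yy == 0)
        if case_idx.size >= target_cases and ctrl_idx.size >= target_controls:
            take_cases = rng.choice(case_idx, size=target_cases, replace=False)
            take_ctrls = rng.choice(ctrl_idx, size=target_controls, replace=False)
            idx = np.sort(np.concatenate([take_cases, take_ctrls]))
            return yy[idx], idx
    raise RuntimeError(
        f"could not fill {target_cases} cases / {target_controls} controls "
        f"from a pool of {n} in {max_tries} tries (risk too extreme)"
    )


# ---------------------------------------------------------------------------
# whole-study generator
# ---------------------------------------------------------------------------

_AUTOSOMES = [f"chr{i}" for i in range(1, 23)]


def generate_study(
    cfg: StudyConfig,
) -> tuple[GenotypeDataset, MethylationDataset, Phenotype, pd.DataFrame]:
    """Generate a full study plus a truth table of the planted triads.

    Planted SNPs are placed within the cis window (< 500 kb) of their
    probe; background SNPs and probes get random autosomal coordinates.
    The truth table has one row per planted triad: snp_id, probe_id,
    model, and the four effect sizes.
    """
    rng = np.random.default_rng(cfg.seed)
    pool_n = cfg.pool_factor * (cfg.n_cases + cfg.n_controls)

    # --- genotype pool --------------------------------------------------
    mafs = rng.uniform(*cfg.maf_range, size=cfg.n_snps)
    if cfg.planted_maf_range is not None:
        planted = sorted({t.snp_index for t in cfg.planted_triads})
        mafs[planted] = rng.uniform(*cfg.planted_maf_range, size=len(planted))
    G_pool = np.column_stack(
        [simulate_genotypes(pool_n, maf, rng) for maf in mafs]
    )
    if cfg.ld_tau > 0:
        # SNPs acting on one probe form an LD block: each haplotype copies a
        # shared allele with probability tau, else draws fresh at the group
        # MAF.  Copies are independent within a SNP, so HWE is preserved.
        groups: dict[int, list[int]] = {}
        for t in cfg.planted_triads:
            groups.setdefault(t.probe_index, []).append(t.snp_index)
        for snp_ids in groups.values():
            if len(snp_ids) < 2:
                continue
            gmaf = float(mafs[snp_ids].mean())
            for copy in range(2):
                shared = rng.random(pool_n) < gmaf
                for j in snp_ids:
                    own = rng.random(pool_n) < gmaf
                    use_shared = rng.random(pool_n) < cfg.ld_tau
                    allele = np.where(use_shared, shared, own)
                    if copy == 0:
                        G_pool[:, j] = allele.astype(float)
                    else:
                        G_pool[:, j] += allele
            mafs[snp_ids] = gmaf

    # --- probe coordinates and contexts ---------------------------------
    probe_chrom = rng.choice(_AUTOSOMES, size=cfg.n_probes)
    probe_pos = rng.integers(1_000_000, 200_000_000, size=cfg.n_probes)
    contexts = rng.choice(
        list(_CONTEXT_FREQS), size=cfg.n_probes, p=list(_CONTEXT_FREQS.values())
    )
    baselines = rng.uniform(*cfg.baseline_range, size=cfg.n_probes)

    snp_chrom = rng.choice(_AUTOSOMES, size=cfg.n_snps).astype(object)
    snp_pos = rng.integers(1_000_000, 200_000_000, size=cfg.n_snps)
    for t in cfg.planted_triads:  # planted pairs are cis
        snp_chrom[t.snp_index] = probe_chrom[t.probe_index]
        offset = int(rng.integers(1_000, 400_000)) * int(rng.choice([-1, 1]))
        snp_pos[t.snp_index] = max(1, int(probe_pos[t.probe_index]) + offset)

    # --- methylation pool and risk --------------------------------------
    # Triads sharing a probe model several SNPs acting on one mediator CpG
    # (the typical methQTL structure: more unique SNPs than unique CpGs).
    # All triads of a shared probe must agree on model and on b/d.
    M_pool = np.empty((pool_n, cfg.n_probes))
    by_probe: dict[int, list[PlantedTriad]] = {}
    for t in cfg.planted_triads:
        by_probe.setdefault(t.probe_index, []).append(t)
    for j, group in by_probe.items():
        if len({t.model for t in group}) > 1:
            raise ValueError(f"probe {j}: triads sharing a probe must share a model")
        if len({(t.effects.b, t.effects.d) for t in group}) > 1:
            raise ValueError(f"probe {j}: shared-probe triads must share b and d")

    risk = np.zeros(pool_n)
    consequential: list[list[PlantedTriad]] = []
    genetic_part = np.zeros((pool_n, cfg.n_probes))
    for j in range(cfg.n_probes):
        group = by_probe.get(j)
        eps = rng.normal(0.0, cfg.noise_sd, pool_n)
        if group is None:
            M_pool[:, j] = np.clip(baselines[j] + eps, 0.01, 0.99)
            continue
        # genotype contributions are centred so the probe's mean stays at
        # its baseline and extreme baselines do not saturate the beta range
        gpart = np.zeros(pool_n)
        for t in group:
            gcol = G_pool[:, t.snp_index]
            gpart += t.effects.a * (gcol - gcol.mean())
            if t.model in ("independent", "consequential"):
                risk += t.effects.c * (gcol - gcol.mean())
        genetic_part[:, j] = gpart
        model = group[0].model
        if model == "consequential":
            # reactive probes are realised once the outcome is known
            M_pool[:, j] = eps  # noise stored, completed below
            consequential.append(group)
        else:
            M = np.clip(baselines[j] + gpart + eps, 0.01, 0.99)
            M_pool[:, j] = M
            if model == "mediation":
                risk += group[0].effects.b * (M - M.mean())

    status_pool, idx = simulate_phenotype(
        cfg.risk_intercept + risk, cfg.n_cases, cfg.n_controls, rng
    )
    # realise reactive (consequential) probes over the full pool
    y_full = np.zeros(pool_n)
    y_full[idx] = status_pool
    for group in consequential:
        j = group[0].probe_index
        M_pool[:, j] = np.clip(
            baselines[j] + genetic_part[:, j]
            + group[0].effects.d * y_full + M_pool[:, j],
            0.01, 0.99,
        )

    # --- assemble the ascertained study ---------------------------------
    sample_ids = [f"S{i:04d}" for i in idx]
    G = G_pool[idx, :]
    if cfg.missing_rate > 0:
        mask = rng.random(G.shape) < cfg.missing_rate
        G = G.copy()
        G[mask] = np.nan
    M = M_pool[idx, :]

    snps = [
        SNPRecord(f"rs{100000 + j}", str(snp_chrom[j]), int(snp_pos[j]), "A", "G")
        for j in range(cfg.n_snps)
    ]
    probes = [
        ProbeRecord(
            f"cg{200000 + j}",
            str(probe_chrom[j]),
            int(probe_pos[j]),
            "" if contexts[j] == "IGR" else f"GENE{j}",
            str(contexts[j]),
        )
        for j in range(cfg.n_probes)
    ]
    g_ds = GenotypeDataset(sample_ids, snps, G)
    m_ds = MethylationDataset(sample_ids, probes, M)
    y_ds = Phenotype(sample_ids, status_pool)

    truth = pd.DataFrame(
        {
            "snp_id": [snps[t.snp_index].snp_id for t in cfg.planted_triads],
            "probe_id": [probes[t.probe_index].probe_id for t in cfg.planted_triads],
            "model": [t.model for t in cfg.planted_triads],
            "a": [t.effects.a for t in cfg.planted_triads],
            "b": [t.effects.b for t in cfg.planted_triads],
            "c": [t.effects.c for t in cfg.planted_triads],
            "d": [t.effects.d for t in cfg.planted_triads],
        }
    )
    return g_ds, m_ds, y_ds, truth


def planted_study_config(
    n_mediation: int = 5,
    n_consequential: int = 10,
    n_independent: int = 9,
    snps_per_probe: int = 5,
    strong: bool = True,
    seed: int = 0,
    n_extra_snps: int = 20,
    n_extra_probes: int = 5,
) -> StudyConfig:
    """A planted study with the typical methQTL sharing structure.

    Each planted SNP gets its own triad, but triads of the same topology
    share mediator probes in groups of ``snps_per_probe`` and form LD
    blocks — real methQTL hits comprise more unique SNPs than unique
    CpGs, typically as clusters of correlated tag SNPs around one CpG.
    Concentrating the mediated risk on few CpGs and letting tag SNPs
    share haplotypes keeps per-SNP marginal effects detectable in a
    44 + 44 case/control design.  Ascertainment is from a low-prevalence
    pool (negative risk intercept), as in a clinic-recruited severe
    phenotype.  Background SNPs and probes carry no effects.
    """
    triads: list[PlantedTriad] = []
    snp_i = 0
    probe_i = 0
    for model, count in (
        ("mediation", n_mediation),
        ("consequential", n_consequential),
        ("independent", n_independent),
    ):
        eff = default_effects(model, strong=strong)
        for k in range(count):
            if k and k % snps_per_probe == 0:
                probe_i += 1
            triads.append(PlantedTriad(snp_i, probe_i, model, eff))
            snp_i += 1
        if count:
            probe_i += 1
    return StudyConfig(
        n_snps=snp_i + n_extra_snps,
        n_probes=probe_i + n_extra_probes,
        planted_triads=triads,
        planted_maf_range=(0.30, 0.50),
        risk_intercept=-1.5,
        ld_tau=0.65,
        pool_factor=8,
        seed=seed,
    )
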