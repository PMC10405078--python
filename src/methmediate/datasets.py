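"""Core in-memory containers for the three data modalities.

The analysis operates on a triple (G, M, Y): a genotype dosage matrix
(the causal factor), a methylation beta-value matrix (the candidate
mediator), and a binary case/control phenotype (the outcome).  Matrices
are float arrays with ``numpy.nan`` as the single missing-data sentinel;
all downstream statistics use pairwise complete cases.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

#: Mutually exclusive gene-context vocabulary for CpG probes, relative to
#: the annotated RefSeq gene (IGR = intergenic region).
GENE_CONTEXTS = (
    "TSS1500",
    "TSS200",
    "5UTR",
    "1stExon",
    "Body",
    "ExonBnd",
    "3UTR",
    "IGR",
)


@dataclass(frozen=True)
class SNPRecord:
    """A biallelic SNP: identifier, 1-based position, and its two alleles."""

    snp_id: str
    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"SNP {self.snp_id}: pos must be >= 1, got {self.pos}")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"SNP {self.snp_id}: ref and alt alleles are identical")


@dataclass(frozen=True)
class ProbeRecord:
    """A methylation array probe with its gene-context annotation.

    ``gene_context`` is one of :data:`GENE_CONTEXTS`; intergenic probes
    (``IGR``) carry an empty ``gene_name``.
    """

    probe_id: str
    chrom: str
    pos: int
    gene_name: str = ""
    gene_context: str = "IGR"

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"probe {self.probe_id}: pos must be >= 1")
        if self.gene_context not in GENE_CONTEXTS:
            raise ValueError(
                f"probe {self.probe_id}: unknown gene_context {self.gene_context!r}"
            )
        if self.gene_context == "IGR" and self.gene_name:
            object.__setattr__(self, "gene_name", "")


@dataclass(frozen=True)
class DMPRecord:
    """A differentially methylated probe: case-minus-control effect and p."""

    probe_id: str
    delta_beta: float
    p_value: float
    fdr: float

    def __post_init__(self) -> None:
        if not -1.0 <= self.delta_beta <= 1.0:
            raise ValueError(f"DMP {self.probe_id}: delta_beta out of [-1, 1]")


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate {what} ids")


@dataclass
class GenotypeDataset:
    """samples x SNPs additive dosage matrix (0/1/2 alt-allele counts, NaN missing)."""

    sample_ids: list[str]
    snps: list[SNPRecord]
    dosages: np.ndarray  # float, shape (n_samples, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.snps)):
            raise ValueError(
                f"dosage matrix shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.snps)} SNPs"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique([s.snp_id for s in self.snps], "snp")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise ValueError("dosages must be in {0, 1, 2} or NaN")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def snp_index(self) -> dict[str, int]:
        return {s.snp_id: j for j, s in enumerate(self.snps)}

    def subset_samples(self, idx: Sequence[int]) -> "GenotypeDataset":
        idx = list(idx)
        return GenotypeDataset(
            [self.sample_ids[i] for i in idx], self.snps, self.dosages[idx, :]
        )

    def subset_snps(self, idx: Sequence[int]) -> "GenotypeDataset":
        idx = list(idx)
        return GenotypeDataset(
            self.sample_ids, [self.snps[j] for j in idx], self.dosages[:, idx]
        )


@dataclass
class MethylationDataset:
    """samples x probes beta-value matrix, entries in [0, 1] or NaN."""

    sample_ids: list[str]
    probes: list[ProbeRecord]
    betas: np.ndarray  # float, shape (n_samples, n_probes)

    def __post_init__(self) -> None:
        self.betas = np.asarray(self.betas, dtype=float)
        if self.betas.shape != (len(self.sample_ids), len(self.probes)):
            raise ValueError(
                f"beta matrix shape {self.betas.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.probes)} probes"
            )
        _check_unique(self.sample_ids, "sample")
        _check_unique([p.probe_id for p in self.probes], "probe")
        vals = self.betas[~np.isnan(self.betas)]
        if vals.size and (vals.min() < 0.0 or vals.max() > 1.0):
            raise ValueError("beta out of range [0, 1]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_probes(self) -> int:
        return len(self.probes)

    def probe_index(self) -> dict[str, int]:
        return {p.probe_id: j for j, p in enumerate(self.probes)}

    def subset_samples(self, idx: Sequence[int]) -> "MethylationDataset":
        idx = list(idx)
        return MethylationDataset(
            [self.sample_ids[i] for i in idx], self.probes, self.betas[idx, :]
        )


@dataclass
class Phenotype:
    """Binary case/control status per sample (1 = case, 0 = control)."""

    sample_ids: list[str]
    status: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))

    def __post_init__(self) -> None:
        self.status = np.asarray(self.status, dtype=int)
        if self.status.shape != (len(self.sample_ids),):
            raise ValueError("status length does not match sample_ids")
        _check_unique(self.sample_ids, "sample")
        if self.status.size and not np.isin(self.status, (0, 1)).all():
            raise ValueError("status must be 0 or 1")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((self.status == 0).sum())

    def subset_samples(self, idx: Sequence[int]) -> "Phenotype":
        idx = list(idx)
        return Phenotype([self.sample_ids[i] for i in idx], self.status[idx])
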