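"""Tissue-specificity summaries of FPKM expression matrices.

Tissue specificity is quantified with the tau index

    tau = sum_i (1 - x_i / x_max) / (n - 1)

over a gene's per-tissue profile: 0 for a uniform nonzero profile, 1
when expression is confined to a single tissue.  Genes whose maximum
FPKM stays below a threshold (default 1.0) are flagged not expressed;
their tau is still reported but is not meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import FpkmMatrix


@dataclass
class GeneSpecificity:
    gene_id: str
    tau: float
    top_tissue: str
    max_fpkm: float
    expressed: bool


@dataclass
class SpecificityReport:
    genes: list

    def by_gene(self) -> dict:
        return {g.gene_id: g for g in self.genes}


def tau_index(profile: np.ndarray) -> float:
    """Tau for one expression profile (>= 2 tissues, non-negative)."""
    profile = np.asarray(profile, dtype=float)
    if profile.size < 2:
        raise ValueError("tau needs at least 2 tissues")
    if (profile < 0).any():
        raise ValueError("negative expression values")
    top = profile.max()
    if top == 0:
        return 0.0
    return float(np.sum(1.0 - profile / top) / (profile.size - 1))


def specificity(
    matrix: FpkmMatrix, expressed_threshold: float = 1.0
) -> SpecificityReport:
    """Per-gene tau, dominant tissue, and expressed flag."""
    if len(matrix.tissues) < 2:
        raise ValueError("need at least 2 tissues")
    genes = []
    tissues = np.array(matrix.tissues)
    for gene in matrix.genes:
        profile = matrix.profile(gene)
        top_idx = int(np.argmax(profile))
        genes.append(
            GeneSpecificity(
                gene_id=gene,
                tau=tau_index(profile),
                top_tissue=str(tissues[top_idx]),
                max_fpkm=float(profile.max()),
                expressed=bool(profile.max() >= expressed_threshold),
            )
        )
    return SpecificityReport(genes)
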