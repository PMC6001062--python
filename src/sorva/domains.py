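"""Protein-domain variant-depletion analysis.

Tests whether the genic region mapping to a protein domain carries fewer rare
variants than expected from its share of the transcript, assuming each
transcript site is equally likely to be mutated.  The depletion score is the
domain's observed share of the gene's variants divided by its length share
(1 under proportional placement, < 1 when depleted); the P-value is the lower
binomial tail on the cohort-total variant count falling in the domain.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import binom

__all__ = [
    "DomainDepletion",
    "depletion_score",
    "depletion_pvalue",
    "phred_scale",
    "significant_domains",
    "filter_domains",
    "domain_type_summary",
]


@dataclass
class DomainDepletion:
    """Depletion statistics for one protein-domain instance within a gene."""

    instance_id: str
    gene_id: str
    v_dom: float  # variants per individual in the domain
    v_gene: float  # variants per individual in the gene
    v_dom_count: int  # cohort-total variant-carriage events in the domain
    v_gene_count: int  # cohort-total variant-carriage events in the gene
    L_dom: int
    l_tx: int
    score: float = math.nan
    p_value: float = math.nan
    phred: float = math.nan
    significant: bool = False

    def compute(self) -> "DomainDepletion":
        self.score = depletion_score(self.v_dom, self.v_gene, self.L_dom, self.l_tx)
        self.p_value = depletion_pvalue(
            self.v_dom_count, self.v_gene_count, self.L_dom, self.l_tx
        )
        self.phred = phred_scale(self.p_value)
        return self


def depletion_score(v_dom: float, v_gene: float, L_dom: float, l_tx: float) -> float:
    """Observed domain share of the gene's variants over its length share.

    score = (v_dom / v_gene) / (L_dom / l_tx).  1 is expected by chance;
    values below 1 mark domains intolerant of variation relative to the rest
    of the gene.
    """
    if v_gene <= 0:
        raise ValueError("v_gene must be positive (genes without variants are filtered out)")
    if not 0 < L_dom <= l_tx:
        raise ValueError(f"need 0 < L_dom <= l_tx, got L_dom={L_dom}, l_tx={l_tx}")
    return (v_dom / v_gene) / (L_dom / l_tx)


def depletion_pvalue(
    v_dom_count: int, v_gene_total: int, L_dom: float, l_tx: float
) -> float:
    """Lower binomial tail P(X <= v_dom_count), X ~ Binomial(V, L_dom/l_tx).

    Under uniform mutability each of the gene's V cohort-total variant events
    lands in the domain with probability L_dom/l_tx; a small tail probability
    means the domain holds fewer events than its length predicts.
    """
    if v_gene_total < 1:
        raise ValueError("v_gene_total must be >= 1")
    if L_dom > l_tx:
        raise ValueError(f"L_dom={L_dom} exceeds l_tx={l_tx}")
    return float(binom.cdf(v_dom_count, v_gene_total, L_dom / l_tx))


def phred_scale(p: float, scale: float = 10.0, cap: float = 990.0) -> float:
    """-scale * log10(p), with p = 0 capped at ``cap`` with a warning."""
    if p < 0 or p > 1:
        raise ValueError(f"p must be in [0, 1], got {p}")
    if p == 0:
        warnings.warn(f"p = 0: capping scaled score at {cap}", stacklevel=2)
        return cap
    return -scale * math.log10(p)


def filter_domains(depletions: list[DomainDepletion]) -> list[DomainDepletion]:
    """Drop genes without observed variants and over-long domains.

    A domain spanning more than 50% of its transcript is removed (a depletion
    relative to "the rest of the gene" is not meaningful for it); a domain at
    exactly half length is kept.
    """
    return [
        d
        for d in depletions
        if d.v_gene_count > 0 and d.L_dom / d.l_tx <= 0.5
    ]


def significant_domains(
    depletions: list[DomainDepletion], n_genes_tested: int, alpha: float = 0.05
) -> list[DomainDepletion]:
    """Flag domains whose depletion P-value survives Bonferroni correction.

    Correction is by the number of genes surviving the filters (not the
    number of domain instances); returns the flagged subset and sets the
    ``significant`` field on every input.
    """
    if n_genes_tested < 1:
        raise ValueError("n_genes_tested must be >= 1")
    threshold = alpha / n_genes_tested
    flagged = []
    for d in depletions:
        d.significant = d.p_value < threshold
        if d.significant:
            flagged.append(d)
    return flagged


def domain_type_summary(
    instance_counts: dict[str, float],
    instance_meta: dict[str, tuple[str, str]],
) -> dict[str, tuple[float, float]]:
    """Genome-wide per-domain-type mean carrier count, weighting genes equally.

    ``instance_counts`` maps domain-instance id -> carrier count;
    ``instance_meta`` maps instance id -> (domain_type_id, gene_id).  Within
    each gene, repeated instances of a type are averaged first; the summary
    then reports the mean and variance (across genes) of those per-gene
    means, per domain type.
    """
    per_type_gene: dict[str, dict[str, list[float]]] = {}
    for iid, count in instance_counts.items():
        dtype, gene = instance_meta[iid]
        per_type_gene.setdefault(dtype, {}).setdefault(gene, []).append(count)
    summary: dict[str, tuple[float, float]] = {}
    for dtype, genes in per_type_gene.items():
        gene_means = np.array([np.mean(v) for v in genes.values()])
        summary[dtype] = (float(gene_means.mean()), float(gene_means.var()))
    return summary
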