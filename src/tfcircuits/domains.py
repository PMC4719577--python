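"""Per-domain enrichment of somatic mutations relative to common germline
variants.

For each annotated domain of a gene, protein-affecting somatic mutations
and allele-frequency-filtered germline variants are counted inside and
outside the domain and contrasted with a one-sided Fisher test: a
significant domain accumulates a larger share of the gene's somatic
mutations than its share of tolerated germline variation would predict.
A position is inside a domain iff ``start_aa <= pos <= end_aa``;
overlapping domains each count shared positions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .config import PROTEIN_AFFECTING_CONSEQUENCES
from .io import DomainAnnotation, GermlineVariant, MutationRecord
from .stats import ContingencyTable2x2, fisher_exact

__all__ = [
    "DomainEnrichmentResult",
    "filter_germline",
    "domain_mutation_enrichment",
    "domain_enrichment_frame",
]

#: -log10 p cap applied to plotting exports only (stored p is never altered)
EXPORT_LOG10P_CAP = 10.0


@dataclass(frozen=True)
class DomainEnrichmentResult:
    gene: str
    domain_id: str
    domain_name: str
    domain_len_aa: int
    n_mut_in: int
    n_mut_out: int
    n_var_in: int
    n_var_out: int
    frac_mut: float  # NaN when the gene has no counted mutations
    frac_var: float  # NaN when the gene has no retained variants
    p_value: float


def filter_germline(
    variants: Sequence[GermlineVariant], af_min: float
) -> list[GermlineVariant]:
    """Retain common variants: allele frequency >= ``af_min`` (boundary kept)."""
    if not (0.0 < af_min < 1.0):
        raise ValueError("af_min must lie in (0, 1)")
    return [v for v in variants if v.allele_freq >= af_min]


def domain_mutation_enrichment(
    mutations: Sequence[MutationRecord],
    germline: Sequence[GermlineVariant],
    domains: Sequence[DomainAnnotation],
) -> list[DomainEnrichmentResult]:
    """Per-(gene, domain) one-sided Fisher contrast of somatic mutations
    against germline variants, counted within and outside the domain.

    Only protein-affecting somatic mutations are counted; ``germline``
    is expected to be pre-filtered with :func:`filter_germline`.  A gene
    with no counted mutations (or no variants) yields p = 1 with the
    corresponding fraction flagged NaN.
    """
    mut_by_gene: dict = {}
    for rec in mutations:
        if rec.consequence in PROTEIN_AFFECTING_CONSEQUENCES:
            mut_by_gene.setdefault(rec.gene, []).append(rec.protein_pos)
    var_by_gene: dict = {}
    for v in germline:
        var_by_gene.setdefault(v.gene, []).append(v.protein_pos)

    results = []
    for dom in domains:
        mpos = mut_by_gene.get(dom.gene, [])
        vpos = var_by_gene.get(dom.gene, [])
        m_in = sum(1 for p in mpos if dom.contains(p))
        v_in = sum(1 for p in vpos if dom.contains(p))
        m_out, v_out = len(mpos) - m_in, len(vpos) - v_in
        frac_mut = m_in / len(mpos) if mpos else math.nan
        frac_var = v_in / len(vpos) if vpos else math.nan
        if not mpos and not vpos:
            p = 1.0  # nothing observed on the gene at all
        else:
            p = fisher_exact(
                ContingencyTable2x2(m_in, m_out, v_in, v_out), "greater"
            ).p_value
        results.append(
            DomainEnrichmentResult(
                dom.gene,
                dom.domain_id,
                dom.domain_name,
                dom.length_aa,
                m_in,
                m_out,
                v_in,
                v_out,
                frac_mut,
                frac_var,
                p,
            )
        )
    return results


def domain_enrichment_frame(results: Sequence[DomainEnrichmentResult]) -> pd.DataFrame:
    """Tabular export; the -log10 p column is capped for plotting."""
    df = pd.DataFrame(
        [
            (
                r.gene,
                r.domain_id,
                r.domain_name,
                r.domain_len_aa,
                r.n_mut_in,
                r.n_mut_out,
                r.n_var_in,
                r.n_var_out,
                r.frac_mut,
                r.frac_var,
                r.p_value,
            )
            for r in results
        ],
        columns=[
            "gene",
            "domain_id",
            "domain_name",
            "domain_len_aa",
            "n_mut_in",
            "n_mut_out",
            "n_var_in",
            "n_var_out",
            "frac_mut",
            "frac_var",
            "p_value",
        ],
    )
    with np.errstate(divide="ignore"):
        df["minus_log10_p_capped"] = np.minimum(
            EXPORT_LOG10P_CAP, -np.log10(df["p_value"].to_numpy(dtype=float))
        )
    return df
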