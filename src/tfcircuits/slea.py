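"""Sample-level enrichment analysis (SLEA) z-scores.

Expression is first mean-centered per gene across samples.  For each
sample, the observed statistic is the mean (or median) centered value
over the gene set; the null is the same statistic over random gene sets
of the same size drawn from all matrix genes.  The z-score is
``(observed - mean(null)) / sd(null)``.  When the null is degenerate
(sd = 0, e.g. the gene set is the whole matrix) the z-score is 0 if the
observed value equals the null mean and NaN (flagged) otherwise.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alterations import AlterationMatrix
from .config import Config
from .io import GeneSampleMatrix

logger = logging.getLogger(__name__)

__all__ = ["SleaResult", "slea_zscores", "slea_frame", "order_samples_by_alteration"]


@dataclass(frozen=True)
class SleaResult:
    sample_id: str
    gene_set_id: str
    z: float
    n_perm: int


def slea_zscores(
    expression: GeneSampleMatrix,
    gene_set: Iterable[str],
    cfg: Config,
    gene_set_id: str = "set",
    rng: np.random.Generator | None = None,
) -> list[SleaResult]:
    """Per-sample SLEA z-scores of one gene set.

    The same ``cfg.slea_n_perm`` random index draws are shared across
    samples; randomness comes from ``rng`` or ``cfg.rng_seed``.
    """
    genes = list(expression.genes)
    gene_set = sorted(set(gene_set))
    missing = set(gene_set) - set(genes)
    if missing:
        raise ValueError(f"gene set members absent from the matrix: {sorted(missing)[:5]}")
    k = len(gene_set)
    if k == 0:
        raise ValueError("empty gene set")
    if k > len(genes):
        raise ValueError("gene set larger than the gene universe")
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)

    centered = expression.df.sub(expression.df.mean(axis=1), axis=0)
    values = centered.to_numpy()
    summarize = np.mean if cfg.slea_summary == "mean" else np.median

    # indices are sorted so identical gene sets summarize identically
    # (bitwise), making the exhaustive-set null exactly degenerate
    set_idx = np.sort([genes.index(g) for g in gene_set])
    observed = summarize(values[set_idx, :], axis=0)

    null = np.empty((cfg.slea_n_perm, values.shape[1]))
    n_genes = len(genes)
    for i in range(cfg.slea_n_perm):
        idx = np.sort(rng.choice(n_genes, size=k, replace=False))
        null[i] = summarize(values[idx, :], axis=0)
    null_mean = null.mean(axis=0)
    null_sd = null.std(axis=0, ddof=1) if cfg.slea_n_perm > 1 else np.zeros_like(null_mean)

    # a null whose spread is at rounding level (e.g. the exhaustive set)
    # is degenerate: z is 0 when the observed value sits on the null, NaN
    # (flagged) otherwise
    scale = np.abs(values).max() or 1.0
    degenerate = null_sd <= 1e-12 * scale

    results = []
    for j, sample in enumerate(expression.samples):
        if degenerate[j]:
            if abs(observed[j] - null_mean[j]) <= 1e-12 * scale:
                z = 0.0
            else:
                z = float("nan")
                logger.warning(
                    "degenerate SLEA null for sample %s (sd=0, observed!=null)", sample
                )
        else:
            z = float((observed[j] - null_mean[j]) / null_sd[j])
        results.append(SleaResult(sample, gene_set_id, z, cfg.slea_n_perm))
    return results


def slea_frame(results: Sequence[SleaResult]) -> pd.DataFrame:
    """Sample x gene-set z-matrix."""
    df = pd.DataFrame(
        [(r.sample_id, r.gene_set_id, r.z) for r in results],
        columns=["sample", "gene_set", "z"],
    )
    return df.pivot(index="sample", columns="gene_set", values="z")


def order_samples_by_alteration(
    alteration_matrix: AlterationMatrix, tf: str, partner: str
) -> list[str]:
    """Heatmap sample ordering following the mutual-exclusivity pattern:
    TF-only altered, both altered, partner-only altered, then neither."""
    tf_alt = alteration_matrix.altered_samples(tf)
    p_alt = alteration_matrix.altered_samples(partner)
    rank = {}
    for s in alteration_matrix.samples:
        in_tf, in_p = s in tf_alt, s in p_alt
        rank[s] = 0 if (in_tf and not in_p) else 1 if (in_tf and in_p) else 2 if in_p else 3
    return sorted(alteration_matrix.samples, key=lambda s: (rank[s], s))
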