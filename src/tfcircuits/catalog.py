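"""Driver-TF repertoire: TF/driver intersection, over-representation, and
per-cohort mutation enrichment/depletion of driver TFs."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .config import PROTEIN_AFFECTING_CONSEQUENCES
from .io import DriverGene, MutationRecord
from .stats import ContingencyTable2x2, TestResult, fisher_exact

logger = logging.getLogger(__name__)

__all__ = [
    "CohortEnrichment",
    "identify_driver_tfs",
    "tf_overrepresentation",
    "cohort_mutation_enrichment",
    "cohort_enrichment_frame",
]


@dataclass(frozen=True)
class CohortEnrichment:
    """Mutation enrichment/depletion of one driver TF in one cohort,
    with other driver TFs as the reference margin."""

    tf: str
    cohort: str
    n_mut_tf_cohort: int
    n_mut_tf_other: int
    n_mut_rest_cohort: int
    n_mut_rest_other: int
    p_value: float
    direction: str  # enriched | depleted


def identify_driver_tfs(
    drivers: Sequence[DriverGene], tf_catalog: Iterable[str]
) -> list[DriverGene]:
    """Drivers whose gene is in the TF catalog, returned with is_tf set."""
    catalog = set(tf_catalog)
    out = []
    for d in drivers:
        if d.gene in catalog:
            out.append(DriverGene(d.gene, d.tumor_types, d.mode_of_action, True))
    return out


def tf_overrepresentation(
    n_driver_tfs: int, n_drivers: int, n_tfs: int, universe_size: int
) -> TestResult:
    """One-sided Fisher test of TF over-representation among drivers.

    ``universe_size`` (the number of genes drivers could have been drawn
    from) has no sensible default and must be supplied.
    """
    if not (0 <= n_driver_tfs <= min(n_drivers, n_tfs)):
        raise ValueError("n_driver_tfs exceeds one of its margins")
    d = universe_size - n_drivers - n_tfs + n_driver_tfs
    if d < 0:
        raise ValueError("universe_size inconsistent with the margins")
    table = ContingencyTable2x2(
        n_driver_tfs, n_drivers - n_driver_tfs, n_tfs - n_driver_tfs, d
    )
    return fisher_exact(table, alternative="greater")


def cohort_mutation_enrichment(
    mutations: Sequence[MutationRecord],
    driver_tfs: Sequence[DriverGene],
    cohort_labels: Mapping[str, str],
) -> list[CohortEnrichment]:
    """Two-sided Fisher enrichment/depletion of mutations in each driver
    TF in each cohort, against the pooled mutations of the other driver
    TFs.  Counts are protein-affecting mutation events.
    """
    cohorts = sorted(set(cohort_labels.values()))
    if len(cohorts) < 2:
        raise ValueError("cohort enrichment requires at least two cohorts")
    tf_genes = [d.gene for d in driver_tfs]
    tf_set = set(tf_genes)

    counts: dict = {}
    for rec in mutations:
        if rec.consequence not in PROTEIN_AFFECTING_CONSEQUENCES:
            continue
        if rec.gene not in tf_set:
            continue
        if rec.sample_id not in cohort_labels:
            logger.warning("mutation sample %s has no cohort label; skipped", rec.sample_id)
            continue
        key = (rec.gene, cohort_labels[rec.sample_id])
        counts[key] = counts.get(key, 0) + 1

    per_gene = {g: sum(v for (gg, _), v in counts.items() if gg == g) for g in tf_genes}
    total = sum(per_gene.values())
    per_cohort = {
        c: sum(v for (_, cc), v in counts.items() if cc == c) for c in cohorts
    }

    results = []
    for tf in tf_genes:
        for cohort in cohorts:
            a = counts.get((tf, cohort), 0)
            b = per_gene[tf] - a
            c = per_cohort[cohort] - a
            d = total - a - b - c
            if a + b + c + d == 0:
                logger.warning("no protein-affecting mutations at all; skipping table")
                continue
            res = fisher_exact(ContingencyTable2x2(a, b, c, d), "two_sided")
            direction = "enriched" if a * d > b * c else "depleted"
            results.append(
                CohortEnrichment(tf, cohort, a, b, c, d, res.p_value, direction)
            )
    return results


def cohort_enrichment_frame(results: Sequence[CohortEnrichment]) -> pd.DataFrame:
    """Tabular export with a -log10 p column for heatmap rendering."""
    df = pd.DataFrame(
        [
            (
                r.tf,
                r.cohort,
                r.n_mut_tf_cohort,
                r.n_mut_tf_other,
                r.n_mut_rest_cohort,
                r.n_mut_rest_other,
                r.p_value,
                r.direction,
            )
            for r in results
        ],
        columns=[
            "tf",
            "cohort",
            "n_mut_tf_cohort",
            "n_mut_tf_other",
            "n_mut_rest_cohort",
            "n_mut_rest_other",
            "p_value",
            "direction",
        ],
    )
    with np.errstate(divide="ignore"):
        df["minus_log10_p"] = -np.log10(df["p_value"].to_numpy(dtype=float))
    return df
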