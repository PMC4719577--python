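"""Driver-alteration calling: the sample x driver alteration matrix.

A sample is altered for a driver if it carries a qualifying mutation or
a qualifying copy-number event.  Mutation rules depend on the driver's
mode of action: loss-of-function (LoF) drivers count truncating
(stop gained/lost, frameshift, splice donor/acceptor) and missense
mutations; activating (Act) drivers count missense mutations only;
Undetermined drivers follow the Act rule.  CNA calls (deletion
CNA < -0.75 for LoF, amplification CNA > 1 for Act) are emitted only
for drivers whose own expression is concordant with the copy-number
change (significant Mann-Whitney shift in the expected direction
against copy-neutral samples).  Mutation calls are independent of the
CNA concordance gate; the two streams are merged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .config import Config, TRUNCATING_CONSEQUENCES
from .io import DriverGene, GeneSampleMatrix, MutationRecord
from .stats import mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "AlterationCall",
    "AlterationMatrix",
    "classify_driver_mutations",
    "cna_concordance",
    "build_alteration_matrix",
]


@dataclass(frozen=True)
class AlterationCall:
    sample_id: str
    gene: str
    alteration_class: str  # truncating | missense | amplification | deletion


class AlterationMatrix:
    """Per-tumor-type driver alteration calls and the derived boolean matrix."""

    def __init__(
        self,
        tumor_type: str,
        samples: Sequence[str],
        drivers: Sequence[str],
        calls: Sequence[AlterationCall],
    ):
        self.tumor_type = tumor_type
        self.samples = list(samples)
        self.drivers = list(drivers)
        self.calls = list(calls)
        sample_set, driver_set = set(self.samples), set(self.drivers)
        altered = pd.DataFrame(False, index=self.drivers, columns=self.samples)
        for call in self.calls:
            if call.gene not in driver_set or call.sample_id not in sample_set:
                raise ValueError(f"call {call} outside the matrix axes")
            altered.loc[call.gene, call.sample_id] = True
        self.altered = altered

    def altered_samples(self, gene: str) -> set:
        row = self.altered.loc[gene]
        return set(row.index[row])

    def unaltered_samples(self, gene: str) -> set:
        return set(self.samples) - self.altered_samples(gene)

    def calls_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c.sample_id, c.gene, c.alteration_class) for c in self.calls],
            columns=["sample", "gene", "alteration_class"],
        )


def classify_driver_mutations(
    mutations: Sequence[MutationRecord], drivers: Sequence[DriverGene]
) -> list[AlterationCall]:
    """Apply the per-mode mutation rules; mutations on genes that are not
    drivers are skipped with a warning."""
    by_gene = {d.gene: d for d in drivers}
    calls = []
    warned: set = set()
    for rec in mutations:
        driver = by_gene.get(rec.gene)
        if driver is None:
            if rec.gene not in warned:
                logger.warning("mutation on non-driver gene %s skipped", rec.gene)
                warned.add(rec.gene)
            continue
        truncating = rec.consequence in TRUNCATING_CONSEQUENCES
        if driver.effective_mode == "LoF":
            if truncating:
                calls.append(AlterationCall(rec.sample_id, rec.gene, "truncating"))
            elif rec.consequence == "missense":
                calls.append(AlterationCall(rec.sample_id, rec.gene, "missense"))
        else:  # Act (and Undetermined treated as Act)
            if rec.consequence == "missense":
                calls.append(AlterationCall(rec.sample_id, rec.gene, "missense"))
    return calls


def cna_concordance(
    driver: DriverGene,
    cna_row: pd.Series,
    expr_row: pd.Series,
    cfg: Config,
) -> bool:
    """Is the driver's own expression concordant with its CNA events?

    LoF drivers: samples with CNA < ``cna_del_max`` must show lower
    expression than copy-neutral samples; Act (and Undetermined)
    drivers: samples with CNA > ``cna_amp_min`` must show higher
    expression.  Both groups must reach ``min_group_size``; otherwise
    concordance is unestablished and False is returned.
    """
    common = cna_row.index.intersection(expr_row.index)
    cna_row, expr_row = cna_row[common], expr_row[common]
    neutral = (cna_row >= cfg.cna_del_max) & (cna_row <= cfg.cna_amp_min)
    if driver.effective_mode == "LoF":
        group = cna_row < cfg.cna_del_max
        want_lower = True
    else:
        group = cna_row > cfg.cna_amp_min
        want_lower = False
    g_expr = expr_row[group]
    n_expr = expr_row[neutral]
    if len(g_expr) < cfg.min_group_size or len(n_expr) < cfg.min_group_size:
        logger.info(
            "%s: concordance unestablished (groups %d vs %d below %d)",
            driver.gene, len(g_expr), len(n_expr), cfg.min_group_size,
        )
        return False
    res = mann_whitney(g_expr.to_numpy(), n_expr.to_numpy(), "two_sided")
    if res.p_value >= cfg.concordance_p_max:
        return False
    diff = g_expr.median() - n_expr.median()
    return diff < 0 if want_lower else diff > 0


def build_alteration_matrix(
    tumor_type: str,
    mutations: Sequence[MutationRecord],
    cna: GeneSampleMatrix,
    expression: GeneSampleMatrix,
    drivers: Sequence[DriverGene],
    cfg: Config,
) -> AlterationMatrix:
    """Merge mutation calls with concordance-gated CNA calls over the
    samples of the expression matrix."""
    samples = expression.samples
    sample_set = set(samples)

    mut_calls = classify_driver_mutations(mutations, drivers)
    kept_calls = []
    for call in mut_calls:
        if call.sample_id not in sample_set:
            logger.warning(
                "sample %s with a %s mutation is absent from the expression "
                "matrix; excluded", call.sample_id, call.gene,
            )
            continue
        kept_calls.append(call)

    cna_samples = set(cna.samples)
    for driver in drivers:
        if driver.gene not in cna.df.index or driver.gene not in expression.df.index:
            continue
        usable = sorted(sample_set & cna_samples)
        cna_row = cna.row(driver.gene)[usable]
        expr_row = expression.row(driver.gene)[usable]
        if not cna_concordance(driver, cna_row, expr_row, cfg):
            continue
        if driver.effective_mode == "LoF":
            hit = cna_row.index[cna_row < cfg.cna_del_max]
            klass = "deletion"
        else:
            hit = cna_row.index[cna_row > cfg.cna_amp_min]
            klass = "amplification"
        kept_calls.extend(AlterationCall(s, driver.gene, klass) for s in hit)

    return AlterationMatrix(tumor_type, samples, [d.gene for d in drivers], kept_calls)
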