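"""Cross-tumor target-set overlaps and driver-circuit detection.

A driver circuit is a TF paired with a connected non-TF driver (the
partner) whose alterations converge on overlapping sets of misregulated
TF targets.  Partner eligibility requires adjacency in the filtered
functional-interaction network and an altered-sample overlap of at most
half (so the partner's signal is not merely the TF's signal seen
through co-altered samples).  The partner's significant targets are
detected against samples in which *neither* the partner nor the TF is
altered; the up-set and down-set overlaps with the TF's significant
targets are then scored by one-sided Fisher tests over the TF's
annotated-target universe, BH-corrected per direction within the tumor
type.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .alterations import AlterationMatrix
from .config import Config
from .io import DriverGene, GeneSampleMatrix, InteractionNetwork
from .stats import benjamini_hochberg, jaccard, overlap_significance
from .targets import DifferentialTarget, compare_target_groups

logger = logging.getLogger(__name__)

__all__ = [
    "CrossTumorOverlap",
    "Circuit",
    "CircuitCandidate",
    "cross_tumor_overlap",
    "find_partners",
    "partner_differential_targets",
    "score_circuits",
    "detect_circuits",
    "circuits_frame",
]


@dataclass(frozen=True)
class CrossTumorOverlap:
    tf: str
    tumor_a: str
    tumor_b: str
    jaccard: float
    overlap_size: int
    p: float
    q: float


@dataclass(frozen=True)
class Circuit:
    tf: str
    partner: str
    tumor_type: str
    up_overlap_size: int
    down_overlap_size: int
    q_up: float
    q_down: float
    significant: bool


@dataclass(frozen=True)
class CircuitCandidate:
    """One TF-partner pair ready for overlap scoring."""

    tf: str
    partner: str
    tf_up: frozenset
    tf_down: frozenset
    partner_up: frozenset
    partner_down: frozenset
    universe: frozenset


def cross_tumor_overlap(
    tf: str,
    sig_targets_by_tumor: Mapping[str, set],
    universe: set,
) -> list[CrossTumorOverlap]:
    """Jaccard index and BH-corrected one-sided Fisher overlap p for the
    TF's significant-target sets in every unordered tumor-type pair.

    The universe is the whole list of annotated targets of the TF.
    """
    tumors = sorted(sig_targets_by_tumor)
    if len(tumors) < 2:
        raise ValueError("cross-tumor overlap needs at least two tumor types")
    universe = set(universe)
    for t in tumors:
        if not set(sig_targets_by_tumor[t]) <= universe:
            raise ValueError(f"significant targets in {t} exceed the universe")
    rows = []
    pvals = []
    for i, ta in enumerate(tumors):
        for tb in tumors[i + 1 :]:
            a, b = set(sig_targets_by_tumor[ta]), set(sig_targets_by_tumor[tb])
            res = overlap_significance(a, b, universe, "greater")
            rows.append((ta, tb, jaccard(a, b), len(a & b), res.p_value))
            pvals.append(res.p_value)
    qvals = benjamini_hochberg(pvals)
    return [
        CrossTumorOverlap(tf, ta, tb, j, n, p, float(q))
        for (ta, tb, j, n, p), q in zip(rows, qvals)
    ]


def find_partners(
    tf: str,
    drivers: Sequence[DriverGene],
    network: InteractionNetwork,
    alteration_matrix: AlterationMatrix,
    cfg: Config,
) -> list[str]:
    """Eligible partners of ``tf``: adjacent non-TF drivers whose
    altered-sample overlap with the TF is at most ``partner_overlap_max``
    of the smaller altered set; partners with no altered samples are
    excluded."""
    neighbors = network.neighbors(tf)
    if not neighbors:
        logger.warning("TF %s has no neighbors in the filtered network", tf)
        return []
    tf_altered = alteration_matrix.altered_samples(tf)
    if not tf_altered:
        logger.warning("TF %s has no altered samples; no partners", tf)
        return []
    by_gene = {d.gene: d for d in drivers}
    partners = []
    for gene in sorted(neighbors):
        driver = by_gene.get(gene)
        if driver is None or driver.is_tf:
            continue
        if gene not in alteration_matrix.altered.index:
            continue
        p_altered = alteration_matrix.altered_samples(gene)
        if not p_altered:
            continue
        overlap = len(tf_altered & p_altered) / min(len(tf_altered), len(p_altered))
        if overlap <= cfg.partner_overlap_max:
            partners.append(gene)
    return partners


def partner_differential_targets(
    tf: str,
    partner: str,
    alteration_matrix: AlterationMatrix,
    expression: GeneSampleMatrix,
    cna: GeneSampleMatrix | None,
    targets: set,
    cfg: Config,
) -> list[DifferentialTarget]:
    """The TF's targets tested on partner alterations: altered group =
    partner-altered samples, reference = samples where neither the
    partner nor the TF is altered (so the TF's own effect cannot leak
    into the reference)."""
    alt = alteration_matrix.altered_samples(partner)
    ref = (
        set(alteration_matrix.samples)
        - alt
        - alteration_matrix.altered_samples(tf)
    )
    out = []
    for target in sorted(set(targets)):
        if target in (tf, partner) or target not in expression.df.index:
            continue
        res = compare_target_groups(
            partner, target, alteration_matrix.tumor_type, alt, ref, expression, cna, cfg
        )
        if res is not None:
            out.append(res)
    return out


def _direction_sets(results: Sequence[DifferentialTarget]) -> tuple[frozenset, frozenset]:
    up = frozenset(r.target for r in results if r.significant and r.direction == "up")
    down = frozenset(r.target for r in results if r.significant and r.direction == "down")
    return up, down


def score_circuits(
    tumor_type: str,
    candidates: Sequence[CircuitCandidate],
    cfg: Config,
) -> list[Circuit]:
    """Score every TF-partner candidate of one tumor type.

    One-sided overlap p-values of the up-sets and of the down-sets are
    computed over each TF's annotated-target universe, and BH-corrected
    separately per direction across all candidates of the tumor type.
    A circuit is significant when min(q_up, q_down) < ``circuit_q_max``.
    """
    if not candidates:
        return []
    p_up, p_down = [], []
    for c in candidates:
        if not c.universe:
            raise ValueError(f"empty target universe for TF {c.tf}")
        p_up.append(
            overlap_significance(c.tf_up, c.partner_up, c.universe, "greater").p_value
        )
        p_down.append(
            overlap_significance(c.tf_down, c.partner_down, c.universe, "greater").p_value
        )
    q_up = benjamini_hochberg(p_up)
    q_down = benjamini_hochberg(p_down)
    out = []
    for c, qu, qd in zip(candidates, q_up, q_down):
        out.append(
            Circuit(
                c.tf,
                c.partner,
                tumor_type,
                len(c.tf_up & c.partner_up),
                len(c.tf_down & c.partner_down),
                float(qu),
                float(qd),
                bool(min(qu, qd) < cfg.circuit_q_max),
            )
        )
    return out


def detect_circuits(
    tumor_type: str,
    tf_results: Mapping[str, Sequence[DifferentialTarget]],
    targets_by_tf: Mapping[str, set],
    drivers: Sequence[DriverGene],
    network: InteractionNetwork,
    alteration_matrix: AlterationMatrix,
    expression: GeneSampleMatrix,
    cna: GeneSampleMatrix | None,
    cfg: Config,
) -> list[Circuit]:
    """End-to-end circuit search for one tumor type: partner discovery,
    partner-conditioned target DE, and BH-corrected overlap scoring."""
    candidates = []
    for tf in sorted(tf_results):
        tf_up, tf_down = _direction_sets(tf_results[tf])
        universe = frozenset(targets_by_tf[tf])
        for partner in find_partners(tf, drivers, network, alteration_matrix, cfg):
            partner_results = partner_differential_targets(
                tf, partner, alteration_matrix, expression, cna,
                set(targets_by_tf[tf]), cfg,
            )
            if not partner_results:
                logger.info(
                    "%s-%s: no scorable targets for the partner comparison",
                    tf, partner,
                )
                continue
            p_up, p_down = _direction_sets(partner_results)
            candidates.append(
                CircuitCandidate(tf, partner, tf_up, tf_down, p_up, p_down, universe)
            )
    return score_circuits(tumor_type, candidates, cfg)


def circuits_frame(circuits: Sequence[Circuit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            (
                c.tf,
                c.partner,
                c.tumor_type,
                c.up_overlap_size,
                c.down_overlap_size,
                c.q_up,
                c.q_down,
                c.significant,
            )
            for c in circuits
        ],
        columns=[
            "tf",
            "partner",
            "tumor_type",
            "up_overlap_size",
            "down_overlap_size",
            "q_up",
            "q_down",
            "significant",
        ],
    )
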