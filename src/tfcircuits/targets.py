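"""Differential expression of TF targets upon driver alterations.

For each annotated target of a driver TF, expression in samples bearing
driver alterations of the TF is compared with unaltered samples by a
two-sided Mann-Whitney test, after excluding — per target — the samples
in which the target itself is amplified or deleted (so copy-number
changes of the target cannot masquerade as transcriptional
misregulation).  A target is significantly misregulated when p < 0.05
and |log2 fold-change| > 1 (both thresholds configurable).  Raw
p-values are thresholded deliberately — no multiple-testing correction
is applied at this stage; BH correction is reserved for the overlap
tests downstream.

The fold-change is the ratio of group medians with a pseudocount:
``log2((median_alt + eps) / (median_unalt + eps))``, robust to outliers
and defined at zero expression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .alterations import AlterationCall, AlterationMatrix
from .config import Config, TRUNCATING_CONSEQUENCES
from .io import GeneSampleMatrix
from .stats import TestResult, mann_whitney

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialTarget",
    "differential_targets",
    "compare_target_groups",
    "background_de_rate",
    "truncating_vs_missense",
    "differential_targets_frame",
]


@dataclass(frozen=True)
class DifferentialTarget:
    tf: str
    target: str
    tumor_type: str
    n_alt: int
    n_unalt: int
    p_value: float
    log2_fc: float
    direction: str  # up | down
    significant: bool


def _log2_fc(alt: np.ndarray, unalt: np.ndarray, eps: float) -> float:
    return float(np.log2((np.median(alt) + eps) / (np.median(unalt) + eps)))


def _excluded_by_target_cna(
    target: str, samples: Iterable[str], cna: GeneSampleMatrix | None, cfg: Config
) -> set:
    """Samples whose copy number of the tested target is outside the
    copy-neutral interval."""
    if cna is None or target not in cna.df.index:
        return set()
    row = cna.row(target)
    keep = [s for s in samples if s in row.index]
    vals = row[keep]
    mask = (vals < cfg.cna_del_max) | (vals > cfg.cna_amp_min)
    return set(vals.index[mask])


def compare_target_groups(
    tf: str,
    target: str,
    tumor_type: str,
    alt_samples: set,
    ref_samples: set,
    expression: GeneSampleMatrix,
    cna: GeneSampleMatrix | None,
    cfg: Config,
) -> DifferentialTarget | None:
    """One target's altered-vs-reference comparison; None when a group
    falls below ``min_group_size`` after the target-CNA exclusion."""
    excluded = _excluded_by_target_cna(target, alt_samples | ref_samples, cna, cfg)
    alt = sorted(alt_samples - excluded)
    ref = sorted(ref_samples - excluded)
    if len(alt) < cfg.min_group_size or len(ref) < cfg.min_group_size:
        logger.info(
            "%s target %s skipped: groups %d vs %d below %d after CNA exclusion",
            tf, target, len(alt), len(ref), cfg.min_group_size,
        )
        return None
    row = expression.row(target)
    x, y = row[alt].to_numpy(), row[ref].to_numpy()
    res = mann_whitney(x, y, "two_sided")
    fc = _log2_fc(x, y, cfg.fc_pseudocount)
    significant = res.p_value < cfg.de_p_max and abs(fc) > cfg.de_abs_log2fc_min
    return DifferentialTarget(
        tf,
        target,
        tumor_type,
        len(alt),
        len(ref),
        res.p_value,
        fc,
        "up" if fc >= 0 else "down",
        significant,
    )


def differential_targets(
    tf: str,
    alteration_matrix: AlterationMatrix,
    expression: GeneSampleMatrix,
    cna: GeneSampleMatrix | None,
    targets: Iterable[str],
    cfg: Config,
) -> list[DifferentialTarget]:
    """Test every annotated target of ``tf`` present in the expression
    matrix, altered vs unaltered samples of the TF."""
    targets = sorted(set(targets))
    if not targets:
        logger.warning("TF %s has no annotated targets", tf)
        return []
    alt = alteration_matrix.altered_samples(tf)
    ref = alteration_matrix.unaltered_samples(tf)
    out = []
    for target in targets:
        if target == tf or target not in expression.df.index:
            continue
        res = compare_target_groups(
            tf, target, alteration_matrix.tumor_type, alt, ref, expression, cna, cfg
        )
        if res is not None:
            out.append(res)
    return out


def background_de_rate(
    tf: str,
    alteration_matrix: AlterationMatrix,
    expression: GeneSampleMatrix,
    cna: GeneSampleMatrix | None,
    targets: Iterable[str],
    cfg: Config,
    n_random_sets: int,
    rng: np.random.Generator,
) -> dict:
    """Observed count of significant targets against the counts obtained
    on random same-size gene sets drawn from the non-target genes.

    Returns a record with the observed count, the random counts, and
    the empirical percentile of the observed count (mid-rank for ties).
    """
    if n_random_sets < 1:
        raise ValueError("n_random_sets must be >= 1")
    if n_random_sets == 1:
        logger.warning("n_random_sets=1 gives a degenerate percentile")
    targets = sorted(set(targets))
    observed = sum(
        r.significant
        for r in differential_targets(tf, alteration_matrix, expression, cna, targets, cfg)
    )
    candidates = sorted(set(expression.genes) - set(targets) - {tf})
    size = len(targets)
    if size > len(candidates):
        raise ValueError("fewer candidate genes than the target-set size")
    random_counts = []
    for _ in range(n_random_sets):
        picked = list(rng.choice(candidates, size=size, replace=False))
        random_counts.append(
            sum(
                r.significant
                for r in differential_targets(
                    tf, alteration_matrix, expression, cna, picked, cfg
                )
            )
        )
    rc = np.asarray(random_counts)
    percentile = float(((rc < observed).sum() + 0.5 * (rc == observed).sum()) / len(rc))
    return {
        "tf": tf,
        "n_significant_targets": int(observed),
        "random_counts": random_counts,
        "percentile": percentile,
    }


def truncating_vs_missense(
    tf: str,
    calls: Sequence[AlterationCall],
    expression: GeneSampleMatrix,
    targets: Iterable[str],
    cfg: Config,
) -> TestResult | None:
    """Pooled |log2 fold-change| contrast of truncating-only vs
    missense-only altered samples.

    Per target, |log2FC| is computed for samples whose only alterations
    of the TF are truncating (resp. missense) against unaltered
    samples; the two pooled vectors are compared two-sided.  Returns
    None when any of the three groups is below ``min_group_size``.
    """
    classes_by_sample: dict = {}
    for call in calls:
        if call.gene == tf:
            classes_by_sample.setdefault(call.sample_id, set()).add(call.alteration_class)
    altered = set(classes_by_sample)
    trunc_only = {s for s, cl in classes_by_sample.items() if cl == {"truncating"}}
    mis_only = {s for s, cl in classes_by_sample.items() if cl == {"missense"}}
    unaltered = set(expression.samples) - altered
    if min(len(trunc_only), len(mis_only), len(unaltered)) < cfg.min_group_size:
        logger.info(
            "%s: truncating-vs-missense skipped (groups %d/%d/%d below %d)",
            tf, len(trunc_only), len(mis_only), len(unaltered), cfg.min_group_size,
        )
        return None
    t_sorted, m_sorted, u_sorted = sorted(trunc_only), sorted(mis_only), sorted(unaltered)
    fc_trunc, fc_mis = [], []
    for target in sorted(set(targets)):
        if target == tf or target not in expression.df.index:
            continue
        row = expression.row(target)
        u = row[u_sorted].to_numpy()
        fc_trunc.append(abs(_log2_fc(row[t_sorted].to_numpy(), u, cfg.fc_pseudocount)))
        fc_mis.append(abs(_log2_fc(row[m_sorted].to_numpy(), u, cfg.fc_pseudocount)))
    if not fc_trunc:
        logger.warning("%s: no targets usable for truncating-vs-missense", tf)
        return None
    return mann_whitney(fc_trunc, fc_mis, "two_sided")


def differential_targets_frame(results: Sequence[DifferentialTarget]) -> pd.DataFrame:
    """Tabular export, including volcano-plot coordinates."""
    df = pd.DataFrame(
        [
            (
                r.tf,
                r.target,
                r.tumor_type,
                r.n_alt,
                r.n_unalt,
                r.p_value,
                r.log2_fc,
                r.direction,
                r.significant,
            )
            for r in results
        ],
        columns=[
            "tf",
            "target",
            "tumor_type",
            "n_alt",
            "n_unalt",
            "p_value",
            "log2_fc",
            "direction",
            "significant",
        ],
    )
    with np.errstate(divide="ignore"):
        df["minus_log10_p"] = -np.log10(df["p_value"].to_numpy(dtype=float))
    return df
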