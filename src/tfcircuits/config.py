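"""Analysis configuration: every numeric threshold of the pipeline in one place.

Defaults mirror the published analysis: germline variants kept at allele
frequency >= 1e-4, deletion CNA < -0.75 and amplification CNA > 1 with the
in-between interval treated as copy-neutral, differential targets at
Mann-Whitney p < 0.05 with |log2 fold-change| > 1, and circuit overlaps at
BH q < 1e-3.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = [
    "Config",
    "TRUNCATING_CONSEQUENCES",
    "PROTEIN_AFFECTING_CONSEQUENCES",
    "CONSEQUENCE_VOCABULARY",
]

#: mutation consequence classes treated as truncating
TRUNCATING_CONSEQUENCES = frozenset(
    {"stop_gained", "stop_lost", "frameshift", "splice_donor", "splice_acceptor"}
)

#: consequence classes deemed to affect the protein sequence
PROTEIN_AFFECTING_CONSEQUENCES = frozenset(TRUNCATING_CONSEQUENCES | {"missense"})

#: closed consequence vocabulary; anything else maps to "other" on read
CONSEQUENCE_VOCABULARY = frozenset(PROTEIN_AFFECTING_CONSEQUENCES | {"other"})


@dataclass
class Config:
    """Tunable thresholds for every pipeline stage.

    Attributes
    ----------
    af_min
        Minimum germline allele frequency retained (common-polymorphism
        filter for the domain contrast).
    cna_del_max, cna_amp_min
        Continuous CNA bounds: deletion strictly below ``cna_del_max``,
        amplification strictly above ``cna_amp_min``, copy-neutral in
        the closed interval between them.
    de_p_max, de_abs_log2fc_min
        Joint significance rule for a misregulated target.
    concordance_p_max
        Mann-Whitney threshold for CNA/expression concordance of a
        driver's own transcript.
    min_group_size
        Smallest group admitted to any two-group expression comparison.
    partner_overlap_max
        Maximum altered-sample overlap fraction between a TF and an
        eligible network partner.
    circuit_q_max
        BH q-value below which a circuit overlap is called significant.
    fc_pseudocount
        Pseudocount (RPKM units) added to both group medians in the
        fold-change ratio.
    slea_n_perm
        Number of random same-size gene sets in the SLEA null.
    slea_summary
        Per-sample summary of the centered set expression: mean or median.
    """

    af_min: float = 1e-4
    cna_del_max: float = -0.75
    cna_amp_min: float = 1.0
    de_p_max: float = 0.05
    de_abs_log2fc_min: float = 1.0
    concordance_p_max: float = 0.05
    min_group_size: int = 5
    partner_overlap_max: float = 0.5
    circuit_q_max: float = 1e-3
    fc_pseudocount: float = 1.0
    slea_n_perm: int = 1000
    slea_summary: str = "mean"
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.af_min < 1.0):
            raise ValueError("af_min must lie in (0, 1)")
        if self.cna_del_max >= self.cna_amp_min:
            raise ValueError("cna_del_max must be below cna_amp_min")
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.slea_n_perm < 1:
            raise ValueError("slea_n_perm must be >= 1")
        if self.slea_summary not in ("mean", "median"):
            raise ValueError("slea_summary must be 'mean' or 'median'")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "Config":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
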