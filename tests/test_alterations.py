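"""Driver-alteration calling rules, CNA concordance, and the toy cohort.

The toy tumor type used here (10 samples, 3 drivers) exercises every
calling branch by hand: LoF truncating and missense calls, Act
stop-gain exclusion, concordant and discordant CNA, the Undetermined
-> Act rule, and the copy-neutral boundary values -0.75 and 1.0.
"""

import numpy as np
import pandas as pd
import pytest

from tfcircuits.alterations import (
    build_alteration_matrix,
    classify_driver_mutations,
    cna_concordance,
)
from tfcircuits.config import Config
from tfcircuits.io import DriverGene, GeneSampleMatrix, MutationRecord


def _driver(gene, mode):
    return DriverGene(gene, frozenset({"TOY"}), mode, is_tf=True)


SAMPLES = [f"s{i:02d}" for i in range(1, 11)]
DRIVERS = [_driver("DLOF", "LoF"), _driver("DACT", "Act"), _driver("DUND", "Undetermined")]

# mutations covering the per-mode rules
MUTATIONS = [
    MutationRecord("s07", "DLOF", 10, "missense"),
    MutationRecord("s08", "DLOF", 20, "frameshift"),
    MutationRecord("s09", "DACT", 30, "stop_gained"),   # excluded: Act driver
    MutationRecord("s10", "DACT", 40, "missense"),
    MutationRecord("s01", "DUND", 50, "missense"),      # Undetermined -> Act rule
    MutationRecord("s02", "DUND", 60, "splice_donor"),  # excluded: Act rule
]

# DLOF: s01-s05 deleted, s06 at the -0.75 boundary (copy-neutral), rest neutral
# DACT: s01-s05 amplified, s06 at the 1.0 boundary (copy-neutral), rest neutral
CNA = pd.DataFrame(
    {
        "DLOF": [-1.2, -1.2, -1.2, -1.2, -1.2, -0.75, 0, 0, 0, 0],
        "DACT": [1.5, 1.5, 1.5, 1.5, 1.5, 1.0, 0, 0, 0, 0],
        "DUND": [0.0] * 10,
    },
    index=SAMPLES,
).T

# DLOF expression concordant with deletion (deleted samples low);
# DACT expression DISCORDANT with amplification (amplified samples low)
EXPR = pd.DataFrame(
    {
        "DLOF": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        "DACT": [1, 2, 3, 4, 5, 6, 7, 8, 9, 10],
        "DUND": [5.0] * 10,
    },
    index=SAMPLES,
).T


class TestClassifyDriverMutations:
    def test_lof_driver_counts_truncating_and_missense(self):
        calls = classify_driver_mutations(MUTATIONS, DRIVERS)
        dlof = {(c.sample_id, c.alteration_class) for c in calls if c.gene == "DLOF"}
        assert dlof == {("s07", "missense"), ("s08", "truncating")}

    def test_act_driver_counts_missense_only(self):
        calls = classify_driver_mutations(MUTATIONS, DRIVERS)
        dact = {(c.sample_id, c.alteration_class) for c in calls if c.gene == "DACT"}
        assert dact == {("s10", "missense")}

    def test_undetermined_follows_act_rule(self):
        calls = classify_driver_mutations(MUTATIONS, DRIVERS)
        dund = {(c.sample_id, c.alteration_class) for c in calls if c.gene == "DUND"}
        assert dund == {("s01", "missense")}

    def test_mutation_on_unknown_gene_skipped(self):
        extra = MUTATIONS + [MutationRecord("s01", "NOPE", 1, "missense")]
        calls = classify_driver_mutations(extra, DRIVERS)
        assert all(c.gene != "NOPE" for c in calls)


class TestCnaConcordance:
    def test_planted_downshift_is_concordant(self, cfg):
        rng = np.random.default_rng(0)
        samples = [f"t{i}" for i in range(70)]
        cna = pd.Series([-1.5] * 20 + [0.0] * 50, index=samples)
        expr = pd.Series(
            np.concatenate([rng.lognormal(0, 0.3, 20) * 0.25, rng.lognormal(0, 0.3, 50)]),
            index=samples,
        )
        assert cna_concordance(_driver("DLOF", "LoF"), cna, expr, cfg)

    def test_identical_distributions_are_discordant(self, cfg):
        samples = [f"t{i}" for i in range(40)]
        cna = pd.Series([-1.5] * 20 + [0.0] * 20, index=samples)
        expr = pd.Series(list(range(20)) + list(range(20)), index=samples, dtype=float)
        assert not cna_concordance(_driver("DLOF", "LoF"), cna, expr, cfg)

    def test_small_group_is_unestablished(self, cfg):
        samples = [f"t{i}" for i in range(12)]
        cna = pd.Series([-1.5, -1.5] + [0.0] * 10, index=samples)
        expr = pd.Series([0.1, 0.2] + list(range(10, 20)), index=samples, dtype=float)
        assert not cna_concordance(_driver("DLOF", "LoF"), cna, expr, cfg)

    def test_direction_must_match(self, cfg):
        # amplified samples with LOWER expression: significant but discordant
        samples = [f"t{i}" for i in range(40)]
        cna = pd.Series([1.5] * 20 + [0.0] * 20, index=samples)
        expr = pd.Series(list(range(20)) + list(range(100, 120)), index=samples,
                         dtype=float)
        assert not cna_concordance(_driver("DACT", "Act"), cna, expr, cfg)


class TestToyCohortMatrix:
    def test_expected_altered_matrix(self, cfg):
        expression = GeneSampleMatrix(EXPR, "expression_rpkm")
        cna = GeneSampleMatrix(CNA, "cna_continuous")
        altmat = build_alteration_matrix("TOY", MUTATIONS, cna, expression, DRIVERS, cfg)
        # DLOF: concordant deletions s01-s05 plus mutations s07, s08;
        # boundary CNA -0.75 (s06) is copy-neutral
        assert altmat.altered_samples("DLOF") == {"s01", "s02", "s03", "s04", "s05",
                                                  "s07", "s08"}
        # DACT: discordant CNA contributes nothing; boundary 1.0 neutral;
        # stop_gained excluded; only the missense call remains
        assert altmat.altered_samples("DACT") == {"s10"}
        # DUND follows the Act mutation rule
        assert altmat.altered_samples("DUND") == {"s01"}

    def test_deletion_calls_labelled(self, cfg):
        expression = GeneSampleMatrix(EXPR, "expression_rpkm")
        cna = GeneSampleMatrix(CNA, "cna_continuous")
        altmat = build_alteration_matrix("TOY", MUTATIONS, cna, expression, DRIVERS, cfg)
        classes = {
            (c.sample_id, c.alteration_class) for c in altmat.calls if c.gene == "DLOF"
        }
        assert ("s01", "deletion") in classes
        assert ("s06", "deletion") not in classes

    def test_sample_missing_from_expression_excluded(self, cfg):
        expression = GeneSampleMatrix(EXPR.drop(columns=["s07"]), "expression_rpkm")
        cna = GeneSampleMatrix(CNA, "cna_continuous")
        altmat = build_alteration_matrix("TOY", MUTATIONS, cna, expression, DRIVERS, cfg)
        assert "s07" not in altmat.altered_samples("DLOF")

    def test_no_calls_gives_all_false_matrix(self, cfg):
        expression = GeneSampleMatrix(EXPR, "expression_rpkm")
        neutral = GeneSampleMatrix(CNA * 0.0, "cna_continuous")
        altmat = build_alteration_matrix("TOY", [], neutral, expression, DRIVERS, cfg)
        assert not altmat.altered.to_numpy().any()

    def test_mutation_calls_survive_without_concordance(self, cfg):
        # monotonicity: removing the CNA stream never removes mutation calls
        expression = GeneSampleMatrix(EXPR, "expression_rpkm")
        neutral = GeneSampleMatrix(CNA * 0.0, "cna_continuous")
        altmat = build_alteration_matrix("TOY", MUTATIONS, neutral, expression,
                                         DRIVERS, cfg)
        assert altmat.altered_samples("DLOF") == {"s07", "s08"}


def test_called_alterations_match_truth_on_synthetic_cohort(small_cohort, cfg):
    altmat = build_alteration_matrix(
        "SIM", small_cohort.mutations, small_cohort.cna, small_cohort.expression,
        small_cohort.drivers, cfg,
    )
    for d in small_cohort.drivers:
        assert altmat.altered_samples(d.gene) == small_cohort.truth.altered_samples[d.gene]
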