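"""Target differential expression, background comparison, mutation-class contrast."""

import numpy as np
import pandas as pd
import pytest

from tfcircuits.alterations import AlterationCall, AlterationMatrix, build_alteration_matrix
from tfcircuits.config import Config
from tfcircuits.io import GeneSampleMatrix
from tfcircuits.targets import (
    background_de_rate,
    differential_targets,
    truncating_vs_missense,
)

ALT = [f"a{i}" for i in range(6)]
UNALT = [f"u{i}" for i in range(6)]
SAMPLES = ALT + UNALT


def _altmat(tf="TF", alt_samples=ALT, samples=SAMPLES, klass="missense"):
    calls = [AlterationCall(s, tf, klass) for s in alt_samples]
    return AlterationMatrix("TOY", samples, [tf], calls)


def _expr(rows: dict) -> GeneSampleMatrix:
    return GeneSampleMatrix(pd.DataFrame(rows, index=SAMPLES).T, "expression_rpkm")


class TestDifferentialTargets:
    def test_worked_fold_change_example(self, cfg):
        # alt medians 11.5 (+1 -> 12.5), unalt 2.5 (+1 -> 3.5)
        expr = _expr({"t1": [10, 12, 11, 13, 10, 12, 2, 3, 2, 4, 3, 2]})
        (res,) = differential_targets("TF", _altmat(), expr, None, {"t1"}, cfg)
        assert res.log2_fc == pytest.approx(np.log2(12.5 / 3.5))
        assert res.p_value < 0.05
        assert res.significant and res.direction == "up"

    def test_identical_groups_are_null(self, cfg):
        expr = _expr({"t1": [2, 3, 2, 4, 3, 2, 2, 3, 2, 4, 3, 2]})
        (res,) = differential_targets("TF", _altmat(), expr, None, {"t1"}, cfg)
        assert res.log2_fc == 0.0
        assert res.p_value > 0.9
        assert not res.significant

    def test_joint_rule_requires_both_thresholds(self, cfg):
        # consistent 1.5x shift: p small but |log2FC| < 1 -> not significant
        unalt = np.linspace(10, 10.9, 6)
        alt = unalt * 1.5
        expr = _expr({"t1": np.concatenate([alt, unalt])})
        (res,) = differential_targets("TF", _altmat(), expr, None, {"t1"}, cfg)
        assert res.p_value < 0.05
        assert abs(res.log2_fc) < 1.0
        assert not res.significant

    def test_target_cna_samples_excluded(self, cfg):
        expr = _expr({"t1": [10, 12, 11, 13, 10, 12, 2, 3, 2, 4, 3, 2]})
        cna_df = pd.DataFrame(0.0, index=["t1"], columns=SAMPLES)
        cna_df.loc["t1", "a0"] = -1.2  # deleted target copy in one altered sample
        cna_df.loc["t1", "u0"] = 1.4   # amplified target copy in one reference sample
        cna = GeneSampleMatrix(cna_df, "cna_continuous")
        (res,) = differential_targets("TF", _altmat(), expr, cna, {"t1"}, cfg)
        assert (res.n_alt, res.n_unalt) == (5, 5)

    def test_small_group_skipped(self, cfg):
        expr = _expr({"t1": range(12)})
        altmat = _altmat(alt_samples=ALT[:3])
        assert differential_targets("TF", altmat, expr, None, {"t1"}, cfg) == []

    def test_no_targets_warns_and_returns_empty(self, cfg):
        expr = _expr({"t1": range(12)})
        assert differential_targets("TF", _altmat(), expr, None, set(), cfg) == []

    def test_down_direction(self, cfg):
        expr = _expr({"t1": [2, 3, 2, 4, 3, 2, 10, 12, 11, 13, 10, 12]})
        (res,) = differential_targets("TF", _altmat(), expr, None, {"t1"}, cfg)
        assert res.direction == "down" and res.log2_fc < -1


class TestRecoveryOnSyntheticCohort:
    def test_planted_targets_recovered_with_correct_direction(self, small_cohort, cfg):
        altmat = build_alteration_matrix(
            "SIM", small_cohort.mutations, small_cohort.cna,
            small_cohort.expression, small_cohort.drivers, cfg,
        )
        tf = "TF02"  # no planted circuit dilution on this TF's reference group
        res = differential_targets(
            tf, altmat, small_cohort.expression, small_cohort.cna,
            small_cohort.targets[tf].targets, cfg,
        )
        truth = small_cohort.truth.planted_targets[tf]
        recovered = {r.target: r.direction for r in res if r.significant}
        assert len(set(recovered) & set(truth)) / len(truth) >= 0.9
        for target, direction in recovered.items():
            if target in truth:
                assert truth[target][0] == direction


class TestBackgroundRate:
    def test_planted_effects_exceed_random_background(self, small_cohort, cfg):
        altmat = build_alteration_matrix(
            "SIM", small_cohort.mutations, small_cohort.cna,
            small_cohort.expression, small_cohort.drivers, cfg,
        )
        rec = background_de_rate(
            "TF02", altmat, small_cohort.expression, small_cohort.cna,
            small_cohort.targets["TF02"].targets, cfg,
            n_random_sets=20, rng=np.random.default_rng(0),
        )
        assert rec["percentile"] >= 0.95
        assert rec["n_significant_targets"] > max(rec["random_counts"])

    def test_single_random_set_is_degenerate(self, cfg):
        expr = _expr({"t1": range(12), "g1": range(12), "g2": range(12)})
        rec = background_de_rate(
            "TF", _altmat(), expr, None, {"t1"}, cfg,
            n_random_sets=1, rng=np.random.default_rng(0),
        )
        assert rec["percentile"] in (0.0, 0.5, 1.0)

    def test_set_larger_than_candidates_rejected(self, cfg):
        expr = _expr({"t1": range(12)})
        with pytest.raises(ValueError, match="candidate"):
            background_de_rate("TF", _altmat(), expr, None, {"t1"}, cfg,
                               n_random_sets=2, rng=np.random.default_rng(0))


class TestTruncatingVsMissense:
    @staticmethod
    def _cohort(trunc_shift, mis_shift, n_targets=15, seed=0):
        rng = np.random.default_rng(seed)
        trunc = [f"t{i}" for i in range(5)]
        mis = [f"m{i}" for i in range(5)]
        un = [f"n{i}" for i in range(10)]
        samples = trunc + mis + un
        rows = {}
        for i in range(n_targets):
            base = rng.lognormal(2.0, 0.3, len(samples))
            base[:5] *= 2.0 ** trunc_shift
            base[5:10] *= 2.0 ** mis_shift
            rows[f"g{i}"] = base
        expr = GeneSampleMatrix(pd.DataFrame(rows, index=samples).T, "expression_rpkm")
        calls = [AlterationCall(s, "TF", "truncating") for s in trunc] + [
            AlterationCall(s, "TF", "missense") for s in mis
        ]
        return expr, calls, [f"g{i}" for i in range(n_targets)]

    def test_stronger_truncating_effect_detected(self, cfg):
        expr, calls, targets = self._cohort(2.0, 0.5)
        res = truncating_vs_missense("TF", calls, expr, targets, cfg)
        assert res is not None and res.p_value < 0.05

    def test_equal_shifts_are_null(self, cfg):
        expr, calls, targets = self._cohort(1.0, 1.0)
        res = truncating_vs_missense("TF", calls, expr, targets, cfg)
        assert res.p_value > 0.05

    def test_single_target_is_degenerate(self, cfg):
        expr, calls, targets = self._cohort(2.0, 0.5, n_targets=1)
        res = truncating_vs_missense("TF", calls, expr, targets, cfg)
        assert res.p_value == 1.0

    def test_insufficient_groups_skipped(self, cfg):
        expr, calls, targets = self._cohort(2.0, 0.5)
        trunc_only = [c for c in calls if c.alteration_class == "truncating"][:2]
        mis = [c for c in calls if c.alteration_class == "missense"]
        res = truncating_vs_missense("TF", trunc_only + mis, expr, targets, cfg)
        assert res is None
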