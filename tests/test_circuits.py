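"""Cross-tumor overlaps, partner eligibility, and circuit scoring."""

import pytest

from tfcircuits.alterations import AlterationCall, AlterationMatrix, build_alteration_matrix
from tfcircuits.circuits import (
    CircuitCandidate,
    cross_tumor_overlap,
    detect_circuits,
    find_partners,
    partner_differential_targets,
    score_circuits,
)
from tfcircuits.io import DriverGene, InteractionNetwork
from tfcircuits.targets import differential_targets

from _oracles import fisher_oracle


def _driver(gene, is_tf=False):
    return DriverGene(gene, frozenset({"T"}), "Act", is_tf)


def _altmat(altered_by_gene, samples):
    calls = [
        AlterationCall(s, g, "missense")
        for g, alt in altered_by_gene.items()
        for s in alt
    ]
    return AlterationMatrix("T", samples, list(altered_by_gene), calls)


class TestCrossTumorOverlap:
    def test_identical_sets(self):
        universe = {f"g{i}" for i in range(20)}
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}}
        (res,) = cross_tumor_overlap("TF", sets, universe)
        assert res.jaccard == 1.0 and res.overlap_size == 2

    def test_disjoint_sets(self):
        universe = {f"g{i}" for i in range(20)}
        sets = {"A": {"g1"}, "B": {"g2"}}
        (res,) = cross_tumor_overlap("TF", sets, universe)
        assert res.jaccard == 0.0
        assert res.p == pytest.approx(1.0)

    def test_matches_enumeration_and_single_pair_q(self):
        universe = {f"g{i}" for i in range(100)}
        a = {f"g{i}" for i in range(10)}
        (res,) = cross_tumor_overlap("TF", {"A": a, "B": set(a)}, universe)
        want = fisher_oracle(10, 0, 0, 90, "greater")
        assert res.p == pytest.approx(want, abs=1e-12)
        assert res.q == pytest.approx(res.p)

    def test_bh_applied_across_pairs(self):
        universe = {f"g{i}" for i in range(50)}
        sets = {"A": {"g1", "g2"}, "B": {"g1", "g2"}, "C": {"g40"}}
        res = cross_tumor_overlap("TF", sets, universe)
        assert len(res) == 3
        assert all(r.q >= r.p for r in res)

    def test_universe_violation_rejected(self):
        with pytest.raises(ValueError):
            cross_tumor_overlap("TF", {"A": {"x"}, "B": set()}, {"y"})

    def test_single_tumor_rejected(self):
        with pytest.raises(ValueError):
            cross_tumor_overlap("TF", {"A": {"x"}}, {"x"})


class TestFindPartners:
    SAMPLES = [f"s{i}" for i in range(20)]
    DRIVERS = [_driver("TF1", is_tf=True), _driver("TF2", is_tf=True),
               _driver("P1"), _driver("P2"), _driver("P3")]

    def _network(self, *pairs):
        return InteractionNetwork([(a, b, "in-complex-with") for a, b in pairs])

    def test_disjoint_altered_partner_eligible(self, cfg):
        altmat = _altmat(
            {"TF1": self.SAMPLES[:6], "P1": self.SAMPLES[10:16]}, self.SAMPLES
        )
        net = self._network(("TF1", "P1"))
        assert find_partners("TF1", self.DRIVERS, net, altmat, cfg) == ["P1"]

    def test_identical_altered_sets_excluded(self, cfg):
        altmat = _altmat(
            {"TF1": self.SAMPLES[:6], "P1": self.SAMPLES[:6]}, self.SAMPLES
        )
        net = self._network(("TF1", "P1"))
        assert find_partners("TF1", self.DRIVERS, net, altmat, cfg) == []

    def test_half_overlap_is_still_eligible(self, cfg):
        altmat = _altmat(
            {"TF1": self.SAMPLES[:6], "P1": self.SAMPLES[3:9]}, self.SAMPLES
        )
        net = self._network(("TF1", "P1"))
        assert find_partners("TF1", self.DRIVERS, net, altmat, cfg) == ["P1"]

    def test_tf_neighbors_excluded(self, cfg):
        altmat = _altmat(
            {"TF1": self.SAMPLES[:6], "TF2": self.SAMPLES[10:16]}, self.SAMPLES
        )
        net = self._network(("TF1", "TF2"))
        assert find_partners("TF1", self.DRIVERS, net, altmat, cfg) == []

    def test_partner_without_alterations_excluded(self, cfg):
        altmat = _altmat({"TF1": self.SAMPLES[:6], "P1": []}, self.SAMPLES)
        net = self._network(("TF1", "P1"))
        assert find_partners("TF1", self.DRIVERS, net, altmat, cfg) == []

    def test_tf_absent_from_network(self, cfg):
        altmat = _altmat({"TF1": self.SAMPLES[:6]}, self.SAMPLES)
        net = self._network(("P1", "P2"))
        assert find_partners("TF1", self.DRIVERS, net, altmat, cfg) == []


class TestScoreCircuits:
    UNIVERSE = frozenset(f"g{i}" for i in range(50))

    def test_empty_tf_set_gives_unit_p(self, cfg):
        cand = CircuitCandidate(
            "TF", "P", frozenset(), frozenset(), frozenset({"g1"}), frozenset(),
            self.UNIVERSE,
        )
        (c,) = score_circuits("T", [cand], cfg)
        assert c.q_up == pytest.approx(1.0) and c.q_down == pytest.approx(1.0)
        assert not c.significant

    def test_single_candidate_q_equals_p(self, cfg):
        up = frozenset(f"g{i}" for i in range(10))
        cand = CircuitCandidate("TF", "P", up, frozenset(), up, frozenset(),
                                self.UNIVERSE)
        (c,) = score_circuits("T", [cand], cfg)
        want = fisher_oracle(10, 0, 0, 40, "greater")
        assert c.q_up == pytest.approx(want, abs=1e-12)
        assert c.significant

    def test_empty_universe_rejected(self, cfg):
        cand = CircuitCandidate("TF", "P", frozenset(), frozenset(), frozenset(),
                                frozenset(), frozenset())
        with pytest.raises(ValueError, match="universe"):
            score_circuits("T", [cand], cfg)


@pytest.fixture(scope="module")
def analysis(small_cohort):
    from tfcircuits.config import Config

    cfg = Config()
    altmat = build_alteration_matrix(
        "SIM", small_cohort.mutations, small_cohort.cna,
        small_cohort.expression, small_cohort.drivers, cfg,
    )
    tf_results = {
        tf: differential_targets(
            tf, altmat, small_cohort.expression, small_cohort.cna,
            small_cohort.targets[tf].targets, cfg,
        )
        for tf in sorted(small_cohort.targets)
    }
    circuits = detect_circuits(
        "SIM", tf_results,
        {tf: set(small_cohort.targets[tf].targets) for tf in tf_results},
        small_cohort.drivers, small_cohort.network, altmat,
        small_cohort.expression, small_cohort.cna, cfg,
    )
    return altmat, tf_results, circuits, cfg


class TestOnSyntheticCohort:
    def test_planted_circuit_significant_decoy_not(self, analysis):
        _, _, circuits, _ = analysis
        by_pair = {(c.tf, c.partner): c for c in circuits}
        assert by_pair[("TF01", "PT01")].significant
        assert not by_pair[("TF02", "PT02")].significant

    def test_partner_recovers_shared_targets(self, small_cohort, analysis):
        altmat, _, _, cfg = analysis
        res = partner_differential_targets(
            "TF01", "PT01", altmat, small_cohort.expression, small_cohort.cna,
            set(small_cohort.targets["TF01"].targets), cfg,
        )
        shared = {
            t for rec in small_cohort.truth.planted_circuits
            if rec["tf"] == "TF01"
            for t in rec["shared_targets"]
        }
        sig = {r.target for r in res if r.significant}
        assert len(sig & shared) / len(shared) >= 0.8

    def test_partner_reference_excludes_tf_altered(self, small_cohort, analysis):
        altmat, _, _, cfg = analysis
        res = partner_differential_targets(
            "TF01", "PT01", altmat, small_cohort.expression, small_cohort.cna,
            set(small_cohort.targets["TF01"].targets), cfg,
        )
        n_neither = len(
            set(altmat.samples)
            - altmat.altered_samples("TF01")
            - altmat.altered_samples("PT01")
        )
        assert all(r.n_unalt <= n_neither for r in res)
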