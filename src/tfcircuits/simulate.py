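"""Synthetic tumor-cohort generator with a ground-truth manifest.

The generator emulates the statistical structure the downstream analysis
assumes: a cohort of tumor samples in which each driver TF is altered in
a fraction of samples (by protein-affecting mutations or by concordant
copy-number events), log-normal RPKM-like expression in which a planted
subset of each TF's annotated targets is shifted by an exact log2 effect
in altered samples, continuous gene-level CNA values, domain-localized
somatic mutation hotspots against uniformly scattered germline variants,
and TF-partner driver pairs whose alterations converge on a shared
subset of the TF's planted targets.

Every planted signal is recorded in a :class:`SyntheticTruth` manifest
so recovery can be scored exactly.  All randomness flows from one
integer seed through per-component `numpy` SeedSequence streams, so the
output is bit-reproducible and adding one component does not perturb the
others.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import TRUNCATING_CONSEQUENCES
from .io import (
    DomainAnnotation,
    DriverGene,
    GeneSampleMatrix,
    GermlineVariant,
    InteractionNetwork,
    MutationRecord,
    TargetAnnotation,
    write_domains,
    write_drivers,
    write_gene_sample_matrix,
    write_genesets_gmt,
    write_germline,
    write_mutations,
    write_network_sif,
)

__all__ = ["SimConfig", "SyntheticTruth", "Cohort", "simulate_cohort",
           "plant_circuit", "plant_domain_hotspot", "write_cohort"]

_MUTATION_CLASSES = sorted(TRUNCATING_CONSEQUENCES | {"missense"})


@dataclass
class SimConfig:
    """Parameters of the synthetic cohort.

    Expression is multiplicative log-normal: gene baselines are
    ``exp(N(baseline_log_mean, baseline_log_sd))`` (natural log), each
    cell gets ``exp(N(0, noise_log_sd))`` noise, and planted effects
    multiply by ``2**effect_log2`` so the pipeline's log2 fold-change
    has a known expectation.
    """

    n_samples: int = 100
    n_genes: int = 300            # non-driver gene pool
    n_tfs: int = 3
    n_partners: int = 2           # non-TF partner drivers
    targets_per_tf: int = 50
    planted_fraction: float = 0.6  # share of annotated targets with planted effects
    alt_fraction: float = 0.3     # per-sample alteration probability per driver TF
    partner_alt_fraction: float = 0.15  # alteration probability per partner driver
    cna_fraction: float = 0.3     # share of a driver's alterations that are CNA events
    effect_log2: float = 2.0
    baseline_log_mean: float = 2.0
    baseline_log_sd: float = 1.0
    noise_log_sd: float = 0.5
    cna_alt_value: float = 1.5    # magnitude; sign follows mode of action
    cna_neutral_sd: float = 0.1
    mutation_rate_bg: float = 1e-4
    hotspot_multiplier: float = 10.0
    germline_sites: int = 100
    protein_len: int = 500
    n_cohorts: int = 2
    tumor_type: str = "SIM"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_samples", "n_genes", "n_tfs", "targets_per_tf",
                     "germline_sites", "protein_len", "n_cohorts"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if self.n_partners < 0:
            raise ValueError("n_partners must be >= 0")
        if not (0.0 < self.alt_fraction < 1.0):
            raise ValueError("alt_fraction must lie in (0, 1)")
        if not (0.0 < self.partner_alt_fraction < 1.0):
            raise ValueError("partner_alt_fraction must lie in (0, 1)")
        if not (0.0 < self.planted_fraction <= 1.0):
            raise ValueError("planted_fraction must lie in (0, 1]")
        if not (0.0 <= self.cna_fraction < 1.0):
            raise ValueError("cna_fraction must lie in [0, 1)")
        if self.targets_per_tf > self.n_genes:
            raise ValueError("targets_per_tf exceeds the gene pool")
        if self.n_tfs * self.targets_per_tf > self.n_genes:
            raise ValueError("gene pool too small for disjoint target sets")
        if abs(self.cna_alt_value) <= 1.0:
            raise ValueError("cna_alt_value magnitude must exceed the amplification bound 1.0")


@dataclass
class SyntheticTruth:
    """Manifest of every planted signal, the oracle for recovery tests."""

    planted_targets: dict = field(default_factory=dict)  # tf -> {target: (dir, log2)}
    planted_circuits: list = field(default_factory=list)  # dicts: tf, partner, ...
    hotspot_domains: dict = field(default_factory=dict)  # (gene, domain_id) -> mult
    altered_samples: dict = field(default_factory=dict)  # driver -> set of samples

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_targets": {
                tf: {t: [d, e] for t, (d, e) in sorted(m.items())}
                for tf, m in sorted(self.planted_targets.items())
            },
            "planted_circuits": self.planted_circuits,
            "hotspot_domains": {
                f"{g}|{d}": m for (g, d), m in sorted(self.hotspot_domains.items())
            },
            "altered_samples": {
                g: sorted(s) for g, s in sorted(self.altered_samples.items())
            },
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        with open(path) as fh:
            raw = json.load(fh)
        return cls(
            planted_targets={
                tf: {t: (d, e) for t, (d, e) in m.items()}
                for tf, m in raw["planted_targets"].items()
            },
            planted_circuits=raw["planted_circuits"],
            hotspot_domains={
                tuple(k.split("|", 1)): m for k, m in raw["hotspot_domains"].items()
            },
            altered_samples={g: set(s) for g, s in raw["altered_samples"].items()},
        )


@dataclass
class Cohort:
    """All simulated inputs of one tumor-type cohort plus the truth manifest."""

    config: SimConfig
    mutations: list
    cna: GeneSampleMatrix
    expression: GeneSampleMatrix
    targets: dict                 # tf -> TargetAnnotation
    network: InteractionNetwork
    drivers: list
    domains: list
    germline: list
    truth: SyntheticTruth
    cohort_labels: dict           # sample -> cohort name
    _rng_plant: np.random.Generator = field(repr=False, default=None)

    @property
    def tumor_type(self) -> str:
        return self.config.tumor_type

    def driver_by_gene(self, gene: str) -> DriverGene:
        for d in self.drivers:
            if d.gene == gene:
                return d
        raise KeyError(gene)


def _assign_modes(n_tfs: int) -> list[str]:
    # half LoF / half Act; one Undetermined (treated as Act) when there is room
    modes = ["LoF" if i % 2 == 0 else "Act" for i in range(n_tfs)]
    if n_tfs >= 3:
        modes[-1] = "Undetermined"
    return modes


def simulate_cohort(cfg: SimConfig) -> Cohort:
    """Generate one cohort; deterministic under ``cfg.seed``."""
    streams = np.random.SeedSequence(cfg.seed).spawn(8)
    rng_struct, rng_expr, rng_noise, rng_cna, rng_mut, rng_germ, rng_net, rng_plant = (
        np.random.default_rng(s) for s in streams
    )

    samples = [f"S{i:04d}" for i in range(1, cfg.n_samples + 1)]
    pool = [f"G{i:04d}" for i in range(1, cfg.n_genes + 1)]
    tf_genes = [f"TF{i:02d}" for i in range(1, cfg.n_tfs + 1)]
    partner_genes = [f"PT{i:02d}" for i in range(1, cfg.n_partners + 1)]
    all_genes = pool + tf_genes + partner_genes

    modes = _assign_modes(cfg.n_tfs)
    drivers = [
        DriverGene(g, frozenset({cfg.tumor_type}), mode, is_tf=True)
        for g, mode in zip(tf_genes, modes)
    ] + [
        DriverGene(g, frozenset({cfg.tumor_type}), "Act", is_tf=False)
        for g in partner_genes
    ]

    # --- target annotation: disjoint sets drawn from the pool --------------
    shuffled = list(rng_struct.permutation(pool))
    targets: dict = {}
    truth = SyntheticTruth()
    n_planted = max(1, round(cfg.planted_fraction * cfg.targets_per_tf))
    for i, tf in enumerate(tf_genes):
        block = shuffled[i * cfg.targets_per_tf : (i + 1) * cfg.targets_per_tf]
        targets[tf] = TargetAnnotation(tf, frozenset(block), frozenset({"synthetic"}))
        planted = block[:n_planted]
        dirs = rng_struct.choice(["up", "down"], size=n_planted)
        truth.planted_targets[tf] = {
            t: (str(d), cfg.effect_log2) for t, d in zip(planted, dirs)
        }

    # --- altered samples per driver ----------------------------------------
    tf_altered: dict = {}
    for d in drivers:
        if d.is_tf:
            mask = rng_struct.random(cfg.n_samples) < cfg.alt_fraction
            chosen = [s for s, m in zip(samples, mask) if m]
            tf_altered[d.gene] = chosen
        else:
            # partners: same marginal rate, drawn preferring samples not
            # altered for the paired TF so the overlap stays below half
            paired_tf = tf_genes[partner_genes.index(d.gene) % cfg.n_tfs]
            k = rng_struct.binomial(cfg.n_samples, cfg.partner_alt_fraction)
            taken = set(tf_altered[paired_tf])
            free = [s for s in samples if s not in taken]
            order = list(rng_struct.permutation(free)) + list(
                rng_struct.permutation(sorted(taken))
            )
            chosen = sorted(order[:k])
        truth.altered_samples[d.gene] = set(chosen)

    # --- alteration mechanism: CNA vs mutation ------------------------------
    cna_altered: dict = {d.gene: [] for d in drivers}
    mut_altered: dict = {d.gene: [] for d in drivers}
    for d in drivers:
        for s in sorted(truth.altered_samples[d.gene]):
            if d.is_tf and rng_struct.random() < cfg.cna_fraction:
                cna_altered[d.gene].append(s)
            else:
                mut_altered[d.gene].append(s)

    # --- expression ----------------------------------------------------------
    base = np.exp(rng_expr.normal(cfg.baseline_log_mean, cfg.baseline_log_sd,
                                  size=len(all_genes)))
    noise = np.exp(rng_noise.normal(0.0, cfg.noise_log_sd,
                                    size=(len(all_genes), cfg.n_samples)))
    expr = base[:, None] * noise
    expr_df = pd.DataFrame(expr, index=all_genes, columns=samples)

    sample_pos = {s: j for j, s in enumerate(samples)}
    gene_pos = {g: i for i, g in enumerate(all_genes)}
    for tf in tf_genes:
        cols = [sample_pos[s] for s in sorted(truth.altered_samples[tf])]
        if not cols:
            continue
        for t, (direction, eff) in truth.planted_targets[tf].items():
            sign = 1.0 if direction == "up" else -1.0
            expr_df.iloc[gene_pos[t], cols] *= 2.0 ** (sign * eff)
        # concordant shift of the TF's own transcript in CNA-altered samples
        mode = next(d for d in drivers if d.gene == tf).effective_mode
        cna_cols = [sample_pos[s] for s in cna_altered[tf]]
        if cna_cols:
            sign = -1.0 if mode == "LoF" else 1.0
            expr_df.iloc[gene_pos[tf], cna_cols] *= 2.0 ** (sign * cfg.effect_log2)

    expression = GeneSampleMatrix(expr_df, "expression_rpkm")

    # --- CNA ------------------------------------------------------------------
    cna_vals = rng_cna.normal(0.0, cfg.cna_neutral_sd,
                              size=(len(all_genes), cfg.n_samples))
    cna_df = pd.DataFrame(cna_vals, index=all_genes, columns=samples)
    for d in drivers:
        sign = -1.0 if d.effective_mode == "LoF" else 1.0
        for s in cna_altered[d.gene]:
            cna_df.loc[d.gene, s] = sign * abs(cfg.cna_alt_value)
    cna = GeneSampleMatrix(cna_df, "cna_continuous")

    # --- somatic mutations ----------------------------------------------------
    mutations: list[MutationRecord] = []
    for d in drivers:
        if d.effective_mode == "LoF":
            classes = _MUTATION_CLASSES
        else:
            classes = ["missense"]
        for s in mut_altered[d.gene]:
            pos = int(rng_mut.integers(1, cfg.protein_len + 1))
            cons = str(rng_mut.choice(classes))
            mutations.append(MutationRecord(s, d.gene, pos, cons))
    n_bg = rng_mut.poisson(cfg.mutation_rate_bg * cfg.n_samples * len(all_genes))
    for _ in range(n_bg):
        s = samples[int(rng_mut.integers(cfg.n_samples))]
        g = pool[int(rng_mut.integers(cfg.n_genes))]
        pos = int(rng_mut.integers(1, cfg.protein_len + 1))
        cons = str(rng_mut.choice(["missense", "other"]))
        mutations.append(MutationRecord(s, g, pos, cons))

    # --- domains & germline variants -------------------------------------------
    domains = []
    for tf in tf_genes:
        domains.append(DomainAnnotation(tf, f"DOM_{tf}_1", "DNA-binding-like",
                                        100, 200, "synthetic"))
        domains.append(DomainAnnotation(tf, f"DOM_{tf}_2", "dimerization-like",
                                        300, 350, "synthetic"))
    germline = []
    for tf in tf_genes:
        pos = rng_germ.integers(1, cfg.protein_len + 1, size=cfg.germline_sites)
        # log-uniform allele frequencies spanning the common-variant cutoff
        afs = 10.0 ** rng_germ.uniform(-6.0, -1.0, size=cfg.germline_sites)
        germline.extend(
            GermlineVariant(tf, int(p), float(a)) for p, a in zip(pos, afs)
        )

    # --- background network edges among pool genes -------------------------------
    edges = []
    n_edges = max(1, cfg.n_genes // 10)
    for _ in range(n_edges):
        i, j = rng_net.choice(cfg.n_genes, size=2, replace=False)
        edges.append((pool[int(i)], pool[int(j)], "interacts-with"))
    network = InteractionNetwork(edges)

    labels = {s: f"C{(j % cfg.n_cohorts) + 1}" for j, s in enumerate(samples)}

    return Cohort(
        config=cfg,
        mutations=mutations,
        cna=cna,
        expression=expression,
        targets=targets,
        network=network,
        drivers=drivers,
        domains=domains,
        germline=germline,
        truth=truth,
        cohort_labels=labels,
        _rng_plant=rng_plant,
    )


def plant_circuit(
    cohort: Cohort, tf: str, partner: str, shared_fraction: float
) -> Cohort:
    """Wire ``partner`` to ``tf`` in the network and shift ``shared_fraction``
    of the TF's planted targets, in the planted directions, in
    partner-altered samples.  ``shared_fraction = 0`` plants a decoy:
    the edge exists but the partner has no downstream effect."""
    if not (0.0 <= shared_fraction <= 1.0):
        raise ValueError("shared_fraction must lie in [0, 1]")
    driver_genes = {d.gene for d in cohort.drivers}
    if tf not in driver_genes or partner not in driver_genes:
        raise ValueError("tf and partner must both be simulated drivers")
    planted = sorted(cohort.truth.planted_targets[tf])
    k = round(shared_fraction * len(planted))
    order = list(cohort._rng_plant.permutation(planted))
    shared = sorted(order[:k])
    partner_samples = sorted(cohort.truth.altered_samples[partner])
    cols = [cohort.expression.samples.index(s) for s in partner_samples]
    gene_pos = {g: i for i, g in enumerate(cohort.expression.genes)}
    for t in shared:
        direction, eff = cohort.truth.planted_targets[tf][t]
        sign = 1.0 if direction == "up" else -1.0
        cohort.expression.df.iloc[gene_pos[t], cols] *= 2.0 ** (sign * eff)
    cohort.network = InteractionNetwork(
        cohort.network.edge_list() + [(tf, partner, "in-complex-with")]
    )
    cohort.truth.planted_circuits.append(
        {
            "tf": tf,
            "partner": partner,
            "shared_target_fraction": shared_fraction,
            "shared_targets": shared,
        }
    )
    return cohort


def plant_domain_hotspot(
    cohort: Cohort, gene: str, domain_id: str, multiplier: float
) -> Cohort:
    """Re-draw the positions of the somatic mutations on ``gene`` so the
    within-domain mutation density is ``multiplier`` times the outside
    density.  Germline variant positions stay uniform."""
    if multiplier < 0:
        raise ValueError("multiplier must be nonnegative")
    dom = next(
        (d for d in cohort.domains if d.gene == gene and d.domain_id == domain_id),
        None,
    )
    if dom is None:
        raise ValueError(f"domain {domain_id!r} is not annotated on {gene!r}")
    length = cohort.config.protein_len
    weights = np.ones(length)
    weights[dom.start_aa - 1 : dom.end_aa] = multiplier
    weights = weights / weights.sum()
    new_records = []
    for rec in cohort.mutations:
        if rec.gene == gene:
            pos = int(cohort._rng_plant.choice(length, p=weights)) + 1
            rec = MutationRecord(rec.sample_id, rec.gene, pos, rec.consequence)
        new_records.append(rec)
    cohort.mutations = new_records
    cohort.truth.hotspot_domains[(gene, domain_id)] = multiplier
    return cohort


def write_cohort(cohort: Cohort, out_dir: str | Path) -> dict:
    """Write every simulated input in the pipeline's file formats plus
    ``truth.json``; returns ``{name: path}``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "mutations": out / "mutations.tsv",
        "cna": out / "cna.tsv",
        "expression": out / "expression.tsv",
        "targets": out / "targets.gmt",
        "network": out / "network.sif",
        "drivers": out / "drivers.tsv",
        "domains": out / "domains.tsv",
        "germline": out / "germline.tsv",
        "truth": out / "truth.json",
        "cohorts": out / "cohorts.tsv",
        "sim_config": out / "sim_config.json",
    }
    write_mutations(cohort.mutations, paths["mutations"])
    write_gene_sample_matrix(cohort.cna, paths["cna"])
    write_gene_sample_matrix(cohort.expression, paths["expression"])
    write_genesets_gmt(
        [cohort.targets[tf] for tf in sorted(cohort.targets)], paths["targets"]
    )
    write_network_sif(cohort.network, paths["network"])
    write_drivers(cohort.drivers, paths["drivers"])
    write_domains(cohort.domains, paths["domains"])
    write_germline(cohort.germline, paths["germline"])
    cohort.truth.to_json(paths["truth"])
    pd.DataFrame(
        sorted(cohort.cohort_labels.items()), columns=["sample", "cohort"]
    ).to_csv(paths["cohorts"], sep="\t", index=False)
    with open(paths["sim_config"], "w") as fh:
        json.dump(dataclasses.asdict(cohort.config), fh, indent=1, sort_keys=True)
    return {k: str(v) for k, v in paths.items()}
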