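"""Stage orchestration: file-based pipeline over one simulated or user cohort.

Stages communicate only through declared files: the alteration stage
writes the call table and boolean matrix, the DE stage writes the
differential-target table, the circuit stage writes the circuit table
plus a GMT of the overlapping up/down target sets, and the SLEA stage
reads that GMT.  A run manifest records the configuration snapshot,
the seed, and SHA-256 digests of every input and output file.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .alterations import AlterationCall, AlterationMatrix, build_alteration_matrix
from .catalog import cohort_enrichment_frame, cohort_mutation_enrichment
from .circuits import circuits_frame, detect_circuits, cross_tumor_overlap
from .config import Config
from .domains import domain_enrichment_frame, domain_mutation_enrichment, filter_germline
from .io import (
    ALLOWED_EDGE_TYPES,
    read_domains,
    read_drivers,
    read_gene_sample_matrix,
    read_genesets_gmt,
    read_germline,
    read_mutations,
    read_network_sif,
    merge_target_sources,
    write_genesets_gmt,
    TargetAnnotation,
)
from .simulate import Cohort, SimConfig, plant_circuit, plant_domain_hotspot, \
    simulate_cohort, write_cohort
from .slea import slea_frame, slea_zscores
from .targets import differential_targets, differential_targets_frame

logger = logging.getLogger(__name__)

__all__ = [
    "InputBundle",
    "load_inputs",
    "default_scenario",
    "run_pipeline",
    "verify_manifest",
]


@dataclass
class InputBundle:
    """All cohort-level inputs loaded from one directory of declared files."""

    mutations: list
    cna: object
    expression: object
    targets: dict            # tf -> TargetAnnotation (sources merged)
    network: object
    drivers: list
    domains: list
    germline: list
    cohort_labels: dict
    tumor_type: str = "COHORT"


def load_inputs(input_dir: str | Path, tumor_type: str = "COHORT") -> InputBundle:
    d = Path(input_dir)
    for name in ("mutations.tsv", "cna.tsv", "expression.tsv", "targets.gmt",
                 "network.sif", "drivers.tsv", "domains.tsv", "germline.tsv",
                 "cohorts.tsv"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing input file: {d / name}")
    labels_df = pd.read_csv(d / "cohorts.tsv", sep="\t", dtype=str)
    return InputBundle(
        mutations=read_mutations(d / "mutations.tsv"),
        cna=read_gene_sample_matrix(d / "cna.tsv", "cna_continuous"),
        expression=read_gene_sample_matrix(d / "expression.tsv", "expression_rpkm"),
        targets=merge_target_sources(read_genesets_gmt(d / "targets.gmt")),
        network=read_network_sif(d / "network.sif", ALLOWED_EDGE_TYPES),
        drivers=read_drivers(d / "drivers.tsv"),
        domains=read_domains(d / "domains.tsv"),
        germline=read_germline(d / "germline.tsv"),
        cohort_labels=dict(zip(labels_df["sample"], labels_df["cohort"])),
        tumor_type=tumor_type,
    )


def default_scenario(cohort: Cohort) -> Cohort:
    """The standard planted scenario used by the simulate stage: one true
    circuit (shared fraction 0.8) and, when a second partner exists, one
    decoy circuit (shared fraction 0), plus one domain hotspot on the
    first TF."""
    tfs = [d.gene for d in cohort.drivers if d.is_tf]
    partners = [d.gene for d in cohort.drivers if not d.is_tf]
    if partners:
        plant_circuit(cohort, tfs[0], partners[0], 0.8)
    if len(partners) > 1 and len(tfs) > 1:
        plant_circuit(cohort, tfs[1], partners[1], 0.0)
    plant_domain_hotspot(
        cohort, tfs[0], f"DOM_{tfs[0]}_1", cohort.config.hotspot_multiplier
    )
    return cohort


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _calls_from_frame(df: pd.DataFrame) -> list[AlterationCall]:
    return [
        AlterationCall(r.sample, r.gene, r.alteration_class)
        for r in df.itertuples(index=False)
    ]


def run_pipeline(
    cfg: Config,
    out_dir: str | Path,
    sim_cfg: SimConfig | None = None,
    input_dir: str | Path | None = None,
) -> dict:
    """Run every stage and return the manifest (also written to
    ``manifest.json``).  Either simulate inputs (``sim_cfg``) into
    ``out_dir/inputs`` or load them from ``input_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stages = []

    if input_dir is None:
        if sim_cfg is None:
            sim_cfg = SimConfig(seed=cfg.rng_seed)
        cohort = default_scenario(simulate_cohort(sim_cfg))
        input_dir = out / "inputs"
        write_cohort(cohort, input_dir)
        stages.append("simulate")
    bundle = load_inputs(input_dir, tumor_type="SIM")

    # --- alteration calling --------------------------------------------------
    altmat = build_alteration_matrix(
        bundle.tumor_type, bundle.mutations, bundle.cna, bundle.expression,
        bundle.drivers, cfg,
    )
    altmat.calls_frame().to_csv(out / "alteration_calls.tsv", sep="\t", index=False)
    altmat.altered.astype(int).to_csv(out / "altered_matrix.tsv", sep="\t",
                                      index_label="gene")
    stages.append("call-alterations")

    # --- differential targets ------------------------------------------------
    tf_results = {}
    for tf in sorted(bundle.targets):
        if tf not in {d.gene for d in bundle.drivers}:
            continue
        tf_results[tf] = differential_targets(
            tf, altmat, bundle.expression, bundle.cna,
            bundle.targets[tf].targets, cfg,
        )
    all_de = [r for res in tf_results.values() for r in res]
    differential_targets_frame(all_de).to_csv(
        out / "differential_targets.tsv", sep="\t", index=False
    )
    stages.append("de-targets")

    # --- domain enrichment ---------------------------------------------------
    germline = filter_germline(bundle.germline, cfg.af_min)
    dom_res = domain_mutation_enrichment(bundle.mutations, germline, bundle.domains)
    domain_enrichment_frame(dom_res).to_csv(
        out / "domain_enrichment.tsv", sep="\t", index=False
    )
    stages.append("domain-enrich")

    # --- per-cohort mutation enrichment -------------------------------------
    driver_tfs = [d for d in bundle.drivers if d.is_tf]
    enr = cohort_mutation_enrichment(bundle.mutations, driver_tfs, bundle.cohort_labels)
    cohort_enrichment_frame(enr).to_csv(
        out / "cohort_enrichment.tsv", sep="\t", index=False
    )
    stages.append("cohort-enrich")

    # --- cross-stratum overlap of significant targets ------------------------
    # cohort labels act as strata: DE is recomputed within each and the
    # TF's significant sets are compared across strata
    strata = sorted(set(bundle.cohort_labels.values()))
    overlap_rows = []
    if len(strata) >= 2:
        for tf in sorted(tf_results):
            sig_by_stratum = {}
            for stratum in strata:
                keep = [s for s in altmat.samples
                        if bundle.cohort_labels.get(s) == stratum]
                sub = AlterationMatrix(
                    stratum, keep, altmat.drivers,
                    [c for c in altmat.calls if c.sample_id in set(keep)],
                )
                res = differential_targets(
                    tf, sub, bundle.expression.subset_samples(keep),
                    bundle.cna.subset_samples(keep),
                    bundle.targets[tf].targets, cfg,
                )
                sig_by_stratum[stratum] = {r.target for r in res if r.significant}
            for row in cross_tumor_overlap(
                tf, sig_by_stratum, set(bundle.targets[tf].targets)
            ):
                overlap_rows.append(row)
    pd.DataFrame(
        [
            (r.tf, r.tumor_a, r.tumor_b, r.jaccard, r.overlap_size, r.p, r.q)
            for r in overlap_rows
        ],
        columns=["tf", "tumor_a", "tumor_b", "jaccard", "overlap_size", "p", "q"],
    ).to_csv(out / "cross_tumor_overlap.tsv", sep="\t", index=False)
    stages.append("overlap")

    # --- circuits -------------------------------------------------------------
    circuits = detect_circuits(
        bundle.tumor_type, tf_results,
        {tf: set(bundle.targets[tf].targets) for tf in tf_results},
        bundle.drivers, bundle.network, altmat, bundle.expression, bundle.cna, cfg,
    )
    circuits_frame(circuits).to_csv(out / "circuits.tsv", sep="\t", index=False)

    circuit_sets = []
    for c in circuits:
        if not c.significant:
            continue
        res_tf = tf_results[c.tf]
        up = {r.target for r in res_tf if r.significant and r.direction == "up"}
        down = {r.target for r in res_tf if r.significant and r.direction == "down"}
        for name, members in ((f"{c.tf}|{c.partner}|up", up),
                              (f"{c.tf}|{c.partner}|down", down)):
            if members:
                circuit_sets.append(
                    TargetAnnotation(name, frozenset(members), frozenset({"circuit"}))
                )
    write_genesets_gmt(circuit_sets, out / "circuit_sets.gmt")
    stages.append("circuits")

    # --- SLEA -----------------------------------------------------------------
    slea_results = []
    for ann in read_genesets_gmt(out / "circuit_sets.gmt") if circuit_sets else []:
        slea_results.extend(
            slea_zscores(bundle.expression, ann.targets, cfg, gene_set_id=ann.tf)
        )
    if slea_results:
        slea_frame(slea_results).to_csv(out / "slea_zscores.tsv", sep="\t",
                                        index_label="sample")
    else:
        pd.DataFrame(columns=["sample"]).to_csv(out / "slea_zscores.tsv", sep="\t",
                                                index=False)
    stages.append("slea")

    # --- manifest -------------------------------------------------------------
    digests = {}
    for path in sorted(Path(input_dir).glob("*")) + sorted(out.glob("*.tsv")) + \
            sorted(out.glob("*.gmt")):
        if path.is_file():
            digests[str(path.resolve())] = _sha256(path)
    manifest = {
        "version": __version__,
        "config": cfg.to_dict(),
        "sim_config": dataclasses.asdict(sim_cfg) if sim_cfg else None,
        "seed": cfg.rng_seed,
        "stages": stages,
        "file_digests": digests,
        "started": t0,
        "finished": time.time(),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def verify_manifest(out_dir: str | Path) -> bool:
    """Recompute the digests stored in a run manifest; True iff all match."""
    out = Path(out_dir)
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    for name, digest in manifest["file_digests"].items():
        path = Path(name)
        if not path.exists() or _sha256(path) != digest:
            return False
    return True


def load_run_config(path: str | Path) -> tuple[Config, SimConfig | None]:
    """A run-all YAML with optional ``analysis:`` and ``simulation:`` blocks."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    cfg = Config(**(raw.get("analysis") or {}))
    sim = SimConfig(**raw["simulation"]) if raw.get("simulation") else None
    return cfg, sim
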