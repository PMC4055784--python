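"""End-to-end orchestration: generate/load → bioactivity → target space →
interactome → phi network → metabolic → chemical space.

Every stage is a pure function of its inputs and the configuration; a run
writes each stage's output as TSV (with the configuration serialized
alongside as JSON for provenance) and returns a report of per-stage record
counts.  Identical configuration and seed give identical reports and files.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from phytonet import bioactivity as bio
from phytonet import chemspace, correlation, interactome, metabolic
from phytonet import io as pio
from phytonet import target_space as ts
from phytonet.synthetic_data import (
    GeneratorConfig,
    SyntheticDataset,
    generate_dataset,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All thresholds of the analysis with their standard defaults.

    pChEMBL > 5.5, inhibition > 20 %, potency < 500 µM, interaction
    probability P ≥ 0.5, Tc ≥ 0.85 with |ΔMW| < 50 g/mol, PPI confidence
    score > 400, Bonferroni-adjusted p ≤ 0.05, pathway highlight above 20
    plants.
    """

    thresholds: bio.Thresholds = field(default_factory=bio.Thresholds)
    tc_threshold: float = 0.85
    mw_window: float = 50.0
    score_threshold: float = 400.0
    alpha: float = 0.05
    pathway_highlight_plants: int = 20
    allowed_organisms: tuple[str, ...] = tuple(sorted(bio.DEFAULT_ORGANISMS))
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    outdir: str | None = None
    rng_seed: int | None = None  # overrides generator.rng_seed when set

    def to_json(self) -> dict[str, Any]:
        return dataclasses.asdict(self)


@dataclass
class RunReport:
    """Per-stage record counts plus the output-file manifest."""

    counts: dict[str, int]
    manifest: dict[str, str]
    config: PipelineConfig

    def to_json(self) -> dict[str, Any]:
        return {"counts": self.counts, "manifest": self.manifest,
                "config": self.config.to_json()}


@dataclass
class PipelineResult:
    """In-memory results of a full run."""

    dataset: SyntheticDataset
    evidence: pd.DataFrame
    space: ts.CandidateTargetSpace
    interactions: pd.DataFrame
    matrix: interactome.PlantProteinMatrix
    efficacy: pd.DataFrame
    projection: pd.DataFrame
    phi_network: correlation.PhiNetwork
    metabolite_matches: pd.DataFrame
    reaction_loads: pd.DataFrame
    plant_reaction_counts: pd.DataFrame
    embedding: pd.DataFrame
    report: RunReport


class StageError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
        return wrapper
    return deco


def run(config: PipelineConfig | None = None,
        dataset: SyntheticDataset | None = None) -> PipelineResult:
    """Execute the full analysis on ``dataset`` (generated from
    ``config.generator`` when absent)."""
    cfg = config or PipelineConfig()
    if dataset is None:
        gen_cfg = cfg.generator
        if cfg.rng_seed is not None:
            gen_cfg = dataclasses.replace(gen_cfg, rng_seed=cfg.rng_seed)
        dataset = _stage("generate")(generate_dataset)(gen_cfg)
    counts: dict[str, int] = {}
    counts["plants"] = dataset.plant_catalog["plant_id"].nunique()
    counts["compounds"] = len(dataset.compounds)
    counts["bioactivity_records"] = len(dataset.bioactivity)

    # bioactivity evidence
    filtered = _stage("bioactivity")(bio.filter_records)(
        dataset.bioactivity, cfg.allowed_organisms)
    evidence = _stage("bioactivity")(bio.aggregate)(filtered,
                                                    cfg.thresholds)
    counts["records_filtered_out"] = len(dataset.bioactivity) - len(filtered)
    counts["evidence_pairs"] = len(evidence)
    counts["interacting_pairs"] = int(evidence["interacting"].sum())

    # candidate target space
    seed_map = {
        cat: set(sub["protein_id"])
        for cat, sub in dataset.seeds.groupby("category")
    }
    expressed = set(dataset.expression.loc[dataset.expression["positive"],
                                           "protein_id"])
    space = _stage("targets")(ts.assemble)(
        seed_map, dataset.ppi, expressed, cfg.allowed_organisms,
        cfg.score_threshold)
    counts["seed_proteins"] = len(space.all_seeds)
    counts["neighbor_proteins"] = len(space.all_neighbors)

    # interaction table
    compounds = bio.compounds_from_table(dataset.compounds)
    references = list(bio.compounds_from_table(
        dataset.reference_compounds).values())
    interactions = _stage("interactions")(bio.build_interaction_table)(
        dataset.plant_catalog, compounds, evidence,
        reference_compounds=references,
        direct_proteins=space.all_proteins,
        similar_proteins=space.all_seeds,
        tc_threshold=cfg.tc_threshold, mw_window=cfg.mw_window)
    counts["interaction_rows"] = len(interactions)

    # interactome
    plant_ids = sorted(dataset.plant_catalog["plant_id"].unique())
    edible = dict(dataset.plant_catalog
                  .drop_duplicates("plant_id")
                  .set_index("plant_id")["edible"])
    matrix = _stage("interactome")(interactome.build_matrix)(
        interactions, proteins=sorted(space.all_proteins),
        plants=plant_ids, edible=edible)
    counts["proteins_targeted"] = len(matrix.targeted_union())
    eff = _stage("interactome")(interactome.efficacy)(matrix)
    projection = interactome.plant_projection(matrix)
    counts["projection_edges"] = len(projection)

    # phi co-targeting network
    net = _stage("phi")(correlation.build_phi_network)(matrix, cfg.alpha)
    counts["phi_pairs_tested"] = net.n_tested
    counts["phi_edges_significant"] = len(net.edges)
    counts["phi_components"] = len(net.components)

    # metabolic perturbation
    met_compounds = bio.compounds_from_table(dataset.metabolites)
    network = _stage("metabolic")(metabolic.MetabolicNetwork.from_table)(
        dataset.reactions, met_compounds)
    matches = metabolic.match_metabolites(
        compounds.values(), met_compounds, cfg.tc_threshold, cfg.mw_window)
    plant_compounds = {
        plant: list(sub["compound_id"])
        for plant, sub in dataset.plant_catalog.groupby("plant_id")
    }
    reaction_loads, plant_counts = metabolic.pathway_load(
        plant_compounds, matches, network, cfg.pathway_highlight_plants)
    counts["metabolite_matches"] = len(matches)
    counts["perturbed_reactions"] = int(
        (reaction_loads["plant_count"] > 0).sum())

    # chemical space
    combined = pd.concat(
        [dataset.compounds, dataset.reference_compounds,
         dataset.metabolites], ignore_index=True)
    embedding = _stage("chemspace")(chemspace.embed_compounds)(combined)
    counts["embedded_molecules"] = len(embedding)

    manifest: dict[str, str] = {}
    if cfg.outdir is not None:
        outdir = Path(cfg.outdir)
        manifest.update(dataset.write(outdir / "inputs"))
        for name, frame in {
            "evidence": evidence,
            "interactions": interactions,
            "efficacy": eff,
            "plant_projection": projection,
            "phi_edges": net.to_frame(),
            "metabolite_matches": matches,
            "reaction_loads": reaction_loads,
            "plant_reaction_counts": plant_counts,
            "chemspace_coordinates": embedding,
            "top_targeted": interactome.top_targeted(matrix),
        }.items():
            manifest[name] = str(pio.write_table(frame,
                                                 outdir / f"{name}.tsv"))
        g = net.graph()
        manifest["phi_network_graphml"] = str(pio.write_graphml(
            ((n, d) for n, d in g.nodes(data=True)),
            ((a, b, d) for a, b, d in g.edges(data=True)),
            outdir / "phi_network.graphml"))
        manifest["config"] = str(pio.write_json(cfg.to_json(),
                                                outdir / "config.json"))
        report_json = {"counts": counts, "manifest": manifest}
        manifest["report"] = str(pio.write_json(report_json,
                                                outdir / "report.json"))
    for name, value in counts.items():
        logger.info("stage count %s = %d", name, value)
    report = RunReport(counts=counts, manifest=manifest, config=cfg)
    return PipelineResult(
        dataset=dataset, evidence=evidence, space=space,
        interactions=interactions, matrix=matrix, efficacy=eff,
        projection=projection, phi_network=net,
        metabolite_matches=matches, reaction_loads=reaction_loads,
        plant_reaction_counts=plant_counts, embedding=embedding,
        report=report)
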