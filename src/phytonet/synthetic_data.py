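"""Synthetic input generator with planted ground truth.

Emulates every input table the pipeline consumes — plant→compound catalog,
compound structures/descriptors, bioactivity records, scored PPI edges,
seed target lists, tissue-expression flags and a metabolic reaction table —
with known planted structure so each downstream stage can be scored against
truth:

* heavy-tailed compound sharing: most phytochemicals are plant specific
  (found in a single plant), a few occur in many plants;
* planted compound→protein interactions whose bioactivity records mostly
  exceed the positivity thresholds (per-record positive mass 0.85), while
  decoy pairs mostly fall below (0.10) — so the P ≥ 0.5 gate recovers
  planted pairs with high recall by construction;
* planted (plant-group, protein-cluster) co-targeting assignments: the
  plants of a group share "hub" compounds that hit every protein of the
  paired cluster, making the clusters recoverable by the phi network;
* a handful of compounds reachable only through the similar-compound route,
  and metabolites that match plant compounds exactly or by similarity.

All randomness flows from one :func:`numpy.random.default_rng` stream
seeded by ``rng_seed``; a fixed seed yields byte-identical output files.

The generated "structures" are random bit-set fingerprints with
molecular-weight/TPSA/SlogP values drawn from ranges typical of natural
products; no chemically valid molecules are implied.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from phytonet import io as pio
from phytonet.bioactivity import Compound
from phytonet.interactome import PlantProteinMatrix
from phytonet.target_space import SEED_CATEGORIES


class ConfigurationError(ValueError):
    """The generator configuration is inconsistent or infeasible."""


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic dataset.

    ``planted_clusters`` lists (plant-group size, protein-cluster size)
    pairs; groups are disjoint plant subsets and clusters are disjoint
    neighbour-protein subsets, co-targeted through shared hub compounds.
    """

    n_plants: int = 40
    edible_fraction: float = 0.25
    n_compounds: int = 400
    #: probability a compound is plant specific (occurs in one plant);
    #: non-specific compounds occur in 1 + Zipf(sharing_zipf_a) plants.
    p_plant_specific: float = 0.57
    sharing_zipf_a: float = 2.2
    n_seed_targets_per_category: tuple[int, int, int] = (8, 10, 9)
    n_neighbor_proteins: int = 60
    #: uniform score range for sub-threshold noise PPI edges; neighbour
    #: edges are drawn above the confidence threshold.
    ppi_score_low: float = 100.0
    ppi_score_high: float = 999.0
    ppi_confidence_threshold: float = 400.0
    expression_positive_rate: float = 0.9
    #: records per (compound, protein) pair: uniform on this inclusive range
    records_per_pair: tuple[int, int] = (3, 5)
    positive_rate_planted: float = 0.85
    positive_rate_decoy: float = 0.10
    planted_clusters: tuple[tuple[int, int], ...] = ((12, 4), (10, 3), (8, 3))
    hub_compounds_per_group: int = 2
    n_background_interactions: int = 250
    n_decoy_pairs: int = 400
    n_similar_route_compounds: int = 5
    n_reactions: int = 80
    n_metabolites: int = 120
    n_exact_metabolite_matches: int = 12
    n_similar_metabolite_matches: int = 4
    fingerprint_bits: int = 1024
    fingerprint_on_bits: int = 48
    rng_seed: int = 0

    def validate(self) -> None:
        counts = {
            "n_plants": self.n_plants,
            "n_compounds": self.n_compounds,
            "n_neighbor_proteins": self.n_neighbor_proteins,
            "n_reactions": self.n_reactions,
            "n_metabolites": self.n_metabolites,
            "fingerprint_bits": self.fingerprint_bits,
            "fingerprint_on_bits": self.fingerprint_on_bits,
        }
        for name, value in counts.items():
            if value <= 0:
                raise ConfigurationError(f"{name} must be > 0, got {value}")
        for name in ("edible_fraction", "expression_positive_rate",
                     "p_plant_specific", "positive_rate_planted",
                     "positive_rate_decoy"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ConfigurationError(
                    f"{name} must be in [0, 1], got {value}")
        if any(n <= 0 for n in self.n_seed_targets_per_category):
            raise ConfigurationError("seed category counts must be > 0")
        lo, hi = self.records_per_pair
        if not 1 <= lo <= hi:
            raise ConfigurationError("records_per_pair must be 1 <= lo <= hi")
        if sum(g for g, _ in self.planted_clusters) > self.n_plants:
            raise ConfigurationError(
                "planted plant groups exceed the number of plants")
        if sum(c for _, c in self.planted_clusters) > self.n_neighbor_proteins:
            raise ConfigurationError(
                "planted protein clusters exceed the neighbour protein pool")
        if any(g <= 0 or c <= 0 for g, c in self.planted_clusters):
            raise ConfigurationError("planted cluster sizes must be > 0")
        if self.sharing_zipf_a <= 1.0:
            raise ConfigurationError("sharing_zipf_a must be > 1")


@dataclass
class SyntheticTruth:
    """What was planted: the true interactions, the protein clusters and
    the plant groups paired with them (index-aligned)."""

    planted_interactions: set[tuple[str, str]]
    planted_clusters: list[set[str]]
    planted_plant_groups: list[set[str]]

    def to_json(self) -> dict:
        return {
            "planted_interactions": sorted(self.planted_interactions),
            "planted_clusters": [sorted(c) for c in self.planted_clusters],
            "planted_plant_groups": [sorted(g)
                                     for g in self.planted_plant_groups],
        }

    @classmethod
    def from_json(cls, obj: dict) -> "SyntheticTruth":
        return cls(
            planted_interactions={tuple(p)
                                  for p in obj["planted_interactions"]},
            planted_clusters=[set(c) for c in obj["planted_clusters"]],
            planted_plant_groups=[set(g)
                                  for g in obj["planted_plant_groups"]],
        )


@dataclass
class SyntheticDataset:
    """All generated tables plus the planted truth."""

    plant_catalog: pd.DataFrame
    compounds: pd.DataFrame
    reference_compounds: pd.DataFrame
    bioactivity: pd.DataFrame
    ppi: pd.DataFrame
    seeds: pd.DataFrame
    expression: pd.DataFrame
    reactions: pd.DataFrame
    metabolites: pd.DataFrame
    truth: SyntheticTruth
    config: GeneratorConfig

    def write(self, outdir: str | Path) -> dict[str, str]:
        outdir = Path(outdir)
        manifest = {}
        for name in ("plant_catalog", "compounds", "reference_compounds",
                     "bioactivity", "ppi", "seeds", "expression",
                     "reactions", "metabolites"):
            path = pio.write_table(getattr(self, name),
                                   outdir / f"{name}.tsv")
            manifest[name] = str(path)
        manifest["truth"] = str(
            pio.write_json(self.truth.to_json(), outdir / "truth.json"))
        return manifest


_ALLOWED_ORGANISMS = ("Homo sapiens", "Rattus norvegicus", "Mus musculus")
_PATHWAYS = (
    "Lipid metabolism", "Fatty acid biosynthesis", "Pyruvate metabolism",
    "TCA cycle", "Glycolysis", "Amino acid metabolism",
    "Nucleotide metabolism", "Bile acid biosynthesis",
)


def _inchikey(rng: np.random.Generator) -> str:
    letters = np.array(list(string.ascii_uppercase))
    block1 = "".join(rng.choice(letters, 14))
    block2 = "".join(rng.choice(letters, 10))
    return f"{block1}-{block2}-N"


def _fingerprint(rng: np.random.Generator, cfg: GeneratorConfig
                 ) -> frozenset[int]:
    return frozenset(
        int(b) for b in rng.choice(cfg.fingerprint_bits,
                                   size=cfg.fingerprint_on_bits,
                                   replace=False))


def _perturb_fingerprint(rng: np.random.Generator, fp: frozenset[int],
                         n_bits: int, n_flip: int = 2) -> frozenset[int]:
    """Swap ``n_flip`` on-bits for fresh ones; keeps Tc well above 0.85
    for the default on-bit count."""
    bits = sorted(fp)
    drop = set(rng.choice(bits, size=min(n_flip, len(bits)),
                          replace=False).tolist())
    keep = [b for b in bits if b not in drop]
    free = [b for b in range(n_bits) if b not in fp]
    add = rng.choice(free, size=len(drop), replace=False).tolist()
    return frozenset(keep + [int(b) for b in add])


def _compound_row(rng: np.random.Generator, cfg: GeneratorConfig,
                  compound_id: str, group: str = "phytochemical") -> dict:
    fp = _fingerprint(rng, cfg)
    return {
        "compound_id": compound_id,
        "inchikey": _inchikey(rng),
        "mw": float(np.round(rng.lognormal(np.log(350.0), 0.35), 2)),
        "tpsa": float(np.round(max(0.0, rng.normal(90.0, 30.0)), 2)),
        "slogp": float(np.round(rng.normal(2.5, 1.5), 2)),
        "fingerprint": pio.encode_fingerprint(fp),
        "group": group,
    }


def _measurement(rng: np.random.Generator, positive: bool
                 ) -> tuple[str, float]:
    kind = rng.choice(["Ki", "IC50", "EC50", "Kd", "inhibition", "potency"],
                      p=[0.3, 0.3, 0.1, 0.1, 0.1, 0.1])
    if kind in ("Ki", "IC50", "EC50", "Kd"):
        value = rng.uniform(5.6, 9.0) if positive else rng.uniform(3.0, 5.4)
    elif kind == "inhibition":
        value = rng.uniform(25.0, 100.0) if positive else rng.uniform(0.0,
                                                                      18.0)
    else:  # potency, micromolar
        value = rng.uniform(1.0, 450.0) if positive else rng.uniform(
            550.0, 10000.0)
    return str(kind), float(np.round(value, 3))


def _records_for_pair(rng: np.random.Generator, cfg: GeneratorConfig,
                      inchikey: str, protein: str, p_positive: float
                      ) -> list[dict]:
    lo, hi = cfg.records_per_pair
    n = int(rng.integers(lo, hi + 1))
    rows = []
    for _ in range(n):
        positive = bool(rng.random() < p_positive)
        kind, value = _measurement(rng, positive)
        rows.append({
            "compound_inchikey": inchikey,
            "protein_id": protein,
            "organism": str(rng.choice(_ALLOWED_ORGANISMS)),
            "type": kind,
            "value": value,
        })
    return rows


def generate_dataset(config: GeneratorConfig | None = None
                     ) -> SyntheticDataset:
    """Generate the full synthetic input bundle (see module docstring).

    Deterministic under ``config.rng_seed``: two calls with equal configs
    produce identical tables.
    """
    cfg = config or GeneratorConfig()
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)

    # --- plants ---------------------------------------------------------
    plant_ids = [f"PL{i:03d}" for i in range(1, cfg.n_plants + 1)]
    n_edible = int(round(cfg.edible_fraction * cfg.n_plants))
    edible_ids = set(rng.choice(plant_ids, size=n_edible, replace=False)
                     .tolist()) if n_edible else set()
    plant_names = {p: f"plant_{p[2:]}" for p in plant_ids}

    # --- protein space --------------------------------------------------
    sizes = cfg.n_seed_targets_per_category
    pool_size = max(max(sizes), int(round(0.85 * sum(sizes))))
    seed_pool = [f"PR{i:04d}" for i in range(1, pool_size + 1)]
    seeds: dict[str, set[str]] = {}
    for cat, size in zip(SEED_CATEGORIES, sizes):
        seeds[cat] = set(rng.choice(seed_pool, size=size,
                                    replace=False).tolist())
    all_seeds = sorted(set().union(*seeds.values()))
    neighbor_ids = [f"NB{i:04d}" for i in range(1, cfg.n_neighbor_proteins
                                                + 1)]
    decoy_protein_ids = [f"XX{i:04d}" for i in range(1, 11)]

    ppi_rows: list[dict] = []
    threshold = cfg.ppi_confidence_threshold
    for nb in neighbor_ids:
        # each neighbour hangs off 1-2 seeds through confident edges
        n_links = int(rng.integers(1, 3))
        for seed in rng.choice(all_seeds, size=n_links, replace=False):
            ppi_rows.append({
                "protein_a": str(seed), "protein_b": nb,
                "score": float(np.round(rng.uniform(threshold + 5,
                                                    cfg.ppi_score_high), 1)),
                "organism": str(rng.choice(_ALLOWED_ORGANISMS)),
            })
    # sub-threshold noise edges: these proteins must NOT become neighbours
    for decoy in decoy_protein_ids[:5]:
        ppi_rows.append({
            "protein_a": str(rng.choice(all_seeds)), "protein_b": decoy,
            "score": float(np.round(rng.uniform(cfg.ppi_score_low,
                                                threshold - 1), 1)),
            "organism": str(rng.choice(_ALLOWED_ORGANISMS)),
        })
    # disallowed-species edges: confident score but removed pre-expansion
    for decoy in decoy_protein_ids[5:]:
        ppi_rows.append({
            "protein_a": str(rng.choice(all_seeds)), "protein_b": decoy,
            "score": float(np.round(rng.uniform(threshold + 5,
                                                cfg.ppi_score_high), 1)),
            "organism": "Saccharomyces cerevisiae",
        })
    # edges among neighbours, to give the PPI graph internal structure
    n_internal = max(1, cfg.n_neighbor_proteins)
    for _ in range(n_internal):
        a, b = rng.choice(neighbor_ids, size=2, replace=False)
        ppi_rows.append({
            "protein_a": str(a), "protein_b": str(b),
            "score": float(np.round(rng.uniform(threshold + 5,
                                                cfg.ppi_score_high), 1)),
            "organism": str(rng.choice(_ALLOWED_ORGANISMS)),
        })
    ppi = pd.DataFrame(ppi_rows)

    all_proteins = sorted(set(all_seeds) | set(neighbor_ids)
                          | set(decoy_protein_ids))
    expressed = {
        p for p in all_proteins
        if rng.random() < cfg.expression_positive_rate
    }

    # --- planted clusters & plant groups -------------------------------
    cluster_pool = list(neighbor_ids)
    plant_pool = list(plant_ids)
    planted_clusters: list[set[str]] = []
    planted_groups: list[set[str]] = []
    for group_size, cluster_size in cfg.planted_clusters:
        cluster = set(rng.choice(cluster_pool, size=cluster_size,
                                 replace=False).tolist())
        cluster_pool = [p for p in cluster_pool if p not in cluster]
        group = set(rng.choice(plant_pool, size=group_size,
                               replace=False).tolist())
        plant_pool = [p for p in plant_pool if p not in group]
        planted_clusters.append(cluster)
        planted_groups.append(group)
        expressed |= cluster  # planted structure survives the filter

    # --- compounds & sharing --------------------------------------------
    compound_rows = [
        _compound_row(rng, cfg, f"CP{i:05d}")
        for i in range(1, cfg.n_compounds + 1)
    ]
    catalog_rows: list[dict] = []
    for row in compound_rows:
        if rng.random() < cfg.p_plant_specific:
            k = 1
        else:
            k = min(1 + int(rng.zipf(cfg.sharing_zipf_a)), cfg.n_plants)
        for plant in rng.choice(plant_ids, size=k, replace=False):
            catalog_rows.append({
                "plant_id": str(plant), "plant_name": plant_names[plant],
                "edible": plant in edible_ids, "compound_id":
                    row["compound_id"],
            })

    # hub compounds: present in exactly the group's plants
    hub_ids_per_group: list[list[str]] = []
    for gi, group in enumerate(planted_groups):
        hubs = []
        for hj in range(cfg.hub_compounds_per_group):
            hub_id = f"CPHUB{gi:02d}{hj:02d}"
            compound_rows.append(_compound_row(rng, cfg, hub_id))
            hubs.append(hub_id)
            for plant in sorted(group):
                catalog_rows.append({
                    "plant_id": plant, "plant_name": plant_names[plant],
                    "edible": plant in edible_ids, "compound_id": hub_id,
                })
        hub_ids_per_group.append(hubs)

    compounds = pd.DataFrame(compound_rows)
    key_of = dict(zip(compounds["compound_id"], compounds["inchikey"]))

    # --- planted interactions -------------------------------------------
    planted: set[tuple[str, str]] = set()
    for hubs, cluster in zip(hub_ids_per_group, planted_clusters):
        for hub in hubs:
            for protein in sorted(cluster):
                planted.add((hub, protein))
    target_space = sorted((set(all_seeds) | set(neighbor_ids)) & expressed)
    cluster_proteins = set().union(*planted_clusters)
    background_eligible = [p for p in target_space
                           if p not in cluster_proteins]
    regular_ids = [r["compound_id"] for r in compound_rows
                   if not r["compound_id"].startswith("CPHUB")]
    # keep a reserve of compounds with no evidence for the similar route
    n_reserved = cfg.n_similar_route_compounds
    evidence_free = set(rng.choice(regular_ids, size=n_reserved,
                                   replace=False).tolist()) \
        if n_reserved else set()
    usable = [c for c in regular_ids if c not in evidence_free]
    while len(planted) - sum(len(h) * len(c) for h, c in
                             zip(hub_ids_per_group, planted_clusters)) \
            < cfg.n_background_interactions:
        pair = (str(rng.choice(usable)),
                str(rng.choice(background_eligible)))
        planted.add(pair)

    # --- bioactivity records --------------------------------------------
    bio_rows: list[dict] = []
    for compound_id, protein in sorted(planted):
        bio_rows += _records_for_pair(rng, cfg, key_of[compound_id],
                                      protein, cfg.positive_rate_planted)
    decoy_pairs: set[tuple[str, str]] = set()
    while len(decoy_pairs) < cfg.n_decoy_pairs:
        pair = (str(rng.choice(usable)), str(rng.choice(target_space)))
        if pair not in planted:
            decoy_pairs.add(pair)
    for compound_id, protein in sorted(decoy_pairs):
        bio_rows += _records_for_pair(rng, cfg, key_of[compound_id],
                                      protein, cfg.positive_rate_decoy)
    # pure-noise records that the organism/type filter must remove
    n_noise = max(1, len(bio_rows) // 20)
    for _ in range(n_noise):
        compound_id = str(rng.choice(regular_ids))
        protein = str(rng.choice(all_proteins))
        kind, value = _measurement(rng, bool(rng.random() < 0.5))
        bio_rows.append({
            "compound_inchikey": key_of[compound_id],
            "protein_id": protein,
            "organism": "Danio rerio" if rng.random() < 0.5
            else str(rng.choice(_ALLOWED_ORGANISMS)),
            "type": kind if rng.random() < 0.5 else "AC50",
            "value": value,
        })

    # --- similar-route reference compounds ------------------------------
    ref_rows: list[dict] = []
    expressed_seeds = sorted(set(all_seeds) & expressed)
    fp_of = {r["compound_id"]: pio.decode_fingerprint(r["fingerprint"])
             for r in compound_rows}
    for ci, compound_id in enumerate(sorted(evidence_free)):
        ref_id = f"RF{ci:04d}"
        base_fp = fp_of[compound_id]
        ref_fp = _perturb_fingerprint(rng, base_fp, cfg.fingerprint_bits)
        base_mw = float(
            compounds.loc[compounds["compound_id"] == compound_id,
                          "mw"].iloc[0])
        ref_rows.append({
            "compound_id": ref_id,
            "inchikey": _inchikey(rng),
            "mw": float(np.round(base_mw + rng.uniform(-30, 30), 2)),
            "tpsa": float(np.round(max(0.0, rng.normal(90.0, 30.0)), 2)),
            "slogp": float(np.round(rng.normal(2.5, 1.5), 2)),
            "fingerprint": pio.encode_fingerprint(ref_fp),
            "group": "drug",
        })
        n_targets = int(rng.integers(1, 3))
        for protein in rng.choice(expressed_seeds, size=n_targets,
                                  replace=False):
            bio_rows += _records_for_pair(rng, cfg, ref_rows[-1]["inchikey"],
                                          str(protein),
                                          cfg.positive_rate_planted)
    reference_compounds = pd.DataFrame(
        ref_rows, columns=list(compounds.columns))
    bioactivity = pd.DataFrame(bio_rows)

    # --- metabolic network ----------------------------------------------
    met_rows = []
    met_ids = [f"MB{i:04d}" for i in range(1, cfg.n_metabolites + 1)]
    for mid in met_ids:
        met_rows.append({**_compound_row(rng, cfg, mid,
                                         group="colon-metabolite")})
    metabolites = pd.DataFrame(met_rows)
    # exact matches: copy key/structure from widely shared compounds first
    share_counts = pd.DataFrame(catalog_rows).groupby(
        "compound_id").size().sort_values(ascending=False)
    donors = [c for c in share_counts.index if not c.startswith("CPHUB")]
    n_exact = min(cfg.n_exact_metabolite_matches, len(met_ids), len(donors))
    exact_slots = rng.choice(len(met_ids), size=n_exact + min(
        cfg.n_similar_metabolite_matches, len(met_ids) - n_exact),
        replace=False).tolist()
    for slot, donor in zip(exact_slots[:n_exact], donors[:n_exact]):
        src = compounds.loc[compounds["compound_id"] == donor].iloc[0]
        for col in ("inchikey", "mw", "tpsa", "slogp", "fingerprint"):
            metabolites.loc[slot, col] = src[col]
    for slot, donor in zip(exact_slots[n_exact:],
                           donors[n_exact:n_exact + len(exact_slots)]):
        src = compounds.loc[compounds["compound_id"] == donor].iloc[0]
        sim_fp = _perturb_fingerprint(
            rng, pio.decode_fingerprint(src["fingerprint"]),
            cfg.fingerprint_bits)
        metabolites.loc[slot, "fingerprint"] = pio.encode_fingerprint(sim_fp)
        metabolites.loc[slot, "mw"] = float(
            np.round(src["mw"] + rng.uniform(-30, 30), 2))

    rxn_rows = []
    for i in range(1, cfg.n_reactions + 1):
        rid = f"RX{i:04d}"
        pathway = str(rng.choice(_PATHWAYS))
        enzyme = f"EZ{int(rng.integers(1, cfg.n_reactions)):04d}"
        k_sub = int(rng.integers(1, 4))
        k_prod = int(rng.integers(1, 4))
        chosen = rng.choice(met_ids, size=k_sub + k_prod, replace=False)
        for mid in chosen[:k_sub]:
            rxn_rows.append({"reaction_id": rid, "metabolite_id": str(mid),
                             "role": "substrate", "enzyme_id": enzyme,
                             "pathway": pathway})
        for mid in chosen[k_sub:]:
            rxn_rows.append({"reaction_id": rid, "metabolite_id": str(mid),
                             "role": "product", "enzyme_id": enzyme,
                             "pathway": pathway})
    reactions = pd.DataFrame(rxn_rows)

    # --- final tables ----------------------------------------------------
    plant_catalog = pd.DataFrame(catalog_rows).sort_values(
        ["plant_id", "compound_id"]).reset_index(drop=True)
    seeds_table = pd.DataFrame(
        [(p, cat) for cat in SEED_CATEGORIES for p in sorted(seeds[cat])],
        columns=["protein_id", "category"])
    expression = pd.DataFrame({
        "protein_id": all_proteins,
        "positive": [p in expressed for p in all_proteins],
    })
    truth = SyntheticTruth(
        planted_interactions=planted,
        planted_clusters=planted_clusters,
        planted_plant_groups=planted_groups,
    )
    return SyntheticDataset(
        plant_catalog=plant_catalog,
        compounds=compounds,
        reference_compounds=reference_compounds,
        bioactivity=bioactivity,
        ppi=ppi,
        seeds=seeds_table,
        expression=expression,
        reactions=reactions,
        metabolites=metabolites,
        truth=truth,
        config=cfg,
    )


def generate_worked_example_matrix(n_targeted_by_plant: int,
                                   n_total_targeted: int
                                   ) -> PlantProteinMatrix:
    """A minimal plant–protein matrix with a prescribed efficacy numerator
    and denominator.

    The focal plant targets exactly ``n_targeted_by_plant`` proteins; a
    single background plant covers the full union, so the union of all
    plants' targets has exactly ``n_total_targeted`` members.
    """
    if n_total_targeted <= 0:
        raise ValueError("n_total_targeted must be > 0")
    if not 0 <= n_targeted_by_plant <= n_total_targeted:
        raise ValueError(
            "need 0 <= n_targeted_by_plant <= n_total_targeted")
    proteins = [f"X{i}" for i in range(1, n_total_targeted + 1)]
    focal = np.zeros(n_total_targeted, dtype=int)
    focal[:n_targeted_by_plant] = 1
    background = np.ones(n_total_targeted, dtype=int)
    incidence = pd.DataFrame([focal, background],
                             index=["focal", "background"],
                             columns=proteins)
    return PlantProteinMatrix(incidence=incidence,
                              compound_counts=incidence.copy(),
                              edible=pd.Series({"focal": True,
                                                "background": False}))


def load_dataset(directory: str | Path) -> SyntheticDataset:
    """Re-load a dataset written by :meth:`SyntheticDataset.write`."""
    directory = Path(directory)
    read = pio.read_table
    return SyntheticDataset(
        plant_catalog=read(directory / "plant_catalog.tsv",
                           pio.PLANT_CATALOG),
        compounds=read(directory / "compounds.tsv", pio.COMPOUND_TABLE),
        reference_compounds=read(directory / "reference_compounds.tsv",
                                 pio.COMPOUND_TABLE),
        bioactivity=read(directory / "bioactivity.tsv",
                         pio.BIOACTIVITY_TABLE),
        ppi=read(directory / "ppi.tsv", pio.PPI_TABLE),
        seeds=read(directory / "seeds.tsv", pio.SEED_TABLE),
        expression=read(directory / "expression.tsv", pio.EXPRESSION_TABLE),
        reactions=read(directory / "reactions.tsv", pio.REACTION_TABLE),
        metabolites=read(directory / "metabolites.tsv", pio.COMPOUND_TABLE),
        truth=SyntheticTruth.from_json(
            pio.read_json(directory / "truth.json")),
        config=GeneratorConfig(),
    )
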