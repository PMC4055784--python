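"""Metabolic-reaction perturbation by plant phytochemicals.

Plant compounds are matched to metabolites of a tissue metabolic network by
exact InChIKey identity or by structural similarity (the same Tc ≥ 0.85,
|ΔMW| < 50 g/mol rule used for bioactivity matching).  A matched metabolite
perturbs a reaction only when it appears on the substrate side; product-only
occurrences never count.  Per-reaction distinct-plant counts aggregate into
pathway loads, highlighting reactions perturbed by strictly more than 20
plants.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from phytonet.bioactivity import Compound, match_compound

DEFAULT_HIGHLIGHT_PLANTS = 20

#: common currency metabolites; filtering is available but OFF by default —
#: the perturbation rule is stated purely in terms of substrates.
CURRENCY_METABOLITES = frozenset(
    {"H2O", "ATP", "ADP", "AMP", "NAD+", "NADH", "NADP+", "NADPH", "CO2",
     "Pi", "PPi", "H+", "CoA", "O2"}
)


@dataclass
class Reaction:
    reaction_id: str
    substrates: set[str]
    products: set[str]
    enzymes: set[str] = field(default_factory=set)
    pathway: str = ""
    reversible: bool = False  # pass-through flag; not resolved here


@dataclass
class MetabolicNetwork:
    """Reactions with substrate/product roles plus metabolite structures
    (where available) for matching."""

    reactions: dict[str, Reaction]
    metabolites: dict[str, Compound] = field(default_factory=dict)

    @classmethod
    def from_table(
        cls,
        reaction_table: pd.DataFrame,
        metabolites: Mapping[str, Compound] | None = None,
    ) -> "MetabolicNetwork":
        """Build from the flat one-row-per-reaction–metabolite–role table
        (columns reaction_id, metabolite_id, role, enzyme_id, pathway)."""
        reactions: dict[str, Reaction] = {}
        for row in reaction_table.itertuples(index=False):
            rxn = reactions.setdefault(
                row.reaction_id,
                Reaction(row.reaction_id, set(), set(), set(), row.pathway))
            role = str(row.role).lower()
            if role == "substrate":
                rxn.substrates.add(row.metabolite_id)
            elif role == "product":
                rxn.products.add(row.metabolite_id)
            else:
                raise ValueError(
                    f"reaction {row.reaction_id}: unknown role {row.role!r}")
            if str(row.enzyme_id):
                rxn.enzymes.add(row.enzyme_id)
            if not str(row.pathway):
                raise ValueError(
                    f"reaction {row.reaction_id}: empty pathway label")
        for rxn in reactions.values():
            if not rxn.substrates:
                raise ValueError(
                    f"reaction {rxn.reaction_id} has no substrates")
        return cls(reactions=reactions,
                   metabolites=dict(metabolites or {}))


def match_metabolites(
    compounds: Iterable[Compound],
    metabolites: Mapping[str, Compound],
    tc_threshold: float = 0.85,
    mw_window: float = 50.0,
) -> pd.DataFrame:
    """Map each compound to the metabolites it matches.

    Returns rows (compound_id, metabolite_id, route) with route ``exact``
    (full InChIKey identity) or ``similar`` (Tc/ΔMW rule).  Compounds
    without structural data and without a key match are simply absent.
    """
    refs = list(metabolites.values())
    met_by_obj = {id(m): mid for mid, m in metabolites.items()}
    rows = []
    for comp in compounds:
        exact, similar = match_compound(comp, refs, tc_threshold, mw_window)
        for hit in exact:
            rows.append((comp.compound_id, met_by_obj[id(hit)], "exact"))
        matched_keys = {h.inchikey for h in exact}
        for sim in similar:
            for mid, met in metabolites.items():
                if met.inchikey == sim.hit_key and \
                        met.inchikey not in matched_keys:
                    rows.append((comp.compound_id, mid, "similar"))
    return pd.DataFrame(
        rows, columns=["compound_id", "metabolite_id", "route"]
    ).drop_duplicates().reset_index(drop=True)


def perturbed_reactions(
    plant_compound_ids: Iterable[str],
    matches: pd.DataFrame,
    network: MetabolicNetwork,
    filter_currency: bool = False,
) -> set[str]:
    """Reactions perturbed by a plant: any matched metabolite of any of the
    plant's compounds occurs as a substrate.  Product-only occurrences are
    excluded by construction."""
    comp_ids = set(plant_compound_ids)
    mets = set(matches.loc[matches["compound_id"].isin(comp_ids),
                           "metabolite_id"])
    if filter_currency:
        mets -= CURRENCY_METABOLITES
    return {
        rid for rid, rxn in network.reactions.items()
        if rxn.substrates & mets
    }


def pathway_load(
    plant_compounds: Mapping[str, Iterable[str]],
    matches: pd.DataFrame,
    network: MetabolicNetwork,
    highlight_plants: int = DEFAULT_HIGHLIGHT_PLANTS,
    filter_currency: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-reaction plant counts into pathway loads.

    Returns ``(reaction_table, plant_table)``:

    * reaction_table — reaction_id, pathway, plant_count, highlighted
      (strictly more than ``highlight_plants`` distinct plants);
    * plant_table — plant_id, n_perturbed_reactions.
    """
    per_plant = {
        plant: perturbed_reactions(comps, matches, network, filter_currency)
        for plant, comps in plant_compounds.items()
    }
    counts: dict[str, int] = {rid: 0 for rid in network.reactions}
    for rxns in per_plant.values():
        for rid in rxns:
            counts[rid] += 1
    reaction_table = pd.DataFrame({
        "reaction_id": list(counts),
        "pathway": [network.reactions[r].pathway for r in counts],
        "plant_count": list(counts.values()),
    })
    reaction_table["highlighted"] = \
        reaction_table["plant_count"] > highlight_plants
    reaction_table = reaction_table.sort_values(
        ["plant_count", "reaction_id"], ascending=[False, True],
        kind="stable").reset_index(drop=True)
    plant_table = pd.DataFrame({
        "plant_id": list(per_plant),
        "n_perturbed_reactions": [len(v) for v in per_plant.values()],
    }).sort_values("plant_id").reset_index(drop=True)
    return reaction_table, plant_table


def pathway_summary(reaction_table: pd.DataFrame) -> pd.DataFrame:
    """Per-pathway summary: reaction count, summed and maximum per-reaction
    plant counts, and whether any reaction is highlighted."""
    return (reaction_table.groupby("pathway")
            .agg(n_reactions=("reaction_id", "size"),
                 total_plant_count=("plant_count", "sum"),
                 max_plant_count=("plant_count", "max"),
                 any_highlighted=("highlighted", "any"))
            .reset_index())
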