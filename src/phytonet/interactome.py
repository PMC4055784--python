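"""Plant → protein incidence networks, efficacy scores and projections.

The central object is the binary plant × protein incidence matrix (1 = at
least one of the plant's phytochemicals interacts with the protein),
accompanied by the integer matrix of unique-compound counts per cell.  From
it derive:

* efficacy E(P) = |targets(P)| / |union of all plants' targets| — the
  fraction of the jointly targeted candidate protein space hit by plant P;
* weighted efficacy E_w(P): the plant's total compound-target count scaled
  to [0, 1] by the maximum over plants, preserving relative differences;
* the plant–plant projection weighted by shared targets, whose mean edge
  weight is the connectivity ratio;
* most-targeted protein rankings.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations
from typing import Mapping

import numpy as np
import pandas as pd


def round_half_up(x: float, ndigits: int = 2) -> float:
    """Decimal round-half-up (report rounding; 0.675 -> 0.68)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class PlantProteinMatrix:
    """Binary incidence plus unique-compound counts, plant × protein.

    ``incidence`` and ``compound_counts`` share index (plants) and columns
    (proteins); incidence(p, t) == 1 exactly when compound_counts(p, t) >= 1.
    """

    incidence: pd.DataFrame
    compound_counts: pd.DataFrame
    edible: pd.Series | None = None
    protein_categories: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.incidence.index.equals(self.compound_counts.index) or \
                not self.incidence.columns.equals(self.compound_counts.columns):
            raise ValueError("incidence and compound_counts must be aligned")
        mism = (self.incidence.to_numpy() != 0) != \
            (self.compound_counts.to_numpy() >= 1)
        if mism.any():
            raise ValueError(
                "incidence must be 1 exactly where compound_counts >= 1")

    @property
    def plants(self) -> list[str]:
        return list(self.incidence.index)

    @property
    def proteins(self) -> list[str]:
        return list(self.incidence.columns)

    def targets(self, plant: str) -> set[str]:
        row = self.incidence.loc[plant]
        return set(row.index[row.to_numpy() != 0])

    def targeted_union(self) -> set[str]:
        any_hit = self.incidence.to_numpy().any(axis=0)
        return set(np.asarray(self.incidence.columns)[any_hit])

    def subset_plants(self, plants: list[str]) -> "PlantProteinMatrix":
        return PlantProteinMatrix(
            incidence=self.incidence.loc[plants],
            compound_counts=self.compound_counts.loc[plants],
            edible=None if self.edible is None else self.edible.loc[plants],
            protein_categories=dict(self.protein_categories),
        )


def build_matrix(
    interaction_table: pd.DataFrame,
    proteins: list[str] | None = None,
    plants: list[str] | None = None,
    edible: Mapping[str, bool] | None = None,
    keep_untargeted: bool = True,
) -> PlantProteinMatrix:
    """Populate the incidence/count matrices from the interaction table.

    ``compound_counts`` counts unique phytochemicals per (plant, protein)
    cell.  Proteins (or plants) absent from the table appear as zero
    columns (rows) when listed explicitly and ``keep_untargeted`` is true.
    """
    tbl = interaction_table[["plant_id", "compound_id", "protein_id"]] \
        .drop_duplicates()
    counts = tbl.groupby(["plant_id", "protein_id"]).size().unstack(
        fill_value=0)
    row_index = list(plants) if plants is not None else sorted(counts.index)
    col_index = (list(proteins) if proteins is not None and keep_untargeted
                 else sorted(counts.columns))
    counts = counts.reindex(index=row_index, columns=col_index,
                            fill_value=0).astype(int)
    incidence = (counts >= 1).astype(int)
    edible_series = None
    if edible is not None:
        edible_series = pd.Series({p: bool(edible.get(p, False))
                                   for p in row_index}, name="edible")
    return PlantProteinMatrix(incidence=incidence, compound_counts=counts,
                              edible=edible_series)


def efficacy(m: PlantProteinMatrix) -> pd.DataFrame:
    """Per-plant efficacy table.

    ``efficacy`` is targeted_count over the size of the union of targeted
    proteins (the denominator is the jointly targeted space, not the full
    candidate space); ``weighted_raw`` sums compound counts over targets and
    ``weighted_scaled`` divides by the maximum over plants.  Values are kept
    at full precision — rounding is for reports only
    (:func:`round_half_up`).
    """
    union = m.targeted_union()
    if not union:
        raise ValueError("no plant targets any protein")
    inc = m.incidence.to_numpy()
    targeted = inc.sum(axis=1)
    weighted_raw = m.compound_counts.to_numpy().sum(axis=1)
    max_raw = weighted_raw.max()
    table = pd.DataFrame({
        "plant_id": m.plants,
        "targeted_count": targeted.astype(int),
        "efficacy": targeted / len(union),
        "weighted_raw": weighted_raw.astype(int),
        "weighted_scaled": (weighted_raw / max_raw if max_raw > 0
                            else np.zeros_like(weighted_raw, dtype=float)),
    })
    if m.edible is not None:
        table.insert(1, "edible", m.edible.to_numpy())
    return table.sort_values("efficacy", ascending=False,
                             kind="stable").reset_index(drop=True)


def plant_projection(m: PlantProteinMatrix) -> pd.DataFrame:
    """Plant–plant projection: weight(P, Q) = number of shared targets.

    Zero-weight pairs and self-edges are omitted.
    """
    inc = m.incidence.to_numpy()
    shared = inc @ inc.T
    rows = []
    plants = m.plants
    for i, j in combinations(range(len(plants)), 2):
        w = int(shared[i, j])
        if w > 0:
            rows.append((plants[i], plants[j], w))
    return pd.DataFrame(rows, columns=["plant_a", "plant_b", "weight"])


def connectivity_ratio(edges: pd.DataFrame) -> float:
    """Mean edge weight of the plant–plant projection — the sum of all edge
    weights divided by the number of edges."""
    if len(edges) == 0:
        raise ValueError("connectivity ratio of an empty edge set")
    return float(edges["weight"].mean())


def top_targeted(m: PlantProteinMatrix, edible_only: bool = False,
                 k: int | None = None) -> pd.DataFrame:
    """Proteins ranked by how many plants target them.

    ``fraction`` is plant count over the number of plants in scope (edible
    plants only when ``edible_only``).  Ties break lexicographically on
    protein id for determinism.  ``k`` beyond the protein count returns the
    full list.
    """
    mm = m
    if edible_only:
        if m.edible is None:
            raise ValueError("matrix has no edible annotation")
        mm = m.subset_plants([p for p in m.plants if m.edible[p]])
    n_plants = len(mm.plants)
    counts = mm.incidence.sum(axis=0)
    table = pd.DataFrame({
        "protein_id": counts.index,
        "plant_count": counts.to_numpy().astype(int),
    })
    table["fraction"] = (table["plant_count"] / n_plants if n_plants
                         else 0.0)
    table = table.sort_values(["plant_count", "protein_id"],
                              ascending=[False, True],
                              kind="stable").reset_index(drop=True)
    if k is not None:
        table = table.head(k).reset_index(drop=True)
    return table
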