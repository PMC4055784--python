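"""Assembly of the candidate disease protein space.

Three seed categories — approved-drug targets, disease-pathway members and a
prognostic gene signature — are expanded by first-degree neighbours in a
scored protein–protein interaction (PPI) graph at medium confidence
(score strictly > 400), then filtered to proteins with positive evidence of
expression in the target tissue.  PPI evidence from disallowed species is
removed before expansion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations
from typing import Collection, Iterable, Mapping

import pandas as pd

logger = logging.getLogger(__name__)

SEED_CATEGORIES = ("drug_target", "kegg_pathway", "prognostic_signature")

DEFAULT_SCORE_THRESHOLD = 400.0


@dataclass
class CandidateTargetSpace:
    """Seeds per category, their first-degree-neighbour expansions, the
    retained PPI edges and the expression-positive protein set.

    A protein may be a seed in one category and a neighbour in another;
    de-duplication happens only in the union totals.
    """

    seeds: dict[str, set[str]]
    neighbors: dict[str, set[str]] = field(default_factory=dict)
    ppi_edges: set[tuple[str, str, float]] = field(default_factory=set)
    expression_positive: set[str] = field(default_factory=set)

    @property
    def all_seeds(self) -> set[str]:
        return set().union(*self.seeds.values()) if self.seeds else set()

    @property
    def all_neighbors(self) -> set[str]:
        return (set().union(*self.neighbors.values())
                if self.neighbors else set())

    @property
    def all_proteins(self) -> set[str]:
        return self.all_seeds | self.all_neighbors


def dedupe_edges(ppi: pd.DataFrame,
                 allowed_organisms: Collection[str] | None = None
                 ) -> dict[frozenset[str], float]:
    """Canonicalize a scored edge table into undirected unique edges.

    (A, B) and (B, A) rows collapse keeping the maximum score.  When
    ``allowed_organisms`` is given, edges from other species are removed
    first; edges lacking an organism annotation are kept with a warning.
    """
    df = ppi
    if allowed_organisms is not None and "organism" in df.columns:
        blank = df["organism"].isna() | (df["organism"].astype(str).str.strip()
                                         == "")
        if blank.any():
            logger.warning(
                "%d PPI edge(s) lack an organism annotation; kept",
                int(blank.sum()))
        df = df[blank | df["organism"].isin(set(allowed_organisms))]
    edges: dict[frozenset[str], float] = {}
    for a, b, score in zip(df["protein_a"], df["protein_b"], df["score"]):
        if a == b:
            continue
        key = frozenset((a, b))
        score = float(score)
        if key not in edges or score > edges[key]:
            edges[key] = score
    return edges


def expand_neighbors(
    seeds: Collection[str],
    ppi: pd.DataFrame | Mapping[frozenset[str], float],
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> set[str]:
    """First-degree neighbours of ``seeds`` through edges with score
    strictly above ``score_threshold``; the seeds themselves are excluded.

    The graph is undirected: edge direction and row order are irrelevant.
    """
    edges = ppi if isinstance(ppi, Mapping) else dedupe_edges(ppi)
    seeds = set(seeds)
    out: set[str] = set()
    for key, score in edges.items():
        if score <= score_threshold:
            continue
        pair = tuple(key)
        if len(pair) != 2:
            continue
        a, b = pair
        if a in seeds and b not in seeds:
            out.add(b)
        elif b in seeds and a not in seeds:
            out.add(a)
    return out


def assemble(
    seeds: Mapping[str, Collection[str]],
    ppi: pd.DataFrame,
    expression_positive: Collection[str],
    allowed_organisms: Collection[str] | None = None,
    score_threshold: float = DEFAULT_SCORE_THRESHOLD,
) -> CandidateTargetSpace:
    """Build the full candidate space: species-filter the PPI evidence,
    expand each seed category, then apply the expression filter to seeds
    and neighbours alike."""
    edges = dedupe_edges(ppi, allowed_organisms)
    space = CandidateTargetSpace(
        seeds={c: set(s) for c, s in seeds.items()},
        neighbors={
            c: expand_neighbors(s, edges, score_threshold)
            for c, s in seeds.items()
        },
        ppi_edges={(min(k), max(k), v) for k, v in edges.items()
                   if v > score_threshold},
        expression_positive=set(expression_positive),
    )
    return apply_filters(space, expression_positive)


def apply_filters(space: CandidateTargetSpace,
                  expression_positive: Collection[str]
                  ) -> CandidateTargetSpace:
    """Drop proteins without positive tissue expression from every seed and
    neighbour set (the species filter acts earlier, on edges)."""
    keep = set(expression_positive)
    return CandidateTargetSpace(
        seeds={c: s & keep for c, s in space.seeds.items()},
        neighbors={c: s & keep for c, s in space.neighbors.items()},
        ppi_edges=set(space.ppi_edges),
        expression_positive=keep,
    )


def category_overlap(space: CandidateTargetSpace) -> dict[str, int]:
    """Venn-region counts of the seed categories plus unique totals.

    Region keys join category names with ``&`` (exclusive regions, i.e. the
    classical Venn cells); ``unique_seeds`` and ``unique_neighbors`` are the
    de-duplicated totals.
    """
    cats = sorted(space.seeds)
    counts: dict[str, int] = {}
    universe = space.all_seeds
    for r in range(1, len(cats) + 1):
        for combo in combinations(cats, r):
            inside = set(universe)
            for c in combo:
                inside &= space.seeds[c]
            for c in cats:
                if c not in combo:
                    inside -= space.seeds[c]
            counts["&".join(combo)] = len(inside)
    counts["unique_seeds"] = len(universe)
    counts["unique_neighbors"] = len(space.all_neighbors)
    return counts


def space_to_tables(space: CandidateTargetSpace
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten the space to (membership table, edge table) for writing."""
    rows = []
    for cat, ids in sorted(space.seeds.items()):
        rows += [(p, cat, "seed") for p in sorted(ids)]
    for cat, ids in sorted(space.neighbors.items()):
        rows += [(p, cat, "neighbor") for p in sorted(ids)]
    membership = pd.DataFrame(rows,
                              columns=["protein_id", "category", "role"])
    edges = pd.DataFrame(sorted(space.ppi_edges),
                         columns=["protein_a", "protein_b", "score"])
    return membership, edges
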