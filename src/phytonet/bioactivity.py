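"""High-confidence compound → protein interactions from raw bioactivity
records.

Records of six pharmacological measurement kinds (Ki, IC50, EC50, Kd,
potency, inhibition) are filtered by organism, called positive or negative
per measurement-kind threshold, and aggregated per (compound, protein) pair
into an interaction probability P — the empirical positive fraction.  A pair
interacts when the positive evidence outweighs the negative, i.e. P >= 0.5.

Compound matching follows the two routes of the source workflow:
exact (full 27-character InChIKey identity) and similar (Morgan-fingerprint
Tanimoto coefficient Tc >= 0.85 together with a molecular-weight difference
strictly below 50 g/mol).  The similar route transfers interactions only to
the seed target set; the direct route reaches seeds and their first-degree
neighbours.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Collection, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: measurement kinds retained by the evidence filter
PCHEMBL_TYPES = frozenset({"Ki", "IC50", "EC50", "Kd"})
MEASUREMENT_TYPES = PCHEMBL_TYPES | {"potency", "inhibition"}

#: species whose assay evidence is accepted
DEFAULT_ORGANISMS = frozenset(
    {"Homo sapiens", "Rattus norvegicus", "Mus musculus"}
)


@dataclass(frozen=True)
class Thresholds:
    """Positivity thresholds per measurement kind.

    ``pchembl`` applies to Ki/IC50/EC50/Kd on the -log10(molar) scale
    (strictly greater); ``inhibition_pct`` to percent inhibition (strictly
    greater); ``potency_um`` to micromolar potency (strictly lower).
    ``probability`` is the inclusive P cut for calling a pair interacting.
    """

    pchembl: float = 5.5
    inhibition_pct: float = 20.0
    potency_um: float = 500.0
    probability: float = 0.5


DEFAULT_THRESHOLDS = Thresholds()


@dataclass(frozen=True)
class Compound:
    """A small molecule: the unit of matching.

    ``fingerprint`` is the set of on-bit positions of a circular
    (Morgan-style, radius 2) fingerprint of ``n_bits`` bits; precomputed bit
    sets can be injected directly, so the core pipeline never requires a
    chemistry toolkit.
    """

    compound_id: str
    inchikey: str
    mw: float
    fingerprint: frozenset[int] = field(default_factory=frozenset)
    tpsa: float = math.nan
    slogp: float = math.nan
    smiles: str | None = None
    n_bits: int = 1024


@dataclass(frozen=True)
class SimilarityResult:
    """A similar-compound hit: Tc and absolute MW difference for the pair."""

    query_key: str
    hit_key: str
    tanimoto: float
    delta_mw: float


def filter_records(
    records: pd.DataFrame,
    allowed_organisms: Collection[str] = DEFAULT_ORGANISMS,
) -> pd.DataFrame:
    """Keep records with a recognized measurement type and allowed organism.

    Row order is preserved.  Unknown measurement types are dropped with a
    logged count rather than an error.  Negative potency values are dropped;
    inhibition percentages outside [0, 100] are clamped with a warning.
    """
    allowed = set(allowed_organisms)
    known = records["type"].isin(MEASUREMENT_TYPES)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.info("dropped %d record(s) with unknown measurement type",
                    n_unknown)
    out = records[known & records["organism"].isin(allowed)].copy()

    bad_potency = (out["type"] == "potency") & (out["value"] < 0)
    if bad_potency.any():
        logger.warning("dropped %d record(s) with negative potency",
                       int(bad_potency.sum()))
        out = out[~bad_potency]
    inhib = out["type"] == "inhibition"
    outside = inhib & ((out["value"] < 0) | (out["value"] > 100))
    if outside.any():
        logger.warning("clamped %d inhibition value(s) into [0, 100]",
                       int(outside.sum()))
        out.loc[outside, "value"] = out.loc[outside, "value"].clip(0.0, 100.0)
    return out


def is_positive(measurement_type: str, value: float,
                thresholds: Thresholds = DEFAULT_THRESHOLDS) -> bool:
    """Call a single measurement positive per its kind's threshold.

    All three rules are strict inequalities, so a value sitting exactly on a
    threshold is negative.
    """
    if measurement_type in PCHEMBL_TYPES:
        return value > thresholds.pchembl
    if measurement_type == "inhibition":
        return value > thresholds.inhibition_pct
    if measurement_type == "potency":
        return value < thresholds.potency_um
    raise ValueError(f"unknown measurement type {measurement_type!r}")


def positive_mask(records: pd.DataFrame,
                  thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.Series:
    """Vectorized :func:`is_positive` over a filtered record table."""
    t = records["type"]
    v = records["value"]
    return (
        (t.isin(PCHEMBL_TYPES) & (v > thresholds.pchembl))
        | ((t == "inhibition") & (v > thresholds.inhibition_pct))
        | ((t == "potency") & (v < thresholds.potency_um))
    )


def aggregate(records: pd.DataFrame,
              thresholds: Thresholds = DEFAULT_THRESHOLDS) -> pd.DataFrame:
    """Aggregate filtered records into per-(compound, protein) evidence.

    Returns one row per pair with ``n_positive``, ``n_total``,
    ``probability`` = n_positive / n_total, and ``interacting`` =
    (probability >= 0.5).  The result is independent of record order within
    a group.
    """
    if records.empty:
        raise ValueError("cannot aggregate an empty record set")
    work = records.assign(_pos=positive_mask(records, thresholds))
    grouped = work.groupby(["compound_inchikey", "protein_id"], sort=True)
    summary = grouped["_pos"].agg(n_positive="sum", n_total="size")
    summary = summary.reset_index()
    summary["n_positive"] = summary["n_positive"].astype(int)
    summary["probability"] = summary["n_positive"] / summary["n_total"]
    summary["interacting"] = summary["probability"] >= thresholds.probability
    return summary


def tanimoto(a, b) -> float:
    """Tanimoto coefficient |a ∩ b| / |a ∪ b| of two fingerprints.

    Accepts either bit-position sets or equal-length 0/1 arrays.  Two empty
    fingerprints score 0 by convention: absence of features is no evidence
    of similarity.
    """
    if isinstance(a, (set, frozenset)) and isinstance(b, (set, frozenset)):
        union = len(a | b)
        if union == 0:
            return 0.0
        return len(a & b) / union
    av = np.asarray(a).astype(bool)
    bv = np.asarray(b).astype(bool)
    if av.shape != bv.shape:
        raise ValueError(
            f"fingerprint length mismatch: {av.shape} vs {bv.shape}")
    union = int(np.count_nonzero(av | bv))
    if union == 0:
        return 0.0
    return int(np.count_nonzero(av & bv)) / union


def match_compound(
    query: Compound,
    reference_compounds: Iterable[Compound],
    tc_threshold: float = 0.85,
    mw_window: float = 50.0,
) -> tuple[list[Compound], list[SimilarityResult]]:
    """Exact and similar hits of ``query`` among ``reference_compounds``.

    Exact hits share the full InChIKey.  Similar hits satisfy
    Tc >= ``tc_threshold`` (inclusive) and |ΔMW| < ``mw_window`` (strict) and
    exclude the exact hits.
    """
    exact: list[Compound] = []
    similar: list[SimilarityResult] = []
    for ref in reference_compounds:
        if ref.inchikey == query.inchikey:
            exact.append(ref)
            continue
        if not query.fingerprint and not ref.fingerprint:
            # convention: featureless molecules never match by similarity
            continue
        if query.fingerprint is None:
            raise ValueError(
                f"query {query.compound_id} has no fingerprint but a "
                "similarity search was requested")
        tc = tanimoto(query.fingerprint, ref.fingerprint)
        delta = abs(query.mw - ref.mw)
        if tc >= tc_threshold and delta < mw_window:
            similar.append(SimilarityResult(query.inchikey, ref.inchikey,
                                            tc, delta))
    return exact, similar


def compounds_from_table(df: pd.DataFrame, n_bits: int = 1024
                         ) -> dict[str, Compound]:
    """Build :class:`Compound` objects from a compound TSV table
    (``fingerprint`` column holds comma-joined on-bit positions)."""
    from phytonet.io import decode_fingerprint

    out: dict[str, Compound] = {}
    for row in df.itertuples(index=False):
        out[row.compound_id] = Compound(
            compound_id=row.compound_id,
            inchikey=row.inchikey,
            mw=float(row.mw),
            fingerprint=decode_fingerprint(str(row.fingerprint)),
            tpsa=float(getattr(row, "tpsa", math.nan)),
            slogp=float(getattr(row, "slogp", math.nan)),
            smiles=getattr(row, "smiles", None),
            n_bits=n_bits,
        )
    return out


def build_interaction_table(
    plant_catalog: pd.DataFrame,
    compounds: Mapping[str, Compound],
    evidence: pd.DataFrame,
    reference_compounds: Sequence[Compound] | None = None,
    direct_proteins: Collection[str] | None = None,
    similar_proteins: Collection[str] | None = None,
    tc_threshold: float = 0.85,
    mw_window: float = 50.0,
) -> pd.DataFrame:
    """Assemble the plant → compound → protein interaction table.

    Two interaction routes are supported:

    * ``direct`` — the plant's compound itself carries interacting evidence
      (exact InChIKey match into the evidence table); eligible targets are
      ``direct_proteins`` (seeds and their first-degree neighbours).
    * ``similar`` — the compound has no evidence of its own but is
      structurally similar (Tc/ΔMW rule) to a reference compound that does;
      transferred interactions are restricted to ``similar_proteins``
      (the seed set only).

    Only interacting evidence summaries contribute.  Returns a DataFrame
    with columns plant_id, compound_id, protein_id, route, probability.
    """
    interacting = evidence[evidence["interacting"]]
    by_key: dict[str, list[tuple[str, float]]] = {}
    for row in interacting.itertuples(index=False):
        by_key.setdefault(row.compound_inchikey, []).append(
            (row.protein_id, float(row.probability)))
    evidence_keys = set(evidence["compound_inchikey"])

    direct_ok = (lambda p: True) if direct_proteins is None else \
        set(direct_proteins).__contains__
    similar_ok = (lambda p: True) if similar_proteins is None else \
        set(similar_proteins).__contains__

    # similarity hits are per compound, independent of plant: cache them
    similar_cache: dict[str, list[tuple[str, float]]] = {}

    def similar_links(compound: Compound) -> list[tuple[str, float]]:
        if compound.compound_id in similar_cache:
            return similar_cache[compound.compound_id]
        links: dict[str, float] = {}
        if reference_compounds is not None and compound.fingerprint:
            _, sims = match_compound(compound, reference_compounds,
                                     tc_threshold, mw_window)
            for hit in sims:
                for protein, prob in by_key.get(hit.hit_key, []):
                    if similar_ok(protein):
                        links[protein] = max(links.get(protein, 0.0), prob)
        result = sorted(links.items())
        similar_cache[compound.compound_id] = result
        return result

    rows: list[tuple[str, str, str, str, float]] = []
    pairs = plant_catalog[["plant_id", "compound_id"]].drop_duplicates()
    for plant_id, compound_id in pairs.itertuples(index=False):
        compound = compounds.get(compound_id)
        if compound is None:
            continue
        if compound.inchikey in evidence_keys:
            for protein, prob in by_key.get(compound.inchikey, []):
                if direct_ok(protein):
                    rows.append((plant_id, compound_id, protein,
                                 "direct", prob))
        else:
            for protein, prob in similar_links(compound):
                rows.append((plant_id, compound_id, protein,
                             "similar", prob))
    table = pd.DataFrame(
        rows, columns=["plant_id", "compound_id", "protein_id", "route",
                       "probability"],
    )
    return table.sort_values(
        ["plant_id", "compound_id", "protein_id"]).reset_index(drop=True)
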