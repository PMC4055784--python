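# Methods

This note documents the models, rules and numerical choices behind
`phytonet`, and what the synthetic benchmark does and does not show about
real data.

## Evidence model

A bioactivity record is one experimental measurement of a compound against
a protein. Six measurement kinds are accepted; everything else is dropped
with a logged count. Records from species other than *Homo sapiens*,
*Rattus norvegicus* and *Mus musculus* are removed (the set is
configurable). Positivity is a strict per-kind threshold:

| kind               | scale               | positive when | default |
|--------------------|---------------------|---------------|---------|
| Ki, IC50, EC50, Kd | pChEMBL = −log10(M) | value > t     | 5.5     |
| inhibition         | percent             | value > t     | 20      |
| potency            | micromolar          | value < t     | 500     |

A value sitting exactly on a threshold is negative. Inhibition values
outside [0, 100] are clamped with a warning; negative potencies are
dropped. Per (compound, protein) pair the interaction probability is the
empirical positive fraction *P* = n_positive / n_total, and the pair is
called interacting when *P* ≥ 0.5 (boundary inclusive: one positive and
one negative measurement count as interacting). The positive-fraction form
is the natural frequency-based estimator for this verdict; no prior or
shrinkage is applied, so pairs with a single record are decided by that
record alone — a known limitation with sparse evidence.

## Compound matching

Exact identity uses the full 27-character InChIKey, not the connectivity
block, so stereoisomers and salts standardized to different keys never
merge. Similarity uses a Morgan-style circular fingerprint (radius 2,
1024 bits; any precomputed bit set can be injected, keeping the core free
of a chemistry toolkit) compared by the Tanimoto coefficient:
two compounds are similar when Tc ≥ 0.85 (inclusive) **and** |ΔMW| <
50 g/mol (strict). Tanimoto of two empty fingerprints is defined as 0 —
featureless molecules are never declared similar. In the interaction
table, the similar route applies only to compounds with no exact evidence
key of their own, and transfers interactions to seed targets only; the
direct route reaches seeds and their first-degree neighbours. This
asymmetry limits similarity-based extrapolation to the best-curated part
of the target space.

## Candidate target space

Seeds come in three categories (drug targets, pathway members, prognostic
signature). First-degree neighbours are proteins connected to any seed by
a PPI edge with confidence score strictly above 400 (STRING's medium
confidence); the graph is undirected and duplicate (A,B)/(B,A) rows keep
the maximum score. Edges from disallowed species are removed before
expansion; edges lacking an organism annotation are kept with a warning.
The tissue-expression filter applies to seeds and neighbours alike — a
deliberate reading of "only expressed proteins were included". A protein
may be a seed of one category and a neighbour of another; de-duplication
happens only in union totals.

## Efficacy

E(P) = |targets(P)| / |∪_Q targets(Q)|. The denominator is the union of
proteins targeted by any plant, not the full candidate space — that is the
definition under which the reference values (59/79 → 0.75 etc.) are
reproduced, and it makes E = 1 attainable by a plant covering the joint
space. The weighted efficacy sums unique-compound counts over a plant's
targets and divides by the maximum over plants, giving a [0, 1] score that
preserves relative differences; the divide-by-max form is chosen over
min–max scaling so a hypothetical zero-targeting plant scores 0, not an
arbitrary offset. Values are kept at full precision internally; reports
round half-up to two decimals.

## Phi co-targeting network

For proteins i, j with binary plant-targeting profiles over n plants, the
2×2 table (a = both, b = i only, c = j only, d = neither) gives

    phi = (ad − bc) / sqrt((a+b)(c+d)(a+c)(b+d)),   chi² = n·phi²

with 1 degree of freedom and upper-tail p. No Yates continuity correction
is applied — it would break the stated χ² = nφ² identity. n is the number
of plants in the matrix, including plants with no interactions (they
contribute to the "neither" cell). Pairs are evaluable only when both
proteins are targeted by at least one and missed by at least one plant;
degenerate pairs are neither tested nor counted toward the Bonferroni
multiplier m = number of evaluable pairs, p_adj = min(1, m·p), significant
at p_adj ≤ 0.05 (boundary inclusive). Significant negative edges are
retained and carry their sign — they mark proteins consistently avoided by
the same plants. Components and articulation nodes are computed on the
significant edge set; intra-cluster distances are unweighted BFS shortest
paths over the PPI graph with unreachable pairs counted separately.

## Chemical space

Each molecule gets 1027 descriptors: 1024 fingerprint bits plus MW, TPSA
and SlogP. Columns are scaled to mean 0, sample (n−1) standard deviation 1
jointly after concatenating all compound groups — group labels are pure
metadata. Constant columns become zeros rather than being dropped, so the
matrix keeps its stated shape. Classical MDS eigendecomposes the
double-centered −½D² matrix; negative eigenvalues (non-Euclidean inputs)
are truncated to zero, and if fewer positive eigenvalues exist than
requested axes the remaining coordinates are zero-filled with a warning.
The embedding is unique only up to rotation/reflection; tests compare
configurations after orthogonal Procrustes alignment.

## Metabolic perturbation

A plant perturbs a reaction when any metabolite matched (exactly or by the
same Tc/ΔMW rule) to any of the plant's compounds appears in the
reaction's **substrate** list; product-only occurrences never count, and
reversibility is passed through rather than resolved — the rule is stated
purely in substrate terms. Currency metabolites (water, ATP, …) are not
filtered by default; a flag exists. Pathway loads count distinct plants
per reaction; a reaction is highlighted when perturbed by strictly more
than 20 plants. Mere presence of a compound in a plant suffices — no
abundance criterion is applied, since the inputs carry none.

## Synthetic-data generator

The generator emulates the study conditions end to end with one RNG
stream (`numpy.random.default_rng(rng_seed)`); a fixed seed yields
byte-identical files. Defaults: 40 plants (25 % edible), 400 compounds,
three seed categories of 8/10/9 proteins drawn from a pool sized to
produce modest overlap, 60 neighbour proteins, expression-positive rate
0.9, and three planted (plant-group, protein-cluster) assignments of sizes
(12, 4), (10, 3), (8, 3).

* **Compound sharing.** A compound is plant specific with probability
  0.57 (the observed majority of phytochemicals occur in a single plant);
  otherwise it occurs in 1 + Zipf(2.2) plants, capped at the plant count.
  This reproduces a heavy-tailed sharing profile with a realized
  plant-specific fraction within ±10 % of the target at ≥ 1000 compounds.
* **Bioactivity noise.** Each planted (compound, protein) pair receives
  3–5 records with per-record positive mass 0.85; decoy pairs get the same
  record counts at 0.10. Under the P ≥ 0.5 gate the closed-form recall is
  0.939 / 0.988 / 0.973 for 3/4/5 records (expected ≈ 0.97) and decoy
  acceptance 0.028 / 0.052 / 0.009 — the planted truth is recoverable with
  recall ≥ 0.9 and false-acceptance ≤ 0.15 by construction, not tuning.
  Additional pure-noise records carry disallowed organisms or unknown
  measurement types and must be removed by the filter.
* **Planted co-targeting.** Each plant group shares two hub compounds
  present in exactly the group's plants, with planted interactions on
  every protein of the paired cluster, so cluster proteins have (near-)
  identical plant profiles and phi ≈ 1 at n = 40 — comfortably past the
  Bonferroni bar. Background planted interactions (250 pairs) are sampled
  over non-cluster proteins, making the cluster the sole co-targeting
  signal; decoy noise still hits all proteins. Cluster proteins are forced
  expression-positive so the planted structure survives filtering.
* **Similar-route and metabolite matches.** Five compounds are reserved
  with no evidence of their own and paired with reference compounds
  (perturbed fingerprints, |ΔMW| < 50) that do carry evidence on seed
  proteins — exercising the similarity route. Twelve metabolites copy
  compound InChIKeys (exact matches) and four copy perturbed fingerprints
  (similar matches) into an 80-reaction, 120-metabolite network over eight
  pathway labels.

**What the benchmark does not emulate:** real chemistry (fingerprints are
random bit sets, not valid molecules), correlated assay errors,
database-scale sparsity and curation bias, inter-database identifier
drift, and the size of real inputs (hundreds of plants, thousands of
proteins). Passing tests therefore demonstrate correctness of the rules
and statistics, and recoverability of planted structure under calibrated
noise — not performance on any real plant database. Dataset-dependent
figures from real data (e.g. a 79-protein hot space or specific
connectivity ratios) are outside what a desk-scale synthetic run can or
should reproduce.

## Problem sizes and determinism

The default test and acceptance workloads run a full pipeline on the
40-plant generator (≈ 1 s) plus oracle sweeps of ~1000 random tables;
every stochastic test fixes its seed, and hypothesis-based property tests
use bounded example counts. All pipeline stages are pure functions of
inputs + configuration; re-running any stage from saved intermediates
reproduces downstream outputs exactly.
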