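# Methods

This note documents the models and conventions behind chemspacekit: what each
stage computes, the parameters that matter, the numerical choices made where
the design was open, and what the synthetic benchmark does and does not show.

## Standardization

Structures are normalized by a fixed, idempotent protocol: sanitize (valence
check) → largest organic fragment → element filter → uncharge → reionize →
canonical tautomer → optional stereo stripping → canonical SMILES. The
element whitelist is {H, B, C, N, O, F, Si, P, S, Cl, Se, Br, I}; anything
else yields a removal verdict carrying the reason. Two ordering conventions
are deliberate:

* the element filter runs **after** fragment selection, so a simple
  counterion (Na⁺, Cl⁻) never disqualifies an organic parent — only
  disallowed elements in the retained component do;
* tautomer canonicalization is configured to preserve sp³ and double-bond
  stereo when `keep_chirality=True` (the underlying canonicalizer would
  otherwise erase stereocenters near tautomeric systems), so the
  chirality-keeping and chirality-stripping pipelines differ only in the
  final stereo-removal step.

Deduplication is by canonical SMILES; the first-seen ID wins and every
dropped record is logged, so the curation log accounts for each input. Note
that the curated size of a library therefore depends on the chirality
setting: stripping stereo merges enantiomers/diastereomers and can only
shrink a library.

Cross-library compound overlap compares canonical SMILES, by default without
stereo (stereo annotation quality varies wildly between public databases;
stereo-agnostic comparison is the common denominator). Overlap reports are
exclusive Venn regions: every canonical form belongs to exactly one region,
so regions sum to the union.

## Descriptors and complexity

The panel is computed with RDKit: HBD/HBA, Crippen atom-contribution logP
(implementation-defined to roughly ±0.1 across toolkits), Ertl
fragment-contribution TPSA (Å²), average-mass MW (g/mol), rotatable bonds,
heteroatom and element counts, a ring census (aromatic/aliphatic ×
carbo-/heterocyclic, plus fused ring systems), chiral centers (assigned and
unassigned), and formal charge. Conventions the underlying toolkits leave
open:

* `fraction_rotatable` divides rotatable bonds by the number of
  heavy-atom–heavy-atom bonds (0 when there are none);
* acidic/basic atom counts are the unique atom indices matched by the SMARTS
  sets shipped in `chemspacekit/data/protonation_smarts.json` — an editable
  configuration, not a claim about pKa;
* aromaticity is RDKit's default perception model.

CSP3 is the fraction of carbons that are sp³-hybridized; a carbon-free
molecule is flagged and scored 0.

The unique-subgraph complexity index enumerates every connected induced
subgraph of the heavy-atom graph with 2..`max_fragment_atoms` atoms (default
7), canonicalizes each fragment by element and bond order, counts the
distinct fragments F, and reports min(1, log₂F / N_heavy). Molecules built
from repeating motifs (long saturated chains, symmetric lipids) score low;
scaffold-rich molecules score high. The cap keeps the enumeration polynomial
for chain-like molecules; dense fused ring systems are the expensive case.
This is an operationalized fragment-count index — it is property-tested
(bounds, monotonicity in F, agreement with an exhaustive enumeration oracle
on small molecules) and is not expected to agree numerically with any
desktop package's proprietary complexity score.

## Scaffold diversity

Bemis–Murcko scaffolds (ring systems + connecting linkers, side chains
pruned) are compared without stereo, consistent with overlap handling.
Acyclic molecules form a separate bucket, excluded from the CSR curve and
entropy and reported as an acyclic fraction — folding them into an "empty
scaffold" would swamp both metrics for lipid-rich libraries, which is
exactly the regime the package targets. Scaffold frequency ordering breaks
ties lexicographically so curves are reproducible.

The CSR curve consumes scaffolds in descending frequency; point k is
(k/S, cumulative members / cyclic compounds). The AUC uses the trapezoid
rule with the origin prepended, giving 0.5 for uniform counts (diagonal) and
approaching 1 as frequencies skew. The single-scaffold library is degenerate
— one point (1, 1) — and is reported as AUC 1.0 by convention, the
maximally non-diverse limit; the trapezoid value (0.5) would paradoxically
equal the maximally diverse case.

Scaled Shannon entropy is computed over the top-N scaffold counts (default
N = 15, the conventional choice for inter-database comparison): with
pᵢ = cᵢ/Σc over those N, SSE = −Σ pᵢ log₂ pᵢ / log₂ N. Normalizing over the
top-N subset (not the whole library) keeps the value in [0, 1] with SSE = 1
exactly when the top counts are equal. Fewer than N scaffolds: all are used
and the effective N is recorded.

## Fingerprints and similarity

* `keys166`: the 166 structural keys (the toolkit's unused key 0 is
  dropped).
* `circular4-1024`, `circular6-1024`: extended-connectivity fingerprints of
  bond diameter 4/6 (radius 2/3), folded to 1024 bits. Unfolded environment
  identifiers are exposed for tests (the diameter-4 identifier set nests
  inside diameter-6 by construction). Folded bit collisions are accepted and
  unmitigated; bit-level identity with other toolkits is not promised.
* `map4-2048`: a MinHashed atom-pair fingerprint. For every unordered
  heavy-atom pair (i, j) and radius r ∈ {1, 2}, a shingle joins the two
  canonical environment SMILES (lexicographically ordered) with the
  topological distance: `envᵢ|d|envⱼ`. The shingle set is MinHashed with
  2048 independent universal-hash permutations h(x) = (a·x + b) mod p over
  the Mersenne prime p = 2³¹ − 1, with (a, b) drawn from a seeded generator
  (default seed 42, recorded in outputs; comparisons across libraries
  require equal seeds and this is enforced). Similarity is the fraction of
  equal signature components — an unbiased estimator of the shingle-set
  Jaccard with standard error √(J(1−J)/2048) ≈ 0.011.

All fingerprints are computed on stereo-stripped structures. Tanimoto of two
empty fingerprints is defined as 1.0 with a warning (identical absence of
features).

## Diversity sampling protocol

Libraries above the sample size (default 1000) are profiled by n_samples
(default 5) independent uniform samples without replacement; all
within-sample pairwise similarities are pooled before statistics, matching
the convention of reporting a single mean/median per library. Sample seeds
derive from the master seed by fixed offsets and are recorded. Libraries at
or below the sample size run one full pairwise pass. Empirical CDFs are
evaluated on an even grid (default 200 points) over [0, 1].

## Sphere-exclusion clustering and MCS

Neighbors are pairs with similarity ≥ 1 − cutoff. The default cutoff is a
**dissimilarity** of 0.05 — membership at Tanimoto ≥ 0.95 under the
diameter-4 circular fingerprint. (Sphere exclusion at similarity ≥ 0.05
would collapse a lipid-rich library into one cluster; the tight reading is
the one that yields meaningful common substructures. The parameter is
exposed.) At each step the unassigned compound with the most unassigned
neighbors becomes a centroid (ties: lowest index) and absorbs its unassigned
neighbors; leftovers are singletons. Compounds above 1000 g/mol are filtered
out first to bound the cost. The implementation is verified against an
exhaustive plain-Python sphere-exclusion oracle on small fixtures.

The per-cluster MCS is a sequential reduction — pairwise MCS of the two
largest members, then MCS of the running pattern with each next member in
descending heavy-atom order (deterministic) — with element/bond-order
matching and a per-pair timeout. The running pattern is re-materialized as a
real submolecule after each step. Sequential reduction is at most as large
as any pairwise MCS and can undershoot the simultaneous multi-graph optimum;
it is the tractable choice and the result is always verified to be a
subgraph of every supporting member. Ring-membership matching is not
required (the clusters this pipeline targets consolidate onto acyclic ester
backbones); results below `mcs_min_atoms` (default 3) are discarded.

## NP-likeness

The scorer learns per-fragment contributions from a natural-product corpus
versus a synthetic corpus. Fragments are circular atom environments at radii
0..R (default R = 2). With smoothing s (default 1), total corpus occurrence
counts T, and vocabulary size V:

    contribution(f) = log₁₀( (count_np(f)+s)/(T_np+sV) ÷ (count_syn(f)+s)/(T_syn+sV) )

A molecule's raw score sums the contributions of all its environments
(every atom, every radius; unseen environments contribute 0) divided by its
heavy-atom count — the same environment multiset used in training, so
training and scoring are consistent. Raw scores beyond ±4 are compressed by
±(4 + log₁₀(|raw| − 3)) and clamped to [−5, 5]. Swapping the training
corpora negates every contribution and every raw score.

The model is trainable from any two corpora and ships no pretrained table;
scores are comparable only under the same training data, and no numerical
agreement with previously published NP-likeness values is implied.

## Multiverse projection

Each representation yields one 2-D t-SNE embedding of the pooled libraries,
computed from the precomputed Tanimoto/Jaccard dissimilarity matrix with a
seeded random initialization — deterministic given the seed, and treated as
a locality-preserving contract rather than a coordinate-exact output
(perplexity default 30, automatically reduced below n/3 by the pipeline;
500 iterations). Validation is property-based: determinism, finite
coordinates, duplicates embedding as nearest neighbors, and planted
two-library contrasts separating with silhouette > 0.5.

Purchasability-style queries are answered locally: catalog intersection
counts the query library's members whose canonical form (with or without
stereo) occurs in a catalog library, so a stereo-agnostic query matches at
least as many members as a stereo-aware one, and the count is monotone in
catalog growth.

## Synthetic benchmark: what it emulates, what it does not

The generators plant the exact quantity each stage measures, which makes the
test suite a parameter-recovery suite:

* **Triacylglycerols** — all glycerol tri-esters over a fatty-acid pool.
  The default pool (even saturated chains C8–C18 plus one 18:1 with the
  double bond after carbon 9, geometry unspecified) gives 196 unique esters:
  fully acyclic, mean CSP3 ≈ 0.95, mean MW ≈ 680 g/mol, scaffold-poor, and
  highly self-similar — the signature of a lipid-dominated food-chemical
  collection. `distinct_only` collapses sn-1/sn-3 mirror images by canonical
  form, so a pool of two acids yields 8 ordered but 6 distinct esters.
* **Scaffold series** — each requested scaffold receives exactly its
  requested number of distinct members by attaching acyclic side chains
  (which the scaffold reduction removes again); candidates are standardized
  before acceptance so the planted frequency vector survives curation.
* **NP-like / synthetic-like corpora** — oxygen-decorated saturated ring
  systems versus halogenated small aromatics; the class-distinguishing
  environments are disjoint by construction (oxygen-no-halogen vs
  halogen-no-oxygen), so a correct scorer must separate held-out halves.
* **Overlap triples** — libraries assembled from an endless deterministic
  stream of standardization-stable homologs, reproducing a planted Venn
  plan exactly.

All generators are deterministic given their plan and seed. What passing
these tests does **not** show: real collections have heterogeneous chemistry,
stereo-annotation noise, charged and multi-component records, tautomer-rich
scaffolds, and class boundaries that are statistical rather than disjoint.
The benchmark validates the machinery (exact bookkeeping, estimator
calibration, algorithmic equivalence to oracles), not field performance on
any particular database. Full-scale characterization of public libraries
runs through exactly the same code paths but its summary values depend on
the snapshot and curation settings used.

## Problem sizes and degenerate inputs

The shipped tests and the acceptance script run at desk scale — libraries of
tens to a few hundred molecules, 2048-component signatures, 50-pair
estimator checks, 80-point embeddings — sizes chosen so the whole suite
completes in well under five minutes on one CPU while still exercising every
code path at meaningful statistical resolution (e.g., MinHash mean absolute
error ≈ 0.002 at 2048 components).

Degenerate inputs are handled by contract: carbon-free molecules (CSP3 0,
flagged), single-heavy-atom molecules (complexity 0, flagged; atom-pair
fingerprint is an error — no pairs exist), acyclic-only libraries (CSR is an
error naming the condition; the acyclic fraction is the meaningful output),
fewer than two scaffolds (entropy error), empty fingerprint pairs (Tanimoto
1 with warning), and perplexity too large for the point count (error with a
corrective hint).
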