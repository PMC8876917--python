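# Methods

`abxscreen` implements a ligand-based virtual-screening workflow for
antibacterial drug repurposing: curate a benchmark of active and inactive
antibacterial compounds from raw activity records, train a three-classifier
consensus model on molecular-fingerprint features, apply it to an
approved-drug library, and grade the hits for structural novelty against the
panel of approved antibacterial drugs.  Because the workflow's data sources
are external databases, the package ships a synthetic-data generator that
reproduces the statistical structure the analysis assumes, with full ground
truth, so every stage is testable end to end offline.

## Molecular graphs and the SMILES subset

Molecules are constitutional graphs: atoms carry element, aromatic flag,
formal charge and an implicit-hydrogen count; bonds carry order (1, 2, 3 or
aromatic).  The parser covers the organic subset (B, C, N, O, P, S, F, Cl,
Br, I), lowercase aromatic atoms, bracket atoms with charge and explicit H
counts, branches, ring closures (including `%nn`), and dot-separated
fragments.  Stereo markers (`/`, `\`, `@`) are accepted and discarded —
every downstream consumer (fingerprints, MCS) is constitution-level.
Isotopes and elements outside the subset are parse errors, with one
exception: common monatomic counter-ions (`[Na+]`, `[K+]`, ...) are accepted
so that salt forms can be desalted by the largest-fragment rule (ties broken
by molecular weight, then canonical key).

Implicit hydrogens follow the default-valence model (B 3; C 4; N 3; O 2;
P 3/5; S 2/4/6; halogens 1): the smallest default valence at or above the
bond-order sum determines the count.  Aromatic bonds contribute 1.5 to that
sum, except at aromatic O/S, where they contribute 1.0 (the bonds are
formally single in five-membered rings); this reproduces the expected
hydrogen counts for benzene, pyridine, furan and thiophene without a
full aromaticity model.  Bracket atoms use only their written H count.

Structural identity — the deduplication criterion throughout — is equality
of a canonical key computed by iterative neighbourhood refinement with
individualisation on ties: refine atom classes to a fixed point from the
invariant (element, aromatic, charge, implicit H, degree); while any class
has more than one member, individualise each member of the first such class
in turn, recurse, and keep the lexicographically smallest rendering of the
fully ordered graph.  The key is invariant under atom reordering by
construction; the test suite checks this on hundreds of random permutations
and cross-checks key equality against RDKit canonical SMILES.

## Fingerprints

Two hashed bit-vector families over 1024 bits (any power of two >= 64):

* **Path fingerprints** index every simple path of 1–7 atoms.  A path is
  encoded as atom tokens (element + aromatic flag + charge) alternating with
  bond-order tokens, canonicalised as the lexicographic minimum of the
  forward and reverse strings, hashed with FNV-1a-32 and folded modulo the
  bit count.  The hash and encoding are pinned in this package so that
  fingerprints are bit-exact across runs and platforms; the path-length
  default (7) follows the linear-fragment fingerprint convention.
* **Circular fingerprints** use Morgan-style iterative neighbourhood
  hashing: the radius-0 identifier hashes (element, aromatic, charge,
  degree, implicit H); each iteration rehashes an atom's identifier with the
  sorted multiset of (bond order, neighbour identifier); identifiers from
  all iterations up to the radius (default 2, the ECFP4 equivalent) are
  folded into the bit vector.  Isolated atoms keep their radius-0
  identifier, so a lone atom sets exactly one bit at any radius.

Similarity is the Tanimoto coefficient over set bits.  Two all-zero
fingerprints compare as 1.0 (identical absence of features); zero against
non-zero is 0.0.  A similarity profile against a reference panel reports
mean, min and max Tanimoto.

## Maximum common substructure

Scaffold possession is judged by exact connected MCS under strict label
compatibility (same element and aromatic flag; bond orders equal, aromatic
only matching aromatic).  Common subgraphs are not required to be induced:
a ring may map onto an equally-labelled open chain with the ring-closing
bond omitted, the usual toolkit convention.  The backtracking search seeds
on atom pairs ordered rarest-label-first, grows mappings only through
compatible bonds, prunes with a label-multiset bound, and breaks ties by
bond count and then the lexicographically smallest atom-pair list, so the
result is deterministic.  Exact search is guarded at 80 combined heavy
atoms; larger inputs are rejected with advice to pre-filter by fingerprint
similarity.  A mismatch budget is exposed as a configuration hook but only
the exact (zero-mismatch) search is implemented — the screening statistic,
the overlap coefficient (MCS atoms / smaller molecule's atoms, high when
strictly above 0.9), is defined on exact matches, and exactness is what the
brute-force enumeration oracle in the test suite can verify.

## Benchmark construction

Activity records carry an IC50 in umol/L and/or a bare inactive flag.  A
compound is active iff IC50 < 10 umol/L; the boundary value itself counts
as inactive (activity is defined strictly below the cutoff).  The cutoff is
configurable; its empirical justification by curve fitting is outside this
package's scope.

Cleaning applies three steps in order: (1) structural deduplication by
canonical key, with duplicate groups carrying conflicting labels removed
entirely (ambiguous evidence should enter neither class); (2) removal of
compounds heavier than 1000 Da (strict `>`); (3) removal of every inactive
whose path-fingerprint Tanimoto against any active exceeds 0.9 — the
inactive member is dropped because actives are the scarce class.  Every
removal is counted in a provenance log, and unparseable records are skipped
and logged, never silently dropped.

Because label-only inactives vastly outnumber actives, ten balanced
negative sets are drawn: each contains every IC50-bearing inactive plus a
without-replacement sample of label-only inactives up to the positive-set
size.  Per-set RNG streams are spawned deterministically from one seed.

## The consensus model

Three classifiers — an RBF-kernel SVM, a random forest, and a multi-layer
perceptron — are fitted on the path-fingerprint features of each
positive + negative-set composite.  The module owns the stratified 80/20
split, grid search (repeated k-fold cross-validated accuracy, exact ties
broken by the AUC of a temporary model on the held-out test set), the
rank-based AUC, the confusion-derived metric panel, and mean ± sd
aggregation over the ten negative sets; the learners themselves come from
scikit-learn with non-searched parameters at library defaults.  Default
grids are gamma ∈ {0.001, 0.01, 0.1} × C ∈ {1, 10, 100} (SVM),
n_estimators ∈ {250, 500, 750, 1000} (RF), and hidden ∈ {128, 256, 512} ×
alpha ∈ {1e-4, 1e-3} (MLP); the package's reference optima (gamma 0.01,
C 10; 750 trees; hidden 512, alpha 1e-4) are members of each grid and are
used directly when the search is disabled, which is the default — on the
cleanly separable synthetic corpus every grid point is near-ceiling, so the
search adds cost without information.  Each negative set contributes one
evaluation run (5-fold CV accuracy on the train/validation portion plus a
full panel on its 20% test split) and one final member model fitted on the
whole composite.

Two deliberate metric conventions:

* **MSE on hard 0/1 predictions**, i.e. the misclassification rate, so
  accuracy + MSE = 1 exactly on every run.  This is nonstandard (MSE is
  more often computed on probabilities) but is the only reading under which
  a reported accuracy/MSE pair like 0.852/0.148 is self-consistent, and the
  package states it prominently.
* **AUC as the Mann–Whitney rank statistic with midranks**, which equals
  trapezoidal ROC integration including under ties; the equality is tested
  to 1e-12.

A query's per-method probability is the arithmetic mean over the ten
negative-set fits.  The ten fits differ only in their sampled negatives, so
averaging uses all of them and removes the arbitrariness of picking one;
per-drug probabilities from an aggregate are not claimed to match any
single-fit value.

## Screening and novelty

Library preparation parses, optionally status-filters (approved, not
withdrawn), weight-filters and fingerprints the drug list.  Note the two
weight boundaries are intentionally different: benchmark cleaning removes
strictly above 1000 Da, library preparation removes at or above 1000 Da.
Both conventions are preserved as defined rather than unified.

A drug is called active by one model when its probability is strictly
greater than 0.5, and consensus-active when all three models agree.
Consensus-active drugs whose canonical key is not in the approved-
antibacterial reference panel (membership is structural, not by name) are
the novel predicted antibacterial candidates.  A candidate is *structurally
novel* when its mean Tanimoto against the whole panel is strictly below 0.1
and its maximum strictly below 0.2; a coarser bucket flags mean <= 0.2.
Scaffold possession is a per-core-scaffold overlap coefficient, high when
strictly above 0.9; a drug is scaffold-free iff no core scaffold matches
highly.  All thresholds are configuration keys with these values as
defaults.

## The synthetic-data generator

Molecules are template-decorated rather than randomly grown: each scaffold
family is a SMILES template with substitution slots filled by short random
substituents, which guarantees parseability, a controllable family signal in
fingerprint space, and MCS-verifiable scaffold containment.  Three active
families — pyridine-based (A1), pyrimidine-based (A2) and a halogenated
ether family (A3) — and two aliphatic inactive families (cyclohexane- and
chain-based) are built in.  The approved-antibacterial reference panel and
the core-scaffold list cover A1/A2 only, so A3 library entries are the
planted novel-structure candidates: trained-on but reference-dissimilar.
Rejection sampling on canonical keys guarantees that the only structural
duplicates in a corpus are the planted ones.

Active IC50s are log-normal with median 1 umol/L, inactive IC50s log-normal
with median 100 umol/L, both with sigma 0.5 on the natural-log scale; each
side of the 10 umol/L cutoff is ~4.6 sigma away, so the label split follows
the cutoff essentially surely (closed-form quantile checked in tests).
Planted violations (duplicates, >1000 Da compounds, cross-class
near-duplicate pairs differing by one chain atom, label-conflict pairs) are
inserted in exactly the configured counts, and the truth table records every
compound's class, family and role.

The default scale — 250 actives, 150 IC50-bearing inactives, 700 label-only
inactives plus planted extras (~1.1k records), a 100-drug library, a
20-drug reference panel — keeps a full pipeline run around five minutes on
one CPU while preserving the motif that label-only negatives vastly
outnumber IC50-bearing ones.  What the generator does *not* emulate:
realistic medicinal-chemistry property distributions, activity cliffs,
assay noise, inter-database redundancy, or any 3D structure.  Passing tests
therefore demonstrate the correctness of the machinery (filters, resampling,
metrics, consensus and novelty logic) and its behaviour under clean class
structure — not the accuracy attainable on real bioactivity extracts, where
class boundaries are far noisier and performance is correspondingly lower.
In particular the near-ceiling classifier metrics on synthetic corpora are a
property of the planted separability, not a performance claim.

## Numerical and degenerate-input choices

* Fingerprint bit assignment is FNV-1a-32 modulo a power-of-two length;
  no platform-dependent hashing anywhere.
* Tanimoto of two empty fingerprints is 1.0 by documented convention.
* An IC50 exactly at the cutoff is inactive; a probability exactly 0.5 is
  inactive; a similarity exactly at a novelty cut is not novel; an overlap
  coefficient exactly 0.9 is not a high-similarity match.  Every boundary
  is strict exactly as each rule defines it.
* Empty molecules, empty reference panels, empty grids, single-class label
  vectors and oversized MCS inputs raise typed errors rather than returning
  sentinel values.
* All randomness (sampling, splits, learner seeds) descends from a single
  configured seed through deterministically spawned streams; reruns are
  byte-identical at the artifact level.

## Known limitations

* The SMILES subset has no stereochemistry, isotopes, tautomer handling or
  aromaticity perception from Kekulé forms (aromatic atoms must be written
  lowercase).
* Exact MCS is exponential in the worst case; the 80-atom combined guard
  keeps it practical for scaffold-sized queries only.
* The path-fingerprint hashing is an in-house bit-exact definition in the
  FP2 tradition, not byte-compatible with OpenBabel's FP2.
* Probability calibration, alternative fingerprint dialects (MACCS,
  SMARTS-pattern keys, learned embeddings) and additional learner families
  are out of scope.
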