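# Methods

This note documents the models and procedures implemented in `zincscreen`,
the parameter choices that matter, what the synthetic data does and does not
emulate, and the numerical decisions taken where the design was open.

## Problem setting

Inhibitors of Zn²⁺-dependent metalloenzymes (HDACs, MMPs, carbonic
anhydrases, ...) bind through a metal-binding fragment whose electronic
character — charge distribution, polarizability, π-system extent, donor
count — largely determines coordination strength. Given a set of ligands
with inhibition constants (Ki, nM) harvested from multiple complex entries,
the pipeline builds a two-class activity model on molecular descriptors,
identifies the electronic descriptors that separate the classes, and uses
the model together with descriptor-range gates and substructure rules to
screen fragment libraries for new zinc binders.

## Curation

- **Replicate merging.** Each ligand's lg(Ki) values are merged by
  arithmetic mean when their spread (max − min) is ≤ 1 log unit, and the
  ligand is discarded entirely when the spread exceeds 1: replicates that
  disagree by more than an order of magnitude indicate assay or identity
  problems rather than noise. The mean uses compensated summation so the
  result is exactly permutation-invariant.
- **Class labels.** high ⇔ lg(Ki) < 2, low ⇔ lg(Ki) > 3, both strict;
  merged values in the closed interval [2, 3] are excluded from modelling.
  The buffer zone keeps the two classes unambiguous.
- **Redundancy pruning.** Within each activity class, ligand pairs with
  MACCS-keys Tanimoto similarity strictly greater than 0.75 are redundant.
  The removal rule is made deterministic: ligands are processed in
  ascending id order and kept iff their similarity to every already-kept
  same-class ligand is ≤ 0.75. This greedy rule is idempotent, and its
  output is audited pairwise in the tests. Cross-class pruning is available
  behind a flag (`within_class=False`) but off by default, since duplicated
  structures in *different* activity classes carry signal, not redundancy.
- **Splits.** The external test set is a seeded stratified random draw
  (default modeling fraction 165/208 ≈ 0.79). The inner 7:3 train /
  internal-test split clusters the modeling ligands (k-means, k = max(2,
  n/10), standardized descriptor rows) and allocates each cluster 7:3 by a
  seeded draw, so both halves cover the same structural neighbourhoods.
  When no descriptor matrix is supplied the inner split falls back to a
  plain stratified draw. The `features` argument is the package's addition:
  a cluster-based split needs vectors to cluster on.

## Descriptors

The open 2D provider computes, besides a broad RDKit panel, the eight
electronic descriptors used for gating, from their published definitions:

- **JGI8 / JGI9** — Galvez mean topological charge indices: with `A` the
  heavy-atom adjacency matrix and `D*` the inverse-square topological
  distance matrix, the charge-term matrix is `M = A·D*`, and
  `JGIk = Σ_{i<j, d(i,j)=k} |m_ij − m_ji| / (n − 1)`.
- **BCUTp-1h** — highest eigenvalue of a Burden connectivity matrix with
  tabulated atomic polarizabilities (Å³) on the diagonal, 0.1 × bond order
  on bonded pairs (+0.01 for terminal bonds) and 0.001 elsewhere.
- **PEOE_VSA−4 / +1 / −0** — sums of per-atom Labute approximate
  surface-area contributions over atoms whose Gasteiger partial charge
  falls in [−0.25, −0.20), [0.05, 0.10) and [−0.05, 0.00) respectively
  (half-open bins, as in the original binning scheme).
- **nAtomP** — atom count of the largest connected conjugated system.
- **HBA_Count** — hydrogen-bond acceptor count (RDKit definition).

Quantum-chemical (DFT) descriptors are not computed; externally computed
tables enter through the CSV ingest path and are treated identically
downstream.

Missing values: a column with > 20% missing entries is dropped, otherwise
median-imputed; both actions are recorded in the audit log.

**Filter cascade.** Three stages, in order: (1) remove exactly-constant
columns (exact constancy is tested rather than `var == 0`, since the naive
variance of a constant column can round to ~1e−31); (2) remove columns with
|Pearson r| to lg(Ki) below 0.15 (Spearman available by flag); (3) visit
column pairs with |pairwise r| > 0.8 in descending |r| and delete the member
with the smaller |r to lg(Ki)|, ties going to the lexicographically later
name. The cascade is idempotent and its surviving *set* does not depend on
column order.

**Profiles.** Per descriptor: point-biserial correlation with the class
label, a two-sided Mann–Whitney U p-value (exact enumeration when the
smaller class has ≤ 8 members and the values are tie-free, tie-corrected
normal approximation otherwise), and μ/σ over the high-activity reference
population — the population whose descriptor behaviour the gate encodes.
Descriptors with |r| > 0.3 and p < 0.05 are flagged highly correlated.
The cascade intentionally correlates against continuous lg(Ki) while the
profiles correlate against the class label: the former mirrors the
filtering criterion, the latter the interpretation step.

## Feature selection

- **CFS**: subset merit `k·r̄_cf / √(k + k(k−1)·r̄_ff)` over absolute
  correlations; forward best-first search over subsets with an open list,
  terminating after 5 consecutive expansions that fail to improve the best
  merit (the stale limit standard for this search). Note one algebraic
  property the tests pin down: adding a perfect duplicate of a feature
  leaves the merit exactly unchanged (denominator √(k²) = k), so duplicates
  never help but only strictly hurt when the copy is weaker.
- **Gain ratio**: each feature is discretized by the binary threshold
  (midpoints of consecutive distinct sorted values) maximizing information
  gain; the score divides that gain by the split information. The default
  selection keeps every feature with positive gain ratio (ranker-style);
  `top_k` caps it.
- **Wrapper**: the same best-first search scored by stratified 5-fold
  cross-validated accuracy of the base learner (Gaussian naive Bayes by
  default), seeded folds, ties toward the lower column index.
- **CFS & wrapper**: the wrapper search restricted to the CFS subset.

All four are deterministic given the seed and are exposed both as
scikit-learn transformers (`SelectorMixin`) and as functions returning a
`FeatureSubset` (method, names, score, trace).

## Classifiers

Eight learners under one scikit-learn contract (binary problems only,
classes ordered lexicographically):

- **Naive Bayes** — per-class priors (ML frequencies) and univariate normal
  densities per feature; standard deviations floored at 1e−6 to avoid
  singular likelihoods. Posteriors are normalized in probability space
  after subtracting the row-max log-likelihood; normalizing via
  log-sum-exp loses the last ~5 digits when the floored sd drives
  |log-likelihood| to ~1e11.
- **IBk** — k-nearest neighbours, Euclidean distance on features min-max
  scaled to [0, 1] by the training ranges (constant features contribute
  nothing). Vote ties break toward the class with the smaller mean
  neighbour distance, then lexicographically.
- **J48** — binary-threshold tree grown by gain ratio; a split is
  admissible only if both sides retain at least `min_obj` instances;
  pessimistic error pruning (subtree replacement, confidence 0.25, the
  binomial upper bound inverted through the regularized incomplete beta
  function) is on by default and toggleable. `min_obj ≥ n` degenerates to a
  single majority leaf with a warning-free fallback.
- **ZeroR / OneR** — majority baseline; single-feature rule with greedy
  value bucketing (a bucket closes once its majority class reaches
  `min_bucket` = 6 by default and the next value differs; equal values never
  straddle a boundary; trailing underfull buckets merge backwards; adjacent
  same-class buckets merge). The greedy bucketing can misplace a boundary
  instance relative to the globally optimal rule; this is inherent to the
  rule family, and the tests encode it.
- **ASC_NB / ASC_IBK / ASC_J48** — attribute-selected meta-classifier: CFS
  (best-first) on the training data, then the base learner on the selected
  columns; an empty selection falls back to all features, making the
  meta-classifier reproduce its base learner exactly.

Every learner's predictions are checked against independent brute-force
implementations of its decision rule on enumerable toys, and naive Bayes
additionally against scikit-learn's Gaussian NB. Fitted models serialize to
JSON (trees as nested nodes, NB as parameter tables) and round-trip exactly.

## Evaluation

Accuracy, Active(detected)% = TP/(TP+FP)·100 and HR = TP/A·100 are computed
as exact ratios. Repeated cross-validation uses stratified folds, one fold
assignment per repeat seed (default 10 folds × 10 repeats). ROC/AUC uses
the rank statistic with half credit for ties (identical to the trapezoidal
area under the empirical curve, and to the pairwise Mann–Whitney
probability). Replicated-split validation re-draws the 7:3 inner split n
times (default 10), selects descriptors and fits the model per replicate,
and reports train (resubstitution by default; a CV flag exists because
either reading of a "training set accuracy" column is defensible),
internal-test and external-test accuracy and AUC. The best replicate
maximizes external accuracy, with external AUC and then the lowest
replicate index as tie-breaks; its external false positives are listed with
structures. The learning curve reports held-out accuracy against stratified
training subsamples.

## Screening

The gate is the closed interval [μ − 1.96σ, μ + 1.96σ] per gated
descriptor (default: the eight electronic descriptors), with μ/σ from the
high-activity reference population; σ = 0 collapses to the degenerate point
interval. Bounds are inclusive ("in the range" read inclusively); the
retained set shrinks monotonically as the multiplier decreases. A library
molecule passes the screen iff the model predicts high *and* every gated
value is in-gate; inhibitor-search mode additionally requires ≥ 1 match
against the ZnBF SMARTS table. Hits are ranked by model score with
matched-pattern count as tie-break — a stand-in ordering for
docking-based prioritization, which is out of scope.

The shipped SMARTS table (`data/znbf_patterns.csv`) encodes 15 fragments
with their metal-donor atoms and denticity. Eight are classic zinc-binding
groups (hydroxamate, sulfonamide, urea, phosphonate, carboxylate, thiolate,
sulfonate, imidazole); the remaining seven are best-effort encodings of
known chelator chemotypes (catechol, N-hydroxyurea, β-ketoamide, tetrazole,
boronic acid, 8-hydroxyquinoline, dithiocarbamate), flagged `synthetic` in
the provenance column because they are constructed stand-ins, not
reproductions of any reference fragment depiction. Substructure matching
approximates a pharmacophore-feature search: it preserves the logic
(require a metal-binding motif) without pharmacophore geometry.

`extract_binding_atoms` applies the geometric annotation rule to 3D
complexes: every O/N/S/F atom within 2.8 Å of each metal atom is a binding
atom; a ligand's denticity is its count of binding atoms to one metal.

## Synthetic data

The generators emulate the *statistical* structure of a curated
metalloenzyme-ligand set; the defaults are the study conditions used
throughout the tests and the acceptance script:

| parameter | default | emulates |
|---|---|---|
| n_ligands | 208 | curated set size |
| high_fraction | 131/208 | high:low class balance |
| lg_ki_range | [−4, 7] | observed activity span (lg nM) |
| dup_entry_rate | 0.20 | ligands with 2–4 Ki entries |
| discordant_rate | 0.15 | duplicated ligands with spread > 1 |
| near_dup_rate | 0.10 | analog redundancy (> 0.75 MACCS) |
| effect_size | 1.5 | standardized class separation on informative columns |
| n_informative | 8 (5 in the recovery studies) | electronic-descriptor signal |
| noise_sd | 1.0 | uninformative column dispersion |

Structures come from a closed fragment grammar (prefix × scaffold × linker ×
cap) rather than random graphs, so fingerprints and SMARTS behave
chemically: caps include the real ZnBF motifs (hydroxamic acid, sulfonamide,
urea, phosphonate, carboxylate) and inert decoys, and no decoy combination
matches any shipped pattern (verified exhaustively). lg(Ki) is drawn
per-class from truncated normals centred at 0.5 (high) and 4.5 (low), so
labels are unambiguous by construction; Ki = 10^lg. Replicate records
jitter by centred ±0.4 offsets (spread ≤ 0.8, always concordant), and
discordant ligands displace their most extreme record by 1.2–2.5 log units
toward the interior of the range, guaranteeing a spread > 1 and hence
discard at curation. Near-duplicates are single-atom edits of the largest
parents, kept only if MACCS similarity > 0.75 (an exact copy is the
fallback). Class allocation is deterministic (`round(n·fraction)`,
shuffled), so the realized balance always matches the request. All
randomness derives from one root seed through named substreams
(structures / activities / descriptors / library), so each stage reproduces
independently.

Informative descriptor columns are drawn N(effect, 1) vs N(0, 1) by class
and share names with the electronic descriptors so the gate applies
unchanged; a constant column and a collinear, weakly informative pair are
always planted to exercise the cascade. The library generator plants
exactly k actives (ZnBF caps, high-class descriptor rows) among decoys.

What this does *not* emulate: real structure–activity relationships,
DFT-level electronics, scaffold-class composition of any particular target,
or correlated descriptor blocks beyond the planted pair. Passing tests
therefore demonstrate that the machinery recovers planted statistical
signal at realistic sample sizes — not that any particular accuracy will be
attained on real assay data, where effect sizes, class overlap and
descriptor redundancy are less forgiving.

## Numerical choices and degenerate inputs

- Correlations involving an exactly constant vector are defined as 0; exact
  constancy, not variance, is the test everywhere it matters.
- Pairwise-pruning and search tie-breaks are lexicographic / lowest-index,
  making every selector and the cascade deterministic.
- J48's split search requires strictly positive information gain (> 1e−12)
  and both sides ≥ min_obj; gain-ratio comparisons use a 1e−15 slack so
  float noise cannot flip a tie.
- The problem sizes in the test suite and acceptance script (200-ligand
  sets, 2000-molecule libraries, 10 replicates, 50 recovery seeds, 20
  enrichment seeds) were chosen as the smallest sizes at which the planted
  effects are resolved with comfortable Monte-Carlo margin.

## Known limitations

- Binary classification only; no multiclass or regression mode.
- The descriptor panel is 2D; 3D and quantum descriptors enter only via CSV.
- OneR's bucketing and the best-first searches are greedy; global
  optimality is guaranteed only where the tests enumerate (CFS on ≤ 12
  features).
- Pharmacophore geometry, docking and binding-affinity prediction are out
  of scope; the substructure stage is a topological approximation.
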