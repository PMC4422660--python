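# Methods

## Model

`mldppi` predicts whether two proteins interact from primary sequence
alone. The underlying assumption is that interaction is mediated by local
binding patterns — short stretches whose physicochemical character is
conserved between interacting partners — and that these patterns can occur
at several scales and positions along the chain. The featurization
therefore computes composition/transition/distribution (CTD) descriptors
not on the whole sequence only, but on a family of overlapping continuous
sub-sequences, and the classifier is an ensemble of decision trees that
can pick up combinations of region-local features.

### Reduced alphabet

The 20 standard amino acids are collapsed to 7 classes by side-chain
dipole and volume ({A,G,V}, {C}, {M,S,T,Y}, {F,I,L,P}, {H,N,Q,W}, {K,R},
{D,E}). Residues in the same class are treated as interchangeable; this
trades sequence detail for statistical robustness of the descriptor
estimates on regions as short as a few residues.

### Continuous regions

A sequence of length L is partitioned into S equal segments; segment k
covers positions ⌊(k−1)·L/S⌋+1 … ⌊k·L/S⌋ (1-based, gap-free, each
non-empty for L ≥ S). A region is any contiguous run of segments, written
as a binary mask (`0011` = final half). With S = 4 there are 10 contiguous
masks; the all-ones (full-sequence) mask is excluded by default, leaving
9 regions and the 567-dimensional per-protein layout
(9 × 63). The full mask can be re-included via `EncoderConfig(include_full=True)`
for sensitivity checks. Which single mask to drop from the 10 to obtain a
9-region layout is a design choice; dropping the full-length mask is the
only rule that excludes exactly one mask on a principled ground (it is the
one region that carries no locality). Discontinuous masks (e.g. `1010`)
are never used; `n_binary_region_codes(S) = 2^S − 2` records the size of
the full non-degenerate mask space for reference.

Region masks are ordered by run length, then run start; this order is part
of the versioned layout (`LAYOUT_VERSION`), which is written into feature
sidecars and model artifacts and checked at prediction time.

### CTD descriptors

For a region of length L over the 7-letter alphabet:

- composition: C_g = 100·n_g/L (7 values, sum 100);
- transition: T_gh = 100·n_gh/(L−1) for each unordered pair g<h, where
  n_gh counts adjacent positions alternating g↔h (21 values; a length-1
  region has no adjacencies and yields zeros rather than a division
  error);
- distribution: for a group with occurrences at positions p_1<…<p_n, the
  values 100·p_i/L at i = 1 and i = max(1, ⌊q·n⌋), q ∈ {¼, ½, ¾, 1}
  (35 values; absent group → five zeros).

The floor-based quantile index is the convention consistent with the
published worked derivation (e.g. the 25% occurrence of a group with n = 6
is occurrence ⌊1.5⌋ = 1); ceiling or round-half-up rules contradict it.
Positions are 1-based within the region and normalized by the region
length. All values are stored as percentages (0–100), not fractions. The
quantile index uses exact integer arithmetic (⌊k·n/4⌋), so there is no
floating-point edge case at exact multiples.

A protein's feature vector concatenates [C(7), T(21), D(35)] per region in
mask order; a pair concatenates partner A's vector then partner B's, in
the order the pair list gives them (no symmetrization — concatenation
order is part of the data contract; `pair_feature_matrix(...,
augment_swapped=True)` can add the swapped orientation as an extra
training instance).

## Classifier

A random forest of N unpruned CART trees: each tree is grown on a
bootstrap resample of the training pairs (n draws with replacement, ≈63.2%
unique examples in-bag), choosing at every node the best Gini split among
M freshly sampled candidate features. Prediction is majority vote; the
reported score is the fraction of trees voting "interacting", and a tie at
exactly 0.5 is resolved to the positive class (arbitrary but fixed).
Out-of-bag votes provide an internal accuracy estimate.

Defaults are **N = 60, M = 10**. Accuracy is insensitive to M over a wide
range (the `sweep` command reproduces this: on the default synthetic
benchmark the accuracy span across M ∈ {5,…,30} is under 2 points) and
saturates in N beyond a few tens of trees, so these defaults favour the
cheaper end of the plateau.

The ensemble is backed by scikit-learn's `RandomForestClassifier`, which
implements exactly this contract; `ReferenceGiniTree` is an independent
minimal CART kept in the package so the tree-level contract (Gini splits,
purity stopping, per-node feature subsampling) can be cross-checked
without circularity.

Cross-validation is stratified k-fold (default k = 5) with a fixed seed;
stratification prevents degenerate folds on small balanced sets and is
declared here rather than silently assumed. Metrics are computed per fold
from that fold's confusion counts and then averaged (mean ± sample std
across folds), not pooled — the convention matches how per-run tables are
usually reported; pooling would weight folds by size instead.

## Evaluation measures

From fold confusion counts (TP, FP, TN, FN): ACC, SN (recall), Spec, PPV
(precision), NPV, F-score = 2·SN·PPV/(SN+PPV), and MCC =
(TP·TN − FP·FN)/√((TP+FN)(TN+FP)(TP+FP)(TN+FN)). A measure whose
denominator is zero is reported as 0 with an explicit `undefined` flag —
never a silent NaN. Values are available as fractions or percentages.

## Synthetic benchmark generator

Real benchmark corpora (curated interaction databases plus sampled
negatives) are external inputs; the generator provides a self-contained
stand-in with a *known* signal so the whole pipeline can be exercised and
calibrated offline:

- background proteins: length uniform in `seq_len_range` (default 50–120
  residues, respecting the 50-residue minimum-length curation rule used
  with `filter_min_length`); each position's group drawn from
  `background_group_frequencies` (default uniform over the 7 groups; a
  natural-composition preset is provided), residue uniform within the
  group;
- a library of `motif_library_size` = 8 motif *pairs*, each motif 14
  residues drawn from two randomly chosen signature groups — a strong
  local composition signature;
- every interacting pair receives one library motif pair:
  `motif_insertions_per_positive` = 2 copies of motif A overwrite random
  non-overlapping windows of partner A (likewise B), placed uniformly over
  all non-overlapping layouts via the gap construction; non-interacting
  pairs are background only;
- a JSON truth manifest records the library, each positive pair's motif id
  and all insertion coordinates.

The signal is planted in the *sequences*, not the labels or features, so a
passing recovery test exercises the encoder's actual claim — detecting
correlated local composition patterns — and not merely the classifier. The
defaults (400 pairs, 14-residue motifs, two insertions) were fixed by a
parameter-recovery calibration: they are the weakest of the scanned
settings at which a default forest reliably exceeds 90% cross-validated
accuracy across seeds, giving the recovery test a margin without making it
trivial. What the generator does **not** emulate: real interaction network
topology (proteins appear in exactly one pair), homology/redundancy
structure, sequence-identity filtering, subcellular-localization-based
negative sampling, length/composition biases of real proteomes. Passing
tests therefore demonstrate correctness and sensitivity of the pipeline,
not expected accuracy on biological data.

## Numerical and interface conventions

- Ambiguous residues: policy `skip_record` (default, with logged warning),
  `reject` (error naming residue and position), or `map_to_nearest`
  (B→D, Z→E, U→C; X still skips). A trailing `*` (stop codon) is stripped.
- Pair lists are TSV or CSV (`id_a, id_b, label`), delimiter sniffed from
  the first line, optional header detected by a non-numeric third column.
- All randomness flows through explicit integer seeds (NumPy `default_rng`
  / scikit-learn `random_state`); identical seeds reproduce fold splits,
  bootstraps, sequences and reports byte for byte.
- Every CLI artifact gets a `*.provenance.json` (config SHA-256, layout
  version, seeds, timestamp) sufficient to reproduce the run.
- Test and calibration problem sizes (400-pair default benchmark; 120-pair
  datasets, 20 seeds for the ensemble-dominance check; 80-pair datasets,
  5 seeds for signal monotonicity) were chosen as the smallest sets whose
  binomial noise is well inside the tested margins.

## Known limitations

- The encoder requires length ≥ S; proteins shorter than the configured
  `min_length` (default 50) are dropped before pairing, which can orphan
  pairs referencing them (reported as unknown ids).
- Feature-subset size M interacts with the 63-per-region block structure
  only implicitly; no per-block feature grouping or selection is
  implemented.
- No probability calibration: scores are raw vote fractions.
- Cross-species or homology-aware evaluation is out of scope; so is any
  sequence-identity redundancy filter.
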