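# mldppi

Sequence-only prediction of protein–protein interactions (PPIs) with a
multi-scale local descriptor (MLD) featurization and a random-forest
classifier.

Experimental detection of PPIs is slow and expensive, so a long line of
methods tries to predict whether two proteins interact from their primary
sequences alone. `mldppi` implements one such pipeline for computational
biologists who want a compact, fully reproducible reference implementation:
a CTD-over-continuous-regions encoder, a seedable random-forest classifier,
the standard seven evaluation measures, a synthetic benchmark generator
with planted interaction signal, and a CLI that wires them together.

## The featurization

Each protein sequence is mapped to a reduced 7-letter alphabet (amino acids
grouped by side-chain dipole and volume):

| group | 1 | 2 | 3 | 4 | 5 | 6 | 7 |
|-------|---|---|---|---|---|---|---|
| residues | A,G,V | C | M,S,T,Y | F,I,L,P | H,N,Q,W | K,R | D,E |

The sequence is cut into S = 4 equal-length segments; every binary mask
whose set bits form one contiguous run selects a *continuous region* (e.g.
`0011` = the final half). Excluding the full-length mask this gives 9
regions at multiple scales. Each region is summarised by the classical
composition / transition / distribution (CTD) descriptors:

- **C** (7 values): percentage of region residues in each group,
  C_g = 100·n_g / L;
- **T** (21 values): for each unordered group pair (g,h), the percentage of
  adjacent residue pairs alternating between g and h,
  T_gh = 100·n_gh / (L−1);
- **D** (35 values): for each group, the relative position 100·p_i/L of its
  first, 25%, 50%, 75% and 100% occurrence (quantile index
  max(1, ⌊q·n⌋)).

That is 63 values per region, 9 × 63 = **567 per protein**, and **1134 per
pair** (concatenation of both partners). The pair vectors feed a random
forest of N = 60 unpruned Gini trees, each grown on a bootstrap resample
with a random subset of M = 10 candidate features per split; prediction is
by majority vote, and seven measures (ACC, SN, Spec, PPV, NPV, F-score,
MCC) are reported from stratified k-fold cross-validation.

## Worked example

`mldppi worked-example` derives the full CTD encoding of the reference
22-residue sequence and checks every value against the published reference
derivation:

```text
$ mldppi worked-example
sequence      : GGYCCCYYGYYYGCCGGYYGCG
group encoding: 1132223313331221133121

composition C (%):
  group 1:  36.36  (reference 36.36)
  group 2:  27.27  (reference 27.27)
  group 3:  36.36  (reference 36.36)
...
all values match the reference derivation
```

Eight of the 22 residues fall in group 1, so C₁ = 8/22 = 36.36%; four of
the 21 adjacent pairs alternate between groups 1 and 2, so T₁₂ = 4/21 =
19.05%; the 4th of the eight group-1 residues (the 50% occurrence) sits at
position 13, so D₁(50%) = 13/22 = 59.09%; and so on.

A full pipeline run on a simulated benchmark:

```text
$ mldppi simulate --n-positive 30 --n-negative 30 --seed 5 --out-dir demo
wrote 120 proteins and 60 pairs to demo
$ mldppi cv --fasta demo/proteins.fasta --pairs demo/pairs.tsv -N 60 -M 10 -k 5 --seed 0 --out-prefix demo/report
fold tp fp tn fn   acc     sn   spec    ppv    npv  f_score   mcc
   0  5  1  5  1 83.33  83.33  83.33  83.33  83.33    83.33 66.67
   1  5  3  3  1 66.67  83.33  50.00  62.50  75.00    71.43 35.36
   2  6  1  5  0 91.67 100.00  83.33  85.71 100.00    92.31 84.52
   3  4  0  6  2 83.33  66.67 100.00 100.00  75.00    80.00 70.71
   4  5  3  3  1 66.67  83.33  50.00  62.50  75.00    71.43 35.36
mean             78.33  83.33  73.33  78.81  81.67    79.70 58.52
 std             11.18  11.79  22.36  16.20  10.87     8.79 22.16
```

Each fold row gives the held-out confusion counts and the seven metrics in
percent; the planted motif signal in this tiny 60-pair demo is recovered
well above chance (at the default 400-pair benchmark size the mean
accuracy exceeds 90%). Other subcommands: `featurize` (FASTA → feature
matrix + layout sidecar), `train` / `predict` (model artifact with
provenance), `sweep` (cross-validated (M, N) grid).

Library use mirrors the CLI:

```python
from mldppi import SyntheticConfig, generate, pair_feature_matrix, cross_validate, ForestConfig

records, pairs, manifest = generate(SyntheticConfig(seed=0))
X, y = pair_feature_matrix(records, pairs)         # (400, 1134)
report = cross_validate(X, y, ForestConfig(), k=5, seed=0)
print(report.mean["acc"], report.mean["mcc"])
```

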