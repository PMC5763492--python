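# Methods

`carbmotif` identifies protein carbonylation sites — the irreversible
oxidation of K, R, T and P side chains by reactive oxygen species — from
sequence context alone, and does so through explicit motif subgroups rather
than a single monolithic classifier.

## Model

### Site windows

A candidate site is represented by the 2n+1-mer window centred on it
(default n = 10, i.e. 21-mers, offsets −10..+10 with 0 the site). Windows
running past a terminus are padded with the dummy symbol `-`, which is
excluded from every count in the package. Annotated sites are positives;
every other K/R/T/P residue in the same proteins is a candidate negative.
Near-duplicate fragments are removed by greedy clustering on ungapped
positional identity (threshold 0.5): a fragment is dropped when it matches
any retained fragment — or, for negatives, any positive — at ≥ 50% of the
positions where both are non-dummy. This is a deterministic, dependency-free
analogue of CD-HIT at the fragment level; it does not do gapped alignment
and will not catch homology that is only visible with gaps. Negatives are
then down-sampled uniformly to twice the positive count (the 2:1 ratio is
kept because the deployment base rate is unknown and heavier imbalance
destabilises the downstream SVM).

### Maximal dependence decomposition (MDD)

The 20 amino acids are collapsed into five biochemical groups — polar
{C,G,N,Q,S,T,Y}, acidic {D,E}, basic {H,K,R}, hydrophobic {A,I,L,M,P,V},
aromatic {F,W} — so the dependence between two window offsets i ≠ j (centre
excluded: it is constant within a residue type) can be tested by the
Pearson statistic on the 5×5 co-occurrence table,

    chi2(A_i, A_j) = sum_mn (X_mn − E_mn)^2 / E_mn,   E_mn = X_mR X_Cn / X .

Cells with E_mn = 0 are skipped (equivalently, empty rows/columns are
collapsed). A pair is *significant* when chi2 > 34.3, the upper 0.005
quantile of chi-squared at (5−1)(5−1) = 16 degrees of freedom, rounded to
one decimal. Positive fragments are partitioned recursively: take the pair
with maximal chi2 (ties: smaller |i|, upstream before downstream, smaller
group index; the mirror orientations (i,j)/(j,i) are computed once so they
tie exactly); if significant, split at position i into the fragments
carrying the **consensus group** (the modal group at i) versus the rest.
Recursion stops when a subgroup is smaller than `max_cluster_size`
(default 30 — the original protocol does not state its value; 30 keeps
leaves large enough to estimate 21×20 emission tables) or no significant
pair remains.

The consensus in-group is a deliberate choice. Defining the split group as
the row with the largest chi-squared contribution fails exactly when the
motif is strong: the motif group then dominates the margin, its row matches
expectation almost perfectly, and the largest relative deviations sit in
the depleted background rows — so that rule splits off background, not
motif. The modal rule follows the original dependence-decomposition
formulation (split on the consensus) and recovers planted motifs reliably
(20/20 seeded replicates at penetrance 0.9; see the acceptance suite).

Two variants sit behind flags: ranking split positions by the summed chi2
over all partners (`criterion="sum"`), and a five-way split producing one
child per group present at the split position (`split_mode="five_way"`).

### Subgroup profiles and bit scores

Each leaf trains an ungapped position-specific emission model:

    e_p(a) = (count_p(a) + q) / (N_p + 20 q)

with pseudocount q = 0.5 and N_p the non-dummy count at position p. A
fragment scores `sum_p log2(e_p(a_p) / b(a_p))` bits over its non-dummy
positions, against a uniform background b = 1/20 (an empirical background
is configurable; uniform is the neutral default when the negative set is
itself synthetic or subsampled). Dummy positions contribute 0 bits. Because
the fragments are fixed-length and gap-free, this is the degenerate form a
profile HMM takes on such data — match states only, no insert/delete
transitions — so a full HMM architecture would add parameters without
adding expressiveness. Each profile also carries a decision threshold
chosen by sweeping the midpoints of consecutive distinct observed scores
and minimising |Sn − Sp| (ties: larger accuracy, then smaller threshold).

### The two-layer stacker

A fragment's feature vector for the second layer is its bit score against
every leaf profile, in leaf order. Dimensions are scaled to [−1, 1] by
training min/max. An RBF-SVM (K(u,v) = exp(−γ‖u−v‖²)) is tuned over the
classical LIBSVM grid — cost 2^−5..2^15, γ 2^−15..2^3, consecutive points a
factor 2² apart — by internal stratified 5-fold CV accuracy (ties prefer
the smaller cost, then the smaller γ), then refit on all training data.

Two details matter for the stacker to generalise:

* **Leave-one-out training scores.** A positive scored by the profile of
  its own leaf is scored by a model that contains its own counts; at leaf
  size ~100 this inflates the score by several bits, and an SVM fitted on
  such scores puts its boundary where held-out fragments never reach. The
  training matrix therefore uses the exact leave-one-out score on the
  own-leaf dimension (decrement the member's counts; closed form for
  count-based profiles). Scoring of new fragments is unchanged.
* **Balanced operating point.** The raw SVM decision rule on 2:1 data
  favours specificity. The decision value is therefore thresholded with the
  same balance calibration used for profile thresholds, computed on the
  leave-one-out-corrected training decision values. The reported decision
  scores are SVM decision values; predicted labels use the calibrated
  cutoff.

Whole-protein prediction windows every K/R/T/P residue, applies the
matching residue-type model, and reports the decision value, label and the
argmax-bit-score subgroup (the "matched motif").

### Feature encoders

Six fragment encodings are provided for baseline SVMs: amino-acid
composition (20-dim, dummies excluded from numerator and denominator, the
centre residue included), overlapping adjacent-pair composition (400-dim),
orthogonal binary one-hot (21×20, dummy = zero block), positional weight
matrix lookup (one positive-set frequency per position, 21-dim; the
per-position lookup follows the original coding-scheme description rather
than the ambiguous "(2n+1)×w" reading), BLOSUM62 rows (21×20), and a PSSM
encoding: a (2n+1)×20 profile aggregated to 20×20 by summing rows with the
same residue, divided by 2n+1 and squashed through 1/(1+e^−x). PSSM
profiles are read from the PSI-BLAST ASCII format; an internal profile
(positive-set log-odds with pseudocount 1) is computed when no PSI-BLAST
output is available, so the pipeline has no external-tool dependency.

## Evaluation protocol

Sn = TP/(TP+FN), Sp = TN/(TN+FP), Acc = (TP+TN)/total, and MCC with the
standard denominator sqrt((TP+FN)(TN+FP)(TP+FP)(TN+FN)) (defined as 0 when
a factor vanishes). ROC/AUC uses the rank/trapezoid method with ties
counting one half. Cross-validation is stratified k-fold (default 5) with
the metrics computed once on the pooled out-of-fold predictions, not
averaged per fold; stratification preserves the 2:1 ratio within folds.
The resampling evaluation repeats the whole CV with freshly drawn negative
samples (default 30 repeats) and averages. Independent testing refuses to
run when the test sites intersect the model's recorded training sites.
Inside the pipeline's CV, each training fold re-runs MDD clustering and
the full two-layer fit from scratch, so no clustering information leaks
across folds.

## Synthetic data

The generator emulates the *structure* of a curated carbonylation training
set: proteins of length 200, annotated sites spaced so windows never
overlap, positive counts per residue type matching the curated collection
(K 256/512 on 162 proteins, R 115/230, T 109/218, P 109/218), and an
optional positive-flank composition enriched 2× in K/R/T/P and L (the
compositional signature reported for real carbonylation neighbourhoods).
Motif subfamilies are planted as group-coherent residue choices at fixed
offsets with a stated penetrance; a motif couples two offsets (e.g. basic
at −3 co-occurring with basic at +7) because a *single* constrained
position carries no inter-position dependence for the chi-squared scan to
find. Co-positions are placed farther from the centre than the primary
offset so the exactly-tied mirror pair resolves to the primary position
under the tie-break. Default subfamily mix: 50% primary (basic-group motif
at the residue type's characteristic offset), 30% acidic subfamily, 20%
unstructured.

What the generator does **not** model: real amino-acid autocorrelation,
homology between proteins, structural context, and motif families that
overlap or compete. Passing tests on this data therefore demonstrate that
the machinery recovers what it is designed to recover under its own
assumptions — not that the published performance on curated data is
reproduced (the curated set is not available in machine-readable form).

## Numerical and degenerate-input choices

* Chi-squared: cells with zero expectation are skipped; empty tables are an
  error; each unordered position pair is computed once so mirror
  orientations tie exactly.
* A split whose in-group or out-group is empty carries no information and
  is treated as no-split; all-identical inputs therefore terminate
  immediately.
* Pseudocount 0 is allowed but raises when a position was observed only as
  padding (emissions undefined).
* Threshold sweeps include sentinels half a unit beyond the observed score
  range so the trivial accept-all/reject-all rules are reachable.
* Constant feature dimensions scale to 0 (not NaN).
* MCC with a vanishing denominator is 0.
* One global seed is expanded into independent per-stage seeds by hashing
  the stage name through numpy's SeedSequence; all seeds stay below 2^31.

## Problem sizes

Default test-scale runs use the study-shaped K dataset (768 fragments),
200-fragment clustering simulations (20 recovery replicates, 100
false-split replicates) and a 600-fragment held-out set for the two-layer
experiment; the full 30-repeat resampling evaluation is available through
`repeats`/`--repeats` for production runs.

## Known limitations

* The redundancy filter is fragment-level and ungapped; it is not CD-HIT.
* Bit scores are self-consistently defined (uniform null, no E-values);
  they are not HMMER bit scores numerically.
* The chi-squared scan tests ~190 position pairs per node without
  multiplicity correction — by design, following the published 34.3
  per-pair cutoff — so on motif-free data a majority of runs still find
  some significant pair (measured ≈ 0.6 at 200 fragments). The
  maximum-cluster-size stop and the consensus split keep such spurious
  splits shallow, but users clustering weakly structured data should
  expect nuisance leaves.
* Five-way splits and the summed-chi2 position criterion are provided but
  lightly exercised compared to the binary/pair defaults.
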