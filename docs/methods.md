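# Methods

## Problem and model

`hlabind` classifies peptide–HLA class I interactions into high-affinity
(IC50 ≤ 50 nM) and low-affinity (IC50 > 50 nM) binders from sequence alone,
and — more importantly — identifies *which kinds* of sequence information
drive the classification. The unit of analysis is an (HLA protein, peptide)
pair; the pipeline has four stages:

1. **Encoding.** Each pair becomes a 340-dimensional vector
   `V = V_pro ‖ V_pep`. `V_pro` (270) is the HLA protein's amino-acid
   composition (AAC, 20 frequencies in alphabetical residue order) plus
   λ = 50 pseudo-amino-acid-composition (Pse-AAC) sequence-order
   correlation factors for each of five physicochemical property scales.
   `V_pep` (70) is the same construction for the peptide with λ = 10.
   The per-property correlation factor at lag *j* is

       θ_j = (1 / (L − j)) · Σ_{i=1..L−j} (H(R_{i+j}) − H(R_i))²

   where H is the standardized property value of a residue, and the
   Pse-AAC component for lag *j* is `w·θ_j / (1 + w·Σ_m θ_m)` with
   w = 0.15 (the AAC frequencies sum to one, which is why the classic
   normalizing denominator reduces to `1 + w·Σθ`).
2. **Ranking.** Features are discretized into three states (split at
   mean ± 0.5 sd) and ranked by mutual information with the label
   (MaxRel) and by greedy minimum-redundancy maximum-relevance (mRMR):
   first pick = most relevant feature; pick *t* maximizes
   `MI(f, y) − mean_{s∈selected} MI(f, s)`.
3. **Incremental feature selection (IFS).** The nested prefixes
   S_1 ⊂ S_2 ⊂ … of the mRMR list are each evaluated by stratified
   k-fold cross-validation (k = 10 default); fold predictions are pooled
   into one confusion matrix per prefix and SN/SP/ACC/MCC computed from
   the pool. The optimal feature set maximizes MCC (ties → smallest set).
4. **Category analysis.** A selected set is decomposed by entity
   (protein/peptide) × category (AAC, CD, EC, MV, 2nd_stru, polarity) into
   *relative ratios* (selected / total per cell), showing which feature
   families survive de-redundancy.

## Property scales

The five scales — codon diversity (CD), electrostatic charge (EC),
molecular volume (MV), secondary-structure propensity (2nd_stru) and
polarity — are the Atchley et al. (2005) factor scores (factors IV, V,
III, II and I respectively), re-standardized to mean 0 / sd 1 over the 20
residues so squared scale differences are comparable across properties.
User-supplied 20-value scales pass through the same standardization.

## Design choices in genuinely open territory

* **Pse-AAC variant.** The per-property ("parallel") type-1 correlation
  with Θ(R_i, R_j) = (H(R_j) − H(R_i))² on a single standardized property.
  The five separate 50-dimensional property blocks only make sense under a
  per-property distance, so the combined multi-property variant was not
  used. Amphiphilic/series-correlation flavours are out of scope.
* **Lags beyond sequence length.** θ_j := 0 when j ≥ L instead of an
  error: an 8–10-mer peptide cannot support λ = 10 otherwise. These
  components are structurally zero, not estimates.
* **Protein region.** The full allele sequence as given in the FASTA is
  encoded; no slicing to the mature chain or binding groove is attempted
  (the encoder is agnostic, so pre-sliced input works unchanged).
* **Discretization for MI.** Three states at mean ± 0.5 sd — the classic
  mRMR default for continuous descriptors. MI is reported in bits (log2);
  rankings are base-invariant.
* **Pooled-fold metrics.** One confusion matrix over all k folds rather
  than a mean of per-fold metrics: with a ~12.5% positive class, per-fold
  MCC estimates are unstable and their mean is biased toward 0.
* **Tie rules.** Smaller feature index (ranking), smaller training-row
  index (1-NN distance ties), smaller set size (IFS optimum), everywhere —
  so every stage is exactly reproducible under a fixed seed.
* **Stratified folds.** Class proportions are enforced per fold (round-robin
  within a seeded per-class shuffle) because plain folds at a 12.5%
  positive rate can lose the positive class entirely. A class with fewer
  members than k is a hard error.
* **MCC zero-denominator convention = 0.** Degenerate predictors (e.g. an
  all-negative classifier on imbalanced data) occur in practice; they score
  SN = 0, SP = 1, ACC = 1 − positive rate, MCC = 0.
* **Dagging.** m = 9 disjoint subsets of floor(N/m) samples each, drawn
  without replacement under a seed; base learner defaults to 1-NN;
  majority vote, with an even effective vote (after dropping single-class
  subsets) falling back to the majority training class.
* **No feature standardization before 1-NN by default**; the `ifs` command
  exposes `--zscore` for users who want isotropic distances.

## Synthetic data: what it emulates, and what it does not

The generator (`hlabind.simulate`) produces datasets shaped like curated
MHC class I binding compilations: 20 allele sequences of length 365
derived from one base sequence by ≤ 15 point substitutions each (pairwise
identity > 90%, mimicking the strong sequence similarity among HLA class I
alleles), 3,000 (allele, peptide, IC50) pairs with 8–10-mer peptides, and
a ~12.5% high-affinity class at the 50 nM cutoff.

The binding signal is planted at the canonical class I anchor positions
(P2 and the C-terminus): pairs destined high-affinity draw each anchor
from the hydrophobic set {L, V, I, M} with probability 0.9; the latent
score is `β · (#favoured anchors) + N(0, 1)` with β = 3 by default, and
IC50 is a monotone log-scale map of the score centred so that scores above
the empirical (1 − positive_rate) quantile land at or below 50 nM — the
threshold rule is genuinely exercised, not bypassed. Ground truth (the
informative peptide-AAC feature names and per-pair latent scores) is
emitted as a JSON sidecar. β = 0 removes the enrichment entirely, giving
labels independent of sequence for null calibration.

What the generator does **not** emulate: allele-specific (supertype) anchor
motifs, proteasomal cleavage or TAP-transport biases, peptide length
preferences per allele, assay noise structure, or the redundancy pattern of
repeated peptide measurements. Passing recovery tests therefore shows the
pipeline can find a planted composition signal under realistic shape and
class imbalance — not that it reproduces performance on curated
experimental data, which additionally requires the real allele sequences
and binding measurements.

## Evaluation depths and problem sizes

Unit tests exercise full-depth IFS on small feature spaces. The stochastic
recovery suites and the acceptance script run the study conditions
(n = 3,000 pairs, β ∈ {0, 3}, 10 seeds per condition) with the mRMR list
computed to depth 60 and the 1-NN IFS curve evaluated over those first 60
prefixes; the top-decile recovery check uses the first 34 ranks. Greedy
mRMR prefixes are invariant to truncation depth, so these are the same
ranks a full 340-deep run would produce; 60 prefixes is comfortably past
where the planted-signal optimum lands while keeping the whole
double-condition sweep around a minute. The 1-NN IFS evaluator uses an
incremental squared-distance update across nested prefixes; it is tested
to agree exactly with per-prefix refitting.

## Numerical and degenerate-input conventions

* AAC of an empty sequence, MI of mismatched lengths, non-binary labels,
  IC50 ≤ 0, empty confusion matrices: domain errors (`ValueError`).
* Non-standard residues (B, J, O, U, X, Z) reject the whole record with a
  warning — substitution would silently distort the descriptor math.
* Constant feature vectors discretize to a single state and carry zero MI.
* All randomness flows through `numpy.random.default_rng(seed)`; rerunning
  any stage with the same seed and inputs is byte-identical on disk.

## Known limitations

* The mutual-information estimator is the empirical plug-in on 3-state
  discretized features; it is biased upward for small n and is used for
  *ranking*, not for effect-size inference.
* 1-NN distances are computed on unstandardized descriptors by default, so
  blocks with larger numeric spread (AAC) dominate the metric.
* The IFS optimum is a model-selection maximum over many correlated CV
  estimates; the reported optimal MCC is optimistically biased and should
  be confirmed on held-out data for real applications.
* Binary labels only; multi-class and regression on IC50 are out of scope.
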