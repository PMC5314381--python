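# hlabind

Sequence-feature machine learning for peptide–HLA class I binding
affinity: which properties of the HLA protein and of the presented
peptide decide whether a pair binds tightly?

HLA class I molecules present 8–10-mer peptides to CD8+ T cells; a pair is
conventionally called **high-affinity** when its competition-assay IC50 is
≤ 50 nM. `hlabind` encodes every (HLA protein, peptide) pair as a
340-dimensional composition vector, ranks the features by
mutual-information criteria, selects an optimal feature subset with
cross-validated classifiers, and decomposes the selection by feature
category — for immunoinformaticians who want interpretable *feature-level*
answers rather than a black-box binding predictor.

## Method

Each pair is encoded as `V = V_pro ‖ V_pep`:

| entity  | AAC | CD | EC | MV | 2nd_stru | polarity | total |
|---------|----:|---:|---:|---:|---------:|---------:|------:|
| protein |  20 | 50 | 50 | 50 |       50 |       50 |   270 |
| peptide |  20 | 10 | 10 | 10 |       10 |       10 |    70 |

AAC is the 20-vector of residue frequencies. The five property blocks are
pseudo-amino-acid-composition (Pse-AAC) sequence-order correlation factors
computed on standardized physicochemical scales (codon diversity,
electrostatic charge, molecular volume, secondary structure, polarity —
the Atchley factor scores): at lag *j*,
`θ_j = mean_i (H(R_{i+j}) − H(R_i))²`, weighted into components
`w·θ_j / (1 + w·Σθ)` with w = 0.15, λ = 50 per scale for the protein and
λ = 10 for the peptide.

Features are then ranked two ways — **MaxRel** (mutual information with
the high/low label) and **mRMR** (greedily maximizing relevance minus mean
redundancy with already-picked features) — and **incremental feature
selection (IFS)** evaluates the nested prefixes S₁ ⊂ S₂ ⊂ … of the mRMR
list with stratified 10-fold cross-validation, choosing the prefix that
maximizes the Matthews correlation coefficient (MCC). Four classifier
backends are available behind one scikit-learn-style contract:
1-nearest-neighbour and a disjoint-subset voting ensemble (dagging) are
implemented natively; random forest and linear SVM delegate to
scikit-learn.

A synthetic-data generator ships as a first-class module: it emulates
curated binding data (highly similar allele sequences, 8–10-mer peptides,
~12.5% positives at the 50 nM cutoff) with a plantable anchor-residue
signal at peptide position 2 and the C-terminus, so every stage is
testable with known ground truth. See `docs/methods.md` for the full
model, conventions and limitations.

## Worked example

Run the whole pipeline on synthetic data with a planted anchor signal
(effect size β = 3, 1,000 pairs):

```sh
hlabind all --outdir demo --n-pairs 1000 --beta 3 \
            --algorithm nna --max-features 40 --seed 42
```

The run logs the IFS optimum —

```
INFO hlabind: encoded 1000 records x 340 features -> demo/features.tsv
INFO hlabind: nna: optimal size 17, MCC 0.290
```

— meaning the best 1-NN classifier used the top 17 mRMR features and
reached a pooled cross-validated MCC of 0.29 (against ~0 for a label-blind
predictor at this class imbalance). The head of `demo/mrmr_list.tsv`
recovers exactly the planted signal, the peptide-AAC components of the
favoured anchor residues {L, V, I, M}:

```
rank  feature_index  feature_name  criterion  score
1     287            pep_AAC_V     mRMR       0.0237
2     277            pep_AAC_I     mRMR       0.0171
3     279            pep_AAC_L     mRMR       0.0141
4     280            pep_AAC_M     mRMR       0.0093
```

and `demo/breakdown.tsv` (top 10% of 340 features = 34) shows the
selection concentrating in peptide composition — 17 of the 20 peptide-AAC
features selected, a relative ratio of 0.85, versus ≤ 0.02 for every
protein category:

```
entity   category  selected  total  ratio
protein  AAC       0         20     0
peptide  AAC       17        20     0.85
peptide  CD        4         10     0.4
peptide  polarity  4         10     0.4
```

Stages can also be run separately (`simulate`, `encode`, `rank`, `ifs`,
`analyze`) on your own FASTA + interaction TSV, or driven from Python:

```python
import hlabind as hb

dataset, truth = hb.generate_dataset(hb.GeneratorConfig(n_pairs=1000, seed=42))
X, y, catalogue = hb.encode_dataset(dataset)         # (1000, 340)
ranked = hb.mrmr_rank(X, y, names=catalogue.names)
sel = hb.IncrementalFeatureSelector(cv=10, random_state=42).fit(X, y, ranked)
print(sel.optimal_size_, sel.optimal_mcc_)
```

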