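# sixma

Prediction of DNA N6-methyladenine (6mA) sites in plant genomes from
sequence alone, with a two-layer ensemble of support vector machines
and extremely randomized trees.

## The problem

6mA is an epigenetic mark on the adenine base that, in plants such as
rice, clusters at GAGG-containing contexts and influences gene
regulation. Experimental detection (SMRT kinetics, immunoprecipitation)
is expensive, so sequence-based classifiers are used to screen
candidate sites: given a 41-nt window — 20 nt of upstream context, a
central adenine, 20 nt downstream — is the central adenine methylated?

## The model

Each window is encoded under five complementary representations:

| encoding | dim | idea |
|----------|-----|------|
| NUM | 40 | flanking bases mapped alphabetically to 0.25/0.50/0.75/1.0 |
| MBE | 164 | per-position one-hot over (A, C, G, T) |
| DBE_LPF | 200 | 4-bit codes of the 40 overlapping dinucleotides + local position-specific dinucleotide frequencies |
| RFHC | 164 | ring/hydrogen-bond/amino chemical triple per base + cumulative base density |
| KNN | 7 | fraction of methylated sequences among the n = 2, 4, ..., 128 most similar training windows (+2 match / −1 mismatch similarity) |

For every encoding and classifier family (RBF-SVM tuned over
C ∈ {2⁻⁵…2¹⁵}, γ ∈ {2⁻¹⁵…2⁻⁵}; extra-trees tuned over ntree, mtry,
nsplit), features are ranked by the univariate F-score

F(i) = [ (x̄ᵢ⁺ − x̄ᵢ)² + (x̄ᵢ⁻ − x̄ᵢ)² ] / [ s²ᵢ⁺ + s²ᵢ⁻ ]

and a sequential forward search over prefixes of the ranking keeps the
cross-validation-accuracy-maximising subset (the 7-dim KNN encoding is
used as is). The five per-encoding probability streams are then fused
per classifier family with simplex-grid weights w (Σw = 1, step 0.1)
chosen to maximise accuracy on out-of-fold predictions (layer 1), and
the SVM and ERT scores are averaged with equal weights and thresholded
at 0.5 (layer 2). Reported metrics are SN, SP, ACC, MCC and AUC.

A bundled generator (`sixma.simdata`) emulates the benchmark structure
(balanced 41-nt windows, central adenine, GAGG-enriched positives) so
the whole pipeline is testable without downloading data.

## Worked example

`examples/04_train_ensemble.py` trains a reduced configuration on
100+100 synthetic windows and evaluates an independent 100+100 draw:

```
layer-1 weights (SVM): NUM=0.0, MBE=0.0, DBE_LPF=0.3, RFHC=0.7, KNN=0.0
layer-1 weights (ERT): NUM=0.0, MBE=0.6, DBE_LPF=0.2, RFHC=0.1, KNN=0.1
independent evaluation (n=200):
  SN=0.900 SP=0.770 ACC=0.835 MCC=0.676 AUC=0.932
```

The weights show which encodings each classifier family found
informative on this draw; ACC/MCC far above chance (0.5 / 0) mean the
ensemble recovered the planted motif and compositional signal. The
other examples cover simulation (`01`), the encoders (`02`), F-score +
forward search (`03`), and cross-validation, ΔACC robustness and
McNemar model comparison (`05`).

Shell interface for the same workflows:

```bash
sixma simulate --n-pos 400 --n-neg 400 --ag-bias --seed 1 --out-prefix data/train
sixma train data/train_pos.fasta data/train_neg.fasta --small-grids --out model.joblib
sixma predict model.joblib candidates.fasta --out calls.tsv
sixma evaluate data/test_pos.fasta data/test_neg.fasta --mode holdout --model model.joblib
```

## Scope notes

Forward strand only; windows near contig edges are dropped when
scanning longer sequences; RF and XGBoost are available as experimental
plug-in classifier families. See `docs/methods.md` for the full model
description, parameter defaults and limitations.
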