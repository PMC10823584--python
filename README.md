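# neoforest

Prediction of cancer neo-epitope immunogenicity from mutant/wild-type
peptide pairs and their HLA class I restriction, using an ICORE-based
Random Forest ensemble.

## The problem

Somatic point mutations in tumours produce mutated peptides that, when
presented on MHC class I, can be recognised by CD8+ T cells. Deciding
which of the thousands of candidate mutations in a tumour are actually
*immunogenic* is the central computational step in neo-antigen vaccine
design. Presentation alone (predicted MHC binding) is necessary but not
sufficient; features that relate the mutant to its unmutated (wild-type)
counterpart — how disruptive the mutation is, how abundant the source
protein is, where in the binding motif the mutation falls — carry
additional signal.

`neoforest` implements that pipeline end to end for peptides of length
8–12:

1. **ICORE extraction** — every contiguous 8–12-mer sub-window of the
   reported mutant peptide is scored with a presentation %Rank predictor;
   the window with the lowest rank (the *ICORE*) is the predicted
   presented sequence. The wild-type ICORE is the wild-type substring at
   the same coordinates.
2. **Anchor profiles** — per (allele, length), position-specific residue
   frequencies are estimated from predicted strong binders
   (%Rank ≤ 0.25) with a pseudo-count correction of weight β = 20, and
   converted to positional Kullback–Leibler information content
   IC ∈ [0, 1]. Positions with IC ≥ 0.2 are anchors. Five weighting
   schemes (`None`, `Normal` = 1−IC, `NormalMask`, `Inverted` = IC,
   `InvertedMask`) turn IC into per-position weights for composition
   features.
3. **Features** — the base model input is the 20-dimensional weighted
   amino-acid composition of the ICORE plus its %Rank (dimension 21).
   Optional features: wild-type %Rank, the scaled rank agretopicity
   |Rank_mut − Rank_wt| · Rank_mut / Rank_wt, BLOSUM62 and codon
   single-nucleotide mutation scores, the BLOSUM62 k-mer kernel
   self-similarity of mutant vs wild-type, four physico-chemical
   descriptors, expression (TPM, median-imputed when missing), and a
   precomputed foreignness score.
4. **Leakage-free partitioning** — Hobohm-1 redundancy reduction under
   the k-mer kernel (threshold 0.9) followed by round-robin fold dealing
   and maximum-similarity reinsertion, so no two folds share similar
   peptides.
5. **Ensemble** — nested 10-fold cross-validation trains one Random
   Forest (300 trees, depth 8, min 7 samples/leaf, pruning α = 1e-5) per
   ordered fold pair: 90 members. Out-of-fold scores use the 9 members
   that never saw the held-out fold; external predictions average all 90.
6. **Calibration and statistics** — scores are reported as 0–100
   percentile ranks against randomly mutated proteome background
   peptides (0 = most immunogenic-like). Evaluation utilities provide
   ROC AUC, partial AUC (FPR ≤ 0.1), paired bootstrap model comparison,
   one-sided proportion and Welch tests, and harmonic-mean consensus
   model selection.

No external binary is required: a deterministic motif-PSSM surrogate
stands in for the presentation predictor (precomputed NetMHCpan-4.1
output files can be plugged in instead), and a synthetic-data module
generates datasets with the structure of curated neo-epitope databases
(length and allele skew, ~21% positive rate, log-normal TPM) and
controllable injected signal.

## Worked example

```bash
neoforest make-synthetic --n 300 --seed 5 --out neoepitopes.csv
neoforest train --input neoepitopes.csv --model-dir model --k 4 --seed 5 --background-size 500
neoforest predict --input neoepitopes.csv --model-dir model --out predictions.csv
```

The train step prints

```
trained 12 members; out-of-fold AUC 0.6964; leakage audit max similarity 0.8963 (threshold 0.9); model at model
```

— 12 members because nested k-fold training fits k·(k−1) forests
(k = 4 here; the default k = 10 gives 90), an out-of-fold AUC of 0.70 on
this small default-signal dataset, and confirmation that no cross-fold
peptide pair exceeds the 0.9 similarity threshold. The first prediction
rows look like:

```
mutant_peptide  hla_allele icore_mut  rank_mut  prediction_score  percentile_rank
    SETICACTPE HLA-A*01:01 SETICACTP     40.45          0.125225             97.8
      QCPCWWKT HLA-A*01:01  QCPCWWKT     81.25          0.343612             22.2
    NFRYFIRNVN HLA-B*07:02 FRYFIRNVN     39.74          0.201602             65.6
     RTDQTLCQP HLA-A*02:01 RTDQTLCQP     11.68          0.169905             81.2
```

`icore_mut` is the predicted presented sub-peptide (note the trimmed
termini on rows 1 and 3), `rank_mut` its presentation percentile rank,
`prediction_score` the ensemble's mean positive-class probability and
`percentile_rank` its position among mutated background peptides —
lower means more immunogenic-like.

The same steps are available as library calls
(`make_neoepitope_dataset`, `train_pipeline`, `predict_pipeline`); see
`docs/methods.md` for the model description and parameter choices.

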