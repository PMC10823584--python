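# Methods

This note documents the model, its parameters and the design decisions
behind `neoforest`, in the spirit of the methods documentation of
packages like statsmodels or scanpy: what is computed, under what
assumptions, and which choices were genuinely open.

## Rank prediction and the surrogate

All MHC presentation scores are eluted-ligand percentile ranks
(%Rank ∈ [0, 100], lower = stronger predicted presentation). The package
defines a `RankPredictor` contract and ships two backends:

* **Precomputed tables** parsed from NetMHCpan-4.1 textual output
  (peptide-list or pseudo-fasta mode; both emit the same score-table
  shape). The parser locates the `Peptide`, `MHC` and `%Rank_EL` columns
  from each block header and tolerates variable column spacing.
* **A deterministic motif-PSSM surrogate.** Each surrogate allele holds,
  per length 8–12, a (length × 20) log-preference table: background
  noise N(0, 0.1) everywhere, with 2–3 anchor positions (position 2, the
  C terminus, and for half the alleles position 5) assigning +3.0 to two
  preferred residues and −1.0 to the rest. A peptide's raw score is the
  sum of its per-position log-preferences; the percentile rank is
  100 × (fraction of a seeded 10,000-peptide uniform-random background
  with raw score ≥ query), floored at 0.01 so downstream rank ratios
  are defined. This mirrors %Rank semantics exactly (ranks of random
  peptides are uniform on [0, 100] by construction) while being instant
  to build and fully reproducible from a seed. Surrogate motifs are a
  deterministic function of (allele name, base seed), so a dataset
  generated and a model trained with the same seed agree on every rank.

The surrogate is a testing device, not an approximation of any real
allele's motif: anchor positions and preferred residues are synthetic.

## ICORE extraction

All contiguous sub-windows of length 8..min(12, L) of the mutant peptide
are scored; the window with the lowest %Rank is the ICORE. Ties (exact
rank equality) break towards the longer window, then the smaller offset
— the choice is arbitrary but fixed so results are reproducible.
The aligned wild-type ICORE is the wild-type substring at the mutant
ICORE's (offset, length); this requires equal-length pairs, which is why
frameshift records are filtered. Only contiguous windows are considered
(no gapped cores): the ICORE models N/C-terminal trimming, not the
9-mer binding core's deletions. Coordinates are 0-based half-open
internally and 1-based in all user-facing output.

## Record filters

Records are rejected (with per-reason counts) for: non-canonical
residues (X/B/Z/U are rejected, not imputed — BLOSUM62 and the codon
table are defined for the canonical 20 only), missing wild-type
annotation, length mismatch (frameshift), length outside 8–12,
mutant = wild-type (a zero-mutation record is undefined under the
mutation-derived features), unresolvable allele names, and more than 3
mismatches between mutant and wild-type ICOREs. Allele names are
canonicalised to the starred form (`A0201`, `HLA-A02:01` →
`HLA-A*02:01`); unknown patterns are rejected rather than guessed.
Duplicate (mutant peptide, allele) pairs are collapsed before training:
positive if any duplicate is positive, negative only if all labelled
duplicates are negative.

## Anchor profiles and weighting schemes

Per (allele, length), position-specific frequencies are estimated from
1,000 predicted strong binders (%Rank ≤ 0.25, rejection-sampled from a
seeded random-peptide stream) without sequence weighting and with a
pseudo-count low-count correction of weight β = 20:

    freq[p][a] = (n·f_obs[p][a] + β·q[a]) / (n + β)

The background q is uniform (1/20); a proteome-frequency background can
be supplied instead. Positional information content is Kullback–Leibler
divergence to q (or log2(20) − entropy for the Shannon variant; the two
coincide for uniform q), normalised by log2(20) so IC ∈ [0, 1] — the
(1 − IC) weighting schemes require this scale, and the 0.2 anchor
threshold is applied to the normalised value. Whether the published 0.2
threshold refers to raw bits or the normalised scale is ambiguous; the
normalised reading keeps the threshold meaningful for all lengths and
is configurable. Likewise "low count correction of 20" is implemented
as the simple blending above rather than a Henikoff/Altschul
pseudo-count scheme; the blending formula is the documented default.

Weighting schemes map IC to per-position weights: `None` → 1,
`Normal` → 1−IC, `NormalMask` → 1−IC with anchors (IC ≥ 0.2) zeroed,
`Inverted` → IC, `InvertedMask` → IC with non-anchors zeroed. An
all-zero weight vector (possible under extreme masking) falls back to
uniform weights with a logged warning.

## Features

* **Weighted composition** (20 values): OneHot — weighted residue
  frequencies (a probability vector); BLOSUM62 — the weighted mean of
  BLOSUM62 rows. Both divide by the weight sum; whether the BLOSUM
  variant should be renormalised differently is undocumented upstream,
  so the weighted mean is used for both and recorded in the schema.
* **Scaled rank agretopicity** = |Rank_mut − Rank_wt| · Rank_mut/Rank_wt.
  The scaling separates pairs like (0.1, 1) and (10, 100) that share the
  ratio 0.1 but differ completely in presentation plausibility. The
  plain ratio is also available. A zero wild-type rank is clamped to
  1e-3 with a warning (the surrogate never emits 0).
* **Mutation scores**, summed over ICORE mismatch positions:
  BLOSUM62[wt][mut], and the codon score — the probability that one
  random single-nucleotide substitution of a random synonymous codon of
  the wild-type residue yields the mutant residue (standard genetic
  code, stop codons count as misses, no codon-usage weighting since no
  usage table is specified upstream). Derived by enumeration at import.
* **Kernel self-similarity**: the BLOSUM62 k-mer string kernel with
  windows k = 3–8; each window pair scores the product over aligned
  positions of exp(β_k · BLOSUM62), with the published kernel constant
  β_k = 0.11387 (configurable); cosine normalisation makes
  self-similarity exactly 1. By construction the kernel weights peptide
  centres more heavily than termini.
* **Physico-chemical descriptors** of the ICORE: Ikai's aliphatic index
  100·(x_A + 2.9·x_V + 3.9·(x_I + x_L)); mean Kyte–Doolittle hydropathy
  (GRAVY, via Biopython); isoelectric point (Bjellqvist pK set, via
  Biopython's ProtParam); Boman index as the mean negated side-chain
  water→cyclohexane transfer free energy (Pro = 0 by convention,
  positive = interaction-prone).
* **Expression** (TPM) is passed through and median-imputed when
  missing; **foreignness** is accepted as a precomputed column only.

The feature schema (names and order) is serialised with the model and
prediction refuses mismatched schemas.

## Partitioning

Hobohm-1 scans peptides in input order (no pre-sort; input order keeps
the procedure reproducible from the raw file): a peptide joins the
cluster of the maximally similar representative if that similarity
exceeds 0.9, else becomes a representative. Similarity is the same
k-mer kernel as the self-similarity feature, computed on full mutant
peptides. Representatives are shuffled with the seed and dealt
round-robin into k folds (balanced to within one); clustered peptides
are reinserted into their representative's fold; duplicate records
share their peptide's fold. The module's defining invariant — no
cross-fold pair above the threshold — is asserted by a brute-force
audit in the tests and logged after every training run.

## Ensemble

Nested k-fold cross-validation: for each ordered pair of distinct folds
(o, i), one `RandomForestClassifier` (300 trees, max depth 8, min 7
samples per leaf, cost-complexity pruning α = 1e-5, single-threaded,
member-specific seeds derived from the run seed) is fitted on the
remaining k−2 folds — k·(k−1) members, 90 at the default k = 10.
The "regularising factor alpha" of the forest is interpreted as
cost-complexity pruning strength, the only alpha-named regulariser in
common forest implementations. The inner fold serves as the member's
held-out slice for diagnostics; no inner model selection is performed,
and out-of-fold scores for fold o average the k−1 members that excluded
o (external predictions average all members — the pooled-ensemble
reading). No class weighting is applied; this is exposed in config.
Impurity-decrease importances are averaged over members and
renormalised to sum to 1.

Percentile calibration scores a background of randomly mutated proteome
peptides with the same schema and maps a query score s to
100 × #{background ≥ s} / #background — 0 means more immunogenic-like
than every background peptide. The package default background is 5,000
peptides (the hosted-service scale of ~110,000 is linear extra cost).

## Evaluation statistics

* ROC AUC via rank statistics (ties count ½); partial AUC integrates
  the ROC to FPR = 0.1 and divides by 0.1 when normalised (the simplest
  normalisation; no standardised variant is implied).
* The paired bootstrap resamples record indices with replacement — the
  same indices for both score vectors — and reports
  p = 1 − (#rounds with AUC₁ > AUC₂)/#rounds, so small p means method 1
  is reliably better. The two printed formulations of this quantity in
  the source literature disagree (fraction of wins vs one minus it);
  the "one minus" reading is implemented because it is the one under
  which small p means improvement. Single-class rounds are redrawn.
* One-sided two-proportion z-test with pooled variance; one-sided Welch
  t-test with Satterthwaite degrees of freedom (0.5 by convention for
  two degenerate equal-mean samples).
* Consensus selection ranks model configurations by the harmonic mean
  2ab/(a+b) of a cross-validation AUC and an external-test AUC,
  penalising configurations that excel on only one dataset.

## Synthetic data

The generator emulates the *structure* of curated neo-epitope training
sets, not their biology: lengths 8–12 skewed to 9/10-mers, a skewed
allele usage (the most frequent allele takes 40% of records), ~21%
positive rate at the default signal, log-normal TPM (meanlog 1.5,
sdlog 1.5), mutants with 1–3 point substitutions (85/10/5%), and a 5%
near-duplicate rate (exact copies under another allele, or conservative
single substitutions that stay above the 0.9 similarity threshold) to
exercise the redundancy machinery. Labels are drawn from a logistic
model on features computed through the real pipeline — z-scored
−log10(ICORE rank), negated BLOSUM mutation score and log10 TPM — with
intercept −1.45 so the default weights (1.0, 0.5, 0.5) land near the
21% positive rate; `SignalSpec.strong()` (3.0, 1.5, 1.5, no label
noise) is used for recovery runs and `SignalSpec.null()` for negative
controls. Because labels depend on pipeline-computed quantities,
recovering the signal end-to-end genuinely exercises ICORE extraction,
feature assembly, partitioning and training.

What passing tests therefore show: the pipeline recovers injected
signal through its own feature definitions, does not hallucinate signal
under permuted labels, and never leaks similar peptides across folds.
What they do not show: performance on real neo-epitope data, which
depends on real binding motifs, assay-derived label noise and biased
allele/length composition that the generator does not model.

## Problem sizes and numerical choices

Recovery and member-count checks run on 2,000-record synthetic sets
with a 2,000-peptide calibration background and 1,000 strong binders
per profile (tests use smaller profiles where only shape matters);
these sizes give stable statistics while keeping a full training run in
the low minutes on one core. Frequencies are strictly positive for
β > 0, so information content needs no zero-guard in normal operation;
beta = 0 profiles guard the log explicitly. Percentile lookups use
binary search on sorted backgrounds. All randomness flows from
explicit seeds; training, partitioning and generation are bit-for-bit
reproducible given (data, seed).

## Known limitations

* The surrogate predictor's motifs are synthetic; absolute feature
  importances and AUCs on synthetic data do not transfer to real data.
* The codon mutation score averages over synonymous codons uniformly;
  organisms' codon usage would shift the probabilities.
* Hobohm-1 is order-dependent by design; a different input order can
  yield a different (equally valid) representative set.
* The full-peptide input mode scores complete sequences only up to
  length 12 (the predictor contract's range).
* Foreignness and the three expression aggregation variants are
  accepted as precomputed columns, never recomputed.
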