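"""Synthetic data generation for end-to-end testing and calibration.

Real training data for this problem are curated neo-epitope databases and
an external MHC presentation predictor; neither is required here.  This
module emulates their structure: surrogate HLA alleles with 2-3 anchor
positions and a skewed usage distribution (the most common allele covers
~40% of records, mirroring HLA-A*02:01's share in curated sets), a random
"proteome" chopped into 8-12-mers with log-normal TPM values, and
labelled mutant/wild-type datasets whose immunogenicity labels are drawn
from a logistic model on features computed through the real pipeline
(ICORE %Rank, BLOSUM mutation score, log expression) — so parameter
recovery genuinely exercises ICORE extraction and feature code.

Dataset shape defaults follow the curated training set: peptide lengths
8-12 skewed towards 9/10-mers, ~21% positive rate, point mutations only
(85% single, 10% double, 5% triple substitutions).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

from .binding import SurrogateAllele, SurrogatePredictor
from .features import mutation_scores
from .matrices import ALPHABET
from .records import NeoEpitopeRecord, validate_and_filter

_ALLELE_NAMES = [
    "HLA-A*02:01", "HLA-B*07:02", "HLA-A*01:01", "HLA-A*03:01",
    "HLA-B*08:01", "HLA-A*24:02", "HLA-B*15:01", "HLA-C*07:01",
    "HLA-A*11:01", "HLA-B*44:02", "HLA-C*04:01", "HLA-A*68:01",
]

#: Peptide length usage, skewed towards 9/10-mers as in curated sets.
LENGTH_PROBS = {8: 0.08, 9: 0.42, 10: 0.27, 11: 0.13, 12: 0.10}

#: Mutation count distribution: mostly single point mutations.
N_MUTATION_PROBS = {1: 0.85, 2: 0.10, 3: 0.05}

#: Log-normal TPM parameters (natural-log mean and sd).
TPM_MEANLOG = 1.5
TPM_SDLOG = 1.5


@dataclass
class SurrogateAlleleSet:
    """Surrogate alleles plus their (skewed) usage distribution."""

    alleles: list[SurrogateAllele]
    usage: np.ndarray  # probabilities, sums to 1

    def predictor(self) -> SurrogatePredictor:
        return SurrogatePredictor(self.alleles)

    def sample_names(self, n: int, rng: np.random.Generator) -> list[str]:
        idx = rng.choice(len(self.alleles), size=n, p=self.usage)
        return [self.alleles[i].name for i in idx]


def make_alleles(n: int = 6, seed: int = 0) -> SurrogateAlleleSet:
    """Build n surrogate alleles with 2-3 anchors and skewed usage.

    Every allele anchors positions 2 and the C terminus; half additionally
    anchor position 5.  The first allele takes ~40% of the usage mass, the
    remainder decays geometrically.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    from .pipeline import surrogate_allele_for

    alleles = [
        surrogate_allele_for(_ALLELE_NAMES[i % len(_ALLELE_NAMES)], seed)
        for i in range(n)
    ]
    if n == 1:
        usage = np.array([1.0])
    else:
        rest = 0.6 * (0.55 ** np.arange(n - 1))
        usage = np.concatenate([[0.4], rest / rest.sum() * 0.6])
    return SurrogateAlleleSet(alleles=alleles, usage=usage)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(ALPHABET[c] for c in rng.integers(0, 20, size=length))


def make_background_proteome(
    n_peptides: int, seed: int = 0, protein_length: int = 300
):
    """Random proteins chopped into 8-12-mers with single-position mutants.

    Returns (rows, proteins): rows is a list of dicts with wt_peptide,
    mut_peptide and a log-normal TPM (inherited from the source protein);
    proteins is the list of (name, sequence) the peptides came from.
    """
    if n_peptides < 1:
        raise ValueError("n_peptides must be >= 1")
    rng = np.random.default_rng(seed)
    lengths = list(LENGTH_PROBS)
    length_p = np.array(list(LENGTH_PROBS.values()))
    proteins: list[tuple[str, str]] = []
    rows: list[dict] = []
    while len(rows) < n_peptides:
        seq = random_protein(protein_length, rng)
        tpm = float(rng.lognormal(TPM_MEANLOG, TPM_SDLOG))
        proteins.append((f"synthetic_protein_{len(proteins) + 1}", seq))
        pos = 0
        while pos + 12 <= len(seq) and len(rows) < n_peptides:
            length = int(rng.choice(lengths, p=length_p))
            wt = seq[pos:pos + length]
            mut = _mutate(wt, 1, rng)
            rows.append({"wt_peptide": wt, "mut_peptide": mut, "tpm": tpm})
            pos += length
    return rows, proteins


def write_fasta(proteins: Sequence[tuple[str, str]], path) -> None:
    """Write synthetic source proteins as FASTA for calibration runs."""
    with open(path, "w") as fh:
        for name, seq in proteins:
            fh.write(f">{name}\n")
            for i in range(0, len(seq), 60):
                fh.write(seq[i:i + 60] + "\n")


def background_records(
    n: int, allele_set: SurrogateAlleleSet, seed: int = 0
) -> list[NeoEpitopeRecord]:
    """Unlabelled background records (random mutated proteome peptides with
    TPM and skewed allele usage) for percentile calibration."""
    rows, _ = make_background_proteome(n, seed=seed)
    rng = np.random.default_rng(seed + 1)
    names = allele_set.sample_names(n, rng)
    return [
        NeoEpitopeRecord(
            mutant_peptide=row["mut_peptide"],
            wt_peptide=row["wt_peptide"],
            allele=name,
            expression_tpm=row["tpm"],
            source_id=f"bg_{i}",
        )
        for i, (row, name) in enumerate(zip(rows, names))
    ]


@dataclass
class SignalSpec:
    """Logistic label model on pipeline-computed features.

    The linear predictor is

        intercept + w_rank * z(-log10 rank_mut) + w_blosum * z(-blosum)
                  + w_tpm * z(log10 tpm)

    with features z-scored within the generated batch, so low mutant ICORE
    rank, dissimilar mutations and high expression push towards
    immunogenicity.  The intercept targets a ~21% positive rate at the
    default weights; labels are flipped with probability ``label_noise``.
    """

    w_rank: float = 1.0
    w_blosum: float = 0.5
    w_tpm: float = 0.5
    intercept: float = -1.45
    label_noise: float = 0.05
    seed: int = 0

    @classmethod
    def strong(cls, seed: int = 0) -> "SignalSpec":
        """Strong injected signal for parameter-recovery runs."""
        return cls(w_rank=3.0, w_blosum=1.5, w_tpm=1.5,
                   intercept=-1.45, label_noise=0.0, seed=seed)

    @classmethod
    def null(cls, seed: int = 0) -> "SignalSpec":
        """No signal: labels independent of every feature."""
        return cls(w_rank=0.0, w_blosum=0.0, w_tpm=0.0,
                   intercept=-1.45, label_noise=0.0, seed=seed)


def _conservative_variant(
    wt: str, mut: str, rng: np.random.Generator
) -> tuple[str, str]:
    """Near-duplicate of a peptide pair: one conservative substitution
    (high BLOSUM62 score, biased to the termini where the k-mer kernel is
    least sensitive) applied to both sequences at a position where they
    agree, keeping the kernel similarity to the source above the 0.9
    redundancy threshold for most draws."""
    from .matrices import AA_INDEX, BLOSUM62

    agree = [i for i, (a, b) in enumerate(zip(wt, mut)) if a == b]
    pos = agree[0] if rng.random() < 0.5 else agree[-1]
    orig = wt[pos]
    partners = [
        aa for aa in ALPHABET
        if aa != orig and BLOSUM62[AA_INDEX[orig], AA_INDEX[aa]] >= 1
    ]
    repl = partners[rng.integers(0, len(partners))] if partners else "V"
    w, m = list(wt), list(mut)
    w[pos] = m[pos] = repl
    return "".join(w), "".join(m)


def _mutate(wt: str, n_mut: int, rng: np.random.Generator) -> str:
    positions = rng.choice(len(wt), size=n_mut, replace=False)
    seq = list(wt)
    for p in positions:
        choices = [aa for aa in ALPHABET if aa != seq[p]]
        seq[p] = choices[rng.integers(0, 19)]
    return "".join(seq)


def make_neoepitope_dataset(
    n: int,
    alleles: SurrogateAlleleSet,
    signal: Optional[SignalSpec] = None,
    near_duplicate_rate: float = 0.05,
) -> list[NeoEpitopeRecord]:
    """Generate n labelled neo-epitope records through the real pipeline.

    Wild-type peptides are random 8-12-mers; mutants carry 1-3 point
    substitutions; alleles follow the skewed usage distribution; TPM is
    log-normal.  A fraction of records are near-duplicates of earlier ones
    (exact copies under another allele, or single-substitution variants) to
    exercise the redundancy-aware partitioning.  Labels are drawn from the
    SignalSpec's logistic model on ICORE rank, BLOSUM mutation score and
    log TPM, all computed with the package's own pipeline code.
    """
    if n < 50:
        raise ValueError("n must be >= 50 to give both classes a chance")
    signal = signal or SignalSpec()
    rng = np.random.default_rng(signal.seed)
    lengths = list(LENGTH_PROBS)
    length_p = np.array(list(LENGTH_PROBS.values()))
    n_muts = list(N_MUTATION_PROBS)
    n_mut_p = np.array(list(N_MUTATION_PROBS.values()))
    allele_names = alleles.sample_names(n, rng)

    records: list[NeoEpitopeRecord] = []
    for i in range(n):
        if records and rng.random() < near_duplicate_rate:
            src = records[rng.integers(0, len(records))]
            if rng.random() < 0.5:  # exact peptide pair, different allele
                wt, mut = src.wt_peptide, src.mutant_peptide
            else:  # conservative single-substitution variant of an earlier pair
                wt, mut = _conservative_variant(src.wt_peptide, src.mutant_peptide, rng)
        else:
            length = int(rng.choice(lengths, p=length_p))
            wt = random_protein(length, rng)
            mut = _mutate(wt, int(rng.choice(n_muts, p=n_mut_p)), rng)
        records.append(
            NeoEpitopeRecord(
                mutant_peptide=mut,
                wt_peptide=wt,
                allele=allele_names[i],
                expression_tpm=float(rng.lognormal(TPM_MEANLOG, TPM_SDLOG)),
                source_id=f"syn_{i}",
            )
        )

    predictor = alleles.predictor()
    accepted, _ = validate_and_filter(records, predictor)

    rank = np.array([r.icore.mut_rank for r in accepted])
    blosum = np.array(
        [mutation_scores(r.icore.mut_icore, r.icore.wt_icore)[0] for r in accepted]
    )
    log_tpm = np.log10([r.expression_tpm for r in accepted])
    z = (
        signal.intercept
        + signal.w_rank * _zscore(-np.log10(rank))
        + signal.w_blosum * _zscore(-blosum)
        + signal.w_tpm * _zscore(log_tpm)
    )
    prob = 1.0 / (1.0 + np.exp(-z))
    labels = (rng.random(len(accepted)) < prob).astype(int)
    if signal.label_noise > 0:
        flip = rng.random(len(accepted)) < signal.label_noise
        labels[flip] = 1 - labels[flip]
    if len(np.unique(labels)) < 2:
        raise ValueError("degenerate SignalSpec produced a single class")
    for rec, lab in zip(accepted, labels):
        rec.label = int(lab)
    return accepted


def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)
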