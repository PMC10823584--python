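"""Per-record feature computation and model-input assembly.

The base model input is a 21-dimensional vector: the (optionally
position-weighted) amino-acid composition of the mutant ICORE (20 values)
plus the ICORE's predicted presentation %Rank.  Optional features extend
the vector in a fixed schema order: wild-type %Rank, scaled rank
agretopicity, BLOSUM and codon mutation scores, mutant/wild-type kernel
self-similarity, four physico-chemical descriptors, expression (TPM) and a
precomputed foreignness score.

The scaled rank agretopicity is

    |rank_mut - rank_wt| * rank_mut / rank_wt

which keeps the discriminating low-mutant/high-wild-type signature of the
plain rank ratio while penalising pairs where both peptides are non-binders.

Peptide similarity uses a BLOSUM62 k-mer string kernel: every k-mer window
pair (k = 3..8) is scored as the product over aligned positions of
exp(beta * BLOSUM62), summed and cosine-normalised so self-similarity is 1.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from Bio.SeqUtils.ProtParam import ProteinAnalysis

from .matrices import AA_INDEX, BLOSUM62, BOMAN_SCALE, KYTE_DOOLITTLE
from .profiles import ProfileStore, WeightScheme, make_weights
from .records import NeoEpitopeRecord

logger = logging.getLogger(__name__)

#: Published inverse-temperature constant of the exponentiated-BLOSUM kernel.
KERNEL_BETA = 0.11387

#: Floor applied to a zero wild-type rank before forming the rank ratio.
RANK_RATIO_FLOOR = 1e-3

COMPOSITION_NAMES = [f"comp_{aa}" for aa in "ACDEFGHIKLMNPQRSTVWY"]

#: Optional features in fixed schema order.
OPTIONAL_FEATURES = (
    "rank_wt",
    "scaled_agretopicity",
    "blosum_mutation_score",
    "codon_mutation_score",
    "self_similarity",
    "aliphatic_index",
    "hydrophobicity",
    "isoelectric_point",
    "boman_index",
    "expression_tpm",
    "foreignness",
)


class Encoding(str, enum.Enum):
    ONEHOT = "OneHot"
    BLOSUM62 = "BLOSUM62"


def weighted_composition(
    seq: str,
    weights: Sequence[float],
    encoding: Encoding = Encoding.ONEHOT,
) -> np.ndarray:
    """Position-weighted 20-dimensional composition of a peptide.

    OneHot: result[a] = sum_p w[p] * 1[seq[p] == a] / sum_p w[p], a
    probability vector.  BLOSUM62: the weighted mean of the BLOSUM62 rows
    of the residues.  An all-zero weight vector falls back to uniform
    weights with a logged warning.
    """
    weights = np.asarray(weights, dtype=float)
    if len(weights) != len(seq):
        raise ValueError("weight vector length must equal sequence length")
    total = weights.sum()
    if total <= 0:
        logger.warning(
            "all-zero position weights for %r; falling back to uniform", seq
        )
        weights = np.ones(len(seq))
        total = float(len(seq))
    codes = np.array([AA_INDEX[aa] for aa in seq])
    encoding = Encoding(encoding)
    if encoding is Encoding.ONEHOT:
        out = np.zeros(20)
        np.add.at(out, codes, weights)
        return out / total
    rows = BLOSUM62[codes].astype(float)
    return (weights[:, None] * rows).sum(axis=0) / total


def scaled_agretopicity(rank_mut: float, rank_wt: float) -> tuple[float, float]:
    """Scaled and unscaled rank agretopicity of a mutant/wild-type pair.

    Returns (|rank_mut - rank_wt| * rank_mut / rank_wt, rank_mut / rank_wt).
    A non-positive wild-type rank is clamped to a small floor with a warning.
    """
    if rank_wt <= 0:
        warnings.warn(
            f"non-positive wild-type rank {rank_wt}; clamping to {RANK_RATIO_FLOOR}"
        )
        rank_wt = RANK_RATIO_FLOOR
    ratio = rank_mut / rank_wt
    return abs(rank_mut - rank_wt) * ratio, ratio


def mutation_scores(mut_icore: str, wt_icore: str) -> tuple[float, float]:
    """BLOSUM and codon mutation scores summed over mismatch positions.

    The BLOSUM term looks up BLOSUM62[wt][mut] per mismatch; the codon term
    is the probability that one single-nucleotide substitution of a random
    synonymous wild-type codon yields the mutant residue.
    """
    from .matrices import CODON_MUTATION

    if len(mut_icore) != len(wt_icore):
        raise ValueError("mutant and wild-type ICOREs must have equal length")
    blosum = 0.0
    codon = 0.0
    for m, w in zip(mut_icore, wt_icore):
        if m != w:
            blosum += BLOSUM62[AA_INDEX[w], AA_INDEX[m]]
            codon += CODON_MUTATION[AA_INDEX[w], AA_INDEX[m]]
    return float(blosum), float(codon)


# --- BLOSUM62 k-mer kernel ---------------------------------------------------

_EXP_B62 = np.exp(KERNEL_BETA * BLOSUM62.astype(float))
_KMIN, _KMAX = 3, 8


def _encode(p: str) -> np.ndarray:
    return np.array([AA_INDEX[aa] for aa in p], dtype=np.int64)


def _kernel_raw_many(a: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Unnormalised kernel of one peptide against a stack of equal-length
    peptides.  others has shape (m, lb)."""
    la, (m, lb) = len(a), others.shape
    E = _EXP_B62[a[:, None, None], others.T[None, :, :].transpose(0, 2, 1)]
    # E[i, m, j] = exp(beta * B62[a[i], others[m, j]])
    out = np.zeros(m)
    P = E
    kmax = min(_KMAX, la, lb)
    for k in range(2, kmax + 1):
        P = P[: la - k + 1, :, : lb - k + 1] * E[k - 1:, :, k - 1:]
        if k >= _KMIN:
            out += P.sum(axis=(0, 2))
    return out


def _kernel_raw(a: np.ndarray, b: np.ndarray) -> float:
    return float(_kernel_raw_many(a, b[None, :])[0])


def kernel_similarity(a: str, b: str) -> float:
    """Normalised BLOSUM62 k-mer kernel similarity of two peptides, in (0, 1].

    K(a,b) sums, over k = 3..min(8, lengths), the product-of-exp(beta*B62)
    score of every k-mer window pair; the result is
    K(a,b) / sqrt(K(a,a) K(b,b)), so identical peptides score exactly 1.
    """
    if len(a) < _KMIN or len(b) < _KMIN:
        raise ValueError(f"peptides must be at least {_KMIN} residues long")
    ea, eb = _encode(a), _encode(b)
    kab = _kernel_raw(ea, eb)
    return kab / np.sqrt(_kernel_raw(ea, ea) * _kernel_raw(eb, eb))


class KernelSimilarity:
    """Batched kernel similarity with cached self-kernels, for the
    redundancy-reduction scan over thousands of peptides."""

    def __init__(self) -> None:
        self._self: dict[str, float] = {}

    def self_kernel(self, p: str) -> float:
        if p not in self._self:
            e = _encode(p)
            self._self[p] = _kernel_raw(e, e)
        return self._self[p]

    def one_vs_many(self, query: str, others: Sequence[str]) -> np.ndarray:
        """Similarity of query against a list of peptides (any lengths)."""
        sims = np.empty(len(others))
        eq = _encode(query)
        kqq = self.self_kernel(query)
        by_length: dict[int, list[int]] = {}
        for i, p in enumerate(others):
            by_length.setdefault(len(p), []).append(i)
        for length, idxs in by_length.items():
            stack = np.stack([_encode(others[i]) for i in idxs])
            raw = _kernel_raw_many(eq, stack)
            selfs = np.array([self.self_kernel(others[i]) for i in idxs])
            sims[idxs] = raw / np.sqrt(kqq * selfs)
        return sims


# --- physico-chemical descriptors --------------------------------------------


def physchem(seq: str) -> tuple[float, float, float, float]:
    """(aliphatic_index, hydrophobicity, isoelectric_point, boman_index).

    Aliphatic index follows Ikai: 100*(x_A + 2.9 x_V + 3.9 (x_I + x_L)) on
    mole fractions.  Hydrophobicity is the mean Kyte-Doolittle hydropathy
    (GRAVY).  The isoelectric point is located by bisection on the peptide
    net charge (Bjellqvist pK set, via Biopython).  The Boman index is the
    mean negated side-chain water->cyclohexane transfer free energy, so
    higher values mean a more interaction-prone (hydrophilic) peptide.
    """
    n = len(seq)
    frac = lambda aa: seq.count(aa) / n
    aliphatic = 100.0 * (frac("A") + 2.9 * frac("V") + 3.9 * (frac("I") + frac("L")))
    hydro = sum(KYTE_DOOLITTLE[aa] for aa in seq) / n
    pi = ProteinAnalysis(seq).isoelectric_point()
    boman = sum(BOMAN_SCALE[aa] for aa in seq) / n
    return aliphatic, hydro, float(pi), boman


# --- feature assembly --------------------------------------------------------


@dataclass
class FeatureFlags:
    """Selection of optional features appended to the 21-dim base block."""

    rank_wt: bool = False
    scaled_agretopicity: bool = False
    blosum_mutation_score: bool = False
    codon_mutation_score: bool = False
    self_similarity: bool = False
    physchem: bool = False
    expression: bool = False
    foreignness: bool = False

    def feature_names(self) -> list[str]:
        names = list(COMPOSITION_NAMES) + ["rank_mut"]
        if self.rank_wt:
            names.append("rank_wt")
        if self.scaled_agretopicity:
            names.append("scaled_agretopicity")
        if self.blosum_mutation_score:
            names.append("blosum_mutation_score")
        if self.codon_mutation_score:
            names.append("codon_mutation_score")
        if self.self_similarity:
            names.append("self_similarity")
        if self.physchem:
            names += ["aliphatic_index", "hydrophobicity",
                      "isoelectric_point", "boman_index"]
        if self.expression:
            names.append("expression_tpm")
        if self.foreignness:
            names.append("foreignness")
        return names

    def to_dict(self) -> dict:
        return dict(self.__dict__)

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureFlags":
        return cls(**d)


@dataclass
class FeatureConfig:
    """Everything needed to turn a validated record into a feature vector."""

    scheme: WeightScheme = WeightScheme.NONE
    encoding: Encoding = Encoding.ONEHOT
    flags: FeatureFlags = field(default_factory=FeatureFlags)
    use_full_peptide: bool = False  # ICORE is the default input sequence
    tpm_median: Optional[float] = None

    def feature_names(self) -> list[str]:
        return self.flags.feature_names()


def assemble_features(
    record: NeoEpitopeRecord,
    profiles: ProfileStore,
    config: FeatureConfig,
    predictor=None,
) -> np.ndarray:
    """Assemble one record's model input vector in schema order.

    The base block is the weighted composition of the ICORE (or full
    peptide) plus the matching %Rank; optional blocks follow in the fixed
    schema order.  Missing TPM values are imputed with the configured
    median; requesting expression with neither a TPM value nor a median is
    a configuration error.  Full-peptide mode needs a rank predictor to
    score the complete sequences.
    """
    pair = record.icore
    if pair is None:
        raise ValueError("record has no ICORE pair; run validate_and_filter first")
    if config.use_full_peptide:
        if predictor is None:
            raise ValueError("full-peptide mode requires a rank predictor")
        seq, wt_seq = record.mutant_peptide, record.wt_peptide
        rank_mut = float(predictor.predict(seq, record.allele))
        rank_wt = float(predictor.predict(wt_seq, record.allele))
    else:
        seq, wt_seq = pair.mut_icore, pair.wt_icore
        rank_mut, rank_wt = pair.mut_rank, pair.wt_rank
    profile = profiles.get(record.allele, len(seq))
    weights = make_weights(profile, config.scheme)
    values = list(weighted_composition(seq, weights, config.encoding))
    values.append(rank_mut)
    flags = config.flags
    if flags.rank_wt:
        values.append(rank_wt)
    if flags.scaled_agretopicity:
        values.append(scaled_agretopicity(rank_mut, rank_wt)[0])
    if flags.blosum_mutation_score or flags.codon_mutation_score:
        blosum, codon = mutation_scores(seq, wt_seq)
        if flags.blosum_mutation_score:
            values.append(blosum)
        if flags.codon_mutation_score:
            values.append(codon)
    if flags.self_similarity:
        values.append(kernel_similarity(seq, wt_seq))
    if flags.physchem:
        values.extend(physchem(seq))
    if flags.expression:
        tpm = record.expression_tpm
        if tpm is None:
            if config.tpm_median is None:
                raise ValueError(
                    "expression feature requested but record has no TPM and "
                    "no imputation median is configured"
                )
            tpm = config.tpm_median
        values.append(tpm)
    if flags.foreignness:
        values.append(record.foreignness if record.foreignness is not None else 0.0)
    return np.asarray(values, dtype=float)


def feature_matrix(
    records: Sequence[NeoEpitopeRecord],
    profiles: ProfileStore,
    config: FeatureConfig,
    predictor=None,
):
    """Feature matrix (pandas DataFrame, columns in schema order) for a
    list of validated records."""
    import pandas as pd

    names = config.feature_names()
    data = np.vstack(
        [assemble_features(r, profiles, config, predictor) for r in records]
    )
    return pd.DataFrame(data, columns=names)
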