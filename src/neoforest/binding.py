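"""Pluggable MHC class I presentation %Rank prediction.

Three pieces live here:

* the :class:`RankPredictor` contract — ``predict(peptide, allele)`` returns
  an eluted-ligand percentile rank in [0, 100], lower = stronger predicted
  presentation;
* a parser for NetMHCpan-4.1 textual output, so precomputed rank files can
  be plugged in;
* a deterministic motif-PSSM surrogate predictor, so the entire pipeline
  (ICORE extraction, anchor profiles, training, calibration) runs with no
  external binary.  The surrogate scores a peptide as the sum of
  per-position log-preferences and converts the raw score to a percentile
  against a seeded background of random natural peptides, mirroring %Rank
  semantics.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Protocol, Sequence, runtime_checkable

import numpy as np
import pandas as pd

from .matrices import ALPHABET, AA_INDEX
from .records import MIN_LENGTH, MAX_LENGTH

#: Lowest rank the surrogate emits; real %Rank values are strictly positive
#: and downstream rank ratios require a non-zero denominator.
RANK_FLOOR = 0.01


@runtime_checkable
class RankPredictor(Protocol):
    """Behavioural contract for %Rank prediction backends."""

    def supports(self, allele: str) -> bool: ...

    def predict(self, peptide: str, allele: str) -> float: ...

    def predict_many(self, peptides: Sequence[str], allele: str) -> np.ndarray: ...


def encode_peptides(peptides: Sequence[str]) -> np.ndarray:
    """Integer-encode equal-length peptides as an (n, L) array."""
    return np.array([[AA_INDEX[aa] for aa in p] for p in peptides], dtype=np.int64)


@dataclass
class SurrogateAllele:
    """Motif definition of one surrogate allele.

    ``logpref[length]`` is an (length, 20) log-preference table; ``anchors``
    holds 1-based anchor positions resolved per length (negative values
    count from the C terminus, so -1 is the last position).
    """

    name: str
    anchors: tuple[int, ...]
    seed: int
    anchor_strength: float = 3.0
    noise_sd: float = 0.10
    n_background: int = 10_000
    logpref: dict = field(default_factory=dict, repr=False)
    background: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        rng = np.random.default_rng(self.seed)
        # preferred residues are drawn once per anchor slot, shared across
        # lengths, so 9-mer and 10-mer motifs agree at anchor slots
        preferred = {
            a: tuple(rng.choice(20, size=2, replace=False))
            for a in self.anchors
        }
        for length in range(MIN_LENGTH, MAX_LENGTH + 1):
            table = rng.normal(0.0, self.noise_sd, size=(length, 20))
            for a in self.anchors:
                pos = a - 1 if a > 0 else length + a
                table[pos] = -1.0
                for r in preferred[a]:
                    table[pos, r] = self.anchor_strength
            self.logpref[length] = table
            bg = rng.integers(0, 20, size=(self.n_background, length))
            scores = table[np.arange(length), bg].sum(axis=1)
            self.background[length] = np.sort(scores)

    def anchor_positions(self, length: int) -> set[int]:
        """Resolved 1-based anchor positions for a given peptide length."""
        return {a if a > 0 else length + a + 1 for a in self.anchors}

    def raw_scores(self, encoded: np.ndarray) -> np.ndarray:
        length = encoded.shape[1]
        table = self.logpref[length]
        return table[np.arange(length), encoded].sum(axis=1)

    def ranks(self, encoded: np.ndarray) -> np.ndarray:
        """Percentile ranks: 100 x fraction of background raw scores >= query."""
        length = encoded.shape[1]
        raw = self.raw_scores(encoded)
        bg = self.background[length]
        n_ge = len(bg) - np.searchsorted(bg, raw, side="left")
        return np.maximum(100.0 * n_ge / len(bg), RANK_FLOOR)


class SurrogatePredictor:
    """Deterministic RankPredictor backed by surrogate allele motifs."""

    def __init__(self, alleles: Iterable[SurrogateAllele]):
        self.alleles = {a.name: a for a in alleles}
        if not self.alleles:
            raise ValueError("at least one surrogate allele is required")

    def supports(self, allele: str) -> bool:
        return allele in self.alleles

    def _check(self, peptide: str, allele: str) -> SurrogateAllele:
        if allele not in self.alleles:
            raise KeyError(f"unknown allele for this predictor: {allele}")
        if not (MIN_LENGTH <= len(peptide) <= MAX_LENGTH):
            raise ValueError(
                f"peptide length {len(peptide)} outside [{MIN_LENGTH}, {MAX_LENGTH}]: {peptide}"
            )
        return self.alleles[allele]

    def predict(self, peptide: str, allele: str) -> float:
        surrogate = self._check(peptide, allele)
        return float(surrogate.ranks(encode_peptides([peptide]))[0])

    def predict_many(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        """Vectorised prediction for equal-length peptides."""
        if len(peptides) == 0:
            return np.empty(0)
        surrogate = self._check(peptides[0], allele)
        return surrogate.ranks(encode_peptides(peptides))


class TableRankPredictor:
    """RankPredictor backed by a precomputed (peptide, allele) -> rank table,
    e.g. parsed NetMHCpan-4.1 output."""

    def __init__(self, table: pd.DataFrame):
        self._ranks = {
            (row.peptide, row.allele): float(row.rank_el)
            for row in table.itertuples()
        }
        self._alleles = set(table["allele"])

    def supports(self, allele: str) -> bool:
        return allele in self._alleles

    def predict(self, peptide: str, allele: str) -> float:
        try:
            return self._ranks[(peptide, allele)]
        except KeyError:
            raise KeyError(
                f"no precomputed rank for ({peptide}, {allele})"
            ) from None

    def predict_many(self, peptides: Sequence[str], allele: str) -> np.ndarray:
        return np.array([self.predict(p, allele) for p in peptides])


class NetMHCpanFormatError(ValueError):
    """Raised when a NetMHCpan output file contains no scored lines."""


def parse_netmhcpan_output(path) -> pd.DataFrame:
    """Parse NetMHCpan-4.1 textual output into (peptide, allele, rank_el).

    Handles the whitespace-aligned block format, multi-allele runs, and both
    peptide-list and pseudo-fasta modes (the emitted score table is the same
    shape).  Header, separator and summary lines are skipped; the column
    header of each block is used to locate the Peptide, MHC and %Rank_EL
    fields, tolerating the EL/BA column-layout variants.
    """
    rows = []
    colmap: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            tokens = line.split()
            if not tokens:
                continue
            if tokens[0] == "Pos":
                colmap = {name: i for i, name in enumerate(tokens)}
                continue
            if not re.fullmatch(r"\d+", tokens[0]) or not colmap:
                continue
            rank_col = colmap.get("%Rank_EL", colmap.get("%Rank"))
            try:
                rows.append(
                    {
                        "peptide": tokens[colmap["Peptide"]],
                        "allele": tokens[colmap["MHC"]],
                        "rank_el": float(tokens[rank_col]),
                    }
                )
            except (KeyError, IndexError, TypeError, ValueError):
                continue
    if not rows:
        raise NetMHCpanFormatError(f"no scored lines found in {path}")
    df = pd.DataFrame(rows)
    from .records import normalise_allele

    df["allele"] = df["allele"].map(normalise_allele)
    return df


def random_peptides(n: int, length: int, rng: np.random.Generator) -> list[str]:
    """n random natural peptides with uniform residue usage."""
    codes = rng.integers(0, 20, size=(n, length))
    return ["".join(ALPHABET[c] for c in row) for row in codes]


def sample_strong_binders(
    predictor: RankPredictor,
    allele: str,
    length: int,
    n: int,
    rank_threshold: float = 0.25,
    seed: int = 0,
    max_draws: int = 5_000_000,
) -> list[str]:
    """Draw n peptides predicted to bind at %Rank <= rank_threshold.

    Rejection sampling from a seeded stream of random natural peptides; used
    to build the per-allele positional frequency profiles.  Raises if the
    acceptance rate is too low to finish within ``max_draws`` candidates.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    out: list[str] = []
    drawn = 0
    chunk = max(4096, int(n * 100 / max(rank_threshold, 1e-6) / 100))
    while len(out) < n:
        if drawn >= max_draws:
            raise RuntimeError(
                f"could not collect {n} binders for {allele} length {length} "
                f"at %Rank <= {rank_threshold} after {drawn} draws; "
                "consider a looser threshold"
            )
        peptides = random_peptides(chunk, length, rng)
        drawn += chunk
        ranks = predictor.predict_many(peptides, allele)
        out.extend(p for p, r in zip(peptides, ranks) if r <= rank_threshold)
    return out[:n]
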