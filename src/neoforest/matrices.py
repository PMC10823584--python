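"""Scoring tables shared across the package.

BLOSUM62 is vendored verbatim (integer half-bit log-odds) so scores are
bit-exact and independent of any third-party copy.  The codon mutation
matrix is derived at import time from the standard genetic code by brute
force over every sense codon and its nine single-nucleotide neighbours.
"""

from __future__ import annotations

import numpy as np
from Bio.Data import CodonTable

#: Canonical 20-letter amino-acid alphabet, alphabetical by one-letter code.
ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX = {aa: i for i, aa in enumerate(ALPHABET)}

_B62_ORDER = "ARNDCQEGHILKMFPSTWYV"
_B62_ROWS = """
 4 -1 -2 -2  0 -1 -1  0 -2 -1 -1 -1 -1 -2 -1  1  0 -3 -2  0
-1  5  0 -2 -3  1  0 -2  0 -3 -2  2 -1 -3 -2 -1 -1 -3 -2 -3
-2  0  6  1 -3  0  0  0  1 -3 -3  0 -2 -3 -2  1  0 -4 -2 -3
-2 -2  1  6 -3  0  2 -1 -1 -3 -4 -1 -3 -3 -1  0 -1 -4 -3 -3
 0 -3 -3 -3  9 -3 -4 -3 -3 -1 -1 -3 -1 -2 -3 -1 -1 -2 -2 -1
-1  1  0  0 -3  5  2 -2  0 -3 -2  1  0 -3 -1  0 -1 -2 -1 -2
-1  0  0  2 -4  2  5 -2  0 -3 -3  1 -2 -3 -1  0 -1 -3 -2 -2
 0 -2  0 -1 -3 -2 -2  6 -2 -4 -4 -2 -3 -3 -2  0 -2 -2 -3 -3
-2  0  1 -1 -3  0  0 -2  8 -3 -3 -1 -2 -1 -2 -1 -2 -2  2 -3
-1 -3 -3 -3 -1 -3 -3 -4 -3  4  2 -3  1  0 -3 -2 -1 -3 -1  3
-1 -2 -3 -4 -1 -2 -3 -4 -3  2  4 -2  2  0 -3 -2 -1 -2 -1  1
-1  2  0 -1 -3  1  1 -2 -1 -3 -2  5 -1 -3 -1  0 -1 -3 -2 -2
-1 -1 -2 -3 -1  0 -2 -3 -2  1  2 -1  5  0 -2 -1 -1 -1 -1  1
-2 -3 -3 -3 -2 -3 -3 -3 -1  0  0 -3  0  6 -4 -2 -2  1  3 -1
-1 -2 -2 -1 -3 -1 -1 -2 -2 -3 -3 -1 -2 -4  7 -1 -1 -4 -3 -2
 1 -1  1  0 -1  0  0  0 -1 -2 -2  0 -1 -2 -1  4  1 -3 -2 -2
 0 -1  0 -1 -1 -1 -1 -2 -2 -1 -1 -1 -1 -2 -1  1  5 -2 -2  0
-3 -3 -4 -4 -2 -2 -3 -2 -2 -3 -2 -3 -1  1 -4 -3 -2 11  2 -3
-2 -2 -2 -3 -2 -1 -2 -3  2 -1 -1 -2 -1  3 -3 -2 -2  2  7 -1
 0 -3 -3 -3 -1 -2 -2 -3 -3  3  1 -2  1 -1 -2 -2  0 -3 -1  4
"""


def _build_blosum62() -> np.ndarray:
    raw = np.array([int(tok) for tok in _B62_ROWS.split()], dtype=np.int64)
    raw = raw.reshape(20, 20)
    m = np.zeros((20, 20), dtype=np.int64)
    for i, a in enumerate(_B62_ORDER):
        for j, b in enumerate(_B62_ORDER):
            m[AA_INDEX[a], AA_INDEX[b]] = raw[i, j]
    return m


#: BLOSUM62 indexed by (AA_INDEX[a], AA_INDEX[b]).
BLOSUM62 = _build_blosum62()


def blosum62_score(a: str, b: str) -> int:
    """BLOSUM62 log-odds score of substituting residue ``a`` by ``b``."""
    return int(BLOSUM62[AA_INDEX[a], AA_INDEX[b]])


def _build_codon_matrix() -> np.ndarray:
    """P(single-nucleotide codon mutation of wt residue -> mut residue).

    For each wild-type residue, every synonymous codon is weighted
    uniformly, and each codon's nine single-nucleotide neighbours are
    weighted 1/9.  Neighbours that hit a stop codon count as a miss.
    """
    table = CodonTable.unambiguous_dna_by_id[1]  # standard genetic code
    codons_of: dict[str, list[str]] = {}
    for codon, aa in table.forward_table.items():
        codons_of.setdefault(aa, []).append(codon)
    bases = "ACGT"
    m = np.zeros((20, 20), dtype=float)
    for wt, codons in codons_of.items():
        if wt not in AA_INDEX:
            continue
        for codon in codons:
            for pos in range(3):
                for b in bases:
                    if b == codon[pos]:
                        continue
                    neighbour = codon[:pos] + b + codon[pos + 1:]
                    product = table.forward_table.get(neighbour)  # None = stop
                    if product in AA_INDEX:
                        m[AA_INDEX[wt], AA_INDEX[product]] += 1.0
        m[AA_INDEX[wt]] /= 9.0 * len(codons)
    return m


#: CODON_MUTATION[i, j] = probability that one random single-nucleotide
#: substitution of a random synonymous codon of residue i yields residue j.
CODON_MUTATION = _build_codon_matrix()

# --- physico-chemical scales -------------------------------------------------

#: Kyte-Doolittle hydropathy.
KYTE_DOOLITTLE = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
    "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
    "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
    "Y": -1.3, "V": 4.2,
}

#: Negated side-chain transfer free energies (water -> cyclohexane, kcal/mol)
#: used for the Boman protein-interaction index; positive = hydrophilic.
#: Proline has no side-chain analog and is assigned 0 by convention.
BOMAN_SCALE = {
    "A": -1.81, "R": 14.92, "N": 6.64, "D": 8.72, "C": -1.28, "Q": 5.54,
    "E": 6.81, "G": -0.94, "H": 4.66, "I": -4.92, "L": -4.92, "K": 5.55,
    "M": -2.35, "F": -2.98, "P": 0.0, "S": 3.40, "T": 2.57, "W": -2.33,
    "Y": -0.14, "V": -4.04,
}
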