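"""Independent oracles shared by module and acceptance tests.

These deliberately avoid the library code paths they check: the ICORE
oracle enumerates windows with single predict calls, and the codon oracle
re-derives the single-nucleotide substitution probabilities directly from
the standard genetic code.
"""

from __future__ import annotations

from Bio.Data import CodonTable

CANONICAL = "ACDEFGHIKLMNPQRSTVWY"


def brute_force_icore(peptide: str, allele: str, predictor):
    """Exhaustive argmin over all 8..min(12, L) windows with the
    longer-window-then-leftmost tie-break; returns ((rank, -len, off), window)."""
    best = None
    L = len(peptide)
    for length in range(8, min(12, L) + 1):
        for off in range(L - length + 1):
            window = peptide[off:off + length]
            key = (predictor.predict(window, allele), -length, off)
            if best is None or key < best[0]:
                best = (key, window)
    return best


def codon_oracle() -> dict:
    """P(single-nucleotide substitution of a wt codon encodes mut), averaged
    uniformly over synonymous codons, by direct enumeration."""
    table = CodonTable.unambiguous_dna_by_id[1]
    fwd = table.forward_table
    out = {}
    for wt in CANONICAL:
        codons = [c for c, aa in fwd.items() if aa == wt]
        for mut in CANONICAL:
            hits = total = 0
            for codon in codons:
                for pos in range(3):
                    for b in "ACGT":
                        if b == codon[pos]:
                            continue
                        total += 1
                        if fwd.get(codon[:pos] + b + codon[pos + 1:]) == mut:
                            hits += 1
            out[(wt, mut)] = hits / total
    return out
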