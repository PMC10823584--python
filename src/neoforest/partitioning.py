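"""Similarity-aware redundancy reduction and leakage-free fold assignment.

Cross-validation folds must not share near-identical peptides, or the
measured performance is inflated by memorisation.  The Hobohm-1 scan first
separates the data into pairwise-dissimilar representatives and a held-out
pool of similar peptides; the representatives are dealt randomly into k
folds, and each held-out peptide is then reinserted into the fold of its
most similar representative (exact duplicates join their duplicate's
fold).  Similarity is the BLOSUM62 k-mer kernel on full mutant peptides,
with the redundancy threshold defaulting to 0.9.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .features import KernelSimilarity
from .records import NeoEpitopeRecord

DEFAULT_SIMILARITY_THRESHOLD = 0.9
DEFAULT_K = 10


@dataclass
class PartitionPlan:
    """Fold assignment produced by make_partitions."""

    folds: list[int]  # one fold id per input record
    representatives: list[str]
    clusters: dict[str, list[str]]  # representative -> clustered members
    threshold: float
    k: int
    seed: int
    peptide_fold: dict[str, int] = field(default_factory=dict)


def hobohm1(
    peptides: Sequence[str],
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
    kernel: Optional[KernelSimilarity] = None,
) -> tuple[list[str], dict[str, list[str]]]:
    """Greedy redundancy reduction over peptides in input order.

    A peptide becomes a new representative unless some existing
    representative exceeds the similarity threshold, in which case it joins
    the cluster of the maximally similar representative.  The returned
    representative set is pairwise <= threshold by construction.  Duplicate
    strings in the input cluster onto their first occurrence.
    """
    if len(peptides) == 0:
        raise ValueError("peptide list must be non-empty")
    kernel = kernel or KernelSimilarity()
    representatives: list[str] = []
    clusters: dict[str, list[str]] = {}
    seen: set[str] = set()
    for pep in peptides:
        if pep in seen:
            continue  # exact duplicate: already placed at first occurrence
        seen.add(pep)
        if not representatives:
            representatives.append(pep)
            clusters[pep] = []
            continue
        sims = kernel.one_vs_many(pep, representatives)
        best = int(np.argmax(sims))
        if sims[best] > threshold:
            clusters[representatives[best]].append(pep)
        else:
            representatives.append(pep)
            clusters[pep] = []
    return representatives, clusters


def make_partitions(
    records: Sequence[NeoEpitopeRecord],
    k: int = DEFAULT_K,
    seed: int = 0,
    threshold: float = DEFAULT_SIMILARITY_THRESHOLD,
) -> PartitionPlan:
    """Assign every record a fold in 0..k-1 with no cross-fold similarity
    above the threshold.

    Unique mutant peptides are reduced with Hobohm-1; representatives are
    shuffled with the seed and dealt round-robin into k folds (balanced to
    within one before reinsertion); clustered peptides are reinserted into
    the fold of their maximum-similarity representative, and duplicate
    records simply share their peptide's fold.
    """
    peptides = [r.mutant_peptide for r in records]
    unique_in_order = list(dict.fromkeys(peptides))
    kernel = KernelSimilarity()
    representatives, clusters = hobohm1(unique_in_order, threshold, kernel)
    if len(representatives) < k:
        raise ValueError(
            f"only {len(representatives)} dissimilar representatives for k={k} folds"
        )
    rng = np.random.default_rng(seed)
    shuffled = list(representatives)
    rng.shuffle(shuffled)
    peptide_fold = {rep: i % k for i, rep in enumerate(shuffled)}
    for rep, members in clusters.items():
        for pep in members:
            peptide_fold[pep] = peptide_fold[rep]
    folds = [peptide_fold[p] for p in peptides]
    return PartitionPlan(
        folds=folds,
        representatives=representatives,
        clusters=clusters,
        threshold=threshold,
        k=k,
        seed=seed,
        peptide_fold=peptide_fold,
    )


def apply_plan(records: Sequence[NeoEpitopeRecord], plan: PartitionPlan) -> None:
    """Write the plan's fold ids onto the records in place."""
    for rec, fold in zip(records, plan.folds):
        rec.fold = int(fold)


def max_cross_fold_similarity(
    peptides: Sequence[str],
    folds: Sequence[int],
    kernel: Optional[KernelSimilarity] = None,
) -> float:
    """Brute-force leakage audit: the maximum kernel similarity between any
    two peptides assigned to different folds."""
    kernel = kernel or KernelSimilarity()
    unique: dict[str, int] = {}
    for pep, fold in zip(peptides, folds):
        unique.setdefault(pep, int(fold))
    peps = list(unique)
    worst = 0.0
    for i, pep in enumerate(peps[:-1]):
        rest = peps[i + 1:]
        sims = kernel.one_vs_many(pep, rest)
        for other, sim in zip(rest, sims):
            if unique[pep] != unique[other]:
                worst = max(worst, float(sim))
    return worst
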