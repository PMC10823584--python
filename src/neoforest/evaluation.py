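"""Evaluation statistics: ROC AUC, partial AUC, paired bootstrap model
comparison, one-sided proportion and Welch tests, and harmonic-mean
consensus model selection.

The paired bootstrap compares two score vectors on the same labelled data:
each round resamples record indices with replacement (the same indices for
both methods), and the reported p-value is 1 minus the fraction of rounds
in which method 1's AUC strictly exceeds method 2's — small p therefore
means method 1 is reliably better.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

DEFAULT_BOOTSTRAP_ROUNDS = 10_000


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("both classes must be present to compute an AUC")


def roc_auc(labels, scores) -> float:
    """ROC AUC: probability a random positive outranks a random negative,
    ties counting one half."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pauc01(labels, scores, normalised: bool = True) -> float:
    """Partial AUC up to false-positive rate 0.1 (trapezoidal), divided by
    0.1 when normalised so a perfect ranker scores 1."""
    labels = np.asarray(labels)
    _check_two_class(labels)
    fpr, tpr, _ = roc_curve(labels, np.asarray(scores, dtype=float))
    cut = 0.1
    tpr_at_cut = np.interp(cut, fpr, tpr)
    mask = fpr <= cut
    xs = np.concatenate([fpr[mask], [cut]])
    ys = np.concatenate([tpr[mask], [tpr_at_cut]])
    area = float(np.trapezoid(ys, xs))
    return area / cut if normalised else area


def _auc_mann_whitney(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-based AUC used inside the bootstrap loop (ties averaged)."""
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    return (ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


@dataclass
class BootstrapComparison:
    """Result of a paired bootstrap AUC comparison of two methods."""

    n_rounds: int
    seed: int
    auc_c1: np.ndarray  # per-round AUCs of method 1
    auc_c2: np.ndarray
    wins: int  # rounds with auc_c1 strictly greater
    p_value: float


def bootstrap_compare(
    labels,
    scores_c1,
    scores_c2,
    n_rounds: int = DEFAULT_BOOTSTRAP_ROUNDS,
    seed: int = 0,
    max_redraws: int = 1000,
) -> BootstrapComparison:
    """Paired bootstrap comparison of two score vectors on shared labels.

    p = 1 - wins / n_rounds, where a win is a round with
    AUC_c1 > AUC_c2 on the same resampled indices.  Rounds that resample a
    single class are redrawn (bounded)."""
    labels = np.asarray(labels)
    s1 = np.asarray(scores_c1, dtype=float)
    s2 = np.asarray(scores_c2, dtype=float)
    if not (len(labels) == len(s1) == len(s2)):
        raise ValueError("labels and both score vectors must be equally long")
    _check_two_class(labels)
    rng = np.random.default_rng(seed)
    n = len(labels)
    auc1 = np.empty(n_rounds)
    auc2 = np.empty(n_rounds)
    for r in range(n_rounds):
        for _ in range(max_redraws):
            idx = rng.integers(0, n, size=n)
            lab = labels[idx]
            if 0 < lab.sum() < n:
                break
        else:
            raise RuntimeError("could not draw a two-class bootstrap sample")
        auc1[r] = _auc_mann_whitney(lab, s1[idx])
        auc2[r] = _auc_mann_whitney(lab, s2[idx])
    wins = int((auc1 > auc2).sum())
    return BootstrapComparison(
        n_rounds=n_rounds,
        seed=seed,
        auc_c1=auc1,
        auc_c2=auc2,
        wins=wins,
        p_value=1.0 - wins / n_rounds,
    )


def proportions_ztest(
    successes1: int, n1: int, successes2: int, n2: int,
    alternative: str = "smaller",
) -> float:
    """One-sided two-proportion z-test with pooled variance.

    ``alternative='smaller'`` tests whether group 1's proportion is lower
    than group 2's; ``'larger'`` the opposite tail.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("both group sizes must be positive")
    if not (0 <= successes1 <= n1 and 0 <= successes2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    p1, p2 = successes1 / n1, successes2 / n2
    pooled = (successes1 + successes2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1 / n1 + 1 / n2))
    if se == 0:
        return 0.5
    z = (p1 - p2) / se
    if alternative == "smaller":
        return float(stats.norm.cdf(z))
    if alternative == "larger":
        return float(stats.norm.sf(z))
    raise ValueError("alternative must be 'smaller' or 'larger'")


def welch_ttest_onesided(sample_a, sample_b) -> float:
    """Upper-tail Welch t-test p-value for mean(a) > mean(b).

    Uses the Satterthwaite degrees of freedom; two zero-variance samples
    with equal means return 0.5 by convention.
    """
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least two observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        return 0.5
    res = stats.ttest_ind(a, b, equal_var=False, alternative="greater")
    return float(res.pvalue)


def select_consensus(
    candidates: list[tuple[object, float, float]]
) -> list[tuple[object, float, float, float]]:
    """Rank model configurations by the harmonic mean of two AUCs.

    Each candidate is (config, auc_primary, auc_external); the returned
    list appends the harmonic mean 2ab/(a+b) and is sorted descending with
    stable tie order.
    """
    for _, a, b in candidates:
        if a <= 0 or b <= 0:
            raise ValueError("AUCs must be positive to form a harmonic mean")
    scored = [
        (cfg, a, b, 2 * a * b / (a + b)) for cfg, a, b in candidates
    ]
    return sorted(scored, key=lambda t: -t[3])
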