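"""Per-allele positional binding motifs and information-content weights.

For each (HLA allele, peptide length), position-specific residue
frequencies are estimated from predicted strong binders (%Rank <= 0.25),
with a pseudo-count low-count correction of weight beta = 20 blending the
observed frequencies with a background distribution:

    freq[p][a] = (n * f_obs[p][a] + beta * q[a]) / (n + beta)

Positional information content (IC) is the Kullback-Leibler divergence to
the background (or alternatively log2(20) minus the Shannon entropy), both
normalised by log2(20) to land in [0, 1].  Positions with IC >= 0.2 are
called anchors.  Five weighting schemes turn the IC vector into
per-position weights for composition features: None, Normal (1-IC),
NormalMask (1-IC with anchors zeroed), Inverted (IC) and InvertedMask (IC
with non-anchors zeroed).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .matrices import AA_INDEX

LOG2_20 = float(np.log2(20.0))

#: IC threshold defining an anchor position.
ANCHOR_IC_THRESHOLD = 0.2

#: Default pseudo-count weight of the low-count correction.
DEFAULT_BETA = 20.0

#: Default number of strong binders sampled per (allele, length).
DEFAULT_N_BINDERS = 1000

#: Uniform background distribution over the 20 canonical residues.
UNIFORM_BACKGROUND = np.full(20, 1.0 / 20.0)


class WeightScheme(str, enum.Enum):
    NONE = "None"
    NORMAL = "Normal"
    NORMAL_MASK = "NormalMask"
    INVERTED = "Inverted"
    INVERTED_MASK = "InvertedMask"


@dataclass
class AnchorProfile:
    """Positional frequency profile and IC vector of one (allele, length)."""

    allele: str
    length: int
    freq: np.ndarray  # (length, 20), rows sum to 1
    n_binders: int
    pseudo_weight_beta: float = DEFAULT_BETA
    background: np.ndarray = field(default_factory=lambda: UNIFORM_BACKGROUND.copy())
    ic_kind: str = "KL"
    ic: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        self.ic = information_content(self, kind=self.ic_kind)

    def anchor_positions(self, threshold: float = ANCHOR_IC_THRESHOLD) -> set[int]:
        """1-based positions whose IC meets or exceeds the threshold."""
        return {int(p) + 1 for p in np.flatnonzero(self.ic >= threshold)}

    def to_dict(self) -> dict:
        return {
            "allele": self.allele,
            "length": self.length,
            "n_binders": self.n_binders,
            "pseudo_weight_beta": self.pseudo_weight_beta,
            "ic_kind": self.ic_kind,
            "background": [float(x) for x in self.background],
            "freq": [[float(x) for x in row] for row in self.freq],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AnchorProfile":
        return cls(
            allele=d["allele"],
            length=int(d["length"]),
            freq=np.asarray(d["freq"], dtype=float),
            n_binders=int(d["n_binders"]),
            pseudo_weight_beta=float(d["pseudo_weight_beta"]),
            background=np.asarray(d["background"], dtype=float),
            ic_kind=d.get("ic_kind", "KL"),
        )


def build_frequency_profile(
    binders: Sequence[str],
    allele: str = "",
    beta: float = DEFAULT_BETA,
    background: Optional[np.ndarray] = None,
    ic_kind: str = "KL",
) -> AnchorProfile:
    """Estimate a positional frequency profile from same-length binders.

    No sequence weighting is applied; the low-count correction blends the
    observed frequencies with the background using pseudo-count weight beta.
    """
    if len(binders) == 0:
        raise ValueError("cannot build a profile from an empty binder set")
    length = len(binders[0])
    if any(len(b) != length for b in binders):
        raise ValueError("all binders must have the same length")
    q = UNIFORM_BACKGROUND if background is None else np.asarray(background, float)
    n = len(binders)
    counts = np.zeros((length, 20))
    for pep in binders:
        for p, aa in enumerate(pep):
            counts[p, AA_INDEX[aa]] += 1.0
    f_obs = counts / n
    freq = (n * f_obs + beta * q[None, :]) / (n + beta)
    return AnchorProfile(
        allele=allele,
        length=length,
        freq=freq,
        n_binders=n,
        pseudo_weight_beta=beta,
        background=q.copy(),
        ic_kind=ic_kind,
    )


def information_content(profile: AnchorProfile, kind: str = "KL") -> np.ndarray:
    """Per-position information content, normalised to [0, 1] by log2(20).

    KL: sum_a freq * log2(freq / q); Shannon: log2(20) - entropy.  Zero
    frequencies (possible only at beta = 0) contribute zero.
    """
    f = profile.freq
    q = profile.background
    with np.errstate(divide="ignore", invalid="ignore"):
        if kind == "KL":
            terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0) / q), 0.0)
            raw = terms.sum(axis=1)
        elif kind == "Shannon":
            terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
            raw = LOG2_20 + terms.sum(axis=1)
        else:
            raise ValueError(f"unknown information content kind: {kind}")
    return np.clip(raw / LOG2_20, 0.0, 1.0)


def make_weights(
    profile: AnchorProfile,
    scheme: WeightScheme,
    anchor_threshold: float = ANCHOR_IC_THRESHOLD,
) -> np.ndarray:
    """Per-position weight vector for a weighting scheme.

    None -> all ones; Normal -> 1 - IC; NormalMask -> 1 - IC with anchor
    positions (IC >= threshold) zeroed; Inverted -> IC; InvertedMask -> IC
    with non-anchor positions (IC < threshold) zeroed.
    """
    scheme = WeightScheme(scheme)
    ic = profile.ic
    if scheme is WeightScheme.NONE:
        return np.ones_like(ic)
    if scheme is WeightScheme.NORMAL:
        return 1.0 - ic
    if scheme is WeightScheme.NORMAL_MASK:
        w = 1.0 - ic
        w[ic >= anchor_threshold] = 0.0
        return w
    if scheme is WeightScheme.INVERTED:
        return ic.copy()
    w = ic.copy()
    w[ic < anchor_threshold] = 0.0
    return w


def anchor_positions(
    profile: AnchorProfile, threshold: float = ANCHOR_IC_THRESHOLD
) -> set[int]:
    """1-based anchor positions of a profile (IC >= threshold)."""
    return profile.anchor_positions(threshold)


class ProfileStore:
    """Cache of AnchorProfiles keyed by (allele, length), buildable from a
    rank predictor and serialisable to a plain dict for YAML round-trips."""

    def __init__(self, profiles: Optional[dict] = None):
        self._profiles: dict[tuple[str, int], AnchorProfile] = profiles or {}

    def get(self, allele: str, length: int) -> AnchorProfile:
        return self._profiles[(allele, length)]

    def __contains__(self, key: tuple[str, int]) -> bool:
        return key in self._profiles

    def items(self):
        return self._profiles.items()

    @classmethod
    def build(
        cls,
        predictor,
        alleles: Sequence[str],
        lengths: Sequence[int] = (8, 9, 10, 11, 12),
        n_binders: int = DEFAULT_N_BINDERS,
        rank_threshold: float = 0.25,
        beta: float = DEFAULT_BETA,
        seed: int = 0,
        ic_kind: str = "KL",
    ) -> "ProfileStore":
        from .binding import sample_strong_binders

        store = cls()
        for ai, allele in enumerate(sorted(alleles)):
            for length in lengths:
                binders = sample_strong_binders(
                    predictor, allele, length, n_binders,
                    rank_threshold=rank_threshold,
                    seed=seed + 1009 * ai + length,
                )
                store._profiles[(allele, length)] = build_frequency_profile(
                    binders, allele=allele, beta=beta, ic_kind=ic_kind
                )
        return store

    def to_dict(self) -> dict:
        return {
            f"{allele}|{length}": prof.to_dict()
            for (allele, length), prof in self._profiles.items()
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProfileStore":
        profiles = {}
        for key, pd_ in d.items():
            allele, length = key.rsplit("|", 1)
            profiles[(allele, int(length))] = AnchorProfile.from_dict(pd_)
        return cls(profiles)
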