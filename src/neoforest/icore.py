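"""ICORE extraction and mutation localisation.

The ICORE of a reported peptide is the contiguous sub-window (length 8-12)
with the lowest predicted presentation %Rank for the restricting allele —
the sub-peptide predicted to actually be presented.  The aligned wild-type
ICORE is the wild-type substring at the same offset and length, and serves
as the reference sequence for all mutation-derived features.  Coordinates
are 0-based half-open internally and 1-based in user-facing output.
"""

from __future__ import annotations

from dataclasses import dataclass

from .records import MIN_LENGTH, MAX_LENGTH, NeoEpitopeRecord
from .profiles import ANCHOR_IC_THRESHOLD, AnchorProfile


@dataclass
class IcorePair:
    """A mutant ICORE with its aligned wild-type counterpart."""

    mut_icore: str
    wt_icore: str
    offset: int  # 0-based start within the full peptide
    length: int
    mut_rank: float
    wt_rank: float
    allele: str

    @property
    def offset_1based(self) -> int:
        return self.offset + 1

    def mismatch_positions(self) -> list[int]:
        """1-based positions within the ICORE where mutant and WT differ."""
        return [
            i + 1
            for i, (a, b) in enumerate(zip(self.mut_icore, self.wt_icore))
            if a != b
        ]


@dataclass
class MutationProfile:
    """Location and anchor classification of the mutations of one record."""

    icore_mutation_positions: list[int]  # 1-based within the ICORE
    anchor_flags: list[bool]
    any_mutation_outside_icore: bool


def extract_icore(
    mut_peptide: str, allele: str, predictor
) -> IcorePair:
    """Find the sub-window of the mutant peptide with the lowest %Rank.

    All contiguous windows of lengths 8..min(12, L) are scored; ties are
    broken in favour of the longer window, then the smaller offset.  The
    returned pair has its wild-type fields unset (see align_wt_icore).
    """
    L = len(mut_peptide)
    if L < MIN_LENGTH:
        raise ValueError(
            f"peptide shorter than {MIN_LENGTH} residues: {mut_peptide!r}"
        )
    best = None  # (rank, -length, offset, window)
    for length in range(MIN_LENGTH, min(MAX_LENGTH, L) + 1):
        windows = [mut_peptide[off:off + length] for off in range(L - length + 1)]
        ranks = predictor.predict_many(windows, allele)
        for off, (window, rank) in enumerate(zip(windows, ranks)):
            key = (float(rank), -length, off)
            if best is None or key < best[0]:
                best = (key, window)
    (rank, neg_len, offset), window = best
    return IcorePair(
        mut_icore=window,
        wt_icore="",
        offset=offset,
        length=-neg_len,
        mut_rank=rank,
        wt_rank=float("nan"),
        allele=allele,
    )


def align_wt_icore(pair: IcorePair, wt_peptide: str, predictor) -> IcorePair:
    """Fill in the aligned wild-type ICORE and its predicted %Rank.

    The wild-type ICORE is the wild-type substring at the mutant ICORE's
    (offset, length); full mutant and wild-type peptides must therefore be
    equal length (frameshifts are filtered upstream).
    """
    full_len = pair.offset + pair.length
    if len(wt_peptide) < full_len:
        raise ValueError(
            "wild-type peptide shorter than the mutant ICORE span; "
            "frameshift pairs must be filtered before ICORE alignment"
        )
    wt_icore = wt_peptide[pair.offset:pair.offset + pair.length]
    pair.wt_icore = wt_icore
    pair.wt_rank = float(predictor.predict(wt_icore, pair.allele))
    return pair


def mutation_profile(
    record: NeoEpitopeRecord,
    profile: AnchorProfile,
    anchor_threshold: float = ANCHOR_IC_THRESHOLD,
) -> MutationProfile:
    """Locate the record's mutations and classify them as anchor/non-anchor.

    Mutation positions are the mismatches between mutant and wild-type
    ICOREs (1-based within the ICORE); the outside flag is true iff the
    full-peptide mismatch set is not fully covered by the ICORE span.
    """
    pair = record.icore
    if pair is None:
        raise ValueError("record has no ICORE pair attached")
    if profile.length != pair.length:
        raise ValueError(
            f"anchor profile length {profile.length} != ICORE length {pair.length}"
        )
    positions = pair.mismatch_positions()
    anchors = profile.anchor_positions(anchor_threshold)
    flags = [p in anchors for p in positions]
    span = range(pair.offset + 1, pair.offset + pair.length + 1)
    full_mismatches = record.mismatch_positions()
    outside = any(p not in span for p in full_mismatches)
    return MutationProfile(
        icore_mutation_positions=positions,
        anchor_flags=flags,
        any_mutation_outside_icore=outside,
    )
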