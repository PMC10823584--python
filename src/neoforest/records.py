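"""Data model, dataset I/O, label collapsing and record-level filters.

A record is one (mutant peptide, wild-type peptide, HLA allele) observation,
optionally labelled immunogenic/non-immunogenic and optionally annotated with
wild-type expression (TPM), a precomputed foreignness score, and a
cross-validation fold.  Filters mirror the curation applied to the training
data: equal-length point-mutated pairs only (no frameshifts), lengths 8-12,
canonical residues, resolvable class-I allele, and at most a configurable
number of mismatches between the mutant ICORE and its aligned wild-type
ICORE.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import TYPE_CHECKING, Iterable, Mapping, Optional

import pandas as pd

from .matrices import ALPHABET

if TYPE_CHECKING:  # pragma: no cover
    from .icore import IcorePair

_ALPHABET_SET = set(ALPHABET)

MIN_LENGTH = 8
MAX_LENGTH = 12

#: Default column names of the delimited input format.
DEFAULT_COLUMNS = {
    "mutant": "mutant_peptide",
    "wildtype": "wt_peptide",
    "allele": "hla_allele",
    "label": "target",
    "expression": "expression_tpm",
    "foreignness": "foreignness",
    "fold": "partition",
}

_ALLELE_RE = re.compile(
    r"^(?:HLA-)?([ABC])\*?(\d{1,2}):?(\d{2,3})$"
)


class ConfigurationError(ValueError):
    """Raised for unusable inputs (missing columns, unknown alleles...)."""


def normalise_allele(raw: str) -> str:
    """Canonicalise an HLA class I allele name to the starred form.

    Accepts e.g. ``A0201``, ``HLA-A02:01``, ``HLA-A*02:01`` and returns
    ``HLA-A*02:01``.  Unknown patterns raise ``ValueError`` rather than
    guessing.
    """
    s = str(raw).strip().upper().replace(" ", "")
    m = _ALLELE_RE.match(s)
    if m is None:
        raise ValueError(f"unresolvable HLA allele name: {raw!r}")
    gene, group, protein = m.groups()
    if len(group) == 1:
        group = "0" + group
    return f"HLA-{gene}*{group}:{protein}"


@dataclass
class NeoEpitopeRecord:
    """One mutant/wild-type/HLA observation."""

    mutant_peptide: str
    wt_peptide: str
    allele: str
    label: Optional[int] = None
    expression_tpm: Optional[float] = None
    foreignness: Optional[float] = None
    fold: Optional[int] = None
    source_id: str = ""
    icore: Optional["IcorePair"] = None

    def mismatch_positions(self) -> list[int]:
        """1-based positions where mutant and WT full peptides differ."""
        return [
            i + 1
            for i, (a, b) in enumerate(zip(self.mutant_peptide, self.wt_peptide))
            if a != b
        ]


@dataclass
class RejectionReport:
    """Per-reason counts of rejected input rows; accepted + rejected = input."""

    n_input: int = 0
    n_accepted: int = 0
    reasons: dict = field(default_factory=dict)

    def reject(self, reason: str) -> None:
        self.reasons[reason] = self.reasons.get(reason, 0) + 1

    @property
    def n_rejected(self) -> int:
        return sum(self.reasons.values())

    def as_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_accepted": self.n_accepted,
            **{f"rejected_{k}": v for k, v in self.reasons.items()},
        }


def read_dataset(
    path,
    column_map: Optional[Mapping[str, str]] = None,
) -> tuple[list[NeoEpitopeRecord], RejectionReport]:
    """Read a comma-separated dataset into records.

    Required columns (after mapping): mutant, wildtype, allele.  Optional:
    label, expression, foreignness, fold.  Rows with unparseable alleles or
    values are counted in the report rather than aborting the read; the
    structural peptide filters are applied later by :func:`validate_and_filter`.
    """
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(path)
    report = RejectionReport(n_input=len(df))
    for key in ("mutant", "wildtype", "allele"):
        if cols[key] not in df.columns:
            raise ConfigurationError(
                f"required column {cols[key]!r} missing from {path}"
            )
    records: list[NeoEpitopeRecord] = []
    for idx, row in df.iterrows():
        try:
            allele = normalise_allele(row[cols["allele"]])
        except ValueError:
            report.reject("unresolvable_allele")
            continue
        try:
            rec = NeoEpitopeRecord(
                mutant_peptide=str(row[cols["mutant"]]).strip().upper(),
                wt_peptide=str(row[cols["wildtype"]]).strip().upper(),
                allele=allele,
                label=_opt_int(row.get(cols["label"])),
                expression_tpm=_opt_float(row.get(cols["expression"])),
                foreignness=_opt_float(row.get(cols["foreignness"])),
                fold=_opt_int(row.get(cols["fold"])),
                source_id=str(idx),
            )
        except (TypeError, ValueError):
            report.reject("unparseable_row")
            continue
        records.append(rec)
    report.n_accepted = len(records)
    return records, report


def write_dataset(records: Iterable[NeoEpitopeRecord], path) -> None:
    """Write records back to the comma-separated format read_dataset accepts."""
    rows = []
    for r in records:
        row = {
            DEFAULT_COLUMNS["mutant"]: r.mutant_peptide,
            DEFAULT_COLUMNS["wildtype"]: r.wt_peptide,
            DEFAULT_COLUMNS["allele"]: r.allele,
        }
        if r.label is not None:
            row[DEFAULT_COLUMNS["label"]] = r.label
        if r.expression_tpm is not None:
            row[DEFAULT_COLUMNS["expression"]] = r.expression_tpm
        if r.foreignness is not None:
            row[DEFAULT_COLUMNS["foreignness"]] = r.foreignness
        if r.fold is not None:
            row[DEFAULT_COLUMNS["fold"]] = r.fold
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def collapse_labels(records: list[NeoEpitopeRecord]) -> list[NeoEpitopeRecord]:
    """Collapse duplicate (mutant peptide, allele) pairs to a single record.

    A pair is immunogenic if any duplicate is positive, and negative only if
    all labelled duplicates are negative; unlabelled duplicates of a labelled
    pair inherit the collapsed label.  First occurrence order is preserved,
    so the operation is idempotent.
    """
    order: list[tuple[str, str]] = []
    best: dict[tuple[str, str], NeoEpitopeRecord] = {}
    labels: dict[tuple[str, str], Optional[int]] = {}
    for rec in records:
        key = (rec.mutant_peptide, rec.allele)
        if key not in best:
            order.append(key)
            best[key] = rec
            labels[key] = rec.label
        else:
            if rec.label is not None:
                prev = labels[key]
                labels[key] = rec.label if prev is None else max(prev, rec.label)
    return [replace(best[k], label=labels[k]) for k in order]


def validate_and_filter(
    records: Iterable[NeoEpitopeRecord],
    predictor,
    max_icore_mismatches: int = 3,
    min_length: int = MIN_LENGTH,
    max_length: int = MAX_LENGTH,
) -> tuple[list[NeoEpitopeRecord], RejectionReport]:
    """Apply the record-level filters and attach ICORE pairs.

    Rejection reasons: ``bad_alphabet``, ``length_out_of_range``,
    ``missing_wt``, ``frameshift_length_mismatch``, ``no_mutation``,
    ``unresolvable_allele``, ``too_many_icore_mismatches``.
    Raises :class:`ConfigurationError` if the predictor does not cover an
    allele present in the input.
    """
    from .icore import align_wt_icore, extract_icore

    records = list(records)
    alleles = {r.allele for r in records}
    missing = sorted(a for a in alleles if not predictor.supports(a))
    if missing:
        raise ConfigurationError(
            "rank predictor does not cover allele(s): " + ", ".join(missing)
        )

    report = RejectionReport(n_input=len(records))
    accepted: list[NeoEpitopeRecord] = []
    for rec in records:
        if not rec.wt_peptide or rec.wt_peptide in ("NAN", "NA", "-"):
            report.reject("missing_wt")
            continue
        if not (_ALPHABET_SET >= set(rec.mutant_peptide)
                and _ALPHABET_SET >= set(rec.wt_peptide)):
            report.reject("bad_alphabet")
            continue
        if len(rec.mutant_peptide) != len(rec.wt_peptide):
            report.reject("frameshift_length_mismatch")
            continue
        if not (min_length <= len(rec.mutant_peptide) <= max_length):
            report.reject("length_out_of_range")
            continue
        if rec.mutant_peptide == rec.wt_peptide:
            report.reject("no_mutation")
            continue
        core = extract_icore(rec.mutant_peptide, rec.allele, predictor)
        pair = align_wt_icore(core, rec.wt_peptide, predictor)
        n_mm = sum(a != b for a, b in zip(pair.mut_icore, pair.wt_icore))
        if n_mm > max_icore_mismatches:
            report.reject("too_many_icore_mismatches")
            continue
        rec.icore = pair
        accepted.append(rec)
    report.n_accepted = len(accepted)
    return accepted, report


def _opt_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, str) and not value.strip():
        return None
    return float(value)


def _opt_int(value) -> Optional[int]:
    f = _opt_float(value)
    return None if f is None else int(f)
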