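"""End-to-end orchestration: configuration, training, prediction, evaluation.

Ties the modules together the way the command-line interface exposes them:
read and filter a dataset, build anchor profiles, partition leakage-free,
train the nested-CV forest ensemble, calibrate percentile ranks against a
mutated-proteome background, and score new inputs.  A deterministic
surrogate rank predictor is constructed for any allele present in the data
unless a precomputed NetMHCpan output file is supplied.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .binding import SurrogateAllele, SurrogatePredictor, TableRankPredictor, parse_netmhcpan_output
from .ensemble import RFEnsemble, RFHyperparams, train_nested_cv
from .evaluation import bootstrap_compare, pauc01, roc_auc
from .features import Encoding, FeatureConfig, FeatureFlags, feature_matrix
from .partitioning import apply_plan, make_partitions, max_cross_fold_similarity
from .profiles import ProfileStore, WeightScheme
from .records import (
    NeoEpitopeRecord,
    collapse_labels,
    read_dataset,
    validate_and_filter,
)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Run configuration; round-trips losslessly through YAML."""

    # thresholds
    similarity_threshold: float = 0.9
    anchor_ic_threshold: float = 0.2
    strong_binder_rank: float = 0.25
    max_icore_mismatches: int = 3
    # model input
    scheme: str = "NormalMask"
    encoding: str = "OneHot"
    flags: dict = field(default_factory=lambda: FeatureFlags(
        blosum_mutation_score=True, expression=True).to_dict())
    # training
    k: int = 10
    seed: int = 0
    n_binders: int = 1000
    background_size: int = 5000
    hyperparams: dict = field(default_factory=lambda: RFHyperparams().to_dict())
    # optional precomputed NetMHCpan-4.1 output file
    netmhcpan_output: Optional[str] = None

    def __post_init__(self) -> None:
        if not (0 < self.similarity_threshold <= 1):
            raise ValueError("similarity threshold must be in (0, 1]")
        if not (0 < self.anchor_ic_threshold < 1):
            raise ValueError("anchor IC threshold must be in (0, 1)")
        if self.strong_binder_rank <= 0 or self.max_icore_mismatches < 0:
            raise ValueError("thresholds out of range")

    def feature_config(self, tpm_median: Optional[float] = None) -> FeatureConfig:
        return FeatureConfig(
            scheme=WeightScheme(self.scheme),
            encoding=Encoding(self.encoding),
            flags=FeatureFlags.from_dict(self.flags),
            tpm_median=tpm_median,
        )

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))


def surrogate_allele_for(name: str, seed: int = 0) -> SurrogateAllele:
    """Deterministic surrogate motif for an allele name.

    The motif seed derives from a CRC32 of the canonical name, so the same
    allele always gets the same motif for a given base seed — a dataset
    generated and a model trained with the same seed therefore agree on
    every predicted rank.
    """
    h = zlib.crc32(name.encode()) % 65536
    anchors = (2, -1) if h % 2 else (2, 5, -1)
    return SurrogateAllele(name=name, anchors=anchors, seed=seed + h)


def surrogate_for_alleles(names: Sequence[str], seed: int = 0) -> SurrogatePredictor:
    """Deterministic surrogate predictor covering the given allele names."""
    return SurrogatePredictor(
        [surrogate_allele_for(name, seed) for name in sorted(set(names))]
    )


def build_predictor(records: Sequence[NeoEpitopeRecord], config: RunConfig):
    if config.netmhcpan_output:
        return TableRankPredictor(parse_netmhcpan_output(config.netmhcpan_output))
    return surrogate_for_alleles([r.allele for r in records], seed=config.seed)


@dataclass
class TrainedModel:
    """Everything produced by a training run."""

    ensemble: RFEnsemble
    profiles: ProfileStore
    config: RunConfig
    oof_scores: np.ndarray
    oof_labels: np.ndarray
    oof_auc: float
    tpm_median: Optional[float]
    leakage_max_similarity: float
    # training-time artifacts, kept for diagnostics; not persisted
    train_X: Optional[pd.DataFrame] = None
    train_folds: Optional[np.ndarray] = None

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.ensemble.metadata.update(
            {
                "tpm_median": self.tpm_median,
                "oof_auc": self.oof_auc,
                "leakage_max_similarity": self.leakage_max_similarity,
            }
        )
        self.ensemble.save(d)
        (d / "profiles.yaml").write_text(yaml.safe_dump(self.profiles.to_dict()))
        self.config.to_yaml(d / "config.yaml")

    @classmethod
    def load(cls, directory) -> "TrainedModel":
        d = Path(directory)
        ensemble = RFEnsemble.load(d)
        profiles = ProfileStore.from_dict(
            yaml.safe_load((d / "profiles.yaml").read_text())
        )
        config = RunConfig.from_yaml(d / "config.yaml")
        return cls(
            ensemble=ensemble,
            profiles=profiles,
            config=config,
            oof_scores=np.empty(0),
            oof_labels=np.empty(0),
            oof_auc=float(ensemble.metadata.get("oof_auc", float("nan"))),
            tpm_median=ensemble.metadata.get("tpm_median"),
            leakage_max_similarity=float(
                ensemble.metadata.get("leakage_max_similarity", float("nan"))
            ),
        )


def prepare_records(
    records: Sequence[NeoEpitopeRecord], config: RunConfig, predictor=None
):
    """Collapse duplicate labels, filter, and attach ICORE pairs."""
    records = collapse_labels(list(records))
    predictor = predictor or build_predictor(records, config)
    accepted, report = validate_and_filter(
        records, predictor, max_icore_mismatches=config.max_icore_mismatches
    )
    return accepted, report, predictor


def train_pipeline(
    records: Sequence[NeoEpitopeRecord],
    config: Optional[RunConfig] = None,
    background: Optional[Sequence[NeoEpitopeRecord]] = None,
    audit_leakage: bool = True,
    predictor=None,
) -> TrainedModel:
    """Full training run on labelled records.

    Builds the surrogate (or table) predictor, anchor profiles and a
    leakage-free partition plan (unless records already carry folds), fits
    the k*(k-1) forest ensemble, and calibrates percentile ranks against
    the supplied (or generated) background records.
    """
    config = config or RunConfig()
    accepted, report, predictor = prepare_records(records, config, predictor)
    labelled = [r for r in accepted if r.label is not None]
    if not labelled:
        raise ValueError("no labelled records after filtering")
    logger.info("filter report: %s", report.as_dict())

    lengths = sorted({r.icore.length for r in labelled})
    profiles = ProfileStore.build(
        predictor,
        sorted({r.allele for r in labelled}),
        lengths=lengths,
        n_binders=config.n_binders,
        rank_threshold=config.strong_binder_rank,
        seed=config.seed,
    )

    if any(r.fold is None for r in labelled):
        plan = make_partitions(
            labelled, k=config.k, seed=config.seed,
            threshold=config.similarity_threshold,
        )
        apply_plan(labelled, plan)
    leak = float("nan")
    if audit_leakage:
        leak = max_cross_fold_similarity(
            [r.mutant_peptide for r in labelled], [r.fold for r in labelled]
        )
        logger.info("leakage audit: max cross-fold similarity %.4f", leak)

    tpms = [r.expression_tpm for r in labelled if r.expression_tpm is not None]
    tpm_median = float(np.median(tpms)) if tpms else None
    fconfig = config.feature_config(tpm_median)
    X = feature_matrix(labelled, profiles, fconfig)
    y = np.array([r.label for r in labelled])
    folds = np.array([r.fold for r in labelled])
    ensemble, oof = train_nested_cv(
        X, y, folds,
        hyperparams=RFHyperparams(**{**config.hyperparams, "seed": config.seed}),
        scheme=config.scheme, encoding=config.encoding,
    )
    oof_auc = roc_auc(y, oof)
    logger.info("out-of-fold AUC %.4f over %d records", oof_auc, len(y))

    if background is None:
        from .synthetic import SurrogateAlleleSet, background_records

        if isinstance(predictor, SurrogatePredictor):
            allele_pool = list(predictor.alleles.values())
        else:  # table predictors cannot score arbitrary background peptides
            allele_pool = []
        if allele_pool:
            usage = np.full(len(allele_pool), 1.0 / len(allele_pool))
            allele_set = SurrogateAlleleSet(alleles=allele_pool, usage=usage)
            background = background_records(
                config.background_size, allele_set, seed=config.seed + 17
            )
    if background:
        bg_accepted, _, _ = prepare_records(background, config, predictor)
        missing = {
            (r.allele, r.icore.length) for r in bg_accepted
        } - {k for k, _ in profiles.items()}
        for allele, length in sorted(missing):
            from .binding import sample_strong_binders
            from .profiles import build_frequency_profile

            binders = sample_strong_binders(
                predictor, allele, length, config.n_binders,
                rank_threshold=config.strong_binder_rank,
                seed=config.seed + length,
            )
            profiles._profiles[(allele, length)] = build_frequency_profile(
                binders, allele=allele
            )
        bg_X = feature_matrix(bg_accepted, profiles, fconfig)
        ensemble.calibrate(bg_X)

    return TrainedModel(
        ensemble=ensemble,
        profiles=profiles,
        config=config,
        oof_scores=oof,
        oof_labels=y,
        oof_auc=oof_auc,
        tpm_median=tpm_median,
        leakage_max_similarity=leak,
        train_X=X,
        train_folds=folds,
    )


def predict_pipeline(
    records: Sequence[NeoEpitopeRecord], model: TrainedModel
) -> pd.DataFrame:
    """Score records with a trained model.

    Returns one row per accepted record with the ICORE columns, the model
    score in [0, 1] and, when the model is calibrated, the 0-100 percentile
    rank (0 = most immunogenic-like).  Input row order is preserved for
    accepted records.
    """
    config = model.config
    predictor = build_predictor(records, config)
    accepted, report, _ = prepare_records(records, config, predictor)
    if not accepted:
        raise ValueError(f"no records passed filtering: {report.as_dict()}")
    missing = {(r.allele, r.icore.length) for r in accepted} - {
        k for k, _ in model.profiles.items()
    }
    if missing:
        raise ValueError(
            "model has no anchor profile for: "
            + ", ".join(f"{a}/{l}" for a, l in sorted(missing))
        )
    fconfig = config.feature_config(model.tpm_median)
    X = feature_matrix(accepted, model.profiles, fconfig)
    scores = model.ensemble.predict(X)
    out = pd.DataFrame(
        {
            "source_id": [r.source_id for r in accepted],
            "mutant_peptide": [r.mutant_peptide for r in accepted],
            "wt_peptide": [r.wt_peptide for r in accepted],
            "hla_allele": [r.allele for r in accepted],
            "icore_mut": [r.icore.mut_icore for r in accepted],
            "icore_wt": [r.icore.wt_icore for r in accepted],
            "icore_offset_1based": [r.icore.offset_1based for r in accepted],
            "icore_len": [r.icore.length for r in accepted],
            "rank_mut": [r.icore.mut_rank for r in accepted],
            "rank_wt": [r.icore.wt_rank for r in accepted],
            "prediction_score": scores,
        }
    )
    for col in X.columns:
        if col not in out.columns:
            out[col] = X[col].to_numpy()
    if model.ensemble.calibration_scores is not None:
        out["percentile_rank"] = model.ensemble.percentile_rank(scores)
    return out


def evaluate_scores(
    df: pd.DataFrame,
    label_col: str,
    method_cols: Sequence[str],
    n_rounds: int = 1000,
    seed: int = 0,
) -> dict:
    """AUC / normalised pAUC0.1 per method plus pairwise bootstrap p-values."""
    labels = df[label_col].to_numpy(dtype=int)
    report: dict = {"n_records": len(df), "n_rounds": n_rounds, "methods": {}}
    for col in method_cols:
        report["methods"][col] = {
            "auc": roc_auc(labels, df[col]),
            "pauc01_normalised": pauc01(labels, df[col]),
        }
    report["pairwise_p"] = {}
    for i, c1 in enumerate(method_cols):
        for c2 in method_cols[i + 1:]:
            fwd = bootstrap_compare(
                labels, df[c1], df[c2], n_rounds=n_rounds, seed=seed
            )
            rev = bootstrap_compare(
                labels, df[c2], df[c1], n_rounds=n_rounds, seed=seed
            )
            report["pairwise_p"][f"{c1} > {c2}"] = fwd.p_value
            report["pairwise_p"][f"{c2} > {c1}"] = rev.p_value
    return report


def load_dataset(path, column_map=None) -> list[NeoEpitopeRecord]:
    records, report = read_dataset(path, column_map)
    logger.info("read %d records (%s)", len(records), report.as_dict())
    return records
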