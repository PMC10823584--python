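"""Nested cross-validation Random Forest ensemble.

For k folds, each outer fold o is held out in turn and, for every inner
fold i != o, one forest is fitted on the remaining k-2 folds — yielding
k*(k-1) members (90 at k = 10).  The out-of-fold prediction for a record
in fold o is the mean positive-class probability of the k-1 members whose
training data excluded fold o; external predictions average all members.
Final scores are reported as percentile ranks (0-100, 0 = most
immunogenic-like) against a background of randomly mutated proteome
peptides scored with the same feature schema.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass
class RFHyperparams:
    """Random Forest hyperparameters (tuned constants, not searched)."""

    n_trees: int = 300
    max_depth: int = 8
    min_samples_leaf: int = 7
    pruning_alpha: float = 1e-5  # cost-complexity pruning strength
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_trees, self.max_depth, self.min_samples_leaf) <= 0:
            raise ValueError("forest hyperparameters must be positive")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


@dataclass
class EnsembleMember:
    outer_fold: int
    inner_fold: int
    model: RandomForestClassifier


@dataclass
class RFEnsemble:
    """k*(k-1) fitted forests plus the feature schema and calibration."""

    members: list[EnsembleMember]
    feature_names: list[str]
    k: int
    hyperparams: RFHyperparams
    scheme: str = "None"
    encoding: str = "OneHot"
    calibration_scores: Optional[np.ndarray] = None
    metadata: dict = field(default_factory=dict)

    def _check_schema(self, X: pd.DataFrame) -> np.ndarray:
        if isinstance(X, pd.DataFrame):
            missing = [c for c in self.feature_names if c not in X.columns]
            extra = [c for c in X.columns if c not in self.feature_names]
            if missing or extra:
                raise ValueError(
                    f"feature schema mismatch; missing={missing}, extra={extra}"
                )
            return X[self.feature_names].to_numpy(dtype=float)
        arr = np.asarray(X, dtype=float)
        if arr.shape[1] != len(self.feature_names):
            raise ValueError(
                f"expected {len(self.feature_names)} features, got {arr.shape[1]}"
            )
        return arr

    def predict(self, X) -> np.ndarray:
        """Mean positive-class probability over all ensemble members."""
        arr = self._check_schema(X)
        probs = np.zeros(len(arr))
        for m in self.members:
            probs += m.model.predict_proba(arr)[:, 1]
        return probs / len(self.members)

    def feature_importances(self) -> pd.Series:
        """Mean impurity-decrease importance per feature, renormalised to 1."""
        imp = np.zeros(len(self.feature_names))
        for m in self.members:
            imp += m.model.feature_importances_
        imp /= imp.sum()
        return pd.Series(imp, index=self.feature_names)

    # --- percentile calibration ---------------------------------------------

    def calibrate(self, background_X) -> None:
        """Store sorted model scores of the calibration background."""
        scores = self.predict(background_X)
        if len(scores) == 0:
            raise ValueError("calibration background must be non-empty")
        self.calibration_scores = np.sort(scores)

    def percentile_rank(self, scores) -> np.ndarray:
        """Map scores to 0-100 percentile ranks against the background.

        rank = 100 * (#background >= score) / #background, monotone
        non-increasing in the score; 0 means above every background peptide.
        """
        if self.calibration_scores is None or len(self.calibration_scores) == 0:
            raise ValueError("ensemble has no calibration background")
        bg = self.calibration_scores
        scores = np.atleast_1d(np.asarray(scores, dtype=float))
        n_ge = len(bg) - np.searchsorted(bg, scores, side="left")
        return 100.0 * n_ge / len(bg)

    # --- persistence ---------------------------------------------------------

    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "feature_names": self.feature_names,
            "k": self.k,
            "hyperparams": self.hyperparams.to_dict(),
            "scheme": self.scheme,
            "encoding": self.encoding,
            "members": [
                {"outer": m.outer_fold, "inner": m.inner_fold,
                 "file": f"member_{m.outer_fold}_{m.inner_fold}.joblib"}
                for m in self.members
            ],
            **self.metadata,
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=2))
        if self.calibration_scores is not None:
            np.savetxt(d / "calibration_scores.txt", self.calibration_scores)
        for m in self.members:
            joblib.dump(m.model, d / f"member_{m.outer_fold}_{m.inner_fold}.joblib")

    @classmethod
    def load(cls, directory) -> "RFEnsemble":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text())
        members = [
            EnsembleMember(
                outer_fold=spec["outer"],
                inner_fold=spec["inner"],
                model=joblib.load(d / spec["file"]),
            )
            for spec in meta["members"]
        ]
        calib = None
        calib_path = d / "calibration_scores.txt"
        if calib_path.exists():
            calib = np.loadtxt(calib_path)
        extra = {
            k: v for k, v in meta.items()
            if k not in ("feature_names", "k", "hyperparams", "scheme",
                         "encoding", "members")
        }
        return cls(
            members=members,
            feature_names=meta["feature_names"],
            k=meta["k"],
            hyperparams=RFHyperparams(**meta["hyperparams"]),
            scheme=meta["scheme"],
            encoding=meta["encoding"],
            calibration_scores=calib,
            metadata=extra,
        )


def train_nested_cv(
    X: pd.DataFrame,
    y: Sequence[int],
    folds: Sequence[int],
    hyperparams: Optional[RFHyperparams] = None,
    scheme: str = "None",
    encoding: str = "OneHot",
) -> tuple[RFEnsemble, np.ndarray]:
    """Train the k*(k-1) member ensemble and return out-of-fold scores.

    For every ordered pair of distinct folds (o, i), one forest is fitted
    on the records outside folds o and i.  A training split containing a
    single class aborts with an error naming the split.
    """
    hp = hyperparams or RFHyperparams()
    y = np.asarray(y, dtype=int)
    folds = np.asarray(folds, dtype=int)
    fold_ids = sorted(set(folds.tolist()))
    k = len(fold_ids)
    if k < 3:
        raise ValueError("nested cross-validation needs at least 3 folds")
    feature_names = list(X.columns)
    arr = X.to_numpy(dtype=float)
    members: list[EnsembleMember] = []
    oof = np.zeros(len(y))
    oof_counts = np.zeros(len(y))
    for idx_o, o in enumerate(fold_ids):
        for idx_i, i in enumerate(fold_ids):
            if i == o:
                continue
            train_mask = (folds != o) & (folds != i)
            y_train = y[train_mask]
            if len(np.unique(y_train)) < 2:
                raise ValueError(
                    f"training split excluding folds ({o}, {i}) has a single class"
                )
            model = RandomForestClassifier(
                n_estimators=hp.n_trees,
                max_depth=hp.max_depth,
                min_samples_leaf=hp.min_samples_leaf,
                ccp_alpha=hp.pruning_alpha,
                random_state=hp.seed + 9973 * idx_o + idx_i,
                n_jobs=1,
            )
            model.fit(arr[train_mask], y_train)
            members.append(EnsembleMember(o, i, model))
            test_mask = folds == o
            oof[test_mask] += model.predict_proba(arr[test_mask])[:, 1]
            oof_counts[test_mask] += 1
    oof /= np.maximum(oof_counts, 1)
    ensemble = RFEnsemble(
        members=members,
        feature_names=feature_names,
        k=k,
        hyperparams=hp,
        scheme=scheme,
        encoding=encoding,
    )
    return ensemble, oof
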