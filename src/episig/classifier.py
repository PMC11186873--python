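"""SVM episignature classifier and MVP scoring.

A linear-kernel support vector machine is trained on the selected
probes' beta values, cases against everything else in the training
partition (matched controls, 75% of other controls, 75% of each other-
disorder cohort; the remaining 25% of each is held out for testing).
The decision values are mapped to a methylation-variant-pathogenicity
(MVP) score in [0, 1] by a Platt-style sigmoid fitted to the training
decision values; a sample is called positive when its score reaches the
cutoff (default 0.25).

The model is wrapped in a scikit-learn style estimator,
:class:`MvpClassifier`, and persists to JSON (probe ids, weights, bias,
sigmoid coefficients) — no opaque binary artifacts, so a saved model can
be audited probe by probe.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Mapping, Optional

import numpy as np
import pandas as pd
from scipy.special import expit
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .containers import BetaMatrix
from .errors import ConfigError, ValidationError

DEFAULT_CUTOFF = 0.25


@dataclass
class TrainingDesign:
    """Train/test partition for classifier construction.

    Cases and their matched controls are always in training; every other
    cohort is split 75/25 (seeded, without replacement).
    """

    case_ids: List[str]
    matched_control_ids: List[str]
    other_train_ids: List[str]
    test_ids: List[str]
    split: float
    split_seed: int
    warnings: List[str] = field(default_factory=list)

    @property
    def train_ids(self) -> List[str]:
        return self.case_ids + self.matched_control_ids + self.other_train_ids

    def __post_init__(self) -> None:
        overlap = set(self.train_ids) & set(self.test_ids)
        if overlap:
            raise ValidationError(
                f"train and test partitions overlap: {sorted(overlap)[:5]}"
            )

    def roles(self) -> pd.Series:
        """Per-sample role label ('train' or 'test')."""
        roles = {s: "train" for s in self.train_ids}
        roles.update({s: "test" for s in self.test_ids})
        return pd.Series(roles, name="role")


def build_design(
    samples: pd.DataFrame,
    case_ids: Iterable[str],
    matched_control_ids: Iterable[str],
    split: float = 0.75,
    seed: int = 0,
    holdout_cohorts: Iterable[str] = (),
) -> TrainingDesign:
    """Partition the sample sheet into the SVM training design.

    ``samples`` must carry a ``cohort`` column. Cohorts other than the
    cases' and matched controls' own rows are each split
    ``split``/``1 - split`` into train/test by a seeded uniform draw
    without replacement; a cohort with fewer than 2 members cannot be
    split and is placed wholly in test, with a warning recorded on the
    design. Cohorts named in ``holdout_cohorts`` are placed wholly in
    test — the treatment given to validation samples of the target
    syndrome and to related-syndrome cohorts whose overlap with the
    signature is itself under study.
    """
    if not 0.0 <= split <= 1.0:
        raise ConfigError("split fraction must lie in [0, 1]")
    case_ids = list(case_ids)
    matched_control_ids = list(matched_control_ids)
    fixed = set(case_ids) | set(matched_control_ids)
    missing = fixed - set(samples.index)
    if missing:
        raise ValidationError(f"ids absent from sample sheet: {sorted(missing)[:5]}")
    rng = np.random.default_rng(seed)
    holdout = set(holdout_cohorts)
    other = samples.loc[[s for s in samples.index if s not in fixed]]
    other_train: List[str] = []
    test: List[str] = []
    warnings: List[str] = []
    for cohort, members in other.groupby("cohort", sort=True):
        ids = list(members.index)
        if cohort in holdout:
            test.extend(ids)
            continue
        if len(ids) < 2 and split < 1.0:
            warnings.append(
                f"cohort {cohort!r} has {len(ids)} sample(s); placed wholly in test"
            )
            test.extend(ids)
            continue
        n_train = int(np.floor(split * len(ids)))
        picked = rng.choice(len(ids), size=n_train, replace=False)
        picked_set = {ids[i] for i in picked}
        other_train.extend(sorted(picked_set))
        test.extend(sorted(set(ids) - picked_set))
    return TrainingDesign(
        case_ids=case_ids,
        matched_control_ids=matched_control_ids,
        other_train_ids=other_train,
        test_ids=test,
        split=split,
        split_seed=seed,
        warnings=warnings,
    )


class MvpClassifier(BaseEstimator, ClassifierMixin):
    """Linear SVM with Platt-style sigmoid calibration to MVP scores.

    ``fit`` expects ``X`` as a samples x probes beta-value matrix
    (DataFrame, probes in a fixed order) and ``y`` as a binary case
    indicator. ``predict_proba``'s positive-class column is the MVP
    score; ``predict`` applies the positivity cutoff.

    Parameters
    ----------
    C : float
        SVM regularisation constant (margin softness).
    cutoff : float
        MVP positivity threshold; a sample is called positive when its
        score is greater than or equal to the cutoff.

    Attributes
    ----------
    probe_ids_ : list of str
        Feature order the model was trained on.
    coef_, intercept_ : ndarray
        Separating hyperplane on the beta scale.
    sigmoid_a_, sigmoid_b_ : float
        MVP score = expit(a * decision_value + b).
    """

    def __init__(self, C: float = 1.0, cutoff: float = DEFAULT_CUTOFF):
        self.C = C
        self.cutoff = cutoff

    # -- training ---------------------------------------------------------
    def fit(self, X: pd.DataFrame, y) -> "MvpClassifier":
        y = np.asarray(y, dtype=int)
        if len(np.unique(y)) < 2:
            raise ValidationError("training data contain a single class")
        if not isinstance(X, pd.DataFrame):
            X = pd.DataFrame(np.asarray(X, dtype=float))
        svm = SVC(kernel="linear", C=self.C, class_weight="balanced")
        svm.fit(X.to_numpy(dtype=float), y)
        # orient the decision function toward the case class (label 1)
        sign = 1.0 if svm.classes_[1] == 1 else -1.0
        self.coef_ = sign * svm.coef_.ravel()
        self.intercept_ = float(sign * svm.intercept_[0])
        f = X.to_numpy(dtype=float) @ self.coef_ + self.intercept_
        # Platt-style sigmoid on the training decision values; weakly
        # regularised logistic fit keeps the mapping finite even when the
        # classes are linearly separable
        lr = LogisticRegression(C=1.0, solver="lbfgs")
        lr.fit(f.reshape(-1, 1), y)
        self.sigmoid_a_ = float(lr.coef_[0, 0])
        self.sigmoid_b_ = float(lr.intercept_[0])
        self.probe_ids_ = [str(c) for c in X.columns]
        self.classes_ = np.array([0, 1])
        return self

    # -- scoring ----------------------------------------------------------
    def _check_fitted(self) -> None:
        if not hasattr(self, "coef_"):
            raise ValidationError("classifier is not fitted")

    def _features(self, X: pd.DataFrame) -> np.ndarray:
        self._check_fitted()
        if isinstance(X, pd.DataFrame):
            missing = [p for p in self.probe_ids_ if p not in X.columns]
            if missing:
                raise ValidationError(
                    f"{len(missing)} model probes absent from input: {missing[:5]}"
                )
            return X[self.probe_ids_].to_numpy(dtype=float)
        X = np.asarray(X, dtype=float)
        if X.shape[1] != len(self.probe_ids_):
            raise ValidationError("feature count does not match the model")
        return X

    def decision_function(self, X) -> np.ndarray:
        return self._features(X) @ self.coef_ + self.intercept_

    def predict_proba(self, X) -> np.ndarray:
        score = expit(self.sigmoid_a_ * self.decision_function(X) + self.sigmoid_b_)
        return np.column_stack([1.0 - score, score])

    def mvp_scores(self, X) -> np.ndarray:
        """MVP score per sample, in [0, 1]."""
        return self.predict_proba(X)[:, 1]

    def predict(self, X) -> np.ndarray:
        return (self.mvp_scores(X) >= self.cutoff).astype(int)

    # -- persistence --------------------------------------------------------
    def to_json(self, path=None) -> str:
        self._check_fitted()
        payload = {
            "model": "linear_svm_platt",
            "C": self.C,
            "cutoff": self.cutoff,
            "probe_ids": self.probe_ids_,
            "coef": list(map(float, self.coef_)),
            "intercept": self.intercept_,
            "sigmoid_a": self.sigmoid_a_,
            "sigmoid_b": self.sigmoid_b_,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source) -> "MvpClassifier":
        if isinstance(source, Path) or (
            isinstance(source, str) and not source.lstrip().startswith("{")
        ):
            payload = json.loads(Path(source).read_text())
        else:
            payload = json.loads(source)
        model = cls(C=payload["C"], cutoff=payload["cutoff"])
        model.probe_ids_ = list(payload["probe_ids"])
        model.coef_ = np.asarray(payload["coef"], dtype=float)
        model.intercept_ = float(payload["intercept"])
        model.sigmoid_a_ = float(payload["sigmoid_a"])
        model.sigmoid_b_ = float(payload["sigmoid_b"])
        model.classes_ = np.array([0, 1])
        return model


def train_mvp(
    beta: BetaMatrix | pd.DataFrame,
    probe_ids: Iterable[str],
    design: TrainingDesign,
    C: float = 1.0,
    cutoff: float = DEFAULT_CUTOFF,
) -> MvpClassifier:
    """Train the MVP classifier on the design's training partition."""
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    probe_ids = list(probe_ids)
    train = design.train_ids
    X = values.loc[probe_ids, train].T
    y = np.array([1 if s in set(design.case_ids) else 0 for s in train])
    return MvpClassifier(C=C, cutoff=cutoff).fit(X, y)


def score_mvp(
    model: MvpClassifier,
    beta: BetaMatrix | pd.DataFrame,
    sample_ids: Optional[Iterable[str]] = None,
    roles: Optional[Mapping[str, str]] = None,
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """MVP scores and positivity calls for the given samples.

    Returns one row per sample: ``mvp_score``, ``call`` ('positive' /
    'negative'), and ``role`` when a role mapping is supplied.
    """
    values = beta.values if isinstance(beta, BetaMatrix) else beta
    ids = list(sample_ids) if sample_ids is not None else list(values.columns)
    cut = model.cutoff if cutoff is None else cutoff
    scores = model.mvp_scores(values.loc[:, ids].T)
    out = pd.DataFrame(
        {
            "mvp_score": scores,
            "call": np.where(scores >= cut, "positive", "negative"),
        },
        index=pd.Index(ids, name="sample_id"),
    )
    if roles is not None:
        out["role"] = [roles.get(s, "") for s in ids]
    return out


def evaluate_specificity(
    model: MvpClassifier,
    beta: BetaMatrix | pd.DataFrame,
    cohort_test_sets: Mapping[str, Iterable[str]],
    cutoff: Optional[float] = None,
) -> pd.DataFrame:
    """Positive-call rate per cohort at the configured cutoff."""
    rows = []
    for cohort, ids in cohort_test_sets.items():
        ids = list(ids)
        scored = score_mvp(model, beta, ids, cutoff=cutoff)
        rows.append(
            {
                "cohort": cohort,
                "n": len(ids),
                "positive_rate": float((scored["call"] == "positive").mean())
                if ids
                else float("nan"),
                "median_mvp": float(scored["mvp_score"].median()) if ids else float("nan"),
            }
        )
    return pd.DataFrame(rows).set_index("cohort")
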