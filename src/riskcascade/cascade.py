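"""Confidence-thresholded cascade classification.

An ordered sequence of probabilistic classifiers is applied to each subject.
A stage *accepts* a subject when one of its class probabilities reaches that
class's acceptance threshold (default 0.70 for the positive
overweight/obesity class, 0.80 for the negative healthy class, so with these
defaults the two acceptance conditions are mutually exclusive); otherwise the
subject is *deferred* to the next stage.  Subjects deferred by the final
stage remain unclassified unless ``force_final`` is set, in which case the
final stage's argmax label is assigned and flagged as forced.

The module follows the Model/Results convention: :class:`CascadeModel` is
built from a training :class:`~riskcascade.cohort.CohortTable` and a
:class:`CascadeConfig`; ``fit()`` returns a :class:`CascadeResults` whose
``predict()`` yields per-subject :class:`CascadeDecision` records and
per-stage flow counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .cohort import CohortTable
from .errors import (DegenerateDataError, InvalidArgumentError,
                     SchemaMismatchError, StageFitError)

POSITIVE, NEGATIVE = 1, 0

LEARNER_IDS = (
    "adaboost", "bagging", "bernoulli_nb", "decision_tree", "extra_trees",
    "gradient_boosting", "gaussian_nb", "logistic_regression", "random_forest",
)

LEARNER_LABELS = {
    "adaboost": "AdaBoost", "bagging": "Bagging",
    "bernoulli_nb": "Bernoulli NB", "decision_tree": "Decision Tree",
    "extra_trees": "Extra Trees", "gradient_boosting": "Gradient Boosting",
    "gaussian_nb": "Gaussian NB", "logistic_regression": "Logistic Regression",
    "random_forest": "Random Forest",
}


def make_learner(learner_id: str, hyperparameters: dict | None = None,
                 seed: int = 0):
    """Instantiate one of the nine supported scikit-learn base learners."""
    from sklearn.ensemble import (AdaBoostClassifier, BaggingClassifier,
                                  ExtraTreesClassifier,
                                  GradientBoostingClassifier,
                                  RandomForestClassifier)
    from sklearn.linear_model import LogisticRegression
    from sklearn.naive_bayes import BernoulliNB, GaussianNB
    from sklearn.pipeline import make_pipeline
    from sklearn.preprocessing import StandardScaler
    from sklearn.tree import DecisionTreeClassifier

    hp = dict(hyperparameters or {})
    if learner_id not in LEARNER_IDS:
        raise InvalidArgumentError(
            f"unknown learner {learner_id!r}; expected one of {LEARNER_IDS}")
    if learner_id == "adaboost":
        return AdaBoostClassifier(random_state=seed, **hp)
    if learner_id == "bagging":
        return BaggingClassifier(random_state=seed, **hp)
    if learner_id == "bernoulli_nb":
        # center first so the Bernoulli binarization splits at each
        # feature's mean rather than at code zero
        return make_pipeline(StandardScaler(), BernoulliNB(**hp))
    if learner_id == "decision_tree":
        return DecisionTreeClassifier(random_state=seed, **hp)
    if learner_id == "extra_trees":
        return ExtraTreesClassifier(random_state=seed, **hp)
    if learner_id == "gradient_boosting":
        return GradientBoostingClassifier(random_state=seed, **hp)
    if learner_id == "gaussian_nb":
        return GaussianNB(**hp)
    if learner_id == "logistic_regression":
        # scale-sensitive learner: standardize the mixed-unit questionnaire codes
        return make_pipeline(StandardScaler(),
                             LogisticRegression(max_iter=2000, random_state=seed,
                                                **hp))
    if learner_id == "random_forest":
        return RandomForestClassifier(random_state=seed, **hp)


@dataclass(frozen=True)
class StageSpec:
    """One cascade stage: a learner identity plus hyperparameters and seed."""

    learner_id: str
    hyperparameters: tuple = ()  # tuple of (name, value) pairs; hashable
    seed: int = 0

    def __post_init__(self):
        if self.learner_id not in LEARNER_IDS:
            raise InvalidArgumentError(f"unknown learner {self.learner_id!r}")
        if isinstance(self.hyperparameters, dict):
            object.__setattr__(self, "hyperparameters",
                               tuple(sorted(self.hyperparameters.items())))

    @property
    def hp(self) -> dict:
        return dict(self.hyperparameters)

    def build(self):
        return make_learner(self.learner_id, self.hp, self.seed)


DEFAULT_STAGES = (
    StageSpec("gradient_boosting"),
    StageSpec("random_forest"),
    StageSpec("logistic_regression"),
)


@dataclass(frozen=True)
class CascadeConfig:
    """Stage list, acceptance thresholds, ordering policy.

    ``positive_threshold`` / ``negative_threshold`` are the class-probability
    levels a stage must reach to accept a subject as overweight/obesity or
    healthy respectively.  ``ordering_mode`` is ``"manual"`` (use the list as
    given) or ``"by_training_accuracy"`` (reorder stages by descending
    cross-validated training accuracy before fitting).  ``refit_on_deferred``
    is an experimental regime in which stage *i* (> 1) is refitted only on
    the training rows stage *i-1* would defer.
    """

    stages: tuple = DEFAULT_STAGES
    positive_threshold: float = 0.70
    negative_threshold: float = 0.80
    ordering_mode: str = "manual"
    force_final: bool = False
    refit_on_deferred: bool = False

    def __post_init__(self):
        if len(self.stages) < 1:
            raise InvalidArgumentError("cascade needs at least one stage")
        for t in (self.positive_threshold, self.negative_threshold):
            if not (0.5 < t <= 1.0):
                raise InvalidArgumentError(
                    "thresholds must lie in (0.5, 1.0]")
        if self.ordering_mode not in ("manual", "by_training_accuracy"):
            raise InvalidArgumentError(
                f"unknown ordering_mode {self.ordering_mode!r}")
        object.__setattr__(self, "stages", tuple(self.stages))

    def to_dict(self) -> dict:
        return {
            "stages": [{"learner_id": s.learner_id, "hyperparameters": s.hp,
                        "seed": s.seed} for s in self.stages],
            "positive_threshold": self.positive_threshold,
            "negative_threshold": self.negative_threshold,
            "ordering_mode": self.ordering_mode,
            "force_final": self.force_final,
            "refit_on_deferred": self.refit_on_deferred,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CascadeConfig":
        stages = tuple(
            StageSpec(s["learner_id"], tuple(sorted((s.get("hyperparameters")
                                                     or {}).items())),
                      int(s.get("seed", 0)))
            for s in d.get("stages", [])
        ) or DEFAULT_STAGES
        return cls(
            stages=stages,
            positive_threshold=float(d.get("positive_threshold", 0.70)),
            negative_threshold=float(d.get("negative_threshold", 0.80)),
            ordering_mode=d.get("ordering_mode", "manual"),
            force_final=bool(d.get("force_final", False)),
            refit_on_deferred=bool(d.get("refit_on_deferred", False)),
        )

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path) -> "CascadeConfig":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass(frozen=True)
class CascadeDecision:
    """Per-subject decision record.

    ``status`` is ``"classified"`` or ``"unclassified"``; for classified
    subjects ``stage_index`` (1-based), ``predicted_label`` and the class
    probability that met its threshold are present.  ``forced`` marks labels
    assigned by the force-final fallback rather than a threshold.
    """

    subject_id: object
    status: str
    stage_index: int | None = None
    predicted_label: int | None = None
    accepted_probability: float | None = None
    forced: bool = False


def classify_sample(p_negative: float, p_positive: float,
                    positive_threshold: float = 0.70,
                    negative_threshold: float = 0.80):
    """Apply the acceptance rule to one probability pair.

    Returns ``(label, probability)`` when a threshold is met (ties at the
    boundary count as accepted) or ``(None, None)`` for a deferral.  The
    positive class is checked first; with the default thresholds the two
    conditions cannot both hold since 0.70 + 0.80 > 1.
    """
    if not (0.0 <= p_negative <= 1.0 and 0.0 <= p_positive <= 1.0):
        raise InvalidArgumentError("probabilities must lie in [0, 1]")
    if abs(p_negative + p_positive - 1.0) > 1e-9:
        raise InvalidArgumentError("class probabilities must sum to 1")
    if p_positive >= positive_threshold:
        return POSITIVE, p_positive
    if p_negative >= negative_threshold:
        return NEGATIVE, p_negative
    return None, None


class CascadeModel:
    """Cascade classifier model bound to a training cohort.

    Parameters
    ----------
    train : CohortTable
        Training cohort; must contain both outcome classes.
    config : CascadeConfig, optional
        Stage list and thresholds; defaults to the gradient boosting ->
        random forest -> logistic regression cascade with 0.70/0.80
        thresholds.
    """

    def __init__(self, train: CohortTable, config: CascadeConfig | None = None):
        self.train = train
        self.config = config or CascadeConfig()
        if train.outcome().nunique() < 2:
            raise DegenerateDataError("training set contains a single class")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, schema,
                       config: CascadeConfig | None = None) -> "CascadeModel":
        return cls(CohortTable(df, schema), config)

    def _stage_cv_accuracy(self, spec: StageSpec, folds: int = 5) -> float:
        from sklearn.model_selection import StratifiedKFold, cross_val_score

        X = self.train.features().to_numpy(dtype=float)
        y = self.train.outcome().to_numpy()
        cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=spec.seed)
        return float(np.mean(cross_val_score(spec.build(), X, y, cv=cv,
                                             scoring="accuracy")))

    def fit(self) -> "CascadeResults":
        """Fit every stage and return the results object.

        By default all stages are trained on the full training set (deferral
        operates only at prediction time).  With ``refit_on_deferred`` each
        downstream stage is instead refitted on the training rows its
        predecessors would have deferred.
        """
        cfg = self.config
        stages = list(cfg.stages)
        train_cv = None
        if cfg.ordering_mode == "by_training_accuracy":
            train_cv = [self._stage_cv_accuracy(s) for s in stages]
            # stable sort descending; ties keep original list order
            order = sorted(range(len(stages)), key=lambda i: -train_cv[i])
            stages = [stages[i] for i in order]
            train_cv = [train_cv[i] for i in order]

        X = self.train.features().to_numpy(dtype=float)
        y = self.train.outcome().to_numpy()
        fitted, train_acc = [], []
        active = np.ones(len(y), dtype=bool)
        for i, spec in enumerate(stages, start=1):
            Xi, yi = (X[active], y[active]) if cfg.refit_on_deferred else (X, y)
            if len(np.unique(yi)) < 2:
                raise DegenerateDataError(
                    f"stage {i} training subset has a single class")
            model = spec.build()
            try:
                model.fit(Xi, yi)
            except Exception as exc:  # pragma: no cover - defensive
                raise StageFitError(i, spec.learner_id, exc) from exc
            fitted.append(model)
            train_acc.append(float(model.score(Xi, yi)))
            if cfg.refit_on_deferred and i < len(stages):
                proba = model.predict_proba(X)
                pos = proba[:, list(model.classes_).index(POSITIVE)]
                accepted = (pos >= cfg.positive_threshold) | \
                           (1.0 - pos >= cfg.negative_threshold)
                active &= ~accepted
                if not active.any():
                    active = np.zeros(len(y), dtype=bool)
        return CascadeResults(self, tuple(stages), tuple(fitted),
                              tuple(train_acc),
                              tuple(train_cv) if train_cv else None)


def fit_cascade(train: CohortTable,
                config: CascadeConfig | None = None) -> "CascadeResults":
    """Functional convenience wrapper around ``CascadeModel(train, config).fit()``."""
    return CascadeModel(train, config).fit()


class CascadeResults:
    """Fitted cascade: stage models in final order plus training metadata."""

    def __init__(self, model: CascadeModel, stages, fitted_stages,
                 train_accuracy, train_cv_accuracy=None):
        self.model = model
        self.config = model.config
        self.stages = stages
        self.fitted_stages = fitted_stages
        self.train_accuracy = train_accuracy
        self.train_cv_accuracy = train_cv_accuracy
        self.feature_names = list(model.train.feature_names)

    @property
    def n_stages(self) -> int:
        return len(self.stages)

    @property
    def stage_names(self):
        return [LEARNER_LABELS[s.learner_id] for s in self.stages]

    def _check_features(self, cohort: CohortTable):
        names = list(cohort.feature_names)
        if names != self.feature_names:
            missing = [n for n in self.feature_names if n not in names]
            extra = [n for n in names if n not in self.feature_names]
            raise SchemaMismatchError(missing, extra)

    def stage_positive_proba(self, stage: int, X: np.ndarray) -> np.ndarray:
        """P(overweight/obesity) from stage ``stage`` (0-based) on a matrix."""
        model = self.fitted_stages[stage]
        proba = model.predict_proba(X)
        return proba[:, list(model.classes_).index(POSITIVE)]

    def predict(self, test: CohortTable) -> "CascadePrediction":
        """Run the deferral flow over a test cohort.

        Stage 1 receives every row; stage *i* receives exactly the rows
        stage *i-1* deferred; a row's decision records the first accepting
        stage.  Rows deferred by the final stage are returned unclassified
        unless ``force_final`` is set.
        """
        self._check_features(test)
        cfg = self.config
        X = test.features().to_numpy(dtype=float)
        ids = list(test.data.index)
        n = len(ids)
        decisions: dict = {}
        flow = []
        pending = np.arange(n)
        for si in range(self.n_stages):
            received = len(pending)
            if received:
                pos = self.stage_positive_proba(si, X[pending])
            else:
                pos = np.empty(0)
            accept_pos = pos >= cfg.positive_threshold
            accept_neg = (1.0 - pos) >= cfg.negative_threshold
            accepted = accept_pos | accept_neg
            for j, row in enumerate(pending):
                if accept_pos[j]:
                    decisions[row] = CascadeDecision(
                        ids[row], "classified", si + 1, POSITIVE, float(pos[j]))
                elif accept_neg[j]:
                    decisions[row] = CascadeDecision(
                        ids[row], "classified", si + 1, NEGATIVE,
                        float(1.0 - pos[j]))
            deferred = pending[~accepted]
            flow.append({"stage": si + 1,
                         "learner": self.stages[si].learner_id,
                         "received": received,
                         "classified": int(accepted.sum()),
                         "deferred": int((~accepted).sum())})
            pending = deferred
        if len(pending):
            if cfg.force_final:
                pos = self.stage_positive_proba(self.n_stages - 1, X[pending])
                for j, row in enumerate(pending):
                    label = POSITIVE if pos[j] >= 0.5 else NEGATIVE
                    p = float(pos[j] if label == POSITIVE else 1.0 - pos[j])
                    decisions[row] = CascadeDecision(
                        ids[row], "classified", self.n_stages, label, p,
                        forced=True)
            else:
                for row in pending:
                    decisions[row] = CascadeDecision(ids[row], "unclassified")
        ordered = [decisions[i] for i in range(n)]
        return CascadePrediction(ordered, flow, self)

    def summary(self) -> str:
        lines = ["Cascade classifier", "=" * 60,
                 f"Stages ({self.n_stages}), thresholds "
                 f"P(pos) >= {self.config.positive_threshold:.2f} / "
                 f"P(neg) >= {self.config.negative_threshold:.2f}:"]
        for i, s in enumerate(self.stages):
            cv = (f"  cv_acc={self.train_cv_accuracy[i]:.3f}"
                  if self.train_cv_accuracy else "")
            lines.append(f"  {i + 1}. {LEARNER_LABELS[s.learner_id]:<20}"
                         f" train_acc={self.train_accuracy[i]:.3f}{cv}")
        lines.append(f"Training n = {self.model.train.n}, "
                     f"prevalence = {self.model.train.prevalence():.3f}")
        return "\n".join(lines)


class CascadePrediction:
    """Per-subject decisions plus per-stage flow counts for one test run."""

    def __init__(self, decisions, flow, results: CascadeResults):
        self.decisions = list(decisions)
        self.flow = list(flow)
        self.results = results

    @property
    def n(self) -> int:
        return len(self.decisions)

    @property
    def n_classified(self) -> int:
        return sum(d.status == "classified" for d in self.decisions)

    @property
    def n_unclassified(self) -> int:
        return self.n - self.n_classified

    @property
    def coverage(self) -> float:
        return self.n_classified / self.n

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"subject_id": [d.subject_id for d in self.decisions],
             "status": [d.status for d in self.decisions],
             "stage_index": [d.stage_index for d in self.decisions],
             "predicted_label": [d.predicted_label for d in self.decisions],
             "accepted_probability": [d.accepted_probability
                                      for d in self.decisions],
             "forced": [d.forced for d in self.decisions]}
        ).set_index("subject_id")

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, encoding="utf-8")

    def flow_report(self) -> dict:
        return {"n": self.n, "classified": self.n_classified,
                "unclassified": self.n_unclassified,
                "coverage": self.coverage, "stages": self.flow}


def predict_cascade(fitted: CascadeResults,
                    test: CohortTable) -> CascadePrediction:
    """Functional wrapper around ``fitted.predict(test)``."""
    return fitted.predict(test)


def reference_predict(fitted: CascadeResults,
                      test: CohortTable) -> CascadePrediction:
    """Naive per-sample, per-stage loop applying :func:`classify_sample`.

    Deliberately independent of :meth:`CascadeResults.predict`'s vectorised
    flow; used as the oracle in equivalence tests.
    """
    fitted._check_features(test)
    cfg = fitted.config
    X = test.features().to_numpy(dtype=float)
    ids = list(test.data.index)
    decisions = []
    counts = [{"stage": i + 1, "learner": fitted.stages[i].learner_id,
               "received": 0, "classified": 0, "deferred": 0}
              for i in range(fitted.n_stages)]
    for row, sid in enumerate(ids):
        decided = None
        for si in range(fitted.n_stages):
            counts[si]["received"] += 1
            p_pos = float(fitted.stage_positive_proba(si, X[row:row + 1])[0])
            label, prob = classify_sample(1.0 - p_pos, p_pos,
                                          cfg.positive_threshold,
                                          cfg.negative_threshold)
            if label is not None:
                counts[si]["classified"] += 1
                decided = CascadeDecision(sid, "classified", si + 1, label, prob)
                break
            counts[si]["deferred"] += 1
        if decided is None:
            if cfg.force_final:
                p_pos = float(fitted.stage_positive_proba(
                    fitted.n_stages - 1, X[row:row + 1])[0])
                label = POSITIVE if p_pos >= 0.5 else NEGATIVE
                decided = CascadeDecision(
                    sid, "classified", fitted.n_stages, label,
                    p_pos if label == POSITIVE else 1.0 - p_pos, forced=True)
            else:
                decided = CascadeDecision(sid, "unclassified")
        decisions.append(decided)
    return CascadePrediction(decisions, counts, fitted)
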