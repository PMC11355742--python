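"""Shapley-value attributions for the fitted cascade.

The engine computes Shapley values by permutation sampling against a seeded
background sample of the training set: for a shared collection of
(permutation, background-row) pairs, features of the explained subject are
inserted into the background row in permutation order and the model-output
increments are averaged.  Because the same pairs are reused for every
feature, the increments telescope and the attributions satisfy additivity
*exactly* (up to float rounding):

    base_value + sum_f attribution_f = model_output(x)

with ``base_value`` the average model output over the paired background
rows.  For small feature counts (<= 6) an exact mode enumerates every
permutation over every background row, recovering the classical Shapley
value of the interventional value function; the sampling estimator is an
unbiased Monte Carlo version of the same quantity.

The attribution target is the positive-class (overweight/obesity)
probability of a cascade stage.  The default policy explains stage 1, the
model every subject passes through; ``per_stage_classified`` explains each
stage on exactly the subjects it classified.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cascade import CascadeResults
from .cohort import CohortTable
from .errors import InvalidArgumentError

EXACT_MAX_FEATURES = 6


def shapley_values(predict_fn, X: np.ndarray, background: np.ndarray,
                   n_permutations: int = 20, seed: int = 0,
                   exact: bool = False):
    """Permutation-sampling Shapley values of ``predict_fn`` on rows of X.

    Returns ``(values, base_value, outputs)`` where ``values`` is an
    (n_samples, n_features) array, ``base_value`` the mean model output over
    the background rows paired with the sampled permutations, and
    ``outputs`` the model output on each explained row.  With
    ``exact=True`` every permutation of the features is paired with every
    background row (only allowed for <= 6 features).
    """
    X = np.asarray(X, dtype=float)
    background = np.asarray(background, dtype=float)
    if X.ndim != 2 or X.shape[0] == 0:
        raise InvalidArgumentError("X must be a non-empty 2-D array")
    n, p = X.shape
    if background.ndim != 2 or background.shape[1] != p:
        raise InvalidArgumentError("background must match the feature count")

    if exact:
        if p > EXACT_MAX_FEATURES:
            raise InvalidArgumentError(
                f"exact mode limited to {EXACT_MAX_FEATURES} features")
        perms = list(itertools.permutations(range(p)))
        bg_idx = np.repeat(np.arange(len(background)), len(perms))
        perms = perms * len(background)
    else:
        rng = np.random.default_rng(seed)
        perms = [tuple(rng.permutation(p)) for _ in range(n_permutations)]
        bg_idx = rng.integers(0, len(background), size=n_permutations)

    values = np.zeros((n, p))
    base_acc = 0.0
    m = len(perms)
    for perm, bi in zip(perms, bg_idx):
        b = background[bi]
        # hybrid block: row t has the first t features (in perm order) from x
        H = np.empty(((p + 1) * n, p))
        cur = np.tile(b, (n, 1))
        H[:n] = cur
        for t, f in enumerate(perm, start=1):
            cur = cur.copy()
            cur[:, f] = X[:, f]
            H[t * n:(t + 1) * n] = cur
        out = predict_fn(H).reshape(p + 1, n)
        base_acc += float(out[0, 0])  # identical across samples (pure background)
        for t, f in enumerate(perm, start=1):
            values[:, f] += out[t] - out[t - 1]
    values /= m
    base_value = base_acc / m
    outputs = predict_fn(X)
    return values, base_value, np.asarray(outputs, dtype=float)


@dataclass
class AttributionSet:
    """Per-sample, per-feature Shapley attributions for one cascade stage."""

    values: np.ndarray            # n_samples x n_features
    base_value: float
    model_output: np.ndarray      # n_samples
    feature_names: list
    feature_values: pd.DataFrame  # n_samples x n_features (raw codes)
    subject_ids: list
    stage_index: int              # 1-based stage the attribution explains
    method: str

    def __post_init__(self):
        resid = np.abs(self.base_value + self.values.sum(axis=1)
                       - self.model_output)
        self.max_additivity_error = float(resid.max())

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, columns=self.feature_names,
                            index=pd.Index(self.subject_ids,
                                           name="subject_id"))

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, encoding="utf-8")

    def metadata(self) -> dict:
        return {"base_value": self.base_value, "stage_index": self.stage_index,
                "method": self.method, "n_samples": self.n,
                "max_additivity_error": self.max_additivity_error}


def _background_sample(train: CohortTable, size: int, seed: int) -> np.ndarray:
    X = train.features().to_numpy(dtype=float)
    if len(X) <= size:
        return X
    rng = np.random.default_rng(seed)
    return X[rng.choice(len(X), size=size, replace=False)]


def attribute(fitted: CascadeResults, samples: CohortTable,
              stage_policy: str = "first_stage", n_permutations: int = 20,
              background_size: int = 100, seed: int = 0):
    """Explain cascade stages on a cohort.

    ``stage_policy="first_stage"`` returns one :class:`AttributionSet`
    explaining stage 1's positive-class probability on every sample;
    ``"per_stage_classified"`` runs the deferral flow and returns one set per
    stage, each restricted to the subjects that stage classified (stages that
    classified nobody are skipped).
    """
    if samples.n == 0:
        raise InvalidArgumentError("empty sample set")
    fitted._check_features(samples)
    background = _background_sample(fitted.model.train, background_size, seed)
    X = samples.features().to_numpy(dtype=float)
    ids = list(samples.data.index)

    def explain(stage0, rows):
        fn = lambda M: fitted.stage_positive_proba(stage0, M)
        vals, base, out = shapley_values(fn, X[rows], background,
                                         n_permutations, seed)
        return AttributionSet(
            vals, base, out, list(fitted.feature_names),
            samples.features().iloc[rows],
            [ids[i] for i in rows], stage0 + 1,
            f"permutation_sampling(m={n_permutations}, "
            f"background={len(background)})")

    if stage_policy == "first_stage":
        return explain(0, list(range(samples.n)))
    if stage_policy != "per_stage_classified":
        raise InvalidArgumentError(f"unknown stage_policy {stage_policy!r}")
    pred = fitted.predict(samples)
    sets = []
    for si in range(fitted.n_stages):
        rows = [i for i, d in enumerate(pred.decisions)
                if d.status == "classified" and d.stage_index == si + 1]
        if rows:
            sets.append(explain(si, rows))
    return sets


@dataclass
class ImportanceRanking:
    """Global feature importance: normalized mean absolute attribution."""

    table: pd.DataFrame  # columns: mean_abs, importance; sorted descending

    @property
    def order(self) -> list:
        return list(self.table.index)

    def to_csv(self, path) -> None:
        self.table.to_csv(path, encoding="utf-8", index_label="feature")


def importance_ranking(attr) -> ImportanceRanking:
    """Rank features by mean |attribution|, normalized to sum to 1.

    Accepts a single :class:`AttributionSet` or a list of per-stage sets, in
    which case stages are aggregated weighted by the number of subjects each
    classified.  Ties break alphabetically.
    """
    sets = attr if isinstance(attr, (list, tuple)) else [attr]
    if not sets:
        raise InvalidArgumentError("empty attribution input")
    names = sets[0].feature_names
    total = np.zeros(len(names))
    weight = 0
    for s in sets:
        total += np.abs(s.values).sum(axis=0)
        weight += s.n
    mean_abs = total / weight
    norm = mean_abs.sum()
    importance = mean_abs / norm if norm > 0 else np.full_like(mean_abs, np.nan)
    df = pd.DataFrame({"mean_abs": mean_abs, "importance": importance},
                      index=pd.Index(names, name="feature"))
    # descending mean |attribution|; alphabetical within exact ties
    df = df.iloc[np.lexsort((df.index.to_numpy(), -df["mean_abs"].to_numpy()))]
    return ImportanceRanking(df)


@dataclass
class WaterfallEntry:
    feature: str
    value: object
    contribution: float
    direction: str  # "risk-increasing" | "risk-decreasing" | "neutral"


@dataclass
class Waterfall:
    """Single-subject decomposition: base value -> final model output."""

    subject_id: object
    base_value: float
    entries: list          # sorted by |contribution| descending
    final_value: float

    def to_dict(self) -> dict:
        return {"subject_id": str(self.subject_id),
                "base_value": self.base_value,
                "final_value": self.final_value,
                "contributions": [
                    {"feature": e.feature, "value": e.value,
                     "contribution": e.contribution,
                     "direction": e.direction}
                    for e in self.entries]}

    def to_json(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def waterfall(attr: AttributionSet, subject_id) -> Waterfall:
    """Ordered signed contributions for one subject (additivity preserved)."""
    try:
        row = attr.subject_ids.index(subject_id)
    except ValueError:
        raise InvalidArgumentError(f"unknown subject {subject_id!r}") from None
    vals = attr.values[row]
    entries = []
    for f, v in sorted(zip(attr.feature_names, vals), key=lambda t: -abs(t[1])):
        direction = ("risk-increasing" if v > 0
                     else "risk-decreasing" if v < 0 else "neutral")
        entries.append(WaterfallEntry(
            f, attr.feature_values.iloc[row][f], float(v), direction))
    return Waterfall(subject_id, attr.base_value, entries,
                     float(attr.model_output[row]))


def summary_data(attr: AttributionSet) -> pd.DataFrame:
    """Long-form (feature, attribution, feature value) rows for summary plots.

    Rows are ordered by global importance so a beeswarm-style plot built from
    this frame lists the most influential features first; raw feature values
    ride along to make magnitude colouring reproducible.
    """
    order = importance_ranking(attr).order
    frames = []
    for f in order:
        j = attr.feature_names.index(f)
        frames.append(pd.DataFrame({
            "feature": f,
            "subject_id": attr.subject_ids,
            "attribution": attr.values[:, j],
            "feature_value": attr.feature_values[f].to_numpy(),
        }))
    return pd.concat(frames, ignore_index=True)
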