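"""Repeated-evaluation harness and rank-based model comparison.

k competing algorithms are evaluated on n dataset instances; within each
instance the summary scores are converted to ranks r_ij (1 = best, ties get
the mean of the ranks they span) and each algorithm's average rank is

    R_j = (1/n) * sum_i r_ij.

The Friedman statistic

    F_f = [12 n / (k (k + 1))] * [ sum_j R_j^2  -  k (k + 1)^2 / 4 ]

is referred to a chi-square distribution with k - 1 degrees of freedom; the
null hypothesis (all algorithms equivalent) is rejected when F_f exceeds the
1 - alpha quantile.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .cascade import (CascadeConfig, CascadeModel, StageSpec)
from .cohort import CohortTable, split_cohort
from .errors import EmptyClassifiedError, InvalidArgumentError
from .metrics import confusion, metrics_report


def cross_validate(spec: StageSpec, cohort: CohortTable, folds: int = 10,
                   seed: int = 0):
    """Stratified k-fold accuracy of a single learner: (mean, sample std)."""
    from sklearn.model_selection import StratifiedKFold

    if folds < 2:
        raise InvalidArgumentError("folds must be >= 2")
    if folds > cohort.n:
        raise InvalidArgumentError("more folds than subjects")
    X = cohort.features().to_numpy(dtype=float)
    y = cohort.outcome().to_numpy()
    cv = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs = []
    for tr, te in cv.split(X, y):
        model = spec.build()
        model.fit(X[tr], y[tr])
        accs.append(float(model.score(X[te], y[te])))
    accs = np.asarray(accs)
    return float(accs.mean()), float(accs.std(ddof=1))


def _evaluate_single(spec: StageSpec, train: CohortTable, test: CohortTable):
    model = spec.build()
    model.fit(train.features().to_numpy(dtype=float),
              train.outcome().to_numpy())
    pred = model.predict(test.features().to_numpy(dtype=float))
    y = test.outcome().to_numpy()
    tp = int(((pred == 1) & (y == 1)).sum())
    fp = int(((pred == 1) & (y == 0)).sum())
    tn = int(((pred == 0) & (y == 0)).sum())
    fn = int(((pred == 0) & (y == 1)).sum())
    from .metrics import ConfusionSummary
    return metrics_report(ConfusionSummary(tp, fp, tn, fn, 0)), 1.0


def _evaluate_cascade(cfg: CascadeConfig, train: CohortTable,
                      test: CohortTable):
    res = CascadeModel(train, cfg).fit()
    pred = res.predict(test)
    summ = confusion(test.outcome().to_numpy(), pred.decisions)
    try:
        rep = metrics_report(summ)
    except EmptyClassifiedError:
        return None, 0.0
    return rep, pred.coverage


@dataclass
class RunMatrix:
    """Scores of every model over repeated runs of one dataset instance."""

    instance_id: str
    scores: pd.DataFrame           # runs x models, accuracy
    seeds: list
    metrics: pd.DataFrame          # long form: run, model, metric panel

    def summary(self) -> pd.DataFrame:
        """Best/worst/mean/sample-std accuracy per model."""
        s = self.scores
        out = pd.DataFrame({"best": s.max(), "worst": s.min(),
                            "mean": s.mean(), "std": s.std(ddof=1)})
        if len(s) == 1:
            out["std"] = np.nan  # undefined for a single run
        out.index.name = "model"
        return out


def repeated_runs(models: dict, instances: dict, runs: int = 100,
                  base_seed: int = 0, train_fraction: float = 0.75) -> dict:
    """Repeatedly re-split, re-fit and score every model on every instance.

    ``models`` maps a display name to a :class:`StageSpec` (single learner,
    scored on all test subjects) or a :class:`CascadeConfig` (scored on its
    classified subset, with coverage recorded).  Run ``r`` splits every
    instance with seed ``base_seed + r`` so all models see identical splits
    within a run.  Returns ``{instance_id: RunMatrix}``.
    """
    if runs < 1:
        raise InvalidArgumentError("runs must be >= 1")
    out = {}
    for inst_id, cohort in instances.items():
        seeds = [base_seed + r for r in range(runs)]
        acc = {name: [] for name in models}
        records = []
        for r, seed in enumerate(seeds):
            train, test = split_cohort(cohort, train_fraction, seed=seed)
            for name, spec in models.items():
                if isinstance(spec, CascadeConfig):
                    rep, cov = _evaluate_cascade(spec, train, test)
                else:
                    rep, cov = _evaluate_single(spec, train, test)
                a = np.nan if rep is None else rep.accuracy
                acc[name].append(a)
                rec = {"run": r, "model": name, "coverage": cov}
                if rep is not None:
                    rec.update(rep.to_dict())
                records.append(rec)
        out[inst_id] = RunMatrix(inst_id, pd.DataFrame(acc), seeds,
                                 pd.DataFrame(records))
    return out


def rank_scores(scores, higher_is_better: bool = True) -> np.ndarray:
    """Within-instance ranks, 1 = best, exact ties averaged (5.5 is legal)."""
    scores = np.asarray(scores, dtype=float)
    if scores.size == 0:
        raise InvalidArgumentError("cannot rank an empty score vector")
    return stats.rankdata(-scores if higher_is_better else scores,
                          method="average")


@dataclass
class RankTable:
    """Per-instance ranks, average rank and rank dispersion per algorithm."""

    r: pd.DataFrame          # instances x algorithms
    R: pd.Series             # average rank per algorithm
    rank_std: pd.Series      # sample std (ddof = 1); NaN when n = 1
    n: int
    k: int

    def to_frame(self) -> pd.DataFrame:
        out = self.r.copy()
        out.loc["Average"] = self.R
        out.loc["Std"] = self.rank_std
        return out

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, encoding="utf-8",
                               index_label="instance")


def build_rank_table(rank_rows: dict) -> RankTable:
    """Assemble per-instance rank vectors into a :class:`RankTable`.

    ``rank_rows`` maps instance id to a rank vector (same algorithm order
    throughout) or is a DataFrame of instances x algorithms.
    """
    r = (rank_rows if isinstance(rank_rows, pd.DataFrame)
         else pd.DataFrame(rank_rows).T)
    n, k = r.shape
    if k < 2:
        raise InvalidArgumentError("need at least two algorithms to rank")
    R = r.mean(axis=0)
    if n == 1:
        warnings.warn("rank std undefined for a single instance")
        sd = pd.Series(np.nan, index=r.columns)
    else:
        sd = r.std(axis=0, ddof=1)
    return RankTable(r, R, sd, n, k)


def rank_table_from_runs(run_matrices: dict, by: str = "mean",
                         higher_is_better: bool = True) -> RankTable:
    """Rank the per-instance score summaries of a repeated-runs harness.

    ``by`` selects the summary column ranked within each instance
    (default the mean accuracy over runs; ``"best"`` / ``"worst"`` also
    supported, and ``"per_run"`` ranks every run as its own instance).
    """
    rows = {}
    if by == "per_run":
        for inst_id, rm in run_matrices.items():
            for r in range(len(rm.scores)):
                rows[f"{inst_id}/run{r}"] = pd.Series(
                    rank_scores(rm.scores.iloc[r].to_numpy(),
                                higher_is_better),
                    index=rm.scores.columns)
    else:
        for inst_id, rm in run_matrices.items():
            summ = rm.summary()[by]
            rows[inst_id] = pd.Series(
                rank_scores(summ.to_numpy(), higher_is_better),
                index=summ.index)
    return build_rank_table(rows)


@dataclass
class FriedmanResult:
    """Friedman omnibus test outcome over a rank table."""

    F_f: float
    df: int
    alpha: float
    critical_value: float
    reject_null: bool
    n: int
    k: int
    average_ranks: pd.Series

    def summary(self) -> str:
        verdict = ("reject H0: algorithms differ"
                   if self.reject_null else "fail to reject H0")
        lines = ["Friedman rank test", "=" * 48,
                 f"n = {self.n} instances, k = {self.k} algorithms",
                 f"F_f = {self.F_f:.4f}  ~  chi2(df = {self.df})",
                 f"critical value (alpha = {self.alpha}) = "
                 f"{self.critical_value:.4f}",
                 verdict, "", "Average ranks (1 = best):"]
        for name, val in self.average_ranks.sort_values().items():
            lines.append(f"  {name:<24} {val:.2f}")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {"F_f": self.F_f, "df": self.df, "alpha": self.alpha,
                "critical_value": self.critical_value,
                "reject_null": bool(self.reject_null),
                "n": self.n, "k": self.k,
                "average_ranks": self.average_ranks.to_dict()}


def friedman_statistic(table: RankTable, alpha: float = 0.05) -> FriedmanResult:
    """Evaluate F_f on average ranks and decide against the chi-square quantile."""
    n, k = table.n, table.k
    if k < 2:
        raise InvalidArgumentError("k must be >= 2")
    if n < 2:
        warnings.warn("Friedman test on a single instance is uninformative")
    R = table.R.to_numpy(dtype=float)
    F_f = (12.0 * n / (k * (k + 1))) * (np.sum(R ** 2) - k * (k + 1) ** 2 / 4.0)
    df = k - 1
    crit = float(stats.chi2.ppf(1.0 - alpha, df))
    return FriedmanResult(float(F_f), df, alpha, crit, bool(F_f > crit),
                          n, k, table.R.copy())


def probability_of_winning(run_matrices: dict, bootstrap_reps: int = 500,
                           seed: int = 0) -> pd.DataFrame:
    """Fraction of (run, instance) cells each model strictly wins.

    Exact ties split the win equally among the tied models.  The uncertainty
    column is the standard deviation of the win fraction over bootstrap
    resamples of the runs.  Probabilities sum to 1.
    """
    mats = list(run_matrices.values())
    if not mats or mats[0].scores.shape[1] < 2:
        raise InvalidArgumentError("need at least two models")
    cells = pd.concat([rm.scores for rm in mats], axis=0, ignore_index=True)
    A = cells.to_numpy(dtype=float)

    def win_fractions(M):
        best = M.max(axis=1, keepdims=True)
        is_best = M == best
        shares = is_best / is_best.sum(axis=1, keepdims=True)
        return shares.mean(axis=0)

    probs = win_fractions(A)
    rng = np.random.default_rng(seed)
    boots = np.empty((bootstrap_reps, A.shape[1]))
    for b in range(bootstrap_reps):
        idx = rng.integers(0, A.shape[0], size=A.shape[0])
        boots[b] = win_fractions(A[idx])
    return pd.DataFrame({"win_probability": probs,
                         "uncertainty": boots.std(axis=0, ddof=1)},
                        index=cells.columns)


def accuracy_density(run_matrices: dict, grid_size: int = 256) -> dict:
    """Kernel-smoothed accuracy densities per model over all runs/instances.

    Returns per model: the raw accuracy samples, a Gaussian-KDE density on a
    shared grid (``None`` and ``degenerate=True`` when the samples have zero
    spread), and the mode location.
    """
    cells = pd.concat([rm.scores for rm in run_matrices.values()],
                      axis=0, ignore_index=True)
    grid = np.linspace(0.0, 1.0, grid_size)
    out = {}
    for name in cells.columns:
        x = cells[name].dropna().to_numpy(dtype=float)
        if x.size == 0:
            continue
        if np.ptp(x) == 0.0:
            out[name] = {"samples": x, "grid": grid, "density": None,
                         "mode": float(x[0]), "degenerate": True}
            continue
        kde = stats.gaussian_kde(x)
        dens = kde(grid)
        out[name] = {"samples": x, "grid": grid, "density": dens,
                     "mode": float(grid[int(np.argmax(dens))]),
                     "degenerate": False}
    return out
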