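"""Selective-prediction evaluation metrics.

All metrics are computed over *classified* subjects only; the unclassified
count is always carried alongside so coverage is never hidden.  The positive
class is overweight/obesity (label 1) throughout:

    accuracy            = (TP + TN) / n_classified
    precision_positive  = TP / (TP + FP)        (positive predictive value)
    precision_negative  = TN / (TN + FN)        (negative predictive value)
    recall_positive     = TP / (TP + FN)        (sensitivity)
    recall_negative     = TN / (TN + FP)        (specificity)
    F1                  = 2 * precision * recall / (precision + recall)

Macro averages are unweighted means over the two classes; weighted averages
weight by true-class support among classified subjects.  Ratios with a zero
denominator are reported as NaN with an ``undefined`` flag, never silently 0.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (EmptyClassifiedError, FlowConsistencyError,
                     InvalidArgumentError)


@dataclass(frozen=True)
class ConfusionSummary:
    """Confusion counts over classified subjects, plus the abstention count."""

    tp: int = 0
    fp: int = 0
    tn: int = 0
    fn: int = 0
    n_unclassified: int = 0

    @property
    def n_classified(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def n(self) -> int:
        return self.n_classified + self.n_unclassified

    def __add__(self, other: "ConfusionSummary") -> "ConfusionSummary":
        return ConfusionSummary(self.tp + other.tp, self.fp + other.fp,
                                self.tn + other.tn, self.fn + other.fn,
                                self.n_unclassified + other.n_unclassified)


def confusion(labels, decisions) -> ConfusionSummary:
    """Tally the confusion over classified decisions.

    ``labels`` is one true binary label per decision, in the same order;
    ``decisions`` is a sequence of :class:`~riskcascade.cascade.CascadeDecision`
    (or any object with ``status`` / ``predicted_label``).
    """
    labels = np.asarray(labels).astype(int)
    decisions = list(decisions)
    if len(labels) != len(decisions):
        raise InvalidArgumentError(
            f"{len(labels)} labels for {len(decisions)} decisions")
    tp = fp = tn = fn = unc = 0
    for y, d in zip(labels, decisions):
        if d.status != "classified":
            unc += 1
        elif d.predicted_label == 1:
            tp, fp = (tp + 1, fp) if y == 1 else (tp, fp + 1)
        else:
            tn, fn = (tn + 1, fn) if y == 0 else (tn, fn + 1)
    return ConfusionSummary(tp, fp, tn, fn, unc)


def _ratio(num: int, den: int):
    return (num / den, False) if den > 0 else (math.nan, True)


def _f1(p: float, r: float):
    if math.isnan(p) or math.isnan(r) or p + r == 0:
        return math.nan, True
    return 2.0 * p * r / (p + r), False


@dataclass(frozen=True)
class MetricsReport:
    """Full metric panel for one confusion summary."""

    accuracy: float
    precision_positive: float
    precision_negative: float
    recall_positive: float
    recall_negative: float
    f1_positive: float
    f1_negative: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    weighted_precision: float
    weighted_recall: float
    weighted_f1: float
    misclassification_rate: float
    correct_classification_rate: float
    undefined: tuple = ()

    def to_dict(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__
             if k != "undefined"}
        d["undefined"] = list(self.undefined)
        return d

    def round(self, ndigits: int = 2) -> dict:
        """Presentation-layer rounding (half away from zero)."""
        out = {}
        q = 10 ** ndigits
        for k, v in self.to_dict().items():
            if isinstance(v, float) and not math.isnan(v):
                out[k] = math.floor(abs(v) * q + 0.5) / q * (1 if v >= 0 else -1)
            else:
                out[k] = v
        return out


def metrics_report(summary: ConfusionSummary) -> MetricsReport:
    """Evaluate the metric panel on classified subjects."""
    if summary.n_classified == 0:
        raise EmptyClassifiedError("no classified subjects to evaluate")
    undefined = []

    def track(name, pair):
        value, flag = pair
        if flag:
            undefined.append(name)
        return value

    nc = summary.n_classified
    acc = (summary.tp + summary.tn) / nc
    prec_p = track("precision_positive", _ratio(summary.tp, summary.tp + summary.fp))
    prec_n = track("precision_negative", _ratio(summary.tn, summary.tn + summary.fn))
    rec_p = track("recall_positive", _ratio(summary.tp, summary.tp + summary.fn))
    rec_n = track("recall_negative", _ratio(summary.tn, summary.tn + summary.fp))
    f1_p = track("f1_positive", _f1(prec_p, rec_p))
    f1_n = track("f1_negative", _f1(prec_n, rec_n))
    sup_p = summary.tp + summary.fn  # true-class support among classified
    sup_n = summary.tn + summary.fp

    def wavg(vp, vn):
        if math.isnan(vp) or math.isnan(vn):
            return math.nan
        return (vp * sup_p + vn * sup_n) / nc

    return MetricsReport(
        accuracy=acc,
        precision_positive=prec_p, precision_negative=prec_n,
        recall_positive=rec_p, recall_negative=rec_n,
        f1_positive=f1_p, f1_negative=f1_n,
        macro_precision=(prec_p + prec_n) / 2.0,
        macro_recall=(rec_p + rec_n) / 2.0,
        macro_f1=(f1_p + f1_n) / 2.0,
        weighted_precision=wavg(prec_p, prec_n),
        weighted_recall=wavg(rec_p, rec_n),
        weighted_f1=wavg(f1_p, f1_n),
        misclassification_rate=1.0 - acc,
        correct_classification_rate=acc,
        undefined=tuple(undefined),
    )


def per_stage_confusions(labels, prediction) -> list:
    """Split one run's confusion by the stage that classified each subject."""
    labels = np.asarray(labels).astype(int)
    decisions = prediction.decisions
    if len(labels) != len(decisions):
        raise InvalidArgumentError("label/decision length mismatch")
    out = []
    for si in range(prediction.results.n_stages):
        idx = [i for i, d in enumerate(decisions)
               if d.status == "classified" and d.stage_index == si + 1]
        sub = confusion(labels[idx], [decisions[i] for i in idx])
        out.append(sub)
    return out


def stage_report(prediction, labels) -> pd.DataFrame:
    """Per-stage table: flow counts plus that stage's metric panel.

    The final ``total`` row pools the per-stage confusion matrices and must
    equal the overall confusion (checked); inconsistent flow counts raise.
    """
    flow = prediction.flow
    n = prediction.n
    if flow[0]["received"] != n:
        raise FlowConsistencyError("stage 1 did not receive every subject")
    for i in range(1, len(flow)):
        if flow[i]["received"] != flow[i - 1]["deferred"]:
            raise FlowConsistencyError(
                f"stage {i + 1} received != stage {i} deferred")
    for f in flow:
        if f["classified"] + f["deferred"] != f["received"]:
            raise FlowConsistencyError(
                f"stage {f['stage']}: classified + deferred != received")

    confs = per_stage_confusions(labels, prediction)
    overall = confusion(labels, prediction.decisions)
    pooled = sum(confs, ConfusionSummary())
    forced = [d for d in prediction.decisions if d.forced]
    if not forced and (pooled.tp, pooled.fp, pooled.tn, pooled.fn) != \
            (overall.tp, overall.fp, overall.tn, overall.fn):
        raise FlowConsistencyError("per-stage confusions do not pool to overall")

    rows = []
    for f, c in zip(flow, confs):
        row = {"stage": f["stage"], "learner": f["learner"],
               "received": f["received"], "classified": f["classified"],
               "deferred": f["deferred"],
               "tp": c.tp, "fp": c.fp, "tn": c.tn, "fn": c.fn}
        if c.n_classified > 0:
            rep = metrics_report(c)
            row.update(accuracy=rep.accuracy,
                       precision_positive=rep.precision_positive,
                       recall_positive=rep.recall_positive)
        else:
            row.update(accuracy=math.nan, precision_positive=math.nan,
                       recall_positive=math.nan)
        rows.append(row)
    total = {"stage": "total", "learner": "",
             "received": n, "classified": overall.n_classified,
             "deferred": overall.n_unclassified,
             "tp": overall.tp, "fp": overall.fp,
             "tn": overall.tn, "fn": overall.fn}
    if overall.n_classified > 0:
        rep = metrics_report(overall)
        total.update(accuracy=rep.accuracy,
                     precision_positive=rep.precision_positive,
                     recall_positive=rep.recall_positive)
    rows.append(total)
    return pd.DataFrame(rows)


def report_to_json(report: MetricsReport, summary: ConfusionSummary,
                   path) -> None:
    payload = {"confusion": {"tp": summary.tp, "fp": summary.fp,
                             "tn": summary.tn, "fn": summary.fn,
                             "n_classified": summary.n_classified,
                             "n_unclassified": summary.n_unclassified},
               "metrics": report.to_dict()}
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
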