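"""Synthetic questionnaire cohorts with a latent-BMI ground truth.

The study data this package targets (38 mixed-type questionnaire variables,
~1179 adults, binary overweight/obesity outcome) are not publicly deposited,
so every downstream component is exercised on cohorts drawn from a declarative
:class:`FeatureSchema`.  Each subject receives a latent body-mass index

    latent_bmi = intercept + sum(feature effects) + interactions + N(0, noise_sd)

and the binary outcome is ``latent_bmi >= 25`` (the WHO overweight cut-off).
Feature effects are signed weights on the BMI scale, so the generator encodes
the qualitative risk structure reported for this kind of cohort: age dominant
and adverse, protective Mediterranean-diet adherence and physical activity,
adverse ex-smoker / apnea / metabolic-syndrome status, and a bimodal sex
pattern carried by a sex-by-age interaction (elevated female risk above 50,
elevated male risk at 35-50).
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml

from .errors import CalibrationError, InvalidArgumentError

logger = logging.getLogger(__name__)

BMI_THRESHOLD = 25.0

_KINDS = ("binary", "categorical", "ordinal", "continuous")


@dataclass(frozen=True)
class FeatureSpec:
    """One questionnaire variable and its generative parameters.

    Parameters
    ----------
    name : str
        Unique column name.
    kind : {"binary", "categorical", "ordinal", "continuous"}
    categories : tuple of str
        Level labels for non-continuous kinds (empty for continuous).
        Values are stored as integer codes into this tuple.
    marginal : tuple of float
        Probability vector over levels, or ``(low, high)`` of a uniform
        distribution for continuous features.
    effect : tuple of float or float
        Signed latent-BMI weight per level, or per-unit slope for a
        continuous feature (applied to the value centred at ``center``).
    center : float
        Centring constant for continuous effects (ignored otherwise).
    """

    name: str
    kind: str
    categories: tuple = ()
    marginal: tuple = ()
    effect: object = 0.0
    center: float = 0.0

    def __post_init__(self):
        if self.kind not in _KINDS:
            raise InvalidArgumentError(f"unknown feature kind {self.kind!r}")
        if self.kind == "continuous":
            if len(self.marginal) != 2 or self.marginal[0] >= self.marginal[1]:
                raise InvalidArgumentError(
                    f"{self.name}: continuous marginal must be (low, high)"
                )
        else:
            if len(self.categories) < 2:
                raise InvalidArgumentError(
                    f"{self.name}: non-continuous features need >= 2 levels"
                )
            if len(self.marginal) != len(self.categories):
                raise InvalidArgumentError(
                    f"{self.name}: marginal length != category count"
                )
            p = np.asarray(self.marginal, dtype=float)
            if (p < 0).any() or abs(p.sum() - 1.0) > 1e-9:
                raise InvalidArgumentError(
                    f"{self.name}: marginal must be a probability vector"
                )
            eff = np.asarray(self.effect, dtype=float)
            if eff.shape != (len(self.categories),):
                raise InvalidArgumentError(
                    f"{self.name}: effect must give one weight per level"
                )


@dataclass(frozen=True)
class FeatureSchema:
    """Ordered collection of :class:`FeatureSpec` entries with unique names."""

    entries: tuple

    def __post_init__(self):
        names = [e.name for e in self.entries]
        if len(set(names)) != len(names):
            raise InvalidArgumentError("feature names must be unique")

    @property
    def names(self):
        return [e.name for e in self.entries]

    def __len__(self):
        return len(self.entries)

    def __getitem__(self, name: str) -> FeatureSpec:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    def drop(self, names) -> "FeatureSchema":
        names = list(names)
        unknown = [n for n in names if n not in self.names]
        if unknown:
            raise InvalidArgumentError(f"unknown feature(s): {unknown}")
        return FeatureSchema(
            tuple(e for e in self.entries if e.name not in names)
        )


@dataclass(frozen=True)
class Interaction:
    """Indicator-product interaction on the latent-BMI scale.

    ``conditions`` maps feature names to either a level label (categorical
    kinds) or an ``(low, high)`` half-open interval (continuous kinds);
    ``weight`` is added to the latent BMI when every condition holds.
    """

    conditions: tuple  # tuple of (feature_name, selector)
    weight: float


@dataclass(frozen=True)
class EffectConfig:
    """Latent-BMI model parameters: intercept, residual noise, interactions."""

    intercept: float = BMI_THRESHOLD
    noise_sd: float = 2.6
    interactions: tuple = ()
    target_prevalence: float | None = 0.45

    def __post_init__(self):
        if self.noise_sd <= 0:
            raise InvalidArgumentError("noise_sd must be > 0")
        if self.target_prevalence is not None and not (
            0.0 < self.target_prevalence < 1.0
        ):
            raise InvalidArgumentError("target_prevalence must be in (0, 1)")


def default_interactions() -> tuple:
    """Sex-by-age bimodal risk: women above 50 and men at 35-50 gain risk."""
    return (
        Interaction((("sex", "female"), ("age", (50.0, 200.0))), 1.0),
        Interaction((("sex", "male"), ("age", (35.0, 50.0))), 1.0),
    )


def default_effects() -> EffectConfig:
    return EffectConfig(interactions=default_interactions())


def _b(name, p_yes, eff_yes, eff_no=0.0):
    return FeatureSpec(name, "binary", ("no", "yes"),
                       (1.0 - p_yes, p_yes), (eff_no, eff_yes))


def _o(name, labels, probs, effects):
    return FeatureSpec(name, "ordinal", tuple(labels), tuple(probs),
                       tuple(effects))


def _c(name, labels, probs, effects):
    return FeatureSpec(name, "categorical", tuple(labels), tuple(probs),
                       tuple(effects))


def default_schema() -> FeatureSchema:
    """The 38-variable questionnaire schema the generator emulates.

    Effect signs follow the qualitative structure reported for the study
    population: adverse age (dominant), ex-smoker status, apnea, metabolic
    syndrome, sedentarism and short sleep; protective Mediterranean-diet
    adherence, vigorous/medium physical activity and moderate wine/beer
    consumption.  The 14-level recruitment centre is a pure nuisance variable
    (zero effect, skewed toward the university site).
    """
    centers = tuple(f"center_{i:02d}" for i in range(1, 15))
    center_p = (0.65, *np.full(13, 0.35 / 13))  # university site dominates

    entries = (
        FeatureSpec("age", "continuous", (), (18.0, 69.0), 0.105, center=43.5),
        _c("sex", ("male", "female"), (0.483, 0.517), (0.0, 0.0)),
        _o("education_level", ("primary", "secondary", "vocational", "university"),
           (0.10, 0.25, 0.25, 0.40), (0.55, 0.30, 0.05, -0.40)),
        _c("profession", ("manual", "office", "healthcare", "education",
                          "unemployed", "retired"),
           (0.20, 0.33, 0.15, 0.12, 0.10, 0.10),
           (0.15, 0.10, -0.10, -0.10, 0.10, 0.20)),
        _o("earnings", ("low", "medium", "high"),
           (0.30, 0.50, 0.20), (0.25, 0.0, -0.25)),
        _c("smoking_status", ("never", "current", "ex_smoker"),
           (0.50, 0.20, 0.30), (0.0, -0.20, 0.70)),
        _o("wine_weekly", ("none", "moderate", "high"),
           (0.45, 0.40, 0.15), (0.15, -0.35, 0.25)),
        _o("beer_weekly", ("none", "moderate", "high"),
           (0.40, 0.42, 0.18), (0.15, -0.30, 0.25)),
        _o("spirits_weekly", ("none", "occasional", "weekly"),
           (0.60, 0.30, 0.10), (-0.05, 0.05, 0.45)),
        _o("medas_adherence", ("low", "medium", "high"),
           (0.30, 0.45, 0.25), (0.55, 0.0, -0.60)),
        _o("ipaq_activity", ("sedentary", "medium", "vigorous"),
           (0.35, 0.40, 0.25), (0.60, -0.15, -0.50)),
        _o("sleep_hours", ("short", "normal", "long"),
           (0.25, 0.60, 0.15), (0.50, 0.0, 0.10)),
        _b("apnea", 0.12, 0.90),
        _b("metabolic_syndrome", 0.10, 0.85),
        _b("diabetes", 0.08, 0.40),
        _b("hypertension", 0.18, 0.35),
        _b("hypercholesterolemia", 0.20, 0.25),
        _o("stress", ("low", "medium", "high"),
           (0.35, 0.45, 0.20), (0.0, 0.05, 0.15)),
        FeatureSpec("recruitment_center", "categorical", centers,
                    center_p, tuple(np.zeros(14))),
        _c("marital_status", ("single", "married", "divorced", "widowed"),
           (0.35, 0.48, 0.12, 0.05), (0.0, 0.10, 0.05, 0.10)),
        _o("household_size", ("1", "2", "3", "4_plus"),
           (0.22, 0.33, 0.25, 0.20), (0.05, 0.0, 0.0, 0.05)),
        _b("snoring", 0.30, 0.30),
        _o("fast_food_weekly", ("rarely", "weekly", "several"),
           (0.50, 0.35, 0.15), (-0.05, 0.15, 0.35)),
        _o("sugary_drinks", ("rarely", "weekly", "daily"),
           (0.55, 0.30, 0.15), (-0.05, 0.10, 0.30)),
        _o("fruit_servings", ("low", "medium", "high"),
           (0.30, 0.45, 0.25), (0.20, 0.0, -0.20)),
        _o("vegetable_servings", ("low", "medium", "high"),
           (0.30, 0.45, 0.25), (0.20, 0.0, -0.20)),
        _b("breakfast_daily", 0.70, -0.15),
        _o("snacking", ("rarely", "sometimes", "often"),
           (0.40, 0.40, 0.20), (-0.05, 0.05, 0.25)),
        _o("screen_hours", ("low", "medium", "high"),
           (0.30, 0.45, 0.25), (-0.10, 0.05, 0.30)),
        _b("active_commute", 0.35, -0.20),
        _o("work_hours", ("part_time", "standard", "long"),
           (0.20, 0.60, 0.20), (0.0, 0.0, 0.15)),
        _b("night_shift", 0.12, 0.25),
        _b("weight_loss_attempt", 0.30, 0.30),
        _b("family_obesity", 0.25, 0.50),
        _b("anxiety_treatment", 0.10, 0.20),
        _b("depression_treatment", 0.08, 0.20),
        _b("olive_oil_main_fat", 0.70, -0.20),
        _o("legumes_weekly", ("low", "medium", "high"),
           (0.30, 0.50, 0.20), (0.15, 0.0, -0.15)),
    )
    schema = FeatureSchema(entries)
    assert len(schema) == 38
    return schema


@dataclass
class CohortTable:
    """Subjects-by-features table with binary outcome.

    ``data`` holds one column per schema entry (integer level codes for
    non-continuous kinds, floats for continuous), an ``outcome`` column
    (1 = overweight/obesity) and, for synthetic cohorts, the ``latent_bmi``
    ground truth.  The index is the opaque subject identifier.
    """

    data: pd.DataFrame
    schema: FeatureSchema

    def __post_init__(self):
        if len(self.data) == 0:
            raise InvalidArgumentError("cohort must have at least one row")
        missing = [n for n in self.schema.names if n not in self.data.columns]
        if missing or "outcome" not in self.data.columns:
            raise InvalidArgumentError(
                f"cohort data missing columns: {missing + ['outcome'] if 'outcome' not in self.data.columns else missing}"
            )
        if self.data["outcome"].isna().any():
            raise InvalidArgumentError("missing outcome values are not allowed")

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def is_synthetic(self) -> bool:
        return "latent_bmi" in self.data.columns

    @property
    def feature_names(self):
        return self.schema.names

    def features(self) -> pd.DataFrame:
        return self.data[self.schema.names]

    def outcome(self) -> pd.Series:
        return self.data["outcome"].astype(int)

    def prevalence(self) -> float:
        return float(self.outcome().mean())

    def subset(self, index) -> "CohortTable":
        return CohortTable(self.data.loc[index].copy(), self.schema)

    def to_csv(self, path_or_buf) -> None:
        cols = self.schema.names + ["outcome"]
        if self.is_synthetic:
            cols.append("latent_bmi")
        self.data[cols].to_csv(path_or_buf, index=True, index_label="subject_id",
                               encoding="utf-8")

    def to_csv_string(self) -> str:
        buf = io.StringIO()
        self.to_csv(buf)
        return buf.getvalue()


def read_cohort_csv(path_or_buf, schema: FeatureSchema) -> CohortTable:
    """Read a cohort CSV written by :meth:`CohortTable.to_csv`.

    Missing outcomes are rejected; missing feature values are imputed with
    the column mode (categorical kinds) or median (continuous) and logged.
    """
    df = pd.read_csv(path_or_buf, index_col="subject_id", encoding="utf-8")
    if "outcome" not in df.columns or df["outcome"].isna().any():
        raise InvalidArgumentError("cohort CSV has missing outcome values")
    for spec in schema.entries:
        if spec.name not in df.columns:
            raise InvalidArgumentError(f"cohort CSV missing feature {spec.name!r}")
        col = df[spec.name]
        if col.isna().any():
            fill = (col.median() if spec.kind == "continuous"
                    else col.mode().iloc[0])
            logger.warning("imputing %d missing values in %r with %r",
                           int(col.isna().sum()), spec.name, fill)
            warnings.warn(f"imputed missing values in {spec.name!r}")
            df[spec.name] = col.fillna(fill)
    return CohortTable(df, schema)


def linear_predictor(schema: FeatureSchema, effects: EffectConfig,
                     features: pd.DataFrame) -> np.ndarray:
    """Deterministic part of the latent BMI (without intercept or noise)."""
    lp = np.zeros(len(features), dtype=float)
    for spec in schema.entries:
        col = features[spec.name].to_numpy()
        if spec.kind == "continuous":
            lp += float(spec.effect) * (col - spec.center)
        else:
            eff = np.asarray(spec.effect, dtype=float)
            lp += eff[col.astype(int)]
    for term in effects.interactions:
        mask = np.ones(len(features), dtype=bool)
        for name, selector in term.conditions:
            if name not in features.columns:
                mask &= False
                continue
            spec = schema[name]
            col = features[name].to_numpy()
            if spec.kind == "continuous":
                lo, hi = selector
                mask &= (col >= lo) & (col < hi)
            else:
                mask &= col.astype(int) == spec.categories.index(selector)
        lp += np.where(mask, term.weight, 0.0)
    return lp


def _draw_features(schema: FeatureSchema, n: int,
                   rng: np.random.Generator) -> pd.DataFrame:
    cols = {}
    for spec in schema.entries:
        if spec.kind == "continuous":
            lo, hi = spec.marginal
            cols[spec.name] = rng.uniform(lo, hi, size=n)
        else:
            p = np.asarray(spec.marginal, dtype=float)
            cols[spec.name] = rng.choice(len(p), size=n, p=p).astype(int)
    return pd.DataFrame(cols)


_CALIBRATION_SEED = 202_401  # internal, independent of the caller's seed
_CALIBRATION_N = 10_000


def calibrate_intercept(schema: FeatureSchema, effects: EffectConfig,
                        target: float, tol: float = 0.02) -> float:
    """Bisect the intercept until simulated prevalence matches ``target``.

    Uses a fixed internal Monte Carlo sample of 10 000 subjects so the
    calibrated intercept is a deterministic function of (schema, effects).
    """
    rng = np.random.default_rng(_CALIBRATION_SEED)
    X = _draw_features(schema, _CALIBRATION_N, rng)
    lp = linear_predictor(schema, effects, X)
    noise = rng.normal(0.0, effects.noise_sd, size=_CALIBRATION_N)
    z = lp + noise  # prevalence(b) = mean(b + z >= 25), monotone in b

    def prev(b):
        return float(np.mean(b + z >= BMI_THRESHOLD))

    lo, hi = BMI_THRESHOLD + z.min() - 1.0, BMI_THRESHOLD + z.max() + 1.0
    if not (prev(lo) <= target <= prev(hi)):
        raise CalibrationError(
            f"target prevalence {target} unreachable: attainable range "
            f"[{prev(lo):.3f}, {prev(hi):.3f}] under the given effects"
        )
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        if prev(mid) < target:
            lo = mid
        else:
            hi = mid
        if abs(prev(mid) - target) <= 0.25 * tol:
            break
    b = 0.5 * (lo + hi)
    achieved = prev(b)
    if abs(achieved - target) > tol:
        raise CalibrationError(
            f"calibration stalled at prevalence {achieved:.3f} for target {target}"
        )
    return b


def generate_cohort(schema: FeatureSchema, effects: EffectConfig | None = None,
                    n: int = 1179, seed: int = 0) -> CohortTable:
    """Draw a seeded synthetic cohort.

    Features are sampled independently per the schema marginals; the latent
    BMI adds the configured effects, interaction terms and Gaussian noise;
    the outcome is the indicator ``latent_bmi >= 25``.  When
    ``effects.target_prevalence`` is set the intercept is re-calibrated by
    bisection (deterministically) before sampling.  Identical arguments
    reproduce identical tables bit for bit.
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if effects is None:
        effects = default_effects()
    intercept = effects.intercept
    if effects.target_prevalence is not None:
        intercept = calibrate_intercept(schema, effects,
                                        effects.target_prevalence)
    rng = np.random.default_rng(seed)
    X = _draw_features(schema, n, rng)
    lp = linear_predictor(schema, effects, X)
    latent = intercept + lp + rng.normal(0.0, effects.noise_sd, size=n)
    X["outcome"] = (latent >= BMI_THRESHOLD).astype(int)
    X["latent_bmi"] = latent
    X.index = pd.Index([f"S{i:06d}" for i in range(n)], name="subject_id")
    return CohortTable(X, schema)


def split_cohort(cohort: CohortTable, train_fraction: float = 0.75,
                 seed: int = 0, stratify: bool = True):
    """Disjoint train/test partition, stratified by outcome by default."""
    from sklearn.model_selection import train_test_split

    if not (0.0 < train_fraction < 1.0):
        raise InvalidArgumentError("train_fraction must be in (0, 1)")
    y = cohort.outcome()
    strat = y if stratify else None
    if stratify and y.nunique() < 2:
        raise DegenerateSplit("stratified split requires both classes present")
    try:
        idx_train, idx_test = train_test_split(
            cohort.data.index, train_size=train_fraction, random_state=seed,
            stratify=strat, shuffle=True,
        )
    except ValueError as exc:
        raise DegenerateSplit(str(exc)) from exc
    train, test = cohort.subset(idx_train), cohort.subset(idx_test)
    if stratify and (train.outcome().nunique() < 2 or test.outcome().nunique() < 2):
        raise DegenerateSplit("split left a part with a single class")
    return train, test


class DegenerateSplit(InvalidArgumentError):
    """A split would leave one part with a single outcome class."""


def drop_features(cohort: CohortTable, names) -> CohortTable:
    """Return a cohort restricted to the schema without ``names``."""
    schema = cohort.schema.drop(names)
    return CohortTable(cohort.data.copy(), schema)


# ---------------------------------------------------------------------------
# Schema / effects serialization (human-editable YAML)

def schema_to_dict(schema: FeatureSchema) -> dict:
    return {
        "features": [
            {
                "name": e.name, "kind": e.kind,
                "categories": list(e.categories),
                "marginal": [float(x) for x in e.marginal],
                "effect": (float(e.effect) if e.kind == "continuous"
                           else [float(x) for x in np.asarray(e.effect)]),
                "center": float(e.center),
            }
            for e in schema.entries
        ]
    }


def schema_from_dict(d: dict) -> FeatureSchema:
    entries = []
    for f in d["features"]:
        eff = f["effect"]
        entries.append(FeatureSpec(
            f["name"], f["kind"], tuple(f.get("categories", ())),
            tuple(f["marginal"]),
            float(eff) if f["kind"] == "continuous" else tuple(eff),
            float(f.get("center", 0.0)),
        ))
    return FeatureSchema(tuple(entries))


def effects_to_dict(effects: EffectConfig) -> dict:
    return {
        "intercept": float(effects.intercept),
        "noise_sd": float(effects.noise_sd),
        "target_prevalence": effects.target_prevalence,
        "interactions": [
            {"conditions": [[n, list(s) if isinstance(s, tuple) else s]
                            for n, s in t.conditions],
             "weight": float(t.weight)}
            for t in effects.interactions
        ],
    }


def effects_from_dict(d: dict) -> EffectConfig:
    terms = tuple(
        Interaction(tuple((n, tuple(s) if isinstance(s, list) else s)
                          for n, s in t["conditions"]),
                    float(t["weight"]))
        for t in d.get("interactions", ())
    )
    return EffectConfig(
        intercept=float(d.get("intercept", BMI_THRESHOLD)),
        noise_sd=float(d.get("noise_sd", 2.6)),
        interactions=terms,
        target_prevalence=d.get("target_prevalence"),
    )


def save_generator_config(path, schema: FeatureSchema,
                          effects: EffectConfig) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump({"schema": schema_to_dict(schema),
                        "effects": effects_to_dict(effects)}, fh,
                       sort_keys=False)


def load_generator_config(path):
    with open(path, encoding="utf-8") as fh:
        d = yaml.safe_load(fh)
    return schema_from_dict(d["schema"]), effects_from_dict(d["effects"])
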