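"""Synthetic cohorts emulating a pulmonary-embolism study population.

The generator draws 22 clinical features independently from the study's
published marginals — binary comorbidity/history flags at their observed
prevalences, a three-level smoking status, and Gaussian age / body-mass
index / heart rate — and a binary PE outcome from a logistic model

    Y ~ Bernoulli(expit(intercept + sum of signal terms)),

whose intercept is calibrated so the cohort hits a target outcome
prevalence (default 19.1%).  Signal terms may be main effects, pairwise
interactions, or a centered quadratic in a continuous feature, so the
"features jointly influence risk in a complex fashion" premise is
exercised.  Every simulated cohort carries its ground truth (which
features are signal vs null), which is what makes type-I error and power
measurable downstream.

Continuous features enter the linear predictor standardized by their
specified mean/SD, so coefficients are on a comparable per-SD scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import brentq
from scipy.special import expit, logit

from .cohort import CohortTable, FeatureMeta, encode_features

logger = logging.getLogger(__name__)

__all__ = [
    "SignalTerm",
    "SyntheticSpec",
    "SimulatedCohort",
    "pe_study_spec",
    "three_signal_spec",
    "simulate_cohort",
    "calibrate_intercept",
    "make_null_cohort",
]

_N_STUDY = 758

# observed level counts out of 758 patients (prevalence of the non-reference level)
MAJOR_BINARY_COUNTS = {
    "gender": 226,                  # Male
    "pe_history": 80,
    "dvt_history": 42,
    "hypertension": 487,
    "congestive_heart_failure": 137,
    "cancer_history": 262,
    "race": 290,                    # Black
    "cerebrovascular_disease": 37,
    "diabetes": 247,
    "hyperlipidemia": 307,
    "inhaled_steroids": 375,
    "chronic_prednisone": 170,
}
MINOR_BINARY_COUNTS = {
    "atrial_fibrillation": 97,
    "ed_visit_prev_year": 130,
    "cad_or_pvd": 178,
    "contraceptive_use": 13,
    "recent_fracture_or_anesthesia": 4,
    "hemoptysis": 7,
}
SMOKING_COUNTS = {"No": 268, "Yes": 432, "Unknown": 58}
CONTINUOUS_PARAMS = {
    "age": (52.20, 16.20),
    "bmi": (31.50, 9.21),
    "heart_rate": (100.46, 19.05),
}
_BINARY_LEVELS = {"gender": ("Female", "Male"), "race": ("Non-black", "Black")}


@dataclass(frozen=True)
class SignalTerm:
    """One term of the outcome's linear predictor.

    kind: "main" (coef * x), "interaction" (coef * x1 * x2) or
    "quadratic" (coef * (x^2 - 1), centered so it leaves the mean of the
    linear predictor unchanged for a standard-normal feature).
    """

    kind: str
    features: tuple
    coef: float

    def __post_init__(self):
        expected = {"main": 1, "interaction": 2, "quadratic": 1}
        if self.kind not in expected:
            raise ValueError(f"unknown term kind {self.kind!r}")
        if len(self.features) != expected[self.kind]:
            raise ValueError(f"{self.kind} term needs {expected[self.kind]} feature(s)")


@dataclass(frozen=True)
class SyntheticSpec:
    """Full generative description of a simulated cohort."""

    n: int = _N_STUDY
    binary_prevalences: dict = field(
        default_factory=lambda: {
            k: v / _N_STUDY
            for k, v in {**MAJOR_BINARY_COUNTS, **MINOR_BINARY_COUNTS}.items()
        }
    )
    smoking_probs: dict = field(
        default_factory=lambda: {k: v / _N_STUDY for k, v in SMOKING_COUNTS.items()}
    )
    continuous_params: dict = field(default_factory=lambda: dict(CONTINUOUS_PARAMS))
    signal_terms: tuple = ()
    intercept: float | None = None      # None -> calibrated to target_prevalence
    target_prevalence: float = 0.191
    seed: int = 0

    def __post_init__(self):
        for name, p in self.binary_prevalences.items():
            if not 0 < p < 1:
                raise ValueError(f"prevalence of {name!r} outside (0,1)")
        for name, (_, sd) in self.continuous_params.items():
            if sd <= 0:
                raise ValueError(f"sd of {name!r} must be positive")
        if not 0 < self.target_prevalence < 1:
            raise ValueError("target_prevalence must lie in (0,1)")
        known = (set(self.binary_prevalences) | set(self.continuous_params)
                 | {"smoking"})
        for t in self.signal_terms:
            for f in t.features:
                if f not in known:
                    raise ValueError(f"signal term references unknown feature {f!r}")

    @property
    def signal_features(self) -> list[str]:
        seen: list[str] = []
        for t in self.signal_terms:
            for f in t.features:
                if f not in seen:
                    seen.append(f)
        return seen

    @property
    def feature_meta(self) -> list[FeatureMeta]:
        metas = []
        for name in self.binary_prevalences:
            lv = _BINARY_LEVELS.get(name, ("No", "Yes"))
            metas.append(FeatureMeta(name, "binary", lv, lv[0]))
        if self.smoking_probs:
            metas.append(
                FeatureMeta("smoking", "categorical",
                            tuple(self.smoking_probs), next(iter(self.smoking_probs)))
            )
        metas.extend(FeatureMeta(n, "continuous") for n in self.continuous_params)
        return metas

    def to_yaml(self) -> str:
        d = {
            "n": self.n,
            "binary_prevalences": dict(self.binary_prevalences),
            "smoking_probs": dict(self.smoking_probs),
            "continuous_params": {k: list(v) for k, v in self.continuous_params.items()},
            "signal_terms": [
                {"kind": t.kind, "features": list(t.features), "coef": t.coef}
                for t in self.signal_terms
            ],
            "intercept": self.intercept,
            "target_prevalence": self.target_prevalence,
            "seed": self.seed,
        }
        return yaml.safe_dump(d, sort_keys=False)

    @classmethod
    def from_yaml(cls, text: str) -> "SyntheticSpec":
        d = yaml.safe_load(text)
        d["signal_terms"] = tuple(
            SignalTerm(t["kind"], tuple(t["features"]), t["coef"])
            for t in d.get("signal_terms", [])
        )
        d["continuous_params"] = {k: tuple(v) for k, v in d["continuous_params"].items()}
        return cls(**d)


@dataclass(frozen=True)
class SimulatedCohort:
    """An encoded cohort plus its generative ground truth."""

    table: CohortTable
    signal_features: tuple
    intercept: float
    spec: SyntheticSpec

    def is_signal(self, feature: str) -> bool:
        return feature in self.signal_features


def pe_study_spec(n: int = _N_STUDY, seed: int = 0) -> SyntheticSpec:
    """Default study-emulating scenario.

    The signal set mirrors the features the stable-DNN analysis flagged —
    main effects on PE history, chronic prednisone use and DVT history —
    plus a PE-history x prednisone interaction and a quadratic heart-rate
    term, so the outcome is a genuinely nonlinear function of the features.
    Coefficients are per-SD/log-odds-ratio scale choices of this generator
    (prior PE is clinically the dominant risk factor, hence the largest).
    """
    return SyntheticSpec(
        n=n, seed=seed,
        signal_terms=(
            SignalTerm("main", ("pe_history",), 1.8),
            SignalTerm("main", ("chronic_prednisone",), 0.9),
            SignalTerm("main", ("dvt_history",), 1.2),
            SignalTerm("interaction", ("pe_history", "chronic_prednisone"), 0.6),
            SignalTerm("quadratic", ("heart_rate",), 0.4),
        ),
    )


def three_signal_spec(n: int = 2000, seed: int = 0, coef: float = 1.2) -> SyntheticSpec:
    """Three strong main effects (two prevalent binaries + one continuous)
    among 22 features; used for power/ranking studies."""
    return SyntheticSpec(
        n=n, seed=seed,
        signal_terms=(
            SignalTerm("main", ("hypertension",), coef),
            SignalTerm("main", ("diabetes",), coef),
            SignalTerm("main", ("age",), coef * 0.75),
        ),
    )


def _standardized_values(spec: SyntheticSpec, draws: dict) -> dict:
    out = {}
    for name, arr in draws.items():
        if name in spec.continuous_params:
            m, sd = spec.continuous_params[name]
            out[name] = (arr - m) / sd
        elif name == "smoking":
            out[name] = None    # no default signal on smoking levels
        else:
            out[name] = arr.astype(float)
    return out


def _linear_predictor(spec: SyntheticSpec, draws: dict) -> np.ndarray:
    z = _standardized_values(spec, draws)
    eta = np.zeros(len(next(iter(draws.values()))))
    for t in spec.signal_terms:
        if t.kind == "main":
            eta += t.coef * z[t.features[0]]
        elif t.kind == "interaction":
            eta += t.coef * z[t.features[0]] * z[t.features[1]]
        else:   # quadratic, centered for a standard-normal feature
            eta += t.coef * (z[t.features[0]] ** 2 - 1.0)
    return eta


def _draw_features(spec: SyntheticSpec, n: int, rng: np.random.Generator) -> dict:
    draws = {}
    for name, p in spec.binary_prevalences.items():
        draws[name] = (rng.random(n) < p).astype(int)
    if spec.smoking_probs:
        levels = list(spec.smoking_probs)
        probs = np.array([spec.smoking_probs[k] for k in levels], dtype=float)
        draws["smoking"] = rng.choice(levels, size=n, p=probs / probs.sum())
    for name, (m, sd) in spec.continuous_params.items():
        draws[name] = rng.normal(m, sd, size=n)
    return draws


def calibrate_intercept(
    spec: SyntheticSpec, probe_n: int = 100_000, tol: float = 0.005
) -> float:
    """Intercept at which the cohort prevalence hits ``target_prevalence``.

    With no signal terms this is exactly logit(target); otherwise the mean
    of expit(b + eta) over a large fixed probe draw of eta is root-found in
    b.  Deterministic given the spec's seed.
    """
    if not spec.signal_terms:
        return float(logit(spec.target_prevalence))
    probe_seed = int(np.random.SeedSequence([spec.seed, 0xCA1]).generate_state(1)[0])
    rng = np.random.default_rng(probe_seed)
    eta = _linear_predictor(spec, _draw_features(spec, probe_n, rng))

    def gap(b):
        return expit(b + eta).mean() - spec.target_prevalence

    lo, hi = -25.0, 25.0
    if gap(lo) > 0 or gap(hi) < 0:
        raise RuntimeError(
            f"intercept search failed: prevalence range "
            f"[{gap(lo) + spec.target_prevalence:.4f}, "
            f"{gap(hi) + spec.target_prevalence:.4f}] cannot reach target"
        )
    b = float(brentq(gap, lo, hi, xtol=1e-8))
    achieved = expit(b + eta).mean()
    if abs(achieved - spec.target_prevalence) > tol:
        raise RuntimeError(f"intercept calibration off target: {achieved:.4f}")
    return b


def simulate_cohort(spec: SyntheticSpec) -> SimulatedCohort:
    """Draw one cohort from the spec; bit-identical for identical spec+seed."""
    rng = np.random.default_rng(spec.seed)
    draws = _draw_features(spec, spec.n, rng)
    intercept = spec.intercept if spec.intercept is not None else calibrate_intercept(spec)
    prob = expit(intercept + _linear_predictor(spec, draws))
    Y = (rng.random(spec.n) < prob).astype(int)

    metas = spec.feature_meta
    raw = {}
    for m in metas:
        if m.kind == "binary":
            raw[m.name] = np.asarray(m.levels, dtype=object)[draws[m.name]]
        else:
            raw[m.name] = draws[m.name]
    X, column_map, encoded_names = encode_features(pd.DataFrame(raw), metas)
    table = CohortTable(X, Y, metas, column_map, encoded_names)

    prev = Y.mean()
    sd3 = 3 * np.sqrt(spec.target_prevalence * (1 - spec.target_prevalence) / spec.n)
    if abs(prev - spec.target_prevalence) > sd3:
        logger.warning(
            "simulated prevalence %.3f outside 3 SD of target %.3f",
            prev, spec.target_prevalence,
        )
    return SimulatedCohort(
        table=table, signal_features=tuple(spec.signal_features),
        intercept=float(intercept), spec=spec,
    )


def make_null_cohort(spec: SyntheticSpec) -> SimulatedCohort:
    """Same marginals, all signal coefficients forced to zero: Y independent
    of every feature by construction."""
    return simulate_cohort(replace(spec, signal_terms=(), intercept=None))
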