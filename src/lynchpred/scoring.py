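"""Linear-predictor risk models for Lynch-syndrome carrier probability.

Two model shapes are supported, with all numeric coefficients supplied by
configuration rather than hard-coded:

* a four-category multinomial model in the style of PREMM5 — one linear
  predictor per mismatch-repair gene (MLH1, MSH2, MSH6, PMS2), each feeding
  a shared softmax against the "no mutation" baseline; and
* a single-outcome logistic model in the style of MMRpredict, applicable
  only to probands with at least one colorectal cancer.

A coefficient config pairs per-outcome intercepts/coefficients with an
*encoding recipe* per covariate (indicator, capped count, or shifted/scaled
age), so model variants are expressed without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import yaml

from .cohort import GENES, IndexPatient
from .errors import EncodingError, NotApplicableError, ValidationError

__all__ = [
    "Recipe",
    "CoefficientSet",
    "GeneProbabilities",
    "encode_covariates",
    "linear_predictor",
    "multinomial_probabilities",
    "score_premm5",
    "score_mmrpredict",
]


@dataclass(frozen=True)
class Recipe:
    """How one named covariate is computed from an :class:`IndexPatient`.

    kind:
        ``indicator`` — 1.0 if the field equals ``equals`` (or is truthy for
        flag fields), else 0.0;
        ``count`` — integer field capped at ``cap``;
        ``age`` — ``(age - shift) / scale``, with ``default`` used (already
        on the transformed scale) when the age is absent. A missing age with
        no default is an encoding error, never a silent imputation.
    """

    kind: str
    fieldname: str
    equals: Optional[str] = None
    cap: Optional[int] = None
    shift: float = 0.0
    scale: float = 1.0
    default: Optional[float] = None

    def encode(self, patient: IndexPatient) -> float:
        value = getattr(patient, self.fieldname, None)
        if self.kind == "indicator":
            if self.equals is not None:
                return 1.0 if value == self.equals else 0.0
            if value is None:
                if self.default is not None:
                    return self.default
                raise EncodingError(
                    f"covariate field {self.fieldname!r} is undefined for "
                    f"patient {patient.id!r}")
            return 1.0 if bool(value) else 0.0
        if self.kind == "count":
            if value is None:
                raise EncodingError(
                    f"count field {self.fieldname!r} missing for patient "
                    f"{patient.id!r}")
            n = int(value)
            return float(min(n, self.cap) if self.cap is not None else n)
        if self.kind == "age":
            if value is None:
                if self.default is not None:
                    return self.default
                raise EncodingError(
                    f"age field {self.fieldname!r} missing for patient "
                    f"{patient.id!r} and the recipe has no default")
            return (float(value) - self.shift) / self.scale
        raise EncodingError(f"unknown recipe kind {self.kind!r}")


@dataclass
class CoefficientSet:
    """A named risk model: intercepts, coefficients and encoding recipes."""

    model_name: str
    outcomes: list[str]
    intercepts: dict[str, float]
    coefficients: dict[str, dict[str, float]]
    encoding: dict[str, Recipe] = field(default_factory=dict)

    def validate(self) -> "CoefficientSet":
        if len(self.outcomes) not in (1, 4):
            raise ValidationError(
                "a model has one outcome (logistic) or four (multinomial), "
                f"got {len(self.outcomes)}")
        for out in self.outcomes:
            if out not in self.intercepts:
                raise ValidationError(f"missing intercept for outcome {out!r}")
            for name in self.coefficients.get(out, {}):
                if name not in self.encoding:
                    raise ValidationError(
                        f"coefficient {name!r} of outcome {out!r} has no "
                        "encoding recipe")
        return self

    @property
    def is_multinomial(self) -> bool:
        return len(self.outcomes) == 4

    # --- YAML round-trip --------------------------------------------------

    @classmethod
    def from_dict(cls, d: Mapping) -> "CoefficientSet":
        encoding = {}
        for name, spec in d.get("encoding", {}).items():
            spec = dict(spec)
            encoding[name] = Recipe(
                kind=spec.pop("kind"),
                fieldname=spec.pop("field"),
                equals=spec.pop("equals", None),
                cap=spec.pop("cap", None),
                shift=float(spec.pop("shift", 0.0)),
                scale=float(spec.pop("scale", 1.0)),
                default=spec.pop("default", None),
            )
            if spec:
                raise ValidationError(f"unknown recipe keys for {name!r}: {sorted(spec)}")
        outcomes = list(d["outcomes"])
        intercepts = {}
        coefficients = {}
        for out in outcomes:
            block = d["model"][out]
            intercepts[out] = float(block["intercept"])
            coefficients[out] = {k: float(v) for k, v in block.get("coefficients", {}).items()}
        return cls(d["model_name"], outcomes, intercepts, coefficients, encoding).validate()

    def to_dict(self) -> dict:
        enc = {}
        for name, r in self.encoding.items():
            spec = {"kind": r.kind, "field": r.fieldname}
            if r.equals is not None:
                spec["equals"] = r.equals
            if r.cap is not None:
                spec["cap"] = r.cap
            if r.shift:
                spec["shift"] = r.shift
            if r.scale != 1.0:
                spec["scale"] = r.scale
            if r.default is not None:
                spec["default"] = r.default
            enc[name] = spec
        return {
            "model_name": self.model_name,
            "outcomes": list(self.outcomes),
            "encoding": enc,
            "model": {
                out: {"intercept": self.intercepts[out],
                      "coefficients": dict(self.coefficients.get(out, {}))}
                for out in self.outcomes
            },
        }

    @classmethod
    def from_yaml(cls, path) -> "CoefficientSet":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_yaml(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


@dataclass(frozen=True)
class GeneProbabilities:
    """Per-gene carrier probabilities from one multinomial score evaluation."""

    p_mlh1: float
    p_msh2: float
    p_msh6: float
    p_pms2: float
    p_none: float

    @property
    def p_overall(self) -> float:
        return self.p_mlh1 + self.p_msh2 + self.p_msh6 + self.p_pms2

    def per_gene(self) -> dict[str, float]:
        return {"MLH1": self.p_mlh1, "MSH2": self.p_msh2,
                "MSH6": self.p_msh6, "PMS2": self.p_pms2}

    def check(self, tol: float = 1e-12) -> "GeneProbabilities":
        ps = (self.p_mlh1, self.p_msh2, self.p_msh6, self.p_pms2, self.p_none)
        if any(not (0.0 <= p <= 1.0) for p in ps):
            raise ValidationError("probabilities must lie in [0, 1]")
        if abs(self.p_overall + self.p_none - 1.0) > tol:
            raise ValidationError("gene probabilities plus baseline must sum to 1")
        return self


def encode_covariates(patient: IndexPatient, coeffs: CoefficientSet) -> dict[str, float]:
    """Encode every covariate of the recipe deterministically.

    A covariate the recipe requires but the patient cannot supply raises
    :class:`EncodingError`; nothing is imputed silently.
    """
    return {name: recipe.encode(patient) for name, recipe in coeffs.encoding.items()}


def linear_predictor(vector: Mapping[str, float], intercept: float,
                     coefficients: Mapping[str, float]) -> float:
    """intercept + sum of coefficient * encoded covariate, by name."""
    missing = [k for k in coefficients if k not in vector]
    if missing:
        raise EncodingError(f"covariate(s) {missing} absent from encoded vector")
    return intercept + sum(c * vector[k] for k, c in coefficients.items())


def multinomial_probabilities(lp_mlh1: float, lp_msh2: float, lp_msh6: float,
                              lp_pms2: float) -> GeneProbabilities:
    """Softmax of the four gene predictors against the zero baseline.

    p_g = exp(lp_g) / (1 + sum exp(lp)); overflow-safe for |lp| up to ~700
    by shifting by the maximum logit.
    """
    lps = np.array([0.0, lp_mlh1, lp_msh2, lp_msh6, lp_pms2], dtype=float)
    if not np.all(np.isfinite(lps)):
        raise ValidationError("linear predictors must be finite")
    shifted = lps - lps.max()
    ex = np.exp(shifted)
    p = ex / ex.sum()
    return GeneProbabilities(p_mlh1=p[1], p_msh2=p[2], p_msh6=p[3],
                             p_pms2=p[4], p_none=p[0])


def score_premm5(patient: IndexPatient, coeffs: CoefficientSet) -> GeneProbabilities:
    """Evaluate a four-gene multinomial model for one proband."""
    if not coeffs.is_multinomial:
        raise ValidationError("score_premm5 needs a four-outcome model")
    if list(coeffs.outcomes) != list(GENES):
        raise ValidationError(f"multinomial outcomes must be {GENES}")
    vec = encode_covariates(patient, coeffs)
    lps = [linear_predictor(vec, coeffs.intercepts[g], coeffs.coefficients.get(g, {}))
           for g in GENES]
    return multinomial_probabilities(*lps)


def score_mmrpredict(patient: IndexPatient, coeffs: CoefficientSet) -> float:
    """Evaluate a logistic CRC-proband model; errors for CRC-free probands."""
    if coeffs.is_multinomial:
        raise ValidationError("score_mmrpredict needs a single-outcome model")
    if not patient.has_crc:
        raise NotApplicableError(
            f"patient {patient.id!r} has no CRC; this model applies to CRC "
            "probands only")
    out = coeffs.outcomes[0]
    vec = encode_covariates(patient, coeffs)
    lp = linear_predictor(vec, coeffs.intercepts[out], coeffs.coefficients.get(out, {}))
    # expit, overflow-safe
    if lp >= 0:
        return 1.0 / (1.0 + math.exp(-lp))
    e = math.exp(lp)
    return e / (1.0 + e)
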