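"""Constrained multinomial updating of a four-gene carrier risk model.

An existing multinomial model supplies, for each patient, one linear
predictor per gene (lp_g). Updating keeps the multinomial structure —
each original predictor contributes only to its own gene's category — and
refits a small number of parameters by maximum likelihood on new data:

    LP_g = alpha_g + beta_g * lp_g  [+ gamma_g * proximal]
                                    (+ delta * I(>=2 CRCs) for MSH6 only)

* ``recalibrate_plus_msh6`` (adaptation 1) frees the per-gene intercepts
  alpha_g and slopes beta_g, plus delta — a re-estimated coefficient for
  "two or more CRCs" in the MSH6 predictor. The original model's own
  two-or-more-CRCs term is removed from lp_MSH6 before fitting (the term
  was estimated without any eligible carriers and is unreliable), so delta
  replaces rather than augments it.
* ``extend_with_side`` (adaptation 2) additionally frees gamma_g, the
  coefficient of a proximal-CRC indicator in every gene's predictor.

Category probabilities are a softmax of the updated predictors against the
"no mutation" baseline (logit 0). The constraints are structural zeros in
the design, so fitting is plain unconstrained quasi-Newton (BFGS) from the
identity start (alpha=0, beta=1, gamma=0, delta=0), with an analytic
gradient; convergence when the gradient max-norm drops below 1e-6. A
separation guard flags any fit with a parameter beyond +/-15 on the logit
scale as non-converged instead of returning a silently diverged answer.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import minimize

from .cohort import GENES, Cohort
from .errors import FitError, ValidationError
from .scoring import (CoefficientSet, GeneProbabilities, encode_covariates,
                      linear_predictor)

ADAPTATIONS = ("recalibrate_plus_msh6", "extend_with_side")
#: Parameters larger than this on the logit scale signal separation.
SEPARATION_BOUND = 15.0
#: Floor applied to log category probabilities inside the likelihood.
LOG_FLOOR = -700.0


@dataclass
class UpdateDataset:
    """Per-patient inputs of the updating likelihood.

    ``outcome`` codes the observed category: 0 = no mutation, 1..k = the
    gene at ``genes[outcome - 1]``. ``lp`` holds the original per-gene
    linear predictors, column g for ``genes[g]`` (for the MSH6 column,
    already stripped of the original two-or-more-CRCs term when that
    coefficient is known).
    """

    lp: np.ndarray                      # (n, k)
    proximal: np.ndarray                # (n,) in {0,1}
    two_plus: np.ndarray                # (n,) in {0,1}
    outcome: np.ndarray                 # (n,) ints in 0..k
    genes: tuple[str, ...] = GENES

    def __post_init__(self):
        self.lp = np.asarray(self.lp, dtype=float)
        if self.lp.ndim == 1:
            self.lp = self.lp[:, None]
        self.proximal = np.asarray(self.proximal, dtype=float)
        self.two_plus = np.asarray(self.two_plus, dtype=float)
        self.outcome = np.asarray(self.outcome, dtype=int)
        n, k = self.lp.shape
        if k != len(self.genes):
            raise ValidationError("lp must have one column per gene")
        for arr, name in ((self.proximal, "proximal"), (self.two_plus, "two_plus")):
            if arr.shape != (n,):
                raise ValidationError(f"{name} must have length n")
            if not np.isin(arr, (0.0, 1.0)).all():
                raise ValidationError(f"{name} must be a 0/1 indicator")
        if self.outcome.shape != (n,) or self.outcome.min() < 0 or self.outcome.max() > k:
            raise ValidationError("outcome codes must lie in 0..k")

    @property
    def n(self) -> int:
        return self.lp.shape[0]

    @property
    def msh6_index(self) -> Optional[int]:
        return self.genes.index("MSH6") if "MSH6" in self.genes else None


@dataclass
class UpdatedModel:
    """Recalibration/extension parameters with fit diagnostics."""

    genes: tuple[str, ...]
    alpha: dict[str, float]
    beta: dict[str, float]
    gamma: Optional[dict[str, float]]       # None for adaptation 1
    delta_msh6: Optional[float]             # None when MSH6 absent
    adaptation: str = "recalibrate_plus_msh6"
    loglik: float = float("nan")
    converged: bool = False
    n_iter: int = 0
    message: str = ""

    @classmethod
    def identity(cls, genes: tuple[str, ...] = GENES,
                 adaptation: str = "recalibrate_plus_msh6") -> "UpdatedModel":
        return cls(
            genes=tuple(genes),
            alpha={g: 0.0 for g in genes},
            beta={g: 1.0 for g in genes},
            gamma={g: 0.0 for g in genes} if adaptation == "extend_with_side" else None,
            delta_msh6=0.0 if "MSH6" in genes else None,
            adaptation=adaptation,
        )

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "adaptation": self.adaptation,
            "alpha": dict(self.alpha),
            "beta": dict(self.beta),
            "gamma": dict(self.gamma) if self.gamma is not None else None,
            "delta_msh6": self.delta_msh6,
            "loglik": self.loglik,
            "converged": self.converged,
            "n_iter": self.n_iter,
        }


def _normalize_adaptation(adaptation) -> str:
    if adaptation in (1, "1"):
        return "recalibrate_plus_msh6"
    if adaptation in (2, "2"):
        return "extend_with_side"
    if adaptation not in ADAPTATIONS:
        raise ValidationError(f"adaptation must be one of {ADAPTATIONS}")
    return adaptation


# --- likelihood -----------------------------------------------------------

def _updated_logits(model: UpdatedModel, data: UpdateDataset) -> np.ndarray:
    """(n, k+1) logits: column 0 is the baseline (0), then one per gene."""
    k = len(data.genes)
    alpha = np.array([model.alpha[g] for g in data.genes])
    beta = np.array([model.beta[g] for g in data.genes])
    lp = alpha + beta * data.lp
    if model.gamma is not None:
        gamma = np.array([model.gamma[g] for g in data.genes])
        lp = lp + gamma * data.proximal[:, None]
    mi = data.msh6_index
    if mi is not None and model.delta_msh6 is not None:
        lp[:, mi] += model.delta_msh6 * data.two_plus
    return np.concatenate([np.zeros((data.n, 1)), lp], axis=1)


def _log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=1, keepdims=True)
    logz = np.log(np.exp(shifted).sum(axis=1, keepdims=True))
    return np.maximum(shifted - logz, LOG_FLOOR)


def negative_log_likelihood(model: UpdatedModel, data: UpdateDataset) -> float:
    """-sum_i log P(outcome_i) under the updated multinomial model."""
    logp = _log_softmax(_updated_logits(model, data))
    return -float(logp[np.arange(data.n), data.outcome].sum())


# --- fitting --------------------------------------------------------------

def fit_update(data: UpdateDataset, adaptation="recalibrate_plus_msh6",
               fix_beta: bool = False, gtol: float = 1e-6,
               maxiter: int = 500) -> UpdatedModel:
    """Maximum-likelihood fit of the updating parameters.

    Starts at the identity update and runs BFGS with an analytic gradient.
    ``fix_beta`` pins every slope at 1 (pure extension). Fits whose
    parameters exceed the separation bound are reported non-converged.
    """
    adaptation = _normalize_adaptation(adaptation)
    genes = tuple(data.genes)
    k = len(genes)
    if len(np.unique(data.outcome)) < 2:
        raise FitError("need at least two observed outcome categories")

    free_gamma = adaptation == "extend_with_side"
    free_delta = data.msh6_index is not None
    mi = data.msh6_index

    def split(x):
        alpha = x[:k]
        beta = np.ones(k) if fix_beta else x[k:2 * k]
        i = k if fix_beta else 2 * k
        delta = x[i] if free_delta else 0.0
        i += int(free_delta)
        gamma = x[i:i + k] if free_gamma else np.zeros(k)
        return alpha, beta, delta, gamma

    y = data.outcome
    onehot = np.zeros((data.n, k))
    rows = y > 0
    onehot[np.where(rows)[0], y[rows] - 1] = 1.0

    def nll_grad(x):
        alpha, beta, delta, gamma = split(x)
        lp = alpha + beta * data.lp + gamma * data.proximal[:, None]
        if free_delta:
            lp[:, mi] = lp[:, mi] + delta * data.two_plus
        logits = np.concatenate([np.zeros((data.n, 1)), lp], axis=1)
        logp = _log_softmax(logits)
        nll = -logp[np.arange(data.n), y].sum()
        p = np.exp(logp)[:, 1:]                      # (n, k) gene probabilities
        resid = onehot - p                           # d loglik / d LP_g
        g_alpha = -resid.sum(axis=0)
        grads = [g_alpha]
        if not fix_beta:
            grads.append(-(resid * data.lp).sum(axis=0))
        if free_delta:
            grads.append(np.array([-(resid[:, mi] * data.two_plus).sum()]))
        if free_gamma:
            grads.append(-(resid * data.proximal[:, None]).sum(axis=0))
        return nll, np.concatenate(grads)

    n_free = k * (1 + (not fix_beta) + free_gamma) + int(free_delta)
    x0 = np.zeros(n_free)
    if not fix_beta:
        x0[k:2 * k] = 1.0

    res = minimize(nll_grad, x0, jac=True, method="BFGS",
                   options={"gtol": gtol, "maxiter": maxiter})

    alpha, beta, delta, gamma = split(res.x)
    model = UpdatedModel(
        genes=genes,
        alpha=dict(zip(genes, map(float, alpha))),
        beta=dict(zip(genes, map(float, beta))),
        gamma=dict(zip(genes, map(float, gamma))) if free_gamma else None,
        delta_msh6=float(delta) if free_delta else None,
        adaptation=adaptation,
        loglik=-float(res.fun),
        n_iter=int(res.nit),
    )
    separated = np.abs(res.x).max() > SEPARATION_BOUND
    grad_ok = np.abs(res.jac).max() < max(gtol * max(1.0, abs(res.fun)), gtol * 10)
    model.converged = bool((res.success or grad_ok) and not separated)
    if separated:
        model.message = ("separation suspected: parameter magnitude exceeds "
                         f"{SEPARATION_BOUND} on the logit scale")
    else:
        model.message = res.message
    return model


def predict_updated(model: UpdatedModel, lp: Sequence[float], proximal: float,
                    two_plus: float) -> GeneProbabilities:
    """Gene probabilities for one patient under the updated four-gene model."""
    if tuple(model.genes) != GENES:
        raise ValidationError("predict_updated needs the four-gene model")
    data = UpdateDataset(lp=np.asarray(lp, dtype=float)[None, :],
                         proximal=np.array([proximal]),
                         two_plus=np.array([two_plus]),
                         outcome=np.array([0]), genes=GENES)
    logits = _updated_logits(model, data)[0]
    shifted = np.exp(logits - logits.max())
    p = shifted / shifted.sum()
    return GeneProbabilities(p_mlh1=p[1], p_msh2=p[2], p_msh6=p[3],
                             p_pms2=p[4], p_none=p[0]).check(1e-9)


# --- bridging from cohorts and coefficient sets ---------------------------

OUTCOME_CODES = {"none": 0, **{g: i + 1 for i, g in enumerate(GENES)}}


def build_update_dataset(cohort: Cohort, coeffs: CoefficientSet,
                         two_plus_covariate: str = "crc_two_plus") -> UpdateDataset:
    """Compute original linear predictors and indicators for every proband.

    The original model's two-or-more-CRCs term is subtracted from the MSH6
    predictor when the coefficient is present, so the re-estimated delta
    replaces it. Patients with unknown mutation status are rejected: the
    updating likelihood needs observed outcomes.
    """
    if not coeffs.is_multinomial:
        raise ValidationError("updating requires a four-outcome model")
    lp = np.empty((len(cohort), 4))
    prox = np.empty(len(cohort))
    two = np.empty(len(cohort))
    outcome = np.empty(len(cohort), dtype=int)
    msh6_two_coef = coeffs.coefficients.get("MSH6", {}).get(two_plus_covariate, 0.0)
    for i, patient in enumerate(cohort):
        if patient.mutation_status == "unknown":
            raise ValidationError(
                f"patient {patient.id!r} has unknown mutation status; "
                "updating needs observed outcomes")
        vec = encode_covariates(patient, coeffs)
        for g_idx, g in enumerate(GENES):
            lp[i, g_idx] = linear_predictor(vec, coeffs.intercepts[g],
                                            coeffs.coefficients.get(g, {}))
        two[i] = 1.0 if patient.num_crc == "2+" else 0.0
        lp[i, GENES.index("MSH6")] -= msh6_two_coef * two[i]
        prox[i] = 1.0 if patient.any_proximal_crc else 0.0
        outcome[i] = OUTCOME_CODES[patient.mutation_status]
    return UpdateDataset(lp=lp, proximal=prox, two_plus=two, outcome=outcome)


def simulate_outcomes(data: UpdateDataset, truth: UpdatedModel,
                      rng: np.random.Generator) -> UpdateDataset:
    """Redraw outcome labels from the category probabilities under ``truth``.

    Used for parameter-recovery simulations: covariates are kept, outcomes
    are sampled from the model.
    """
    logits = _updated_logits(truth, data)
    shifted = np.exp(logits - logits.max(axis=1, keepdims=True))
    p = shifted / shifted.sum(axis=1, keepdims=True)
    cum = p.cumsum(axis=1)
    u = rng.random((data.n, 1))
    outcome = (u > cum).sum(axis=1)
    return replace(data, outcome=outcome)
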