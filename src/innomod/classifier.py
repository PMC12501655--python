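"""Two-class Gaussian linear discriminant sex classifier.

The DSP-style metric sex estimator: given a reference sample with known
sex, fit per-sex mean vectors and a pooled within-class covariance over a
chosen subset of the eight innominate measurements, then score new
individuals by the posterior probability of being female under the
equal-covariance Gaussian model,

    P(F | x) = 1 / (1 + exp(-s)),
    s = w'x + b,   w = S^-1 (mu_F - mu_M),
    b = -(mu_F + mu_M)' w / 2 + log(prior_F / prior_M).

An individual is assigned a sex only when the winning posterior reaches a
decision threshold (0.85 by default); otherwise it is left indeterminate.
Individuals missing any of the model's traits are excluded from scoring
(strict complete-case evaluation, no imputation).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .io import OsteometricTable, TableValidationError, _check_traits, complete_cases

__all__ = [
    "LdaModel",
    "ClassificationRecord",
    "fit_lda",
    "posterior_female",
    "classify_table",
    "score_classification",
    "ClassificationScore",
]


class InsufficientDataError(ValueError):
    """Fewer than two complete-case individuals in a sex class."""


class RankError(ValueError):
    """Pooled covariance is singular (collinear traits)."""


@dataclass(frozen=True)
class LdaModel:
    """Fitted two-class linear discriminant over a trait subset."""

    traits: tuple[str, ...]
    mean_female: np.ndarray
    mean_male: np.ndarray
    pooled_covariance: np.ndarray
    priors: tuple[float, float] = (0.5, 0.5)  # (female, male)
    n_female: int = 0
    n_male: int = 0

    def __post_init__(self) -> None:
        p_f, p_m = self.priors
        if not (0.0 < p_f < 1.0 and 0.0 < p_m < 1.0
                and abs(p_f + p_m - 1.0) < 1e-12):
            raise TableValidationError("priors must lie in (0,1) and sum to 1")

    def to_json(self) -> str:
        return json.dumps({
            "traits": list(self.traits),
            "mean_female": self.mean_female.tolist(),
            "mean_male": self.mean_male.tolist(),
            "pooled_covariance": self.pooled_covariance.tolist(),
            "priors": list(self.priors),
            "n_female": self.n_female,
            "n_male": self.n_male,
        })

    @classmethod
    def from_json(cls, s: str) -> "LdaModel":
        d = json.loads(s)
        return cls(
            traits=tuple(d["traits"]),
            mean_female=np.asarray(d["mean_female"], dtype=float),
            mean_male=np.asarray(d["mean_male"], dtype=float),
            pooled_covariance=np.asarray(d["pooled_covariance"], dtype=float),
            priors=tuple(d["priors"]),
            n_female=d["n_female"],
            n_male=d["n_male"],
        )


@dataclass(frozen=True)
class ClassificationRecord:
    """Per-individual posterior and threshold-gated assignment."""

    individual_id: str
    posterior_female: float
    assigned: str               # "F", "M" or "indeterminate"
    threshold_used: float


def fit_lda(
    reference: OsteometricTable,
    traits: Iterable[str],
    priors: tuple[float, float] = (0.5, 0.5),
) -> LdaModel:
    """Fit class means and pooled within-class covariance on complete cases.

    The pooled covariance uses the standard unbiased denominator
    ``n_F + n_M - 2``. Records of unknown sex among the complete cases are
    rejected rather than silently dropped: a training table must be fully
    labelled.
    """
    traits = _check_traits(traits)
    cc = complete_cases(reference, traits)
    if (cc.sex == "unknown").any():
        raise TableValidationError(
            "training data contain unknown-sex records among complete cases"
        )
    xf = cc.values(traits)[(cc.sex == "F").to_numpy()]
    xm = cc.values(traits)[(cc.sex == "M").to_numpy()]
    n_f, n_m = len(xf), len(xm)
    if n_f < 2 or n_m < 2:
        raise InsufficientDataError(
            f"need >= 2 complete cases per sex, got F={n_f}, M={n_m}"
        )
    s_f = np.cov(xf, rowvar=False, ddof=1).reshape(len(traits), len(traits))
    s_m = np.cov(xm, rowvar=False, ddof=1).reshape(len(traits), len(traits))
    pooled = ((n_f - 1) * s_f + (n_m - 1) * s_m) / (n_f + n_m - 2)
    # singularity check, with a hint at which traits are collinear
    if np.linalg.matrix_rank(pooled, tol=1e-8 * np.trace(pooled)) < len(traits):
        d = np.sqrt(np.diag(pooled))
        with np.errstate(invalid="ignore", divide="ignore"):
            r = pooled / np.outer(d, d)
        pairs = [
            f"{traits[i]}~{traits[j]}"
            for i in range(len(traits)) for j in range(i + 1, len(traits))
            if abs(r[i, j]) > 1.0 - 1e-8
        ]
        raise RankError(
            "pooled covariance is singular"
            + (f"; collinear traits: {', '.join(pairs)}" if pairs else "")
        )
    return LdaModel(
        traits=tuple(traits),
        mean_female=xf.mean(axis=0),
        mean_male=xm.mean(axis=0),
        pooled_covariance=pooled,
        priors=priors,
        n_female=n_f,
        n_male=n_m,
    )


def _discriminant(model: LdaModel, x: np.ndarray) -> np.ndarray:
    """Linear score s such that P(F|x) = logistic(s); x is (n, M)."""
    w = np.linalg.solve(model.pooled_covariance,
                        model.mean_female - model.mean_male)
    b = (-0.5 * (model.mean_female + model.mean_male) @ w
         + math.log(model.priors[0] / model.priors[1]))
    return x @ w + b


def posterior_female(model: LdaModel, x: Sequence[float]) -> float:
    """Posterior probability of female for one complete measurement vector."""
    x = np.asarray(x, dtype=float)
    if x.shape != (len(model.traits),):
        raise TableValidationError(
            f"expected {len(model.traits)} measurements, got shape {x.shape}"
        )
    if not np.all(np.isfinite(x)):
        raise TableValidationError("measurement vector contains missing values")
    s = float(_discriminant(model, x[None, :])[0])
    # numerically safe logistic
    if s >= 0:
        return 1.0 / (1.0 + math.exp(-s))
    e = math.exp(s)
    return e / (1.0 + e)


def classify_table(
    model: LdaModel, validation: OsteometricTable, threshold: float = 0.85
) -> list[ClassificationRecord]:
    """Score and gate every validation individual complete for the model's traits.

    Individuals missing any model trait are omitted (they may re-enter for a
    different trait subset). Assignment requires the winning class posterior
    to reach *threshold*; with threshold > 0.5 at most one class can win.
    """
    if not 0.5 < threshold < 1.0:
        raise TableValidationError(
            f"threshold must lie in (0.5, 1), got {threshold}"
        )
    cc = complete_cases(validation, model.traits)
    s = _discriminant(model, cc.values(model.traits))
    with np.errstate(over="ignore"):
        post = np.where(s >= 0, 1.0 / (1.0 + np.exp(-np.clip(s, 0, None))),
                        np.exp(np.clip(s, None, 0))
                        / (1.0 + np.exp(np.clip(s, None, 0))))
    records = []
    for pid, p in zip(cc.ids, post):
        if p >= threshold:
            label = "F"
        elif 1.0 - p >= threshold:
            label = "M"
        else:
            label = "indeterminate"
        records.append(ClassificationRecord(pid, float(p), label, threshold))
    return records


@dataclass(frozen=True)
class ClassificationScore:
    accuracy: float             # NaN when nothing was assigned
    pct_assigned: float         # percent
    n_evaluated: int
    n_assigned: int


def score_classification(
    records: Sequence[ClassificationRecord],
    truth: Mapping[str, str],
    n_total: int | None = None,
) -> ClassificationScore:
    """Accuracy among assigned individuals and the assignment rate.

    ``accuracy`` counts correct assignments over assigned individuals only
    (indeterminates excluded from both numerator and denominator) and is
    NaN when nothing was assigned. ``pct_assigned`` defaults to assigned
    over evaluated (complete-case) individuals, in percent; pass
    ``n_total`` to use a fixed denominator (e.g. the whole validation
    table) instead.
    """
    n_eval = len(records)
    n_assigned = 0
    n_correct = 0
    for rec in records:
        t = truth.get(rec.individual_id)
        if t not in ("F", "M"):
            raise TableValidationError(
                f"no truth label for individual {rec.individual_id!r}"
            )
        if rec.assigned in ("F", "M"):
            n_assigned += 1
            if rec.assigned == t:
                n_correct += 1
    denom = n_total if n_total is not None else n_eval
    pct = 100.0 * n_assigned / denom if denom else 0.0
    acc = n_correct / n_assigned if n_assigned else float("nan")
    return ClassificationScore(acc, pct, n_eval, n_assigned)
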