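"""Penalized-regression methylation clocks and group comparison of predictions.

A clock is a sparse linear model on beta values predicting transformed age.
Two output transforms are supported: ``identity`` (years) and
``relative_age`` (age divided by the species' maximum lifespan, so a single
model can serve species with very different lifespans).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from ._stats import welch_t
from .meth_io import MethylationMatrix, SampleSheet, ValidationError

logger = logging.getLogger(__name__)

TRANSFORMS = ("identity", "relative_age")


def relative_age(age: float, max_lifespan: float) -> float:
    """Chronological age divided by the species' maximum lifespan.

    E.g. 122 years for humans and 3.8 years for rats puts both species on a
    common [0, 1]-ish scale.
    """
    if max_lifespan <= 0:
        raise ValueError(f"max_lifespan must be positive, got {max_lifespan}")
    if np.any(np.asarray(age) < 0):
        raise ValueError("age must be non-negative")
    return age / max_lifespan


@dataclass
class ClockModel:
    """Intercept + sparse CpG weights + output transform."""

    intercept: float
    coefficients: dict[str, float]
    transform: str = "identity"
    max_lifespan_years: float | None = None

    def __post_init__(self) -> None:
        if self.transform not in TRANSFORMS:
            raise ValidationError(
                f"unknown transform {self.transform!r}; allowed: {list(TRANSFORMS)}"
            )
        if self.transform == "relative_age":
            if self.max_lifespan_years is None or self.max_lifespan_years <= 0:
                raise ValidationError(
                    "relative_age transform requires a positive max_lifespan_years"
                )

    @property
    def n_terms(self) -> int:
        return len(self.coefficients)


@dataclass
class GroupComparison:
    """Welch comparison of predicted ages between two sample groups."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    df: float
    two_sided_p: float
    one_sided_p: float


def fit_clock(
    matrix: MethylationMatrix,
    ages,
    transform: str = "identity",
    max_lifespan_years: float | None = None,
    lam: float | None = None,
    l1_ratio: float = 0.5,
    seed: int = 0,
    cv_folds: int = 5,
    tol: float = 1e-6,
) -> ClockModel:
    """Fit an elastic-net clock: minimize
    ``(1/2n) * ||y - b0 - Xw||^2 + lam * (l1_ratio*||w||_1 + (1-l1_ratio)/2*||w||^2)``
    with y the (transformed) ages and X the sample-by-CpG beta matrix.

    ``lam=None`` selects the penalty by seeded k-fold cross-validation.
    All-constant CpG columns are dropped (logged). Deterministic given inputs.
    """
    ages = np.asarray(ages, dtype=float)
    if ages.size < 4:
        raise ValueError("need at least 4 samples to fit a clock")
    if not np.all(np.isfinite(ages)):
        raise ValueError("ages must be finite")
    if lam is not None and lam < 0:
        raise ValueError("penalty lam must be non-negative")
    if ages.size != len(matrix.sample_ids):
        raise ValueError("ages length does not match sample count")

    if transform == "relative_age":
        if max_lifespan_years is None or max_lifespan_years <= 0:
            raise ValueError("relative_age transform requires max_lifespan_years > 0")
        y = relative_age(ages, max_lifespan_years)
    elif transform == "identity":
        y = ages
    else:
        raise ValueError(f"unknown transform {transform!r}")

    X = matrix.beta.T  # samples x CpGs
    keep = np.ptp(X, axis=0) > 0
    if not keep.all():
        logger.info("dropped %d all-constant CpG columns", int((~keep).sum()))
    X = X[:, keep]
    cpgs = [c for c, k in zip(matrix.cpg_ids, keep) if k]
    if X.shape[1] == 0:
        raise ValueError("no variable CpG columns to fit on")

    if lam is None:
        folds = KFold(n_splits=min(cv_folds, ages.size), shuffle=True, random_state=seed)
        est = ElasticNetCV(l1_ratio=l1_ratio, cv=folds, alphas=50, max_iter=20000,
                           tol=tol)
        est.fit(X, y)
        lam = float(est.alpha_)
        coef, intercept = est.coef_, float(est.intercept_)
    else:
        est = ElasticNet(alpha=max(lam, 1e-12), l1_ratio=l1_ratio, max_iter=20000,
                         tol=tol)
        est.fit(X, y)
        coef, intercept = est.coef_, float(est.intercept_)

    nz = np.flatnonzero(coef)
    coefficients = {cpgs[j]: float(coef[j]) for j in nz}
    logger.info("fitted clock: lam=%.3g, %d nonzero terms", lam, len(coefficients))
    return ClockModel(intercept=intercept, coefficients=coefficients,
                      transform=transform, max_lifespan_years=max_lifespan_years)


def apply_clock(model: ClockModel, matrix: MethylationMatrix) -> np.ndarray:
    """Predict age in years for every sample of ``matrix``.

    Every model CpG must be present; otherwise an error lists the missing ids.
    """
    index = {c: i for i, c in enumerate(matrix.cpg_ids)}
    missing = [c for c in model.coefficients if c not in index]
    if missing:
        raise KeyError(
            f"{len(missing)} clock CpGs missing from matrix, e.g. {missing[:5]}"
        )
    score = np.full(len(matrix.sample_ids), model.intercept, dtype=float)
    for cpg, w in model.coefficients.items():
        score += w * matrix.beta[index[cpg]]
    if model.transform == "relative_age":
        return np.maximum(score * model.max_lifespan_years, 0.0)
    return score


def compare_groups(
    predictions,
    sample_sheet: SampleSheet,
    contrast: tuple[str, str] = ("old_control", "old_treated"),
) -> GroupComparison:
    """Welch two-sample t-test of predicted age between two groups.

    ``predictions`` maps sample_id -> predicted years (or is an array aligned
    with the sheet's sample order). The one-sided p is for the hypothesis that
    the second contrast group has *lower* DNAm age than the first
    (treated < control by default).
    """
    if not isinstance(predictions, dict):
        predictions = dict(zip(sample_sheet.sample_ids, np.asarray(predictions, float)))
    ga, gb = contrast
    a_ids = sample_sheet.ids_for_group(ga)
    b_ids = sample_sheet.ids_for_group(gb)
    if len(a_ids) < 2 or len(b_ids) < 2:
        raise ValueError("both contrast groups need n >= 2")
    a = np.array([predictions[s] for s in a_ids], dtype=float)
    b = np.array([predictions[s] for s in b_ids], dtype=float)
    t, df, p2 = welch_t(a, b)
    # hypothesized direction: group_b (treated) younger than group_a
    one_sided = p2 / 2.0 if t > 0 else 1.0 - p2 / 2.0
    if t == 0.0:
        one_sided = 0.5
    return GroupComparison(
        group_a=ga, group_b=gb,
        mean_a=float(a.mean()), mean_b=float(b.mean()),
        sem_a=float(a.std(ddof=1) / np.sqrt(a.size)),
        sem_b=float(b.std(ddof=1) / np.sqrt(b.size)),
        n_a=a.size, n_b=b.size,
        t=t, df=df, two_sided_p=p2, one_sided_p=float(one_sided),
    )
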