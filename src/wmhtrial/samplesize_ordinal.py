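"""Sample sizes for two-arm trials with an ordered categorical (Fazekas) outcome.

Whitehead's proportional-odds formula drives the main calculation:

    n per group = ceil[ 6 (z_{1-a/2} + z_{1-b})^2 / ( (log OR)^2 (1 - sum_k pbar_k^3) ) ]

where ``pbar_k`` is the mean of the anticipated control- and treatment-arm
probabilities of category ``k``, the treatment distribution being obtained by
shifting the control cumulative log-odds by ``log OR``.  The module also
provides the inverse (back-solving the distribution term from a published
size), the stratified covariate-adjustment multiplier, OR sensitivity sweeps,
and a tie-corrected Noether formula for Wilcoxon rank-sum designs.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict
from typing import Any, Iterable, Sequence

import numpy as np
from scipy import stats
from scipy.special import expit, logit

from .exceptions import ConfigurationError, DomainError
from .samplesize_continuous import SampleSizeResult, inflate_dropout

__all__ = [
    "CategoryDistribution",
    "OrdinalDesign",
    "StratifiedDistribution",
    "RankDesign",
    "FAZEKAS_BASELINE_PERCENTAGES",
    "fazekas_baseline_distribution",
    "treatment_distribution",
    "whitehead_denominator",
    "whitehead_n_per_group",
    "n_from_denominator",
    "backsolve_denominator",
    "covariate_multiplier",
    "apply_multiplier",
    "rank_superiority_probability",
    "rank_n_per_group",
    "or_sensitivity_sweep",
]

#: Baseline Fazekas (periventricular + deep, 0-6) marginal percentages in the
#: reference mild-stroke cohort; they sum to 100.1 because of rounding and are
#: renormalised on construction.
FAZEKAS_BASELINE_PERCENTAGES = (4.2, 9.0, 36.8, 12.6, 15.3, 9.0, 13.2)


def _z(p: float) -> float:
    return float(stats.norm.ppf(p))


@dataclass(frozen=True)
class CategoryDistribution:
    """Probabilities over ordered outcome categories (lowest burden first)."""

    probs: tuple[float, ...]
    labels: tuple[Any, ...] | None = None

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or p.size < 2:
            raise ConfigurationError("probs must be a 1-D sequence of >= 2 categories")
        if np.any(p < 0):
            raise ConfigurationError("probs must be nonnegative")
        total = p.sum()
        if not math.isclose(total, 1.0, rel_tol=0.05):
            raise ConfigurationError(
                f"probs must sum to ~1 (renormalisable); got sum {total:.4f}"
            )
        if np.count_nonzero(p) < 2:
            raise ConfigurationError("at least two categories need positive mass")
        object.__setattr__(self, "probs", tuple(p / total))
        if self.labels is not None and len(self.labels) != p.size:
            raise ConfigurationError("labels must match the number of categories")

    @classmethod
    def from_percentages(
        cls, percentages: Sequence[float], labels: Sequence[Any] | None = None
    ) -> "CategoryDistribution":
        p = np.asarray(percentages, dtype=float) / 100.0
        return cls(tuple(p / p.sum()), None if labels is None else tuple(labels))

    @property
    def array(self) -> np.ndarray:
        return np.asarray(self.probs)

    @property
    def n_categories(self) -> int:
        return len(self.probs)


def fazekas_baseline_distribution() -> CategoryDistribution:
    """Renormalised baseline Fazekas 0-6 distribution of the reference cohort."""
    return CategoryDistribution.from_percentages(
        FAZEKAS_BASELINE_PERCENTAGES, labels=range(7)
    )


@dataclass(frozen=True)
class OrdinalDesign:
    """A proportional-odds trial design: common OR plus anticipated control distribution."""

    odds_ratio: float
    control_dist: CategoryDistribution
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.odds_ratio <= 0:
            raise ConfigurationError("odds_ratio must be positive")
        if self.odds_ratio == 1:
            raise ConfigurationError("odds_ratio must differ from 1 (null effect gives infinite n)")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ConfigurationError("power must lie in (0, 1)")


@dataclass(frozen=True)
class StratifiedDistribution:
    """Per-stratum outcome distributions with stratum prevalences as weights."""

    weights: tuple[float, ...]
    distributions: tuple[CategoryDistribution, ...]

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if len(self.weights) != len(self.distributions):
            raise ConfigurationError("weights and distributions must have equal length")
        if np.any(w < 0) or not math.isclose(w.sum(), 1.0, rel_tol=1e-6):
            raise ConfigurationError("weights must be nonnegative and sum to 1")


@dataclass(frozen=True)
class RankDesign:
    """A Wilcoxon rank-sum design from two anticipated category distributions."""

    treatment_dist: CategoryDistribution
    control_dist: CategoryDistribution
    alpha: float = 0.05
    power: float = 0.80

    def __post_init__(self) -> None:
        if self.treatment_dist.n_categories != self.control_dist.n_categories:
            raise ConfigurationError("treatment and control need the same categories")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ConfigurationError("power must lie in (0, 1)")


def treatment_distribution(
    control: CategoryDistribution, odds_ratio: float
) -> CategoryDistribution:
    """Shift a control distribution by a common cumulative odds ratio.

    The cumulative log-odds of being at or below each category are shifted by
    ``log(odds_ratio)``; OR > 1 therefore moves mass toward the lower (better)
    categories, the usual direction for a treatment that slows progression.
    """
    if odds_ratio <= 0:
        raise DomainError("odds_ratio must be positive")
    p = control.array
    cum = np.cumsum(p)[:-1]
    cum_t = expit(logit(cum) + math.log(odds_ratio))
    probs = np.diff(np.concatenate([[0.0], cum_t, [1.0]]))
    probs = np.clip(probs, 0.0, None)
    return CategoryDistribution(tuple(probs / probs.sum()), control.labels)


def whitehead_denominator(design: OrdinalDesign) -> float:
    """The distribution term ``1 - sum_k pbar_k^3`` of Whitehead's formula."""
    pc = design.control_dist.array
    pt = treatment_distribution(design.control_dist, design.odds_ratio).array
    pbar = (pc + pt) / 2.0
    denom = 1.0 - float(np.sum(pbar**3))
    if denom <= 0:
        raise ConfigurationError(
            "degenerate category distribution: all mass in one category"
        )
    return denom


def n_from_denominator(
    odds_ratio: float,
    denominator: float,
    alpha: float = 0.05,
    power: float = 0.80,
    *,
    rounding: str = "ceil",
) -> int:
    """Whitehead sample size per group given an explicit distribution term.

    ``rounding='nearest'`` is appropriate when the denominator was back-solved
    from an already-rounded published size, whose ±1 slack ceil would
    otherwise amplify.
    """
    if odds_ratio <= 0 or odds_ratio == 1:
        raise DomainError("odds_ratio must be positive and different from 1")
    if not 0 < denominator <= 1:
        raise DomainError("denominator must lie in (0, 1]")
    value = (
        6.0
        * (_z(1 - alpha / 2) + _z(power)) ** 2
        / (math.log(odds_ratio) ** 2 * denominator)
    )
    if rounding == "ceil":
        n = math.ceil(value - 1e-9)
    elif rounding == "nearest":
        n = round(value)
    else:
        raise ConfigurationError(f"unknown rounding rule {rounding!r}")
    return max(int(n), 2)


def whitehead_n_per_group(design: OrdinalDesign) -> int:
    """Completers per group under Whitehead's proportional-odds formula."""
    return n_from_denominator(
        design.odds_ratio, whitehead_denominator(design), design.alpha, design.power
    )


def backsolve_denominator(
    n_per_group: int, odds_ratio: float, alpha: float = 0.05, power: float = 0.80
) -> float:
    """Invert Whitehead's formula: the distribution term implied by a known size.

    Useful when a published sample size is available but the category
    distribution that produced it is not.
    """
    if n_per_group < 2:
        raise DomainError("n_per_group must be >= 2")
    if odds_ratio <= 0 or odds_ratio == 1:
        raise DomainError("odds_ratio must be positive and different from 1")
    denom = (
        6.0
        * (_z(1 - alpha / 2) + _z(power)) ** 2
        / (n_per_group * math.log(odds_ratio) ** 2)
    )
    if not 0 < denom <= 1:
        raise DomainError(
            f"inputs imply a distribution term of {denom:.4f}, outside (0, 1]"
        )
    return denom


def _one_minus_sum_cubes(dist: CategoryDistribution) -> float:
    return 1.0 - float(np.sum(dist.array ** 3))


def covariate_multiplier(
    strata: StratifiedDistribution, overall: CategoryDistribution
) -> float:
    """Sample-size multiplier for stratifying the analysis on a baseline covariate.

    The ratio of the unstratified Whitehead distribution term to the
    prevalence-weighted average of the within-stratum terms; the adjusted size
    is ``ceil(n_base * multiplier)``.  A stratum concentrated in a single
    category contributes no information and drives the multiplier to infinity.
    """
    stratified = sum(
        w * _one_minus_sum_cubes(d)
        for w, d in zip(strata.weights, strata.distributions)
    )
    if stratified <= 0:
        warnings.warn(
            "a stratum is fully concentrated in one category; multiplier is infinite",
            stacklevel=2,
        )
        return math.inf
    return _one_minus_sum_cubes(overall) / stratified


def apply_multiplier(n_base: int, multiplier: float) -> int:
    """Scale a base per-group size by a covariate multiplier, rounding up."""
    if multiplier < 0:
        raise DomainError("multiplier must be nonnegative")
    if math.isinf(multiplier):
        raise DomainError("multiplier is infinite; the stratified design is degenerate")
    return int(math.ceil(n_base * multiplier - 1e-9))


def rank_superiority_probability(
    treatment: CategoryDistribution, control: CategoryDistribution
) -> float:
    """theta = P(T > C) + 0.5 P(T = C), computed exactly from the two distributions."""
    t = treatment.array
    c = control.array
    joint = np.outer(t, c)  # joint[i, j] = P(T = i, C = j)
    gt = float(np.tril(joint, k=-1).sum())  # i > j
    eq = float(np.trace(joint))
    return gt + 0.5 * eq


def rank_n_per_group(design: RankDesign) -> int:
    """Wilcoxon rank-sum sample size per group (tie-corrected Noether formula).

    Uses ``theta = P(T > C) + 0.5 P(T = C)`` and the combined-sample category
    probabilities ``tbar_k`` for the tie correction:

        n per group = ceil[ (z_{1-a/2} + z_{1-b})^2 (1 - sum_k tbar_k^3)
                            / (6 (theta - 1/2)^2) ]
    """
    theta = rank_superiority_probability(design.treatment_dist, design.control_dist)
    if abs(theta - 0.5) < 1e-12:
        raise ConfigurationError(
            "theta = 1/2: the two distributions imply no location effect"
        )
    tbar = (design.treatment_dist.array + design.control_dist.array) / 2.0
    tie_term = 1.0 - float(np.sum(tbar**3))
    value = (
        (_z(1 - design.alpha / 2) + _z(design.power)) ** 2
        * tie_term
        / (6.0 * (theta - 0.5) ** 2)
    )
    return max(int(math.ceil(value - 1e-9)), 2)


def or_sensitivity_sweep(
    base: OrdinalDesign,
    or_values: Iterable[float],
    *,
    anchor: tuple[int, float] | None = None,
    dropout_per_year: float = 0.20,
    years: float = 1.0,
) -> list[SampleSizeResult]:
    """Sample sizes over a grid of odds ratios with a fixed distribution term.

    By default the term comes from ``base.control_dist``.  With
    ``anchor=(n_published, or_published)`` it is back-solved from a published
    size instead, and sizes are rounded to nearest (the anchor's own rounding
    slack makes ceil overshoot by 1 near integer boundaries).
    """
    if anchor is not None:
        denom = backsolve_denominator(anchor[0], anchor[1], base.alpha, base.power)
        rounding = "nearest"
    else:
        denom = whitehead_denominator(base)
        rounding = "ceil"
    results: list[SampleSizeResult] = []
    for odds_ratio in or_values:
        n = n_from_denominator(odds_ratio, denom, base.alpha, base.power, rounding=rounding)
        per, total = inflate_dropout(n, dropout_per_year, years)
        results.append(
            SampleSizeResult(
                n_per_group=n,
                n_total=2 * n,
                n_recruit_per_group=per,
                n_recruit_total=total,
                inputs={
                    "odds_ratio": odds_ratio,
                    "denominator": denom,
                    "alpha": base.alpha,
                    "power": base.power,
                    "anchor": anchor,
                    "dropout_per_year": dropout_per_year,
                    "years": years,
                },
            )
        )
    return results
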