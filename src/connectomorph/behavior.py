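"""Morphospace mapping and demographic/behavioral association analyses.

Each network is a point (F_c, 1 - F_e) in the trade-off morphospace; the
slope (1 - F_e) / F_c summarizes its relative trade-off between wiring cost
and communication efficiency.  Age trajectories are modeled with quadratic
least squares (an inverted-U corresponds to a negative quadratic
coefficient), sex contrasts are tested on age-residualized indices, and
behavioral correlations are Pearson.  All significance is by permutation:
the observed statistic is compared against a shuffled-label null
distribution, one-sided by default (p = (1 + #{null >= observed}) /
(1 + n_permutations)), with a two-sided absolute-value mode available.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .network import BinaryNetwork, RegionGeometry
from .objectives import TradeoffModelSpec, evaluate_network

__all__ = [
    "MorphospacePoint",
    "AssociationResult",
    "map_to_morphospace",
    "quadratic_age_fit",
    "gender_difference_age_controlled",
    "pearson_association",
    "permutation_test",
]


@dataclass(frozen=True)
class MorphospacePoint:
    f_c: float
    efficiency_index: float
    slope: float | None  # (1 - F_e) / F_c; undefined (None) when F_c = 0


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_perm: float
    n_permutations: int
    sidedness: str
    null_mean: float
    null_sd: float


def map_to_morphospace(
    nets: Sequence[BinaryNetwork],
    geom: RegionGeometry,
    spec: TradeoffModelSpec,
) -> list[MorphospacePoint]:
    """Morphospace coordinates (F_c, 1 - F_e, slope) of each network."""
    points = []
    for net in nets:
        obj = evaluate_network(net, geom, spec)
        eff = obj.efficiency_index
        slope = eff / obj.f_c if obj.f_c > 0 else None
        points.append(MorphospacePoint(obj.f_c, eff, slope))
    return points


def quadratic_age_fit(
    index_values: np.ndarray, ages: np.ndarray
) -> tuple[float, np.ndarray]:
    """OLS fit of index = b0 + b1*age + b2*age^2.

    Returns (r_squared, [b0, b1, b2]); b2 < 0 indicates an inverted-U
    trajectory.
    """
    y = np.asarray(index_values, dtype=float)
    age = np.asarray(ages, dtype=float)
    if y.size < 4:
        raise ValueError("need at least 4 subjects for a quadratic fit")
    if age.std() == 0:
        raise ValueError("age variance must be positive")
    design = np.column_stack([np.ones_like(age), age, age**2])
    if np.linalg.matrix_rank(design) < 3:
        raise ValueError("degenerate design matrix")
    fit = sm.OLS(y, design).fit()
    return float(fit.rsquared), np.asarray(fit.params)


def permutation_test(
    observed: float,
    null_generator: Callable[[np.random.Generator], float] | np.ndarray,
    n_permutations: int = 10_000,
    sidedness: str = "greater",
    seed: int = 0,
) -> AssociationResult:
    """One- or two-sided permutation p-value with an add-one correction.

    ``null_generator`` is either a callable drawing one null statistic per
    call or a precomputed array of null statistics.  ``sidedness="greater"``
    counts null values >= observed; ``"two-sided"`` compares absolute values.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    if callable(null_generator):
        rng = np.random.default_rng(seed)
        null = np.array([null_generator(rng) for _ in range(n_permutations)])
    else:
        null = np.asarray(null_generator, dtype=float)
        n_permutations = null.size
    if sidedness == "greater":
        exceed = int((null >= observed).sum())
    elif sidedness == "two-sided":
        exceed = int((np.abs(null) >= abs(observed)).sum())
    else:
        raise ValueError("sidedness must be 'greater' or 'two-sided'")
    p = (1 + exceed) / (1 + n_permutations)
    return AssociationResult(
        statistic=float(observed),
        p_perm=float(p),
        n_permutations=n_permutations,
        sidedness=sidedness,
        null_mean=float(null.mean()),
        null_sd=float(null.std()),
    )


def _permutation_matrix(rng, n_perm: int, n: int) -> np.ndarray:
    return np.argsort(rng.random((n_perm, n)), axis=1)


def pearson_association(
    index_values: np.ndarray,
    scores: np.ndarray,
    n_permutations: int = 10_000,
    sidedness: str = "greater",
    seed: int = 0,
) -> AssociationResult:
    """Pearson r between a morphospace index and a behavioral score.

    Significance by shuffling the score vector; the null correlations are
    computed vectorized over all permutations.
    """
    x = np.asarray(index_values, dtype=float)
    y = np.asarray(scores, dtype=float)
    if x.size < 3:
        raise ValueError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined: zero variance")
    r = float(stats.pearsonr(x, y)[0])
    rng = np.random.default_rng(seed)
    xc = (x - x.mean()) / (x.std() * x.size)
    yc = y - y.mean()
    null = np.empty(n_permutations)
    chunk = max(1, 10_000_000 // max(x.size, 1))
    for start in range(0, n_permutations, chunk):
        stop = min(start + chunk, n_permutations)
        perms = _permutation_matrix(rng, stop - start, x.size)
        null[start:stop] = (yc[perms] @ xc) / y.std()
    return permutation_test(r, null, sidedness=sidedness)


def _residualize_on_age(y: np.ndarray, age: np.ndarray, quadratic: bool) -> np.ndarray:
    cols = [np.ones_like(age), age]
    if quadratic:
        cols.append(age**2)
    design = np.column_stack(cols)
    beta, *_ = np.linalg.lstsq(design, y, rcond=None)
    return y - design @ beta


def gender_difference_age_controlled(
    index_values: np.ndarray,
    ages: np.ndarray,
    sexes: Sequence[str],
    n_permutations: int = 10_000,
    sidedness: str = "greater",
    quadratic_age: bool = True,
    seed: int = 0,
) -> AssociationResult:
    """Male - female difference of age-residualized index means.

    The index is residualized on age (and age^2 by default, matching the
    quadratic trajectories); significance by permuting sex labels.
    """
    y = np.asarray(index_values, dtype=float)
    age = np.asarray(ages, dtype=float)
    male = np.asarray(pd.Series(sexes).str.lower() == "male")
    n_male = int(male.sum())
    if n_male == 0 or n_male == male.size:
        raise ValueError("both sexes must be represented")
    res = _residualize_on_age(y, age, quadratic_age)
    observed = float(res[male].mean() - res[~male].mean())
    rng = np.random.default_rng(seed)
    null = np.empty(n_permutations)
    chunk = max(1, 10_000_000 // max(y.size, 1))
    n_female = male.size - n_male
    for start in range(0, n_permutations, chunk):
        stop = min(start + chunk, n_permutations)
        perms = _permutation_matrix(rng, stop - start, y.size)
        shuffled_male = perms[:, :n_male]
        male_means = res[shuffled_male].mean(axis=1)
        total = res.sum()
        female_means = (total - res[shuffled_male].sum(axis=1)) / n_female
        null[start:stop] = male_means - female_means
    return permutation_test(observed, null, sidedness=sidedness)
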