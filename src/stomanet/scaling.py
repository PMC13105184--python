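"""The square-root MST scaling law and its fit statistics.

For a stationary random (Poisson) pattern of N points in a window of area
A, the expected Euclidean MST length follows

    L = beta * sqrt(N * A)

with a dimensionless constant beta whose asymptotic (large-N) value under
complete spatial randomness is empirically placed between 0.63 and 0.64.
Clustering shortens the tree (beta below the random range); spatial
inhibition (over-dispersion) lengthens it (beta above). At finite N the
CSR value of ``L / sqrt(N * A)`` sits above the asymptotic constant —
boundary edges decay like N^(-1/2) — which is why sample classification
uses Monte-Carlo envelopes matched to each sample's N and A rather than
the asymptotic band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats


class UndefinedStatisticError(ValueError):
    """Statistic undefined for the given inputs (e.g. beta_hat with n < 2)."""


@dataclass(frozen=True)
class BetaEstimate:
    """Per-sample normalised MST length beta_hat = L / sqrt(n * A)."""

    beta_hat: float
    n: int
    area: float
    mst_length: float


@dataclass(frozen=True)
class StudyBeta:
    """Study-level mean beta with a 95% confidence interval."""

    mean_beta: float
    ci_low: float
    ci_high: float
    n_samples: int
    method: str


@dataclass(frozen=True)
class FitStatistics:
    """Agreement between observed MST lengths and the scaling-law predictions.

    ``r_squared`` is computed against the 1:1 line of predictions
    ``beta_ref * sqrt(n_i * A_i)`` (not a refitted regression), so it can go
    negative when the model is worse than the mean-only predictor.
    """

    r_squared: float
    pearson_r: float
    pearson_ci_low: float
    pearson_ci_high: float


def expected_mst_length(beta: float, n: int, area: float) -> float:
    """Expected MST length ``beta * sqrt(n * area)`` in mm."""
    if beta <= 0:
        raise ValueError(f"beta must be positive, got {beta}")
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    if n < 0:
        raise ValueError(f"n must be non-negative, got {n}")
    return beta * math.sqrt(n * area)


def beta_hat(mst_length: float, n: int, area: float) -> float:
    """Normalised MST length ``L / sqrt(n * area)``; inverse of the scaling law.

    Undefined for n < 2 (a tree with no edges carries no spatial signal);
    such samples are flagged and excluded from study-level aggregation.
    """
    if area <= 0:
        raise ValueError(f"area must be positive, got {area}")
    if mst_length < 0:
        raise ValueError(f"MST length must be non-negative, got {mst_length}")
    if n < 2:
        raise UndefinedStatisticError(f"beta_hat undefined for n={n} (need n >= 2)")
    return mst_length / math.sqrt(n * area)


def aggregate_beta(
    estimates: Sequence[BetaEstimate] | Iterable[float],
    method: Literal["t", "bootstrap"] = "t",
    n_boot: int = 10_000,
    seed: int | np.random.Generator | None = None,
) -> StudyBeta:
    """Mean per-sample beta_hat with a 95% CI.

    ``method="t"`` uses the Student-t interval on the sample mean;
    ``method="bootstrap"`` the 2.5/97.5 percentiles of ``n_boot`` seeded
    resampled means. With zero spread both intervals collapse onto the mean.
    """
    values = np.array(
        [e.beta_hat if isinstance(e, BetaEstimate) else float(e) for e in estimates]
    )
    k = len(values)
    if k < 2:
        raise ValueError(f"need >= 2 estimates to aggregate, got {k}")
    mean = float(values.mean())
    if method == "t":
        sem = values.std(ddof=1) / math.sqrt(k)
        if sem == 0:
            lo = hi = mean
        else:
            lo, hi = stats.t.interval(0.95, df=k - 1, loc=mean, scale=sem)
        return StudyBeta(mean, float(lo), float(hi), k, "t")
    if method == "bootstrap":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        idx = rng.integers(0, k, size=(n_boot, k))
        means = values[idx].mean(axis=1)
        lo, hi = np.percentile(means, [2.5, 97.5])
        return StudyBeta(mean, float(lo), float(hi), k, "bootstrap")
    raise ValueError(f"unknown CI method {method!r}")


def origin_slope(lengths: Sequence[float], ns: Sequence[int], areas: Sequence[float]) -> float:
    """Least-squares slope of L on sqrt(n*A) through the origin.

    Alternative study-level beta estimator (the fitted-line reading of an
    observed-vs-predicted plot); exported alongside the mean-of-ratios
    estimate for comparison.
    """
    x = np.sqrt(np.asarray(ns, dtype=float) * np.asarray(areas, dtype=float))
    y = np.asarray(lengths, dtype=float)
    denom = float(x @ x)
    if denom == 0:
        raise ValueError("all sqrt(n*A) values are zero")
    return float(x @ y / denom)


def pearson_with_ci(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Pearson correlation with a 95% CI via the Fisher z-transform."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    if len(x) < 4:
        raise ValueError(f"need >= 4 observations, got {len(x)}")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined: zero variance")
    res = stats.pearsonr(x, y)
    ci = res.confidence_interval(0.95)
    return float(res.statistic), float(ci.low), float(ci.high)


def fit_predicted_vs_observed(
    samples: Sequence[tuple[float, int, float]], beta_ref: float
) -> FitStatistics:
    """Observed-vs-predicted fit of the scaling law at a reference beta.

    ``samples`` are (mst_length_mm, n, area_mm2) triples. R^2 is measured
    against the prediction line p_i = beta_ref*sqrt(n_i*A_i) itself;
    the Pearson correlation (with Fisher-z CI) is between observed and
    predicted lengths.
    """
    if beta_ref <= 0:
        raise ValueError(f"beta_ref must be positive, got {beta_ref}")
    if len(samples) < 3:
        raise ValueError(f"need >= 3 samples, got {len(samples)}")
    obs = np.array([s[0] for s in samples], dtype=float)
    pred = np.array([expected_mst_length(beta_ref, s[1], s[2]) for s in samples])
    ss_tot = float(((obs - obs.mean()) ** 2).sum())
    if ss_tot == 0:
        raise UndefinedStatisticError("R^2 undefined: observed lengths have zero variance")
    r_squared = 1.0 - float(((obs - pred) ** 2).sum()) / ss_tot
    r, lo, hi = pearson_with_ci(pred, obs)
    return FitStatistics(r_squared, r, lo, hi)
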