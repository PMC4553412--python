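"""Covariate-adjusted permutation inference and partial correlation.

Group differences in network metrics are tested with nonparametric
permutation tests (default 10,000 permutations) that adjust for
nuisance covariates (age, gender) by the Freedman-Lane scheme: the
metric is first regressed on the covariates alone, the residuals are
permuted and re-attached to the covariate fit, and the group t statistic
is recomputed on each permuted outcome.  Two-tailed p values use the
add-one estimator, so the smallest attainable p is 1/(n_perm + 1).

Node-wise maps are corrected with the false-positive rule p < 1/N
(N nodes), and clinical associations are assessed by partial correlation
with the same covariates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "GroupComparison",
    "PartialCorrelationResult",
    "permutation_test",
    "permutation_test_matrix",
    "false_positive_correction",
    "partial_correlation",
]


@dataclass(frozen=True)
class GroupComparison:
    """Result of one covariate-adjusted two-group permutation test."""

    metric: str
    observed_difference: float  # adjusted mean(group A) - mean(group B)
    t_statistic: float
    p_value: float
    n_perm: int
    direction: int  # sign of the adjusted difference
    corrected_significant: bool | None
    seed: int

    def __post_init__(self) -> None:
        if not 0 < self.p_value <= 1:
            raise ValueError("p must lie in (0, 1]")


@dataclass(frozen=True)
class PartialCorrelationResult:
    r: float
    p_value: float
    n: int
    n_covariates: int

    def __post_init__(self) -> None:
        if abs(self.r) > 1 + 1e-12:
            raise ValueError("|r| must be <= 1")


def _residualize(y: np.ndarray, Z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Residuals and fitted values of y (columns) on design Z."""
    beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
    fit = Z @ beta
    return y - fit, fit


def _design(covariates: np.ndarray | None, n: int) -> np.ndarray:
    if covariates is None:
        return np.ones((n, 1))
    Z = np.atleast_2d(np.asarray(covariates, float))
    if Z.shape[0] != n:
        Z = Z.T
    if Z.shape[0] != n:
        raise ValueError("covariates not conformable with the sample")
    return np.column_stack([np.ones(n), Z])


def permutation_test_matrix(
    features: np.ndarray,
    group: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Freedman-Lane permutation test for many features at once.

    Parameters
    ----------
    features:
        ``(n_subjects, n_features)`` metric matrix.
    group:
        Binary indicator (1 = group A / patients).
    covariates:
        Optional ``(n_subjects, k)`` nuisance matrix; an intercept is always
        included.

    Returns ``(t_obs, p, adjusted_diff)`` arrays of length n_features.
    Constant features get p = 1 with a warning.
    """
    Y = np.atleast_2d(np.asarray(features, float))
    if Y.shape[0] != len(group):
        Y = Y.T
    n, m = Y.shape
    g = np.asarray(group, float)
    if len(np.unique(g)) != 2:
        raise ValueError("exactly two groups required")
    g = (g == g.max()).astype(float)
    if g.sum() < 2 or (1 - g).sum() < 2:
        raise ValueError("each group needs at least 2 subjects")
    rng = np.random.default_rng(seed)
    Z = _design(covariates, n)
    # Frisch-Waugh: the group-coefficient t statistic equals the correlation
    # t between covariate-residualized group and outcome.
    gz, _ = _residualize(g[:, None], Z)
    gz = gz[:, 0]
    gz_norm = np.linalg.norm(gz)
    if gz_norm == 0:
        raise ValueError("group indicator is collinear with the covariates")
    ez, fit = _residualize(Y, Z)
    # residual-maker projector, computed once (n is small)
    M = np.eye(n) - Z @ np.linalg.pinv(Z)

    df = n - Z.shape[1] - 1

    def t_stats(ey: np.ndarray) -> np.ndarray:
        # t for the group coefficient when each column of ey is an
        # already covariate-residualized outcome (Frisch-Waugh)
        b = gz @ ey / gz_norm**2
        rss = (ey**2).sum(axis=0) - b**2 * gz_norm**2
        with np.errstate(divide="ignore", invalid="ignore"):
            se = np.sqrt(np.maximum(rss, 0.0) / max(df, 1)) / gz_norm
            return np.where(se > 0, b / se, 0.0)

    t_obs = t_stats(M @ Y)
    count = np.ones(m)
    for _ in range(n_perm):
        perm = rng.permutation(n)
        # Freedman-Lane: permuted outcome is fit + ez[perm]; M annihilates
        # the fitted part, so its residualization is M @ ez[perm]
        count += np.abs(t_stats(M @ ez[perm])) >= np.abs(t_obs)
    p = count / (n_perm + 1)
    const = Y.std(axis=0) == 0
    if const.any():
        warnings.warn(f"{int(const.sum())} constant feature(s); p set to 1")
        p[const] = 1.0
        t_obs[const] = 0.0
    # adjusted group difference: coefficient of the group indicator
    diff = gz @ ez / gz_norm**2
    return t_obs, p, diff


def permutation_test(
    values_a: np.ndarray,
    values_b: np.ndarray,
    covariates: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    metric: str = "metric",
    n_correction: int | None = None,
) -> GroupComparison:
    """Two-group, covariate-adjusted permutation test for one metric.

    ``values_a``/``values_b`` are the metric in groups A and B;
    ``covariates`` stacks group A rows first, then group B.  With
    ``n_correction`` set, the 1/N false-positive rule is applied to the
    resulting p.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    y = np.concatenate([a, b])
    g = np.concatenate([np.ones(len(a)), np.zeros(len(b))])
    t, p, diff = permutation_test_matrix(y[:, None], g, covariates, n_perm, seed)
    corrected = bool(p[0] < 1.0 / n_correction) if n_correction else None
    return GroupComparison(
        metric=metric,
        observed_difference=float(diff[0]),
        t_statistic=float(t[0]),
        p_value=float(p[0]),
        n_perm=n_perm,
        direction=int(np.sign(diff[0])),
        corrected_significant=corrected,
        seed=seed,
    )


def false_positive_correction(p_values: np.ndarray, n_nodes: int) -> np.ndarray:
    """Significance mask under the expected-false-positives rule p < 1/N."""
    if n_nodes < 1:
        raise ValueError("n_nodes must be >= 1")
    p = np.asarray(p_values, float)
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p values must lie in (0, 1]")
    return p < 1.0 / n_nodes


def partial_correlation(
    x: np.ndarray,
    y: np.ndarray,
    covariates: np.ndarray | None = None,
) -> PartialCorrelationResult:
    """Pearson correlation of x and y after removing covariates from both.

    p comes from the t distribution with n - k - 2 degrees of freedom
    (k covariates).  With no covariates this reduces to the plain Pearson
    correlation test.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    Z = _design(covariates, n)
    k = Z.shape[1] - 1
    if n < k + 4:
        raise ValueError(f"need n >= k + 4 (n={n}, k={k})")
    rx, _ = _residualize(x[:, None], Z)
    ry, _ = _residualize(y[:, None], Z)
    rx, ry = rx[:, 0], ry[:, 0]
    # a variable fully explained by the covariates has no residual variance:
    # its partial correlation is 0 by convention (guard against float noise)
    tiny_x = np.linalg.norm(rx) <= 1e-10 * max(np.linalg.norm(x), 1e-300)
    tiny_y = np.linalg.norm(ry) <= 1e-10 * max(np.linalg.norm(y), 1e-300)
    if tiny_x or tiny_y:
        return PartialCorrelationResult(r=0.0, p_value=1.0, n=n, n_covariates=k)
    r = float(rx @ ry / (np.linalg.norm(rx) * np.linalg.norm(ry)))
    r = max(-1.0, min(1.0, r))
    df = n - k - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1 - r**2))
        p = float(2 * stats.t.sf(abs(t), df))
    return PartialCorrelationResult(r=r, p_value=max(p, np.finfo(float).tiny), n=n, n_covariates=k)
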