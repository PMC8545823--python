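"""Information, precision, reliability and posterior-predictive fit checks.

Because the LIM's log-ratio residual variance is constant, the Fisher
information of a test of I items is a diagonal matrix with entries
``I / sigma2`` and the approximate standard error of every trait estimate is
``sqrt(sigma2 / I)`` — independent of where the person or the items sit on
the scale.

Model-data fit is assessed by posterior predictive model checking (PPMC):
replicated datasets are generated from thinned posterior draws and the
observed value of a discrepancy statistic is located within the replicated
distribution.  The discrepancy used here is the sum over persons of profile
differentiation — the range (max minus min) of a person's per-dimension raw
score totals — because differentiating trait profiles is what compositional
items are for.  The exceedance proportion ``pr`` flags misfit outside the
central 95% band.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_model import (
    CompositionMatrix,
    LinkageDesign,
    alr_inverse,
    alr_transform,
    expected_log_ratios,
)
from .sampler import PosteriorSample

__all__ = [
    "PPMCResult",
    "ReliabilityReport",
    "test_information",
    "approx_se",
    "reliability",
    "differentiation",
    "exceedance_pr",
    "ppmc",
]


@dataclass(frozen=True)
class PPMCResult:
    """Posterior predictive check of one discrepancy statistic.

    ``pr`` is the proportion of replicated statistics at least as large as
    the observed one (ties count); values below 0.025 or above 0.975 flag
    misfit.  ``percentile`` locates the observed statistic within the
    replicated distribution.
    """

    observed_stat: float
    replicated_stats: np.ndarray
    pr: float
    percentile: float
    misfit: bool
    T: int
    seed: int


@dataclass(frozen=True)
class ReliabilityReport:
    """Per-dimension trait variance, error variance and reliability.

    ``rho = (var(theta_hat) - error_var) / var(theta_hat)``; a negative
    value (error variance exceeding observed trait variance) is reported as
    is, never clipped.
    """

    table: pd.DataFrame

    @property
    def rho(self) -> np.ndarray:
        return self.table["rho"].to_numpy()


def test_information(sigma2: float, n_items: int) -> np.ndarray:
    """Test information matrix: ``diag(I / sigma2, I / sigma2)``.

    The 2 x 2 block stands for the reference dimension and any other
    dimension; it does not depend on the traits or the utilities.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if n_items < 1:
        raise ValueError("n_items must be at least 1")
    return np.diag([n_items / sigma2, n_items / sigma2])


def approx_se(sigma2: float, n_items: int) -> float:
    """Approximate trait standard error ``sqrt(sigma2 / I)``.

    Constant over persons, dimensions and utilities; halves when the test
    length quadruples.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    if n_items < 1:
        raise ValueError("n_items must be at least 1")
    return float(np.sqrt(sigma2 / n_items))


def reliability(
    theta_hat: np.ndarray,
    error_var: float | np.ndarray,
    dim_names: tuple[str, ...] | None = None,
) -> ReliabilityReport:
    """Reliability per dimension from trait estimates and error variances.

    ``theta_hat`` is persons x D; ``error_var`` is a scalar or one value per
    dimension.  The error variance may come from the Fisher approximation
    (``approx_se(sigma2, I) ** 2``, constant over dimensions) or from the
    mean squared posterior SD of the trait estimates per dimension.
    """
    theta_hat = np.atleast_2d(np.asarray(theta_hat, dtype=float))
    if theta_hat.shape[0] < 2:
        raise ValueError("reliability needs at least two persons")
    D = theta_hat.shape[1]
    err = np.broadcast_to(np.asarray(error_var, dtype=float), (D,)).copy()
    if np.any(err < 0):
        raise ValueError("error_var must be nonnegative")
    var = theta_hat.var(axis=0, ddof=1)
    if np.any(var <= 0):
        raise ValueError("zero trait variance; reliability undefined")
    rho = (var - err) / var
    names = dim_names or tuple(str(d + 1) for d in range(D))
    table = pd.DataFrame({"dimension": names, "var": var, "error_var": err, "rho": rho})
    return ReliabilityReport(table)


def differentiation(person_scores: np.ndarray) -> float:
    """Profile differentiation of one person: range of dimension totals.

    ``person_scores`` is the person's I x D matrix of raw scores; the column
    sums over items are taken and the max minus min of the D totals is
    returned.  Invariant to permuting items; scales linearly with the
    scores.
    """
    scores = np.atleast_2d(np.asarray(person_scores, dtype=float))
    totals = scores.sum(axis=0)
    return float(totals.max() - totals.min())


def _profile_differentiation_sum(scores: np.ndarray) -> float:
    """Sum over persons of profile differentiation, on an (N, I, D) array."""
    totals = scores.sum(axis=1)  # (N, D)
    return float((totals.max(axis=1) - totals.min(axis=1)).sum())


def exceedance_pr(replicated: np.ndarray, observed: float) -> float:
    """Proportion of replicated statistics >= the observed one (ties count)."""
    replicated = np.asarray(replicated, dtype=float)
    return float(np.count_nonzero(replicated >= observed) / replicated.size)


def ppmc(
    sample: PosteriorSample,
    observed: CompositionMatrix,
    design: LinkageDesign,
    T: int = 1000,
    seed: int = 0,
) -> PPMCResult:
    """Posterior predictive check with the profile-differentiation sum.

    For each of ``T`` posterior draws (evenly spaced across chains), a
    replicated dataset is generated from the LIM at that draw — noise on the
    log-ratio scale, mapped back to raw scores with the inverse ALR — and
    the discrepancy is computed on raw scores for replicates and observed
    data alike.
    """
    if sample.model != "lim":
        raise ValueError("PPMC replication is defined for LIM fits")
    if T < 100:
        warnings.warn(f"T={T} replicated datasets make pr unstable; use at least 100", stacklevel=2)
    theta = sample.draws["theta"]    # (chains, n_theta, N, D)
    delta = sample.draws["delta"]
    sigma2 = sample.draws["sigma2"]
    n_chains, n_theta = theta.shape[:2]
    ratio = sample.draws["delta"].shape[1] // n_theta  # stored-draw thinning of theta
    if T > n_chains * n_theta:
        raise ValueError(f"T={T} exceeds the {n_chains * n_theta} stored trait draws")
    # check conformity once via the forward transform
    alr_transform(observed, design)
    obs_stat = _profile_differentiation_sum(observed.scores)

    picks = np.linspace(0, n_chains * n_theta - 1, T).round().astype(int)
    rng = np.random.default_rng(seed)
    rep_stats = np.empty(T)
    for j, flat in enumerate(picks):
        chain, idx = divmod(int(flat), n_theta)
        mean = expected_log_ratios(theta[chain, idx], delta[chain, idx * ratio], design)
        y_rep = mean + np.sqrt(sigma2[chain, idx * ratio]) * rng.standard_normal(mean.shape)
        x_rep = alr_inverse(y_rep, observed.total, design.reference_dim)
        rep_stats[j] = _profile_differentiation_sum(x_rep.scores)

    pr = exceedance_pr(rep_stats, obs_stat)
    percentile = float(100.0 * np.count_nonzero(rep_stats < obs_stat) / T)
    return PPMCResult(
        observed_stat=obs_stat,
        replicated_stats=rep_stats,
        pr=pr,
        percentile=percentile,
        misfit=bool(pr < 0.025 or pr > 0.975),
        T=T,
        seed=seed,
    )
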