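"""Deterministic mathematics of the lognormal ipsative model (LIM).

A compositional forced-choice item asks a respondent to split a fixed total
``C`` (e.g. 100 points) across ``D`` statements, one per latent dimension.
The additive log-ratio (ALR) transform maps each D-part composition to D-1
log ratios against a reference part; the LIM then decomposes each log ratio
into a person-trait contrast plus a statement-utility contrast plus Gaussian
noise:

    Y_kD = (theta_k + delta_k) - (theta_D + delta_D) + eps_kD,
    eps_kD ~ N(0, sigma2)

with theta sum-zero within person (the ipsative constraint) and the
statement utilities sum-zero over each dimension's item slots.  The
Thurstonian comparator (TMC) generalizes this with a slope (discrimination)
per statement and a free location per (item, non-reference slot) pair.

This module holds the domain containers and the pure functions: the ALR
transform and its inverse, expected log ratios for both models, and the
LIM log-likelihood.  Everything random (estimation, simulation) lives in
:mod:`limcomp.sampler` and :mod:`limcomp.simulator`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "LinkageDesign",
    "CompositionMatrix",
    "LogRatioArray",
    "LIMParams",
    "TMCParams",
    "alr_transform",
    "alr_inverse",
    "expected_log_ratio",
    "expected_log_ratios",
    "tmc_expected_log_ratio",
    "tmc_expected_log_ratios",
    "lim_log_likelihood",
]

_SUM_RTOL = 1e-9


@dataclass(frozen=True)
class LinkageDesign:
    """Assignment of statements to item slots and of statements to dimensions.

    Parameters
    ----------
    item_ids
        Opaque item identifiers, length I.
    dim_names
        Dimension names, length D (column order of the design file).
    slots
        Integer array (I, D); ``slots[i, d]`` is the index (into
        ``statement_ids``) of the statement occupying dimension ``d``'s slot
        in item ``i``.
    statement_ids
        Opaque statement identifiers, length S.
    statement_dim
        Integer array (S,); dimension index of each statement.
    reference_dim
        Dimension used as the ALR reference.  The reference statement of an
        item is "arbitrarily selected" in principle; we fix it to the last
        dimension by default and document that the independence assumption
        of the likelihood makes it not invariant to this choice.
    """

    item_ids: tuple[str, ...]
    dim_names: tuple[str, ...]
    slots: np.ndarray
    statement_ids: tuple[str, ...]
    statement_dim: np.ndarray
    reference_dim: int = -1

    def __post_init__(self) -> None:
        slots = np.asarray(self.slots, dtype=np.intp)
        sdim = np.asarray(self.statement_dim, dtype=np.intp)
        object.__setattr__(self, "slots", slots)
        object.__setattr__(self, "statement_dim", sdim)
        I, D = slots.shape
        if I != len(self.item_ids):
            raise ValueError("slots row count does not match item_ids")
        if D != len(self.dim_names):
            raise ValueError("slots column count does not match dim_names")
        if D < 2:
            raise ValueError("a linkage design needs at least two dimensions")
        if sdim.shape != (len(self.statement_ids),):
            raise ValueError("statement_dim length does not match statement_ids")
        if sdim.min(initial=0) < 0 or (len(sdim) and sdim.max() >= D):
            raise ValueError("statement_dim contains an out-of-range dimension")
        if slots.min() < 0 or slots.max() >= len(self.statement_ids):
            raise ValueError("slots reference an unknown statement")
        # every item covers each dimension exactly once, in column order
        if not np.array_equal(sdim[slots], np.broadcast_to(np.arange(D), (I, D))):
            raise ValueError(
                "each item must have exactly one slot per dimension, in "
                "dimension order"
            )
        ref = self.reference_dim
        if ref < 0:
            ref += D
        if not 0 <= ref < D:
            raise ValueError(f"reference_dim {self.reference_dim} outside 1..{D}")
        object.__setattr__(self, "reference_dim", ref)

    # ---- convenience views -------------------------------------------------
    @property
    def n_items(self) -> int:
        return self.slots.shape[0]

    @property
    def n_dims(self) -> int:
        return self.slots.shape[1]

    @property
    def n_statements(self) -> int:
        return len(self.statement_ids)

    @property
    def free_dims(self) -> np.ndarray:
        """Non-reference dimensions, ascending — the ALR column order."""
        return np.delete(np.arange(self.n_dims), self.reference_dim)

    @property
    def ref_slots(self) -> np.ndarray:
        """Statement index of the reference slot per item, shape (I,)."""
        return self.slots[:, self.reference_dim]

    @property
    def nonref_slots(self) -> np.ndarray:
        """Statement indices of non-reference slots per item, shape (I, D-1)."""
        return self.slots[:, self.free_dims]

    def occurrence_counts(self) -> np.ndarray:
        """Number of item slots occupied by each statement, shape (S,)."""
        return np.bincount(self.slots.ravel(), minlength=self.n_statements)

    def item_index(self, item) -> int:
        if isinstance(item, (int, np.integer)):
            if not 0 <= int(item) < self.n_items:
                raise KeyError(f"item index {item} outside 0..{self.n_items - 1}")
            return int(item)
        try:
            return self.item_ids.index(str(item))
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None


@dataclass(frozen=True)
class CompositionMatrix:
    """Raw compositional responses: persons x items x D nonnegative scores.

    Each (person, item) row sums to the constant ``total`` (C).  Strict
    positivity is only required once zeros have been imputed; the ALR
    transform enforces it.
    """

    scores: np.ndarray
    total: float
    person_ids: tuple[str, ...] = ()
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        if scores.ndim != 3:
            raise ValueError("scores must be a persons x items x D array")
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "total", float(self.total))
        if self.total <= 0:
            raise ValueError("total C must be positive")
        if not self.person_ids:
            object.__setattr__(
                self, "person_ids", tuple(str(n + 1) for n in range(scores.shape[0]))
            )
        if not self.item_ids:
            object.__setattr__(
                self, "item_ids", tuple(str(i + 1) for i in range(scores.shape[1]))
            )
        if len(self.person_ids) != scores.shape[0]:
            raise ValueError("person_ids length does not match scores")
        if len(self.item_ids) != scores.shape[1]:
            raise ValueError("item_ids length does not match scores")
        if np.any(scores < 0):
            raise ValueError("scores must be nonnegative")
        sums = scores.sum(axis=2)
        if not np.allclose(sums, self.total, rtol=0, atol=_SUM_RTOL * self.total):
            bad = np.argwhere(~np.isclose(sums, self.total, rtol=0, atol=_SUM_RTOL * self.total))
            n, i = bad[0]
            raise ValueError(
                f"scores for person {self.person_ids[n]!r}, item "
                f"{self.item_ids[i]!r} sum to {sums[n, i]!r}, expected {self.total}"
            )

    @property
    def n_persons(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    @property
    def n_dims(self) -> int:
        return self.scores.shape[2]


@dataclass(frozen=True)
class LogRatioArray:
    """ALR-transformed responses: persons x items x (D-1) finite reals.

    Column ``k`` holds ``log(X_d / X_ref)`` for the k-th non-reference
    dimension ``d`` in ascending dimension order.
    """

    values: np.ndarray
    reference_dim: int
    person_ids: tuple[str, ...] = ()
    item_ids: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("values must be a persons x items x (D-1) array")
        if not np.all(np.isfinite(values)):
            raise ValueError("log ratios must be finite")
        object.__setattr__(self, "values", values)
        if not self.person_ids:
            object.__setattr__(
                self, "person_ids", tuple(str(n + 1) for n in range(values.shape[0]))
            )
        if not self.item_ids:
            object.__setattr__(
                self, "item_ids", tuple(str(i + 1) for i in range(values.shape[1]))
            )

    @property
    def n_persons(self) -> int:
        return self.values.shape[0]

    @property
    def n_items(self) -> int:
        return self.values.shape[1]


def _check_sum_zero(x: np.ndarray, axis: int, what: str, atol: float = 1e-9) -> None:
    sums = x.sum(axis=axis)
    if not np.allclose(sums, 0.0, rtol=0, atol=atol):
        raise ValueError(f"{what} must sum to zero (max |sum| = {np.abs(sums).max():g})")


@dataclass(frozen=True)
class LIMParams:
    """LIM parameters: traits, statement utilities, noise, trait population.

    ``theta`` rows are sum-zero (ipsative constraint); for each dimension the
    utilities summed over that dimension's item slots (one term per slot, so
    shared statements count once per occurrence) are zero.  ``mu`` and
    ``cov`` describe the population of the D-1 free trait coordinates.
    """

    theta: np.ndarray
    delta: np.ndarray
    sigma2: float
    mu: np.ndarray | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        theta = np.atleast_2d(np.asarray(self.theta, dtype=float))
        delta = np.asarray(self.delta, dtype=float)
        object.__setattr__(self, "theta", theta)
        object.__setattr__(self, "delta", delta)
        object.__setattr__(self, "sigma2", float(self.sigma2))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        _check_sum_zero(theta, 1, "each person's traits")
        if self.cov is not None:
            cov = np.asarray(self.cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError("cov must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("cov must be positive definite")
            object.__setattr__(self, "cov", cov)
        if self.mu is not None:
            object.__setattr__(self, "mu", np.asarray(self.mu, dtype=float))

    def validate_against(
        self, design: LinkageDesign, check_constraint: bool = True, atol: float = 1e-9
    ) -> None:
        """Check shapes and (optionally) the per-dimension slot-sum-zero
        delta identification constraint.

        The constraint pins the estimation gauge; the likelihood itself is
        well defined for any utilities, so callers evaluating densities may
        skip it.
        """
        if self.theta.shape[1] != design.n_dims:
            raise ValueError("theta column count does not match design dimensions")
        if self.delta.shape != (design.n_statements,):
            raise ValueError("delta length does not match design statements")
        if check_constraint:
            slot_sums = self.delta[design.slots].sum(axis=0)  # (D,)
            if not np.allclose(slot_sums, 0.0, rtol=0, atol=atol):
                raise ValueError(
                    "delta must have zero slot-sum within each dimension "
                    f"(max |sum| = {np.abs(slot_sums).max():g})"
                )


@dataclass(frozen=True)
class TMCParams:
    """Thurstonian comparator parameters.

    ``pair_location`` is the utility of each non-reference statement relative
    to its item's reference statement (one free location per item x
    non-reference slot); ``slope`` is the per-statement discrimination.
    ``theta`` is unconstrained unless the ipsative special case is imposed.
    """

    pair_location: np.ndarray
    slope: np.ndarray
    theta: np.ndarray
    sigma2: float
    mu: np.ndarray | None = None
    cov: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "pair_location", np.atleast_2d(np.asarray(self.pair_location, dtype=float)))
        object.__setattr__(self, "slope", np.asarray(self.slope, dtype=float))
        object.__setattr__(self, "theta", np.atleast_2d(np.asarray(self.theta, dtype=float)))
        object.__setattr__(self, "sigma2", float(self.sigma2))
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be positive")
        if self.cov is not None:
            cov = np.asarray(self.cov, dtype=float)
            if not np.allclose(cov, cov.T):
                raise ValueError("cov must be symmetric")
            if np.linalg.eigvalsh(cov).min() <= 0:
                raise ValueError("cov must be positive definite")
            object.__setattr__(self, "cov", cov)


# ---------------------------------------------------------------------------
# ALR transform and inverse
# ---------------------------------------------------------------------------

def alr_transform(X: CompositionMatrix, design: LinkageDesign) -> LogRatioArray:
    """Additive log-ratio transform of a composition matrix.

    ``Y[n, i, k] = ln X[n, i, d_k] - ln X[n, i, ref]`` for the non-reference
    dimensions ``d_k`` in ascending order.  Requires strictly positive
    scores; zeros must be repaired first (see
    :func:`limcomp.preprocessing.impute_zeros`).
    """
    scores = X.scores
    if scores.shape[2] != design.n_dims:
        raise ValueError("composition D does not match design dimensions")
    if np.any(scores <= 0):
        n, i, _ = np.argwhere(scores <= 0)[0]
        raise ValueError(
            f"unimputed zero/negative response for person {X.person_ids[n]!r}, "
            f"item {X.item_ids[i]!r}; impute zeros before the ALR transform"
        )
    log_scores = np.log(scores)
    ref = design.reference_dim
    values = log_scores[:, :, design.free_dims] - log_scores[:, :, ref : ref + 1]
    return LogRatioArray(values, ref, X.person_ids, X.item_ids)


def alr_inverse(Y: LogRatioArray | np.ndarray, total: float, reference_dim: int = -1) -> CompositionMatrix:
    """Map log ratios back to compositions summing to ``total``.

    The reference part is ``C / (1 + sum_k exp(Y_k))`` and part ``k`` is the
    reference times ``exp(Y_k)``; this is the exact inverse of
    :func:`alr_transform`.
    """
    if isinstance(Y, LogRatioArray):
        values = Y.values
        ref = Y.reference_dim
        person_ids, item_ids = Y.person_ids, Y.item_ids
    else:
        values = np.asarray(Y, dtype=float)
        ref = reference_dim
        person_ids = item_ids = ()
    if not np.all(np.isfinite(values)):
        raise ValueError("log ratios must be finite")
    N, I, K = values.shape
    D = K + 1
    if ref < 0:
        ref += D
    # compute in a numerically safe way: shift by the row max before exp
    padded = np.concatenate([values, np.zeros((N, I, 1))], axis=2)  # ref ratio = 0
    m = padded.max(axis=2, keepdims=True)
    expv = np.exp(padded - m)
    shares = expv / expv.sum(axis=2, keepdims=True)
    scores = np.empty((N, I, D))
    free = np.delete(np.arange(D), ref)
    scores[:, :, free] = shares[:, :, :K]
    scores[:, :, ref] = shares[:, :, K]
    scores *= total
    return CompositionMatrix(scores, total, person_ids, item_ids)


# ---------------------------------------------------------------------------
# Expected log ratios and likelihood
# ---------------------------------------------------------------------------

def _pairwise_delta(delta: np.ndarray, design: LinkageDesign) -> np.ndarray:
    """Per-item utility contrasts d[i, k] = delta_slot(k) - delta_slot(ref)."""
    return delta[design.nonref_slots] - delta[design.ref_slots][:, None]


def expected_log_ratios(theta: np.ndarray, delta: np.ndarray, design: LinkageDesign) -> np.ndarray:
    """Noise-free LIM expectations for all persons and items, shape (N, I, D-1)."""
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    contrast = theta[:, design.free_dims] - theta[:, design.reference_dim : design.reference_dim + 1]
    return contrast[:, None, :] + _pairwise_delta(np.asarray(delta, float), design)[None, :, :]


def expected_log_ratio(theta_row: Sequence[float], item, params: LIMParams, design: LinkageDesign) -> np.ndarray:
    """Expected log ratios of one person for one item (deterministic part).

    Component ``k`` is ``(theta_k + delta_slot(k)) - (theta_ref +
    delta_slot(ref))``; the noise term is excluded.
    """
    i = design.item_index(item)
    theta_row = np.asarray(theta_row, dtype=float)
    if theta_row.shape != (design.n_dims,):
        raise ValueError("theta_row length does not match design dimensions")
    _check_sum_zero(theta_row[None, :], 1, "theta_row")
    return expected_log_ratios(theta_row[None, :], params.delta, design)[0, i]


def tmc_expected_log_ratios(
    theta: np.ndarray,
    pair_location: np.ndarray,
    slope: np.ndarray,
    design: LinkageDesign,
) -> np.ndarray:
    """TMC expectations for all persons and items, shape (N, I, D-1).

    ``E[Y_nik] = loc_ik + beta_slot(k) * theta_nk - beta_slot(ref) * theta_nref``.
    """
    theta = np.atleast_2d(np.asarray(theta, dtype=float))
    slope = np.asarray(slope, dtype=float)
    loc = np.atleast_2d(np.asarray(pair_location, dtype=float))
    term_k = slope[design.nonref_slots][None, :, :] * theta[:, None, design.free_dims]
    term_ref = slope[design.ref_slots][None, :] * theta[:, None, design.reference_dim]
    return loc[None, :, :] + term_k - term_ref[:, :, None]


def tmc_expected_log_ratio(theta_row: Sequence[float], item, params: TMCParams, design: LinkageDesign) -> np.ndarray:
    """TMC expected log ratios of one person for one item."""
    i = design.item_index(item)
    theta_row = np.asarray(theta_row, dtype=float)
    if theta_row.shape != (design.n_dims,):
        raise ValueError("theta_row length does not match design dimensions")
    if params.slope.shape != (design.n_statements,):
        raise ValueError("slope length does not match design statements")
    return tmc_expected_log_ratios(theta_row[None, :], params.pair_location, params.slope, design)[0, i]


def lim_log_likelihood(Y: LogRatioArray | np.ndarray, params: LIMParams, design: LinkageDesign) -> float:
    """LIM log-likelihood of the log-ratio data.

    The D-1 ratios within an item are treated as independent Gaussians with
    common variance ``sigma2``, exactly as the model's likelihood is written;
    the total is the sum over persons, items and ratio components of the
    normal log-density of the residual.
    """
    values = Y.values if isinstance(Y, LogRatioArray) else np.asarray(Y, dtype=float)
    if params.sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    params.validate_against(design, check_constraint=False)
    resid = values - expected_log_ratios(params.theta, params.delta, design)
    n = resid.size
    return float(-0.5 * (n * (np.log(params.sigma2) + np.log(2.0 * np.pi)) + (resid**2).sum() / params.sigma2))
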