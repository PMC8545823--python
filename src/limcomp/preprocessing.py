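"""Screening of raw survey responses and zero repair.

Compositional responses must be strictly positive before the additive
log-ratio transform is defined (``log 0`` is not).  Zeros are repaired by
multiplicative replacement: each zero becomes a small constant ``kappa`` and
the nonzero entries of the same item row are scaled down so the row still
sums to the fixed total.  Respondents whose answers carry no preference
information (the full total on the same slot in every item) or who answered
implausibly fast are screened out beforehand.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .core_model import CompositionMatrix

__all__ = ["ScreeningConfig", "screen_responses", "impute_zeros"]

#: fraction of zero entries above which multiplicative replacement is
#: considered unreliable and a warning is emitted
ZERO_FRACTION_GUARD = 0.10


@dataclass(frozen=True)
class ScreeningConfig:
    """Screening and imputation settings.

    ``min_response_seconds`` drops respondents who finished faster than the
    threshold (default 300 s) when response times are available.
    ``drop_constant_allocation`` drops respondents who put the full total on
    the same slot position in every item.  ``kappa`` is the zero-replacement
    constant; it must be positive and smaller than the smallest admissible
    nonzero response (0.5 by default for 100-point items answered in whole
    points).
    """

    min_response_seconds: float = 300.0
    drop_constant_allocation: bool = True
    kappa: float = 0.5

    def __post_init__(self) -> None:
        if self.min_response_seconds < 0:
            raise ValueError("min_response_seconds must be nonnegative")
        if self.kappa <= 0:
            raise ValueError("kappa must be positive")


def screen_responses(
    raw: CompositionMatrix,
    cfg: ScreeningConfig | None = None,
    response_seconds: Mapping[str, float] | pd.Series | None = None,
) -> tuple[CompositionMatrix, pd.DataFrame]:
    """Remove nonsense and too-fast respondents.

    Returns the retained responses and an exclusion report with columns
    ``person_id`` and ``reason``.  A respondent is excluded when (a) they
    allocate the full total to the same slot position in *every* item
    (any slot, not only the first — the constant-allocation pattern carries
    no preference information), or (b) their recorded completion time is
    below ``cfg.min_response_seconds``.  An empty result is allowed; it is
    flagged with a warning row in the report.
    """
    cfg = cfg or ScreeningConfig()
    scores = raw.scores
    keep = np.ones(raw.n_persons, dtype=bool)
    records: list[dict[str, str]] = []

    if cfg.drop_constant_allocation and raw.n_items > 0:
        # full total on one fixed slot in every item
        full = scores >= raw.total * (1 - 1e-12)
        constant = (full.all(axis=1)).any(axis=1)
        for n in np.flatnonzero(constant):
            keep[n] = False
            records.append({"person_id": raw.person_ids[n], "reason": "constant allocation"})

    if response_seconds is not None:
        times = pd.Series(dict(response_seconds)) if not isinstance(response_seconds, pd.Series) else response_seconds
        for n, pid in enumerate(raw.person_ids):
            if not keep[n]:
                continue
            t = times.get(pid)
            if t is not None and not pd.isna(t) and float(t) < cfg.min_response_seconds:
                keep[n] = False
                records.append({
                    "person_id": pid,
                    "reason": f"response time {float(t):g} s below {cfg.min_response_seconds:g} s",
                })

    report = pd.DataFrame.from_records(records, columns=["person_id", "reason"])
    kept = CompositionMatrix(
        scores[keep],
        raw.total,
        tuple(pid for n, pid in enumerate(raw.person_ids) if keep[n]),
        raw.item_ids,
    )
    if kept.n_persons == 0:
        warnings.warn("screening removed every respondent", stacklevel=2)
    return kept, report


def impute_zeros(X: CompositionMatrix, kappa: float = 0.5) -> CompositionMatrix:
    """Multiplicative zero replacement preserving the fixed row total.

    In each item row with ``m`` zeros, every zero becomes ``kappa`` and each
    nonzero entry is multiplied by ``1 - m * kappa / C``, so the row total is
    exactly preserved and the rank order of the positive entries is
    unchanged.  Rows without zeros are returned untouched.

    ``kappa`` must be positive and smaller than the smallest positive score
    present in the data (a replacement at least as large as a genuine
    response would reorder the composition).
    """
    if kappa <= 0:
        raise ValueError("kappa must be positive")
    scores = X.scores
    zero = scores == 0
    if zero.any():
        positive_min = scores[scores > 0].min()
        if kappa >= positive_min:
            raise ValueError(
                f"kappa={kappa:g} must be smaller than the smallest positive "
                f"response ({positive_min:g})"
            )
        frac = zero.mean()
        if frac > ZERO_FRACTION_GUARD:
            warnings.warn(
                f"{frac:.1%} of entries are zero; multiplicative replacement is "
                f"only recommended below {ZERO_FRACTION_GUARD:.0%}",
                stacklevel=2,
            )
    m = zero.sum(axis=2, keepdims=True)
    out = scores * (1.0 - m * kappa / X.total)
    out[zero] = kappa
    return CompositionMatrix(out, X.total, X.person_ids, X.item_ids)
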