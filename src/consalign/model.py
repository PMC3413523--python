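"""Power-law model relating normalized column scores to column precision.

Observed (score, precision) pairs are binned by score (default width 0.1,
half-open bins, top bin closed so a score of 1.0 is binnable), a power
function f(x) = x^m is least-squares fitted to the bin means against bin
midpoints, and the fitted model predicts the expected false-positive
error rate 1 - f(score) of a column from its score.  Thresholding on the
score yields a column-filtering data-selection step.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Sequence

from scipy.optimize import minimize_scalar

from .errors import DataError
from .io import Alignment
from .merge import ConsensusResult

__all__ = [
    "ScoreBin",
    "PowerModel",
    "DegenerateFitWarning",
    "bin_columns",
    "fit_power",
    "expected_error",
    "filter_columns",
]

_M_LOWER = 1e-6
_M_UPPER = 50.0


class DegenerateFitWarning(UserWarning):
    """The fitted exponent landed on the search boundary."""


@dataclass(frozen=True)
class ScoreBin:
    """One score bin: half-open [lower, upper), top bin closed at 1.0."""

    lower: float
    upper: float
    mean_precision: float | None
    n_columns: int

    @property
    def midpoint(self) -> float:
        return (self.lower + self.upper) / 2


@dataclass(frozen=True)
class PowerModel:
    """Precision model f(x) = x^m on x in (0, 1]."""

    m: float

    def __post_init__(self) -> None:
        if not self.m > 0:
            raise DataError(f"power-model exponent must be positive, got {self.m}")

    def predict(self, score: float) -> float:
        return score ** self.m


def bin_columns(
    observations: Sequence[tuple[float, float]],
    width: float = 0.1,
) -> list[ScoreBin]:
    """Bin (score, precision) observations by score.

    Scores must lie in (0, 1], precisions in [0, 1]; observations with
    undefined precision must be excluded beforehand.  Returns all bins,
    including empty ones (mean_precision None, n_columns 0).
    """
    if not 0 < width <= 1:
        raise DataError(f"bin width must be in (0, 1], got {width}")
    n_bins = max(1, math.ceil(round(1 / width, 9)))
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    for score, precision in observations:
        if not 0 < score <= 1:
            raise DataError(f"score {score} outside (0, 1]")
        if not 0 <= precision <= 1:
            raise DataError(f"precision {precision} outside [0, 1]")
        # small epsilon keeps boundary scores (e.g. 0.3 = 3 * 0.1) in the
        # bin whose lower edge they nominally equal despite float noise
        idx = min(int(score / width + 1e-9), n_bins - 1)
        sums[idx] += precision
        counts[idx] += 1
    bins = []
    for i in range(n_bins):
        lower = i * width
        upper = min((i + 1) * width, 1.0)
        mean = sums[i] / counts[i] if counts[i] else None
        bins.append(ScoreBin(lower, upper, mean, counts[i]))
    return bins


def fit_power(bins: Sequence[ScoreBin]) -> PowerModel:
    """Least-squares fit of f(x) = x^m to non-empty bin means vs midpoints.

    The residual sum over non-empty bins is minimized over
    m in (1e-6, 50] by bounded scalar minimization; deterministic for a
    fixed input.  A boundary solution is reported with a
    :class:`DegenerateFitWarning` rather than an error.
    """
    occupied = [b for b in bins if b.n_columns > 0]
    if len(occupied) < 2:
        raise DataError(
            f"power fit requires at least 2 non-empty bins, got {len(occupied)}"
        )
    mids = [b.midpoint for b in occupied]
    means = [b.mean_precision for b in occupied]

    def residual(m: float) -> float:
        return sum((p - x ** m) ** 2 for x, p in zip(mids, means))

    res = minimize_scalar(
        residual,
        bounds=(_M_LOWER, _M_UPPER),
        method="bounded",
        options={"xatol": 1e-10},
    )
    m = float(res.x)
    if m < 10 * _M_LOWER or m > _M_UPPER - 1e-3:
        warnings.warn(
            f"fitted exponent m={m:.3g} is at the search boundary; "
            "the score-precision relation is degenerate",
            DegenerateFitWarning,
            stacklevel=2,
        )
    return PowerModel(m)


def expected_error(model: PowerModel, score: float) -> float:
    """Expected false-positive alignment error rate, 1 - score^m."""
    if not 0 < score <= 1:
        raise DataError(f"score {score} outside (0, 1]")
    return 1.0 - model.predict(score)


def filter_columns(result: ConsensusResult, min_score: float) -> Alignment:
    """Keep exactly the consensus columns whose normalized score is
    >= min_score, preserving column order.

    All rows are retained even if they become all-gap, so the sequence
    set is stable for downstream use; a zero-column alignment is a valid
    (reported) outcome, not an error.
    """
    if not 0 <= min_score <= 1:
        raise DataError(f"min_score {min_score} outside [0, 1]")
    keep = [
        j
        for j, s in enumerate(result.normalized_scores)
        if s >= min_score
    ]
    return result.alignment.take_columns(keep)
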