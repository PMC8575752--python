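"""The IVUS calcium score (ICS) and its derived quantities.

The ICS of a pullback is the number of calcium-positive A-lines divided
by the total number of A-lines, times 1000, so it lives on a [0, 1000]
scale.  Because the raw score is strongly right-skewed, regression
analyses use its square root (``sqrt_ics``, range [0, sqrt(1000)]).
Cohorts are dichotomized at a fixed cutoff (default 85, the cohort
median): patients with ICS >= cutoff form the "high" group.

Scores are kept real-valued internally; rounding (1 decimal) is applied
only when formatting for display.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np

MAX_SCORE = 1000.0

#: Default dichotomization cutoff (the clinical cohort median).
DEFAULT_CUTOFF = 85.0


@dataclass(frozen=True)
class ICSResult:
    """Calcium score of one pullback.

    Attributes
    ----------
    n_positive : int
        Number of calcium-positive (frame, A-line) cells.
    n_total : int
        Total number of (frame, A-line) cells in the pullback.
    ics : float
        ``n_positive / n_total * 1000``.
    sqrt_ics : float
        ``sqrt(ics)``.
    """

    n_positive: int
    n_total: int
    ics: float
    sqrt_ics: float

    def __str__(self) -> str:  # display rounding only
        return (
            f"ICS {self.ics:.1f} (sqrt {self.sqrt_ics:.1f}; "
            f"{self.n_positive}/{self.n_total} A-lines)"
        )


@dataclass(frozen=True)
class DichotomyRule:
    """Rule assigning scores to the low/high group.

    ``cutoff=None`` means "use the sample median of the scores being
    dichotomized".  Ties go to the high group (the high group is defined
    as ICS >= cutoff).
    """

    cutoff: Optional[float] = DEFAULT_CUTOFF

    def __post_init__(self) -> None:
        if self.cutoff is not None and self.cutoff < 0:
            raise ValueError("cutoff must be >= 0")


def compute_ics(mask) -> ICSResult:
    """Compute the ICS from a boolean (frame, A-line) mask.

    Parameters
    ----------
    mask : AnnotationMask or array-like of bool, shape (n_frames, n_alines)

    Returns
    -------
    ICSResult
    """
    arr = np.asarray(getattr(mask, "mask", mask), dtype=bool)
    if arr.size == 0:
        raise ValueError("cannot score an empty mask")
    n_positive = int(arr.sum())
    n_total = int(arr.size)
    ics = n_positive / n_total * MAX_SCORE
    return ICSResult(n_positive, n_total, ics, math.sqrt(ics))


def sqrt_transform(ics: float) -> float:
    """Square-root transform of an ICS value (must be non-negative)."""
    ics = float(ics)
    if ics < 0:
        raise ValueError("ICS must be non-negative")
    return math.sqrt(ics)


def dichotomize(scores: Sequence[float], rule: DichotomyRule = DichotomyRule()) -> np.ndarray:
    """Assign each score to the ``"low"`` or ``"high"`` group.

    ``high`` iff ``score >= cutoff``; when the rule has no cutoff the
    sample median of ``scores`` is used (midpoint convention on even n).
    """
    arr = np.asarray(scores, dtype=float)
    if arr.size == 0:
        raise ValueError("no scores to dichotomize")
    cutoff = rule.cutoff if rule.cutoff is not None else float(np.median(arr))
    return np.where(arr >= cutoff, "high", "low")
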