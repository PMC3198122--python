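"""Hypothesis-testing primitives for the co-primary endpoints.

The phase III analysis compares the selected tenecteplase dose with rt-PA
on two trichotomized-Rankin endpoints (proportion poor, proportion good)
with a pooled two-proportion z-test carrying a 1/2-continuity correction,
and combines the two terminal p-values with the Holm step-down procedure
at an overall two-tailed level.

The continuity correction subtracts ``(1/n1 + 1/n2)/2`` from the absolute
difference in proportions before standardization; when the correction
exceeds the difference the statistic is clamped at zero (p = 1) rather
than allowed to change sign, so the corrected test is never more
significant than the uncorrected one.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.special import ndtr

__all__ = ["TestResult", "pooled_z_cc", "pooled_z_cc_arrays", "holm_step_down"]


@dataclass(frozen=True)
class TestResult:
    """Two-sided pooled z-test result.

    ``direction`` is the sign of the *uncorrected* difference in
    proportions (arm 1 minus arm 2), or 0 on a tie.  ``degenerate`` flags
    a pooled proportion of exactly 0 or 1 (zero variance), reported as
    z = 0, p = 1.
    """

    z: float
    p_two_sided: float
    direction: int
    degenerate: bool = False


def pooled_z_cc_arrays(
    events1: np.ndarray,
    n1,
    events2: np.ndarray,
    n2,
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized core: returns (z, two-sided p, direction) arrays.

    ``n1``/``n2`` may be scalars or arrays broadcastable with the event
    counts.
    """
    e1 = np.asarray(events1, dtype=np.float64)
    e2 = np.asarray(events2, dtype=np.float64)
    n1 = np.asarray(n1, dtype=np.float64)
    n2 = np.asarray(n2, dtype=np.float64)
    p1 = e1 / n1
    p2 = e2 / n2
    pbar = (e1 + e2) / (n1 + n2)
    inv = 1.0 / n1 + 1.0 / n2
    var = pbar * (1.0 - pbar) * inv
    diff = np.abs(p1 - p2)
    corrected = np.maximum(diff - 0.5 * inv, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(var > 0.0, corrected / np.sqrt(var), 0.0)
    # 2*ndtr(-z) keeps full precision in the far tail; the floor keeps the
    # p-value strictly positive even when the normal tail underflows.
    p = np.where(var > 0.0, np.maximum(2.0 * ndtr(-z), 1e-300), 1.0)
    direction = np.sign(p1 - p2).astype(np.int8)
    return z, p, direction


def pooled_z_cc(events1: int, n1: int, events2: int, n2: int) -> TestResult:
    """Pooled two-proportion z-test with 1/2-continuity correction.

    z = max(0, |p1 - p2| - (1/n1 + 1/n2)/2) / sqrt(pbar (1 - pbar) (1/n1 + 1/n2))

    with ``pbar`` the pooled proportion; the two-sided p-value is
    ``2 (1 - Phi(z))``.
    """
    if n1 < 1 or n2 < 1:
        raise ValueError("sample sizes must be >= 1")
    for e, n in ((events1, n1), (events2, n2)):
        if not 0 <= e <= n:
            raise ValueError(f"event count {e} outside [0, {n}]")
    z, p, direction = pooled_z_cc_arrays(
        np.array(events1), n1, np.array(events2), n2
    )
    pbar = (events1 + events2) / (n1 + n2)
    degenerate = pbar <= 0.0 or pbar >= 1.0
    return TestResult(
        z=float(z),
        p_two_sided=float(p),
        direction=int(direction),
        degenerate=bool(degenerate),
    )


def holm_step_down(
    p_values: Sequence[float], overall_alpha: float = 0.05
) -> frozenset[int]:
    """Holm step-down for the two co-primary hypotheses.

    The smaller p-value is compared with ``overall_alpha / 2``; only if it
    rejects is the larger compared with ``overall_alpha``.  Returns the
    set of rejected hypothesis indices.  Controls the family-wise error
    rate at ``overall_alpha``.
    """
    if len(p_values) != 2:
        raise ValueError("holm_step_down expects exactly two p-values")
    if not 0.0 < overall_alpha < 1.0:
        raise ValueError("overall_alpha must be in (0, 1)")
    for p in p_values:
        if not 0.0 < p <= 1.0:
            raise ValueError(f"p-value {p!r} outside (0, 1]")
    order = sorted(range(2), key=lambda i: p_values[i])
    rejected: set[int] = set()
    if p_values[order[0]] <= overall_alpha / 2.0:
        rejected.add(order[0])
        if p_values[order[1]] <= overall_alpha:
            rejected.add(order[1])
    return frozenset(rejected)
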