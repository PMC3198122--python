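"""Random generation of null distribution schemes and outcome sampling.

The type I error study evaluates the design over an ensemble of *null*
distribution schemes covering the clinically relevant region of the
parameter space.  An ensemble is built with a nested factorial draw:
``n_x`` rapid-response marginals (one independent draw per arm), for each
of those ``n_y`` Rankin marginals (shared by all four arms — the null
constraint), and for each (X, Y) pair ``n_cond`` conditional laws of the
Rankin category given the rapid response (one independent draw per arm),
each satisfying the marginalization identity exactly by construction and
the clinical monotonicity constraint.

Marginal triples are drawn uniformly over the sub-simplex cut out by a
rectangular region on the worst-category and best-category probabilities
(rejection sampling from the flat simplex).  Default regions follow the
trial's clinical anchors: ICH rates of roughly 6% are typical with
lytic therapy, and the pilot-study range of major neurological
improvement was 16%-36%.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from ._rng import as_generator
from .outcomes import (
    ARMS,
    TNK_ARMS,
    ArmLabel,
    CondMatrix,
    DistributionScheme,
    ProbTriple,
    RankinCategory,
    RapidResponse,
)

__all__ = [
    "XRegionSpec",
    "YRegionSpec",
    "RegionInfeasibleError",
    "sample_x_marginals",
    "sample_y_marginal",
    "sample_conditional",
    "build_scheme_ensemble",
    "sample_outcome_pair",
    "sample_outcome_batch",
    "table1_scheme",
]

#: Interval widths below this are treated as degenerate (point) constraints.
_DEGEN = 1e-12


class RegionInfeasibleError(RuntimeError):
    """Raised when rejection sampling cannot find an admissible point."""


def _check_bounds(name: str, b: Tuple[float, float]) -> Tuple[float, float]:
    lo, hi = float(b[0]), float(b[1])
    if not (0.0 <= lo <= hi <= 1.0):
        raise ValueError(f"{name} bounds {b!r} must satisfy 0 <= lo <= hi <= 1")
    return lo, hi


@dataclass(frozen=True)
class XRegionSpec:
    """Admissible rectangle for the rapid-response marginal.

    ``ich`` bounds P[X = ICH], ``mni`` bounds P[X = MNI]; P[NEI] is the
    complement.
    """

    ich: Tuple[float, float] = (0.01, 0.12)
    mni: Tuple[float, float] = (0.05, 0.45)

    def __post_init__(self) -> None:
        _check_bounds("ich", self.ich)
        _check_bounds("mni", self.mni)

    @property
    def worst(self) -> Tuple[float, float]:
        return self.ich

    @property
    def best(self) -> Tuple[float, float]:
        return self.mni


@dataclass(frozen=True)
class YRegionSpec:
    """Admissible rectangle for the Rankin marginal.

    ``poor`` bounds P[Y = poor], ``good`` bounds P[Y = good].
    """

    poor: Tuple[float, float] = (0.20, 0.60)
    good: Tuple[float, float] = (0.15, 0.55)

    def __post_init__(self) -> None:
        _check_bounds("poor", self.poor)
        _check_bounds("good", self.good)

    @property
    def worst(self) -> Tuple[float, float]:
        return self.poor

    @property
    def best(self) -> Tuple[float, float]:
        return self.good


def _sample_bounded_triples(
    count: int,
    worst: Tuple[float, float],
    best: Tuple[float, float],
    rng: np.random.Generator,
    max_tries: int,
) -> np.ndarray:
    """Uniform triples (p0, p1, p2) on the simplex with p0 in ``worst`` and
    p2 in ``best`` bounds.  Degenerate (zero-width) bounds pin a coordinate.
    Returns an array of shape (count, 3)."""
    lo0, hi0 = worst
    lo2, hi2 = best
    fix0 = hi0 - lo0 <= _DEGEN
    fix2 = hi2 - lo2 <= _DEGEN

    if fix0 and fix2:
        p1 = 1.0 - lo0 - lo2
        if p1 < -_DEGEN:
            raise RegionInfeasibleError(
                f"point region ({lo0}, {lo2}) lies outside the simplex"
            )
        out = np.tile([lo0, max(p1, 0.0), lo2], (count, 1))
        return out

    if fix0 or fix2:
        # One coordinate pinned: sample the other uniformly on its feasible
        # interval, the middle coordinate takes the remainder.
        pinned, (lo, hi) = (lo0, (lo2, hi2)) if fix0 else (lo2, (lo0, hi0))
        hi = min(hi, 1.0 - pinned)
        if hi < lo - _DEGEN:
            raise RegionInfeasibleError("degenerate region has zero admissible length")
        free = rng.uniform(lo, hi, size=count)
        mid = 1.0 - pinned - free
        if fix0:
            return np.column_stack([np.full(count, lo0), mid, free])
        return np.column_stack([free, mid, np.full(count, lo2)])

    out = np.empty((count, 3))
    got = 0
    tried = 0
    while got < count:
        batch = max(1024, 4 * (count - got))
        if tried + batch > max_tries:
            batch = max_tries - tried
            if batch <= 0:
                raise RegionInfeasibleError(
                    f"no admissible point found in {max_tries} draws; "
                    f"region worst={worst}, best={best} may have zero area"
                )
        cand = rng.dirichlet((1.0, 1.0, 1.0), size=batch)
        tried += batch
        ok = (
            (cand[:, 0] >= lo0)
            & (cand[:, 0] <= hi0)
            & (cand[:, 2] >= lo2)
            & (cand[:, 2] <= hi2)
        )
        acc = cand[ok]
        take = min(len(acc), count - got)
        out[got : got + take] = acc[:take]
        got += take
    return out


def sample_x_marginals(
    count: int,
    region: Optional[XRegionSpec] = None,
    rng=None,
    max_tries: int = 1_000_000,
) -> list[ProbTriple]:
    """Draw ``count`` rapid-response marginals uniformly over the region."""
    if count < 1:
        raise ValueError("count must be >= 1")
    region = region or XRegionSpec()
    rng = as_generator(rng)
    arr = _sample_bounded_triples(count, region.worst, region.best, rng, max_tries)
    return [ProbTriple.from_array(a) for a in arr]


def sample_y_marginal(
    region: Optional[YRegionSpec] = None,
    rng=None,
    max_tries: int = 1_000_000,
) -> ProbTriple:
    """Draw one Rankin marginal uniformly over the region.

    Under null usage the same triple is assigned to all four arms.
    """
    region = region or YRegionSpec()
    rng = as_generator(rng)
    arr = _sample_bounded_triples(1, region.worst, region.best, rng, max_tries)
    return ProbTriple.from_array(arr[0])


def conditional_candidate_ok(
    row_ich: np.ndarray,
    row_mni: np.ndarray,
    x: np.ndarray,
    y: np.ndarray,
    tol: float = 1e-12,
) -> tuple[bool, Optional[str], Optional[np.ndarray]]:
    """Acceptance test for one candidate conditional matrix.

    Given candidate rows for X=ICH and X=MNI, solves the middle row from
    the marginalization identity and checks that the result is a valid,
    monotone probability vector.  Returns (accepted, reason, row_nei) where
    ``reason`` names the first violated constraint on rejection.  Exposed
    separately so tests can cross-check it against an independent
    implementation.
    """
    if not (row_ich[0] >= row_mni[0] - tol and row_ich[2] <= row_mni[2] + tol):
        return False, "outer-row ordering", None
    row_nei = (y - x[0] * row_ich - x[2] * row_mni) / x[1]
    if np.any(row_nei < -tol) or np.any(row_nei > 1.0 + tol):
        return False, "middle row outside [0, 1]", None
    if not (row_ich[0] >= row_nei[0] - tol and row_nei[0] >= row_mni[0] - tol):
        return False, "middle-row poor monotonicity", None
    if not (row_ich[2] <= row_nei[2] + tol and row_nei[2] <= row_mni[2] + tol):
        return False, "middle-row good monotonicity", None
    return True, None, np.clip(row_nei, 0.0, 1.0)


def sample_conditional(
    x_marg: ProbTriple,
    y_marg: ProbTriple,
    rng=None,
    max_tries: int = 200_000,
) -> CondMatrix:
    """Draw a conditional matrix P[Y | X] consistent with both marginals.

    Candidate rows for X=ICH and X=MNI are drawn from the flat simplex;
    the X=NEI row is solved from the marginalization identity so the
    identity holds exactly, and the candidate is accepted iff the solved
    row is a valid probability vector and the full matrix satisfies the
    non-strict clinical monotonicity constraint.
    """
    x = x_marg.as_array()
    y = y_marg.as_array()
    if x[1] <= 0.0:
        raise ValueError("x_marg must give positive probability to the middle category")
    rng = as_generator(rng)

    violations: dict[str, int] = {}
    tried = 0
    while tried < max_tries:
        batch = min(256, max_tries - tried)
        cand_ich = rng.dirichlet((1.0, 1.0, 1.0), size=batch)
        cand_mni = rng.dirichlet((1.0, 1.0, 1.0), size=batch)
        tried += batch
        for ri, rm in zip(cand_ich, cand_mni):
            ok, reason, rn = conditional_candidate_ok(ri, rm, x, y)
            if ok:
                return CondMatrix(
                    (
                        ProbTriple.from_array(ri),
                        ProbTriple.from_array(rn / rn.sum()),
                        ProbTriple.from_array(rm),
                    )
                )
            violations[reason] = violations.get(reason, 0) + 1
    worst = max(violations, key=violations.get) if violations else "unknown"
    raise RegionInfeasibleError(
        f"no feasible conditional matrix in {max_tries} tries for "
        f"x={tuple(x_marg)}, y={tuple(y_marg)}; most frequent violation: {worst}"
    )


def build_scheme_ensemble(
    n_x: int,
    n_y: int,
    n_cond: int,
    x_region: Optional[XRegionSpec] = None,
    y_region: Optional[YRegionSpec] = None,
    rng=None,
    max_tries: int = 200_000,
) -> list[DistributionScheme]:
    """Build ``n_x * n_y * n_cond`` null schemes by a nested factorial draw.

    For each of the ``n_x`` cells, one rapid-response marginal is drawn
    independently per arm; within a cell, each of ``n_y`` Rankin marginals
    is shared by all four arms (the null constraint); for each (X, Y)
    pair, ``n_cond`` per-arm conditional matrices are drawn.
    """
    if min(n_x, n_y, n_cond) < 1:
        raise ValueError("n_x, n_y, n_cond must all be >= 1")
    x_region = x_region or XRegionSpec()
    y_region = y_region or YRegionSpec()
    rng = as_generator(rng)

    schemes: list[DistributionScheme] = []
    for _ in range(n_x):
        x_by_arm = {
            arm: sample_x_marginals(1, x_region, rng, max_tries)[0] for arm in ARMS
        }
        for _ in range(n_y):
            y = sample_y_marginal(y_region, rng, max_tries)
            y_by_arm = {arm: y for arm in ARMS}
            for _ in range(n_cond):
                cond = {
                    arm: sample_conditional(x_by_arm[arm], y, rng, max_tries)
                    for arm in ARMS
                }
                schemes.append(
                    DistributionScheme(
                        x_marginal=dict(x_by_arm),
                        y_marginal=y_by_arm,
                        conditional=cond,
                        is_null=True,
                    )
                )
    return schemes


def sample_outcome_pair(
    scheme: DistributionScheme, arm: ArmLabel, rng=None
) -> tuple[RapidResponse, RankinCategory]:
    """Draw one (rapid response, Rankin category) pair for ``arm``."""
    x, y = sample_outcome_batch(scheme, arm, 1, rng)
    return RapidResponse(int(x[0])), RankinCategory(int(y[0]))


def sample_outcome_batch(
    scheme: DistributionScheme, arm: ArmLabel, size: int, rng=None
) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``size`` i.i.d. (X, Y) pairs for ``arm`` as integer arrays.

    X follows the arm's rapid-response marginal; Y follows the arm's
    conditional given the realized X.
    """
    if arm not in scheme.x_marginal:
        raise KeyError(f"arm {arm!r} not present in scheme")
    rng = as_generator(rng)
    xc = np.cumsum(scheme.x_marginal[arm].as_array())[:2]
    u = rng.random(size)
    x = (u > xc[0]).astype(np.int8) + (u > xc[1])
    cc = np.cumsum(scheme.conditional[arm].as_array(), axis=1)[:, :2]
    u2 = rng.random(size)
    y = (u2 > cc[x, 0]).astype(np.int8) + (u2 > cc[x, 1])
    return x, y


def table1_scheme(
    best: Tuple[float, float],
    inferior1: Tuple[float, float],
    inferior2: Tuple[float, float],
) -> dict[ArmLabel, ProbTriple]:
    """Rapid-response marginals for a least-favorable configuration.

    Each argument is a (P[MNI], P[ICH]) pair; P[NEI] is the complement.
    The best dose is assigned to the first tenecteplase arm (A), the two
    inferior doses to B and C.
    """
    out: dict[ArmLabel, ProbTriple] = {}
    for arm, (p_mni, p_ich) in zip(TNK_ARMS, (best, inferior1, inferior2)):
        if p_mni < 0 or p_ich < 0 or p_mni + p_ich > 1.0 + _DEGEN:
            raise ValueError(f"invalid (P[MNI], P[ICH]) pair {(p_mni, p_ich)!r}")
        nei = 1.0 - p_mni - p_ich
        out[arm] = ProbTriple(p_ich, nei if abs(nei) > _DEGEN else 0.0, p_mni)
    return out
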