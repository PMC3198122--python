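"""Ordered trichotomous outcomes and per-arm joint outcome distributions.

The simulated trial observes two correlated trichotomous variables per
patient: a 24-hour *rapid response* — symptomatic intracranial hemorrhage
(ICH), neither (NEI), or major neurological improvement (MNI) — used by the
dose-selection stage, and the 3-month modified Rankin scale trichotomized
into poor / neither / good, which carries the two co-primary endpoints.

A :class:`DistributionScheme` fixes, for each of the four treatment arms
(three tenecteplase doses A, B, C and the rt-PA comparator D), the joint
law of the pair as the marginal of the rapid response plus the conditional
of the Rankin category given the rapid response.  A scheme is *null* when
the implied Rankin marginal is identical across all four arms, so that both
co-primary null hypotheses hold whatever dose is selected.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from enum import Enum, IntEnum
from typing import Dict, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "RapidResponse",
    "RankinCategory",
    "ArmLabel",
    "ARMS",
    "TNK_ARMS",
    "ProbTriple",
    "CondMatrix",
    "DistributionScheme",
    "SUM_TOL",
    "MARGIN_TOL",
]

#: Tolerance for a probability vector summing to one.
SUM_TOL = 1e-12
#: Tolerance for the marginalization identity of a scheme.
MARGIN_TOL = 1e-10
#: Tolerance for (non-strict) monotonicity comparisons.
MONO_TOL = 1e-12


class RapidResponse(IntEnum):
    """24-hour rapid-response category, ordered worst to best.

    The integer value doubles as the cumulative-sum score used by the
    sequential elimination procedure (ICH scores 0, NEI 1, MNI 2).
    """

    ICH = 0
    NEI = 1
    MNI = 2


class RankinCategory(IntEnum):
    """Trichotomized 3-month modified Rankin scale, ordered worst to best.

    ``POOR`` is Rankin 4-6 (including death), ``NEITHER`` is 2-3,
    ``GOOD`` is 0-1.
    """

    POOR = 0
    NEITHER = 1
    GOOD = 2


class ArmLabel(str, Enum):
    """Treatment arm: three tenecteplase doses plus the rt-PA comparator."""

    A = "A"
    B = "B"
    C = "C"
    D = "D"

    @property
    def dose_mg_per_kg(self) -> float:
        return _DOSES[self]

    @property
    def is_tenecteplase(self) -> bool:
        """Only the tenecteplase arms enter the selection procedure."""
        return self is not ArmLabel.D


_DOSES = {
    ArmLabel.A: 0.10,
    ArmLabel.B: 0.25,
    ArmLabel.C: 0.40,
    ArmLabel.D: 0.90,  # standard-dose rt-PA
}

#: All arms, in canonical order.
ARMS: tuple[ArmLabel, ...] = (ArmLabel.A, ArmLabel.B, ArmLabel.C, ArmLabel.D)
#: Tenecteplase arms eligible for selection.
TNK_ARMS: tuple[ArmLabel, ...] = (ArmLabel.A, ArmLabel.B, ArmLabel.C)


@dataclass(frozen=True)
class ProbTriple:
    """Probability vector over the three ordered categories of one outcome.

    ``p0`` is the probability of the worst category (ICH or poor), ``p1``
    the intermediate, ``p2`` the best (MNI or good).  Components must lie
    in [0, 1] and sum to one within :data:`SUM_TOL`.
    """

    p0: float
    p1: float
    p2: float

    def __post_init__(self) -> None:
        for p in (self.p0, self.p1, self.p2):
            if not (-SUM_TOL <= p <= 1.0 + SUM_TOL):
                raise ValueError(f"probability {p!r} outside [0, 1]")
        s = self.p0 + self.p1 + self.p2
        if abs(s - 1.0) > SUM_TOL:
            raise ValueError(f"probabilities sum to {s!r}, not 1")

    @classmethod
    def from_array(cls, a: Sequence[float]) -> "ProbTriple":
        p0, p1, p2 = (float(v) for v in a)
        return cls(p0, p1, p2)

    def as_array(self) -> np.ndarray:
        return np.array([self.p0, self.p1, self.p2], dtype=float)

    def __iter__(self):
        return iter((self.p0, self.p1, self.p2))


@dataclass(frozen=True)
class CondMatrix:
    """Conditional law of the Rankin category given each rapid response.

    ``rows[x]`` is P[Y | X = x] for x in (ICH, NEI, MNI).  Clinical
    monotonicity is enforced non-strictly: the probability of a poor
    outcome may not increase, and the probability of a good outcome may
    not decrease, as the rapid response improves.  Ties are allowed, so
    the independence matrix (all rows equal) is admissible.
    """

    rows: tuple[ProbTriple, ProbTriple, ProbTriple]

    def __post_init__(self) -> None:
        if len(self.rows) != 3:
            raise ValueError("CondMatrix requires exactly three rows")
        ich, nei, mni = self.rows
        if not (ich.p0 >= nei.p0 - MONO_TOL and nei.p0 >= mni.p0 - MONO_TOL):
            raise ValueError("monotonicity violated: P[poor|X] must be non-increasing in X")
        if not (ich.p2 <= nei.p2 + MONO_TOL and nei.p2 <= mni.p2 + MONO_TOL):
            raise ValueError("monotonicity violated: P[good|X] must be non-decreasing in X")

    @classmethod
    def from_array(cls, a: Sequence[Sequence[float]]) -> "CondMatrix":
        rows = tuple(ProbTriple.from_array(r) for r in a)
        return cls(rows)  # type: ignore[arg-type]

    def as_array(self) -> np.ndarray:
        return np.stack([r.as_array() for r in self.rows])


@dataclass(frozen=True)
class DistributionScheme:
    """Per-arm joint distribution of (rapid response X, Rankin category Y).

    The joint law for arm T is specified as P[X | T] (``x_marginal``) plus
    P[Y | X, T] (``conditional``); ``y_marginal`` stores the implied
    P[Y | T] and must satisfy the marginalization identity

        sum_x P[X = x | T] * P[Y | X = x, T] = P[Y | T]

    component-wise within :data:`MARGIN_TOL`.  ``is_null`` asserts that the
    Y-marginal is identical across arms.
    """

    x_marginal: Mapping[ArmLabel, ProbTriple]
    y_marginal: Mapping[ArmLabel, ProbTriple]
    conditional: Mapping[ArmLabel, CondMatrix]
    is_null: bool = False

    def __post_init__(self) -> None:
        for field in (self.x_marginal, self.y_marginal, self.conditional):
            missing = [a for a in ARMS if a not in field]
            if missing:
                raise ValueError(f"scheme missing arms {missing}")
        self.validate()

    def validate(self) -> None:
        for arm in ARMS:
            x = self.x_marginal[arm].as_array()
            c = self.conditional[arm].as_array()
            y = self.y_marginal[arm].as_array()
            implied = x @ c
            err = np.max(np.abs(implied - y))
            if err > MARGIN_TOL:
                raise ValueError(
                    f"marginalization violated for arm {arm.value}: max error {err:.3e}"
                )
        if self.is_null:
            ref = self.y_marginal[ArmLabel.A].as_array()
            for arm in ARMS:
                if np.max(np.abs(self.y_marginal[arm].as_array() - ref)) > SUM_TOL:
                    raise ValueError("null scheme requires identical Y-marginals across arms")

    # -- array views used by the vectorized engine ------------------------

    def x_array(self) -> np.ndarray:
        """P[X | T] as a (4, 3) array in arm order A, B, C, D."""
        return np.stack([self.x_marginal[a].as_array() for a in ARMS])

    def y_array(self) -> np.ndarray:
        """P[Y | T] as a (4, 3) array in arm order A, B, C, D."""
        return np.stack([self.y_marginal[a].as_array() for a in ARMS])

    def cond_array(self) -> np.ndarray:
        """P[Y | X, T] as a (4, 3, 3) array indexed (arm, x, y)."""
        return np.stack([self.conditional[a].as_array() for a in ARMS])

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "is_null": self.is_null,
            "arms": {
                a.value: {
                    "x": list(self.x_marginal[a]),
                    "y": list(self.y_marginal[a]),
                    "cond": self.conditional[a].as_array().tolist(),
                }
                for a in ARMS
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "DistributionScheme":
        arms = d["arms"]
        return cls(
            x_marginal={ArmLabel(k): ProbTriple.from_array(v["x"]) for k, v in arms.items()},
            y_marginal={ArmLabel(k): ProbTriple.from_array(v["y"]) for k, v in arms.items()},
            conditional={ArmLabel(k): CondMatrix.from_array(v["cond"]) for k, v in arms.items()},
            is_null=bool(d["is_null"]),
        )


def ensemble_to_json(schemes: Iterable[DistributionScheme]) -> str:
    """Serialize a list of schemes to a JSON document."""
    return json.dumps({"schemes": [s.to_dict() for s in schemes]}, indent=1)


def ensemble_from_json(text: str) -> list[DistributionScheme]:
    """Inverse of :func:`ensemble_to_json`."""
    doc = json.loads(text)
    return [DistributionScheme.from_dict(d) for d in doc["schemes"]]
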