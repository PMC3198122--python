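"""Truncated sequential elimination of inferior dose arms.

Patients arrive in *matched sets* containing one patient per still-active
tenecteplase arm.  Each rapid response adds its score (MNI 2, NEI 1,
ICH 0) to the arm's cumulative sum.  After every complete set, any arm
whose cumulative sum trails the current maximum by at least the *lead*
(default 6 points) is eliminated; when one arm remains it is selected.
If no selection has occurred after ``truncation_m`` (default 150) sets,
the procedure is truncated and the surviving arms are handed to the
clinical selection criteria.

Elimination *cascades* within a set by default: after removing the arms
at the minimum, the criterion is re-applied to the survivors, since the
post-elimination state may already satisfy it (e.g. sums 10/4/3 with a
lead of 6 eliminate both trailing arms in the same set).  Set
``cascade=False`` in :class:`SelectionConfig` for at most one elimination
round per set (sensitivity analysis).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Tuple

import numpy as np

from .outcomes import TNK_ARMS, ArmLabel, RapidResponse

__all__ = [
    "DEFAULT_SCORES",
    "SelectionConfig",
    "SelectionState",
    "SelectionResult",
    "score_response",
    "advance_one_set",
    "run_selection",
    "SelectionBatch",
    "simulate_selection_batch",
]

DEFAULT_SCORES: Mapping[RapidResponse, int] = {
    RapidResponse.MNI: 2,
    RapidResponse.NEI: 1,
    RapidResponse.ICH: 0,
}


@dataclass(frozen=True)
class SelectionConfig:
    """Parameters of the elimination procedure."""

    lead: int = 6
    truncation_m: int = 150
    scores: Mapping[RapidResponse, int] = field(
        default_factory=lambda: dict(DEFAULT_SCORES)
    )
    cascade: bool = True

    def __post_init__(self) -> None:
        if self.lead < 1:
            raise ValueError("lead must be >= 1")
        if self.truncation_m < 1:
            raise ValueError("truncation_m must be >= 1")
        s = self.scores
        if any(v < 0 for v in s.values()):
            raise ValueError("scores must be non-negative")
        if not (
            s[RapidResponse.ICH] < s[RapidResponse.NEI] < s[RapidResponse.MNI]
        ):
            raise ValueError("scores must respect the outcome ordering ICH < NEI < MNI")

    def score_lut(self) -> np.ndarray:
        """Scores as an array indexed by the rapid-response code."""
        return np.array(
            [
                self.scores[RapidResponse.ICH],
                self.scores[RapidResponse.NEI],
                self.scores[RapidResponse.MNI],
            ],
            dtype=np.int64,
        )


def score_response(x: RapidResponse, config: Optional[SelectionConfig] = None) -> int:
    """Cumulative-sum increment for one rapid response."""
    config = config or SelectionConfig()
    return int(config.scores[RapidResponse(x)])


@dataclass
class SelectionState:
    """Mutable state of the elimination procedure between matched sets."""

    cumsum: Dict[ArmLabel, int]
    active: Tuple[ArmLabel, ...]
    sets_observed: int = 0
    elimination_log: List[Tuple[int, Tuple[ArmLabel, ...]]] = field(default_factory=list)
    selected: Optional[ArmLabel] = None

    @classmethod
    def initial(cls, arms: Tuple[ArmLabel, ...] = TNK_ARMS) -> "SelectionState":
        return cls(cumsum={a: 0 for a in arms}, active=tuple(arms))

    @property
    def complete(self) -> bool:
        return self.selected is not None


def advance_one_set(
    state: SelectionState,
    outcomes: Mapping[ArmLabel, RapidResponse],
    config: Optional[SelectionConfig] = None,
) -> SelectionState:
    """Enter one complete matched set and apply the elimination rule.

    ``outcomes`` must supply exactly one rapid response per active arm.
    Returns a new state; the input state is not modified.
    """
    config = config or SelectionConfig()
    if state.complete:
        raise ValueError("selection already complete")
    if set(outcomes) != set(state.active):
        extra = set(outcomes) - set(state.active)
        missing = set(state.active) - set(outcomes)
        raise ValueError(
            f"outcomes must cover exactly the active arms "
            f"(extra={sorted(a.value for a in extra)}, "
            f"missing={sorted(a.value for a in missing)})"
        )

    cumsum = dict(state.cumsum)
    for arm, x in outcomes.items():
        cumsum[arm] += score_response(x, config)

    t = state.sets_observed + 1
    active = list(state.active)
    log = list(state.elimination_log)
    while len(active) > 1:
        mx = max(cumsum[a] for a in active)
        mn = min(cumsum[a] for a in active)
        if mx - mn < config.lead:
            break
        eliminated = tuple(a for a in active if cumsum[a] == mn)
        active = [a for a in active if cumsum[a] != mn]
        log.append((t, eliminated))
        if not config.cascade:
            break

    return SelectionState(
        cumsum=cumsum,
        active=tuple(active),
        sets_observed=t,
        elimination_log=log,
        selected=active[0] if len(active) == 1 else None,
    )


@dataclass(frozen=True)
class SelectionResult:
    """Outcome of one run of the (possibly truncated) selection procedure.

    ``tnk_patients`` is the total number of tenecteplase patients
    randomized in the selection phase; with first/final elimination times
    N(1) and N and truncation point m it always satisfies

        tnk_patients = 2 * min(N, m) + min(N(1), m),

    where a missing elimination time is replaced by m.  rt-PA patients
    (one per matched set) are not counted.
    """

    selected: Optional[ArmLabel]
    n_first_elim: Optional[int]
    n_final: Optional[int]
    truncated: bool
    tnk_patients: int
    survivors_at_truncation: Tuple[ArmLabel, ...] = ()

    def __post_init__(self) -> None:
        if self.n_first_elim is not None and self.n_final is not None:
            if self.n_first_elim > self.n_final:
                raise ValueError("first elimination cannot follow final selection")


def _result_from_state(state: SelectionState, config: SelectionConfig) -> SelectionResult:
    m = config.truncation_m
    n1 = state.elimination_log[0][0] if state.elimination_log else None
    n = state.sets_observed if state.complete else None
    t = 2 * min(n if n is not None else m, m) + min(n1 if n1 is not None else m, m)
    return SelectionResult(
        selected=state.selected,
        n_first_elim=n1,
        n_final=n,
        truncated=not state.complete,
        tnk_patients=t,
        survivors_at_truncation=() if state.complete else state.active,
    )


def run_selection(
    outcome_source: Iterable[Mapping[ArmLabel, RapidResponse]],
    config: Optional[SelectionConfig] = None,
) -> SelectionResult:
    """Run the procedure to selection or truncation.

    ``outcome_source`` yields one mapping of arm to rapid response per
    matched set; entries for already-eliminated arms are ignored, so a
    source may keep yielding all three arms.
    """
    config = config or SelectionConfig()
    state = SelectionState.initial()
    it: Iterator[Mapping[ArmLabel, RapidResponse]] = iter(outcome_source)
    while not state.complete and state.sets_observed < config.truncation_m:
        try:
            outcomes = next(it)
        except StopIteration as exc:
            raise ValueError("outcome source exhausted before selection/truncation") from exc
        outcomes = {a: x for a, x in outcomes.items() if a in state.active}
        state = advance_one_set(state, outcomes, config)
    return _result_from_state(state, config)


# ---------------------------------------------------------------------------
# Vectorized batch engine
# ---------------------------------------------------------------------------


@dataclass
class SelectionBatch:
    """Replication-level arrays from :func:`simulate_selection_batch`.

    Set indices are 1-based; 0 means the event did not occur before
    truncation.  ``selected`` holds the arm index (0..k-1) or -1.
    """

    n_first_elim: np.ndarray  # (reps,) int32, 0 = no elimination
    n_final: np.ndarray  # (reps,) int32, 0 = truncated
    selected: np.ndarray  # (reps,) int8, -1 = truncated
    survivors: np.ndarray  # (reps, k) bool — active arms at the end

    @property
    def truncated(self) -> np.ndarray:
        return self.n_final == 0

    def min_n1_m(self, m: int) -> np.ndarray:
        return np.where(self.n_first_elim > 0, self.n_first_elim, m)

    def min_n_m(self, m: int) -> np.ndarray:
        return np.where(self.n_final > 0, self.n_final, m)

    def tnk_patients(self, m: int) -> np.ndarray:
        return 2 * self.min_n_m(m) + self.min_n1_m(m)


def simulate_selection_batch(
    scores: np.ndarray, config: Optional[SelectionConfig] = None
) -> SelectionBatch:
    """Run many replications of the elimination procedure at once.

    ``scores`` has shape (reps, k_arms, n_sets) with per-set integer
    scores; only the first ``truncation_m`` sets are used.  Draws for an
    arm after its elimination are ignored, which is distributionally
    equivalent to never sampling them.
    """
    config = config or SelectionConfig()
    reps, k, n_sets = scores.shape
    m = min(config.truncation_m, n_sets)
    if n_sets < config.truncation_m:
        raise ValueError("scores must cover at least truncation_m sets")

    BIG = np.int64(1) << 40
    cum = np.zeros((reps, k), dtype=np.int64)
    active = np.ones((reps, k), dtype=bool)
    running = np.ones(reps, dtype=bool)
    n1 = np.zeros(reps, dtype=np.int32)
    n = np.zeros(reps, dtype=np.int32)

    for t in range(m):
        if not running.any():
            break
        inc = scores[:, :, t] * (active & running[:, None])
        cum += inc
        check = running.copy()
        while True:
            masked_lo = np.where(active, cum, BIG)
            mn = masked_lo.min(axis=1)
            masked_hi = np.where(active, cum, -BIG)
            mx = masked_hi.max(axis=1)
            trig = check & (mx - mn >= config.lead)
            if not trig.any():
                break
            elim = trig[:, None] & active & (cum == mn[:, None])
            active &= ~elim
            np.putmask(n1, trig & (n1 == 0), t + 1)
            done_now = trig & (active.sum(axis=1) == 1)
            np.putmask(n, done_now & (n == 0), t + 1)
            running &= ~done_now
            if not config.cascade:
                break
            check = trig & running

    selected = np.where(n > 0, active.argmax(axis=1), -1).astype(np.int8)
    return SelectionBatch(
        n_first_elim=n1, n_final=n, selected=selected, survivors=active
    )
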