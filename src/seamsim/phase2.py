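"""End-of-phase-II clinical decision rules: promise, futility, and the
truncation-time selection criteria.

At the phase II assessment the selected tenecteplase dose is compared to
rt-PA.  The applicable rule depends on the relative safety profile,
classified from the difference in symptomatic ICH counts on the rapid
response:

* Scenario 1 (tenecteplase at least 2 fewer ICHs): promising iff the
  tenecteplase poor-outcome proportion is less than or equal to rt-PA's.
* Scenario 2 (ICH counts within +/-1): promising iff the tenecteplase
  poor-outcome proportion is at least 8 percentage points lower.
* Scenario 3 (tenecteplase 2 or more ICHs more): unpromising.

In Scenarios 1 and 2 further study is also unpromising if the good-outcome
proportion on tenecteplase is significantly below rt-PA's at the nominal
two-tailed interim level (0.001).  When the elimination procedure is
truncated with two or three surviving doses, Criteria 1-4 pick the dose:
keep the promising doses; break ties by lowest ICH rate, then lowest poor
proportion, then highest good proportion, then a uniform random draw.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

from ._rng import as_generator
from .inference import pooled_z_cc
from .outcomes import ArmLabel

__all__ = [
    "Phase2Config",
    "ArmSummary",
    "Phase2Decision",
    "classify_scenario",
    "assess_promise",
    "truncation_select",
    "PROMISING",
    "UNPROMISING",
    "STOP_SIGNIFICANT",
]

PROMISING = "promising"
UNPROMISING = "unpromising"
STOP_SIGNIFICANT = "stop_significant"


@dataclass(frozen=True)
class Phase2Config:
    """Tunable constants of the clinical decision rules."""

    poor_margin: float = 0.08
    ich_scenario_threshold: int = 2

    def __post_init__(self) -> None:
        if not 0.0 <= self.poor_margin <= 1.0:
            raise ValueError("poor_margin must be in [0, 1]")
        if self.ich_scenario_threshold < 1:
            raise ValueError("ich_scenario_threshold must be >= 1")


@dataclass(frozen=True)
class ArmSummary:
    """Observed outcome counts for one arm at an assessment time."""

    n_rapid: int
    ich_count: int
    n_rankin: int
    poor_count: int
    neither_count: int
    good_count: int

    def __post_init__(self) -> None:
        if self.ich_count > self.n_rapid or self.ich_count < 0:
            raise ValueError("ich_count must lie in [0, n_rapid]")
        if min(self.poor_count, self.neither_count, self.good_count) < 0:
            raise ValueError("Rankin counts must be non-negative")
        if self.poor_count + self.neither_count + self.good_count != self.n_rankin:
            raise ValueError("Rankin counts must sum to n_rankin")

    @property
    def ich_rate(self) -> float:
        return self.ich_count / self.n_rapid

    @property
    def poor_prop(self) -> float:
        return self.poor_count / self.n_rankin

    @property
    def good_prop(self) -> float:
        return self.good_count / self.n_rankin


@dataclass(frozen=True)
class Phase2Decision:
    """Outcome of a promise/futility assessment.

    ``significant_endpoints`` records any endpoint rejected in either
    direction at the interim level — the trial simulator counts these as
    type I errors under a null scheme.  ``scenario`` is None only when the
    decision arises from Criterion 1 emptying the truncation survivor set.
    """

    status: str
    scenario: Optional[int]
    significant_endpoints: frozenset = frozenset()

    def __post_init__(self) -> None:
        if self.status not in (PROMISING, UNPROMISING, STOP_SIGNIFICANT):
            raise ValueError(f"unknown status {self.status!r}")
        if self.scenario not in (None, 1, 2, 3):
            raise ValueError(f"unknown scenario {self.scenario!r}")


def classify_scenario(
    tnk: ArmSummary, rtpa: ArmSummary, threshold: int = 2
) -> int:
    """Safety scenario from the difference in symptomatic ICH counts."""
    d = tnk.ich_count - rtpa.ich_count
    if d <= -threshold:
        return 1
    if d >= threshold:
        return 3
    return 2


def assess_promise(
    tnk: ArmSummary,
    rtpa: ArmSummary,
    alpha_interim: float = 0.001,
    config: Optional[Phase2Config] = None,
) -> Phase2Decision:
    """Apply the scenario-specific promise/futility rule.

    Both endpoints are first tested at ``alpha_interim`` (two-tailed) with
    the continuity-corrected pooled z-test; rejections are recorded in
    ``significant_endpoints`` regardless of direction.  A significant
    good-outcome *deficit* for tenecteplase forces an unpromising status;
    otherwise the scenario rule on poor-outcome proportions decides.
    """
    config = config or Phase2Config()
    if tnk.n_rankin < 1 or rtpa.n_rankin < 1:
        raise ValueError("assessment requires Rankin outcomes on both arms")

    res_poor = pooled_z_cc(tnk.poor_count, tnk.n_rankin, rtpa.poor_count, rtpa.n_rankin)
    res_good = pooled_z_cc(tnk.good_count, tnk.n_rankin, rtpa.good_count, rtpa.n_rankin)
    significant = set()
    if res_poor.p_two_sided <= alpha_interim:
        significant.add("poor")
    if res_good.p_two_sided <= alpha_interim:
        significant.add("good")

    scenario = classify_scenario(tnk, rtpa, config.ich_scenario_threshold)

    if "good" in significant and res_good.direction < 0:
        status = UNPROMISING
    elif scenario == 1:
        status = PROMISING if tnk.poor_prop <= rtpa.poor_prop else UNPROMISING
    elif scenario == 2:
        status = (
            PROMISING
            if rtpa.poor_prop - tnk.poor_prop >= config.poor_margin
            else UNPROMISING
        )
    else:
        status = UNPROMISING

    return Phase2Decision(
        status=status, scenario=scenario, significant_endpoints=frozenset(significant)
    )


def truncation_select(
    survivors: Sequence[Tuple[ArmLabel, ArmSummary]],
    rtpa: ArmSummary,
    alpha_interim: float = 0.001,
    config: Optional[Phase2Config] = None,
    rng=None,
) -> Tuple[Optional[ArmLabel], Phase2Decision]:
    """Clinical Criteria 1-4 at truncation time.

    Returns the selected arm and its decision, or ``(None, unpromising)``
    when no surviving dose passes Criterion 1.  Residual ties after
    Criterion 4 are broken by a uniform random draw from ``rng``.
    """
    if not survivors:
        raise ValueError("survivors must be non-empty")
    config = config or Phase2Config()
    rng = as_generator(rng)

    decisions = [
        (arm, summ, assess_promise(summ, rtpa, alpha_interim, config))
        for arm, summ in survivors
    ]
    promising = [(a, s, d) for a, s, d in decisions if d.status == PROMISING]
    if not promising:
        return None, Phase2Decision(status=UNPROMISING, scenario=None)

    pool: List[Tuple[ArmLabel, ArmSummary, Phase2Decision]] = promising
    for key in (
        lambda s: s.ich_rate,
        lambda s: s.poor_prop,
        lambda s: -s.good_prop,
    ):
        best = min(key(s) for _, s, _ in pool)
        pool = [(a, s, d) for a, s, d in pool if key(s) == best]
        if len(pool) == 1:
            break
    arm, _, decision = pool[int(rng.integers(len(pool)))] if len(pool) > 1 else pool[0]
    return arm, decision
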