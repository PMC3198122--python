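"""Full-trial simulation and Monte-Carlo operating characteristics.

Two studies are supported on top of the same machinery:

* *Group-sequential (GS)*: the complete design — sequential-elimination
  dose selection on the rapid response, the end-of-phase-II promise /
  futility assessment (the first interim analysis, at 100-150 patients
  per continuing arm), further interim analyses when the two continuing
  arms total 500, 1000, and 1500 patients (each endpoint tested two-tailed
  at 0.001), and a terminal analysis at 1908 patients with each endpoint
  tested at 0.025 (the first stage of the Holm step-down at an overall
  0.05).  Under a null scheme, any rejection at any analysis counts as at
  least one type I error; a futility stop without a rejection contributes
  none.

* *Fixed sample size (FSS)*: dose selection only, then a single terminal
  analysis at 954 patients per arm with no futility examination and no
  interim looks — isolating the opposing effects of selection inflation
  and the 1/2-continuity correction.

Interim totals count patients on the two continuing arms (selected
tenecteplase dose plus rt-PA) including their phase II patients, balanced
1:1.  Phase II patients on eliminated doses contribute to selection only;
their Rankin outcomes are never tested.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from ._rng import as_generator, substream
from .inference import holm_step_down, pooled_z_cc_arrays
from .outcomes import ARMS, TNK_ARMS, ArmLabel, DistributionScheme, ProbTriple
from .phase2 import (
    PROMISING,
    STOP_SIGNIFICANT,
    UNPROMISING,
    ArmSummary,
    Phase2Config,
    Phase2Decision,
    classify_scenario,
)
from .selection import SelectionBatch, SelectionConfig, SelectionResult, simulate_selection_batch

__all__ = [
    "GSConfig",
    "TrialResult",
    "OCRow",
    "TypeISummary",
    "estimate_selection_ocs",
    "simulate_full_trial",
    "simulate_fss_trial",
    "estimate_type1_errors",
    "STAGE_NAMES",
]

# Replication block sizes: fixed so that the random-stream layout is part
# of the result definition (rerunning with the same seed is bit-identical).
_BLOCK = 8192
_OC_BLOCK = 20000

# Stage codes, in trial order.
_FUTILITY, _NO_WINNER, _I1, _I2, _I3, _I4, _TERMINAL = range(7)
STAGE_NAMES = (
    "phase2_futility",
    "phase2_no_winner",
    "interim1",
    "interim2",
    "interim3",
    "interim4",
    "terminal",
)

_ENDPOINTS = ("poor", "good")
_DIRECTIONS = ("tnk_better", "tnk_worse")
_FLAG_KEYS = tuple((e, d) for e in _ENDPOINTS for d in _DIRECTIONS)


@dataclass(frozen=True)
class GSConfig:
    """Phase III schedule and significance levels."""

    assessment_min_per_arm: int = 100
    assessment_max_sets: int = 150
    interim_totals: Tuple[int, ...] = (500, 1000, 1500)
    terminal_total: int = 1908
    alpha_interim: float = 0.001
    alpha_terminal: float = 0.025
    holm_overall: float = 0.05
    stop_on_interim_rejection: bool = True

    def __post_init__(self) -> None:
        totals = tuple(self.interim_totals)
        if any(b <= a for a, b in zip(totals, totals[1:])):
            raise ValueError("interim_totals must be strictly increasing")
        if totals and totals[-1] >= self.terminal_total:
            raise ValueError("interim totals must precede the terminal total")
        if self.terminal_total % 2 != 0:
            raise ValueError("terminal_total must be even (1:1 allocation)")
        if not 0 < self.assessment_min_per_arm <= self.assessment_max_sets:
            raise ValueError("need 0 < assessment_min_per_arm <= assessment_max_sets")
        for a in (self.alpha_interim, self.alpha_terminal, self.holm_overall):
            if not 0.0 < a < 1.0:
                raise ValueError("alpha levels must be in (0, 1)")

    @property
    def per_arm_looks(self) -> Tuple[int, ...]:
        """Per-arm sample sizes of interims 2+ (half of each two-arm total)."""
        return tuple(t // 2 for t in self.interim_totals)

    @property
    def terminal_per_arm(self) -> int:
        return self.terminal_total // 2


@dataclass(frozen=True)
class TrialResult:
    """One simulated trial."""

    stop_stage: str
    selection: SelectionResult
    decision: Optional[Phase2Decision]
    rejections: Mapping[str, Mapping[str, bool]]
    any_type1: bool
    holm_rejected: Optional[frozenset] = None


# ---------------------------------------------------------------------------
# Vectorized batch core
# ---------------------------------------------------------------------------


def _pick_uniform(mask: np.ndarray, u: np.ndarray) -> np.ndarray:
    """Per row, index of a uniformly chosen True column (0 if none)."""
    cnt = mask.sum(axis=1)
    tgt = np.minimum((u * cnt).astype(np.int64), np.maximum(cnt - 1, 0))
    csum = mask.cumsum(axis=1)
    return np.argmax((csum == (tgt + 1)[:, None]) & mask, axis=1)


def _criteria_pick(
    cand: np.ndarray,
    ich: np.ndarray,
    poor: np.ndarray,
    good: np.ndarray,
    u: np.ndarray,
) -> np.ndarray:
    """Successive tie-break: lowest ICH count, lowest poor count, highest
    good count (equal denominators at truncation), then uniform random."""
    best = cand.copy()
    for key in (ich, poor, -good):
        k = np.where(best, key, np.int64(1) << 40)
        best &= k == k.min(axis=1, keepdims=True)
    return _pick_uniform(best, u)


def _promise_mask(ich_t, poor_t, good_t, ich_r, poor_r, good_r, n_t, n_r, alpha, p2):
    """Vectorized scenario rules; mirrors phase2.assess_promise exactly."""
    d = ich_t - ich_r
    thr = p2.ich_scenario_threshold
    scen = np.where(d <= -thr, 1, np.where(d >= thr, 3, 2)).astype(np.int8)
    _, pg, dg = pooled_z_cc_arrays(good_t, n_t, good_r, n_r)
    sig_deficit = (pg <= alpha) & (dg < 0)
    ppt = poor_t / n_t
    ppr = poor_r / n_r
    prom = ~sig_deficit & (
        ((scen == 1) & (ppt <= ppr)) | ((scen == 2) & (ppr - ppt >= p2.poor_margin))
    )
    return prom, scen


def _flag(rej: Dict, endpoint: str, rejected: np.ndarray, direction: np.ndarray) -> None:
    better = direction < 0 if endpoint == "poor" else direction > 0
    rej[(endpoint, "tnk_better")] |= rejected & better
    rej[(endpoint, "tnk_worse")] |= rejected & ~better & (direction != 0)


@dataclass
class _BatchResult:
    selection: SelectionBatch
    selected: np.ndarray
    no_winner: np.ndarray
    stage: np.ndarray
    rej: Dict[Tuple[str, str], np.ndarray]
    holm_poor: np.ndarray
    holm_good: np.ndarray
    reached_terminal: np.ndarray
    details: Optional[dict] = None

    @property
    def any_type1(self) -> np.ndarray:
        out = np.zeros_like(self.no_winner)
        for v in self.rej.values():
            out |= v
        return out


def _simulate_trial_batch(
    scheme: DistributionScheme,
    reps: int,
    sel_cfg: SelectionConfig,
    gs_cfg: GSConfig,
    p2_cfg: Phase2Config,
    mode: str,
    rng: np.random.Generator,
    collect_details: bool = False,
) -> _BatchResult:
    """Simulate ``reps`` trials under one scheme (mode 'gs' or 'fss').

    Outcome pairs are pre-drawn for every arm up to the terminal per-arm
    size; an arm's draws beyond its elimination are simply never used,
    which is distributionally identical to stopping its enrollment.
    """
    if mode not in ("gs", "fss"):
        raise ValueError(f"unknown mode {mode!r}")
    xc = np.cumsum(scheme.x_array(), axis=1)[:, :2]
    cc = np.cumsum(scheme.cond_array(), axis=2)[:, :, :2]
    m = sel_cfg.truncation_m
    n_term = gs_cfg.terminal_per_arm
    npat = max(n_term, m)

    u = rng.random((reps, 4, npat))
    X = (u > xc[:, 0][None, :, None]).astype(np.int8)
    X += u > xc[:, 1][None, :, None]
    del u
    u = rng.random((reps, 4, npat))
    arm_ix = np.arange(4)[None, :, None]
    Y = (u > cc[arm_ix, X, 0]).astype(np.int8)
    Y += u > cc[arm_ix, X, 1]
    del u
    # Tie-break draws are taken unconditionally so that stream positions
    # do not depend on realized outcomes.
    u_tie = rng.random(reps)
    u_nw = rng.random(reps)

    lut = sel_cfg.score_lut()
    sel = simulate_selection_batch(lut[X[:, :3, :m]], sel_cfg)
    trunc = sel.truncated

    cumP = np.cumsum(Y == 0, axis=2, dtype=np.int16)
    cumG = np.cumsum(Y == 2, axis=2, dtype=np.int16)
    cumI = np.cumsum(X == 0, axis=2, dtype=np.int16)
    R = np.arange(reps)

    rej = {k: np.zeros(reps, dtype=bool) for k in _FLAG_KEYS}
    stage = np.full(reps, -1, dtype=np.int8)
    holm_poor = np.zeros(reps, dtype=bool)
    holm_good = np.zeros(reps, dtype=bool)
    details: dict = {}

    if mode == "fss":
        selected = np.where(~trunc, sel.selected, _pick_uniform(sel.survivors, u_nw))
        selected = selected.astype(np.int64)
        no_winner = np.zeros(reps, dtype=bool)
        alive = np.ones(reps, dtype=bool)
        looks: List[Tuple[int, float, int]] = [
            (n_term, gs_cfg.alpha_terminal, _TERMINAL)
        ]
    else:
        # Truncation-time clinical criteria on the surviving doses.
        ich_t = cumI[:, :3, m - 1]
        poor_t = cumP[:, :3, m - 1]
        good_t = cumG[:, :3, m - 1]
        ich_r = cumI[:, 3, m - 1][:, None]
        poor_r = cumP[:, 3, m - 1][:, None]
        good_r = cumG[:, 3, m - 1][:, None]
        prom150, _ = _promise_mask(
            ich_t, poor_t, good_t, ich_r, poor_r, good_r,
            float(m), float(m), gs_cfg.alpha_interim, p2_cfg,
        )
        cand = sel.survivors & prom150 & trunc[:, None]
        has_cand = cand.any(axis=1)
        sel_tr = _criteria_pick(cand, ich_t, poor_t, good_t, u_tie)
        sel_nw = _pick_uniform(sel.survivors, u_nw)
        selected = np.where(
            ~trunc, sel.selected, np.where(has_cand, sel_tr, sel_nw)
        ).astype(np.int64)
        no_winner = trunc & ~has_cand

        # First interim analysis = end-of-phase-II assessment.
        a1 = np.clip(sel.min_n_m(m), gs_cfg.assessment_min_per_arm, m).astype(np.int64)
        i_t = cumI[R, selected, a1 - 1]
        i_r = cumI[R, 3, a1 - 1]
        p_t = cumP[R, selected, a1 - 1]
        p_r = cumP[R, 3, a1 - 1]
        g_t = cumG[R, selected, a1 - 1]
        g_r = cumG[R, 3, a1 - 1]
        _, pp, dp = pooled_z_cc_arrays(p_t, a1, p_r, a1)
        _, pg, dg = pooled_z_cc_arrays(g_t, a1, g_r, a1)
        rp = pp <= gs_cfg.alpha_interim
        rg = pg <= gs_cfg.alpha_interim
        _flag(rej, "poor", rp, dp)
        _flag(rej, "good", rg, dg)
        rej1 = rp | rg
        prom1, scen1 = _promise_mask(
            i_t, p_t, g_t, i_r, p_r, g_r,
            a1.astype(np.float64), a1.astype(np.float64),
            gs_cfg.alpha_interim, p2_cfg,
        )

        stage[no_winner] = _NO_WINNER
        stage[~no_winner & rej1] = _I1
        stage[(stage < 0) & ~prom1] = _FUTILITY
        alive = stage < 0  # promising, unrejected, with a winner

        looks = [
            (n, gs_cfg.alpha_interim, code)
            for n, code in zip(gs_cfg.per_arm_looks, (_I2, _I3, _I4))
        ]
        looks.append((n_term, gs_cfg.alpha_terminal, _TERMINAL))

        if collect_details:
            details.update(
                a1=a1, ich_t=i_t, ich_r=i_r, poor_t=p_t, poor_r=p_r,
                good_t=g_t, good_r=g_r, prom1=prom1, scen1=scen1,
                rej1_poor=rp, rej1_good=rg, has_cand=has_cand,
            )

    reached_terminal = np.zeros(reps, dtype=bool)
    for n_k, alpha, code in looks:
        if not alive.any():
            break
        p_t = cumP[R, selected, n_k - 1]
        p_r = cumP[R, 3, n_k - 1]
        g_t = cumG[R, selected, n_k - 1]
        g_r = cumG[R, 3, n_k - 1]
        _, pp, dp = pooled_z_cc_arrays(p_t, float(n_k), p_r, float(n_k))
        _, pg, dg = pooled_z_cc_arrays(g_t, float(n_k), g_r, float(n_k))
        rp = alive & (pp <= alpha)
        rg = alive & (pg <= alpha)
        _flag(rej, "poor", rp, dp)
        _flag(rej, "good", rg, dg)
        rej_any = rp | rg
        np.putmask(stage, rej_any & (stage < 0), code)
        if code == _TERMINAL:
            reached_terminal = alive.copy()
            # Holm step-down, recorded for reporting; error accounting uses
            # the per-endpoint alpha_terminal tests above.
            a2 = gs_cfg.holm_overall
            lo = np.minimum(pp, pg)
            hi = np.maximum(pp, pg)
            first = lo <= a2 / 2.0
            both = first & (hi <= a2)
            holm_poor = alive & ((first & (pp <= pg)) | both)
            holm_good = alive & ((first & (pg < pp)) | both)
            np.putmask(stage, alive & (stage < 0), _TERMINAL)
            alive = np.zeros_like(alive)
        elif gs_cfg.stop_on_interim_rejection:
            alive = alive & ~rej_any

    if collect_details:
        details["trunc"] = trunc

    return _BatchResult(
        selection=sel,
        selected=selected,
        no_winner=no_winner,
        stage=stage,
        rej=rej,
        holm_poor=holm_poor,
        holm_good=holm_good,
        reached_terminal=reached_terminal,
        details=details if collect_details else None,
    )


# ---------------------------------------------------------------------------
# Selection operating characteristics (Table-1-style estimates)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OCRow:
    """Monte-Carlo operating characteristics of the selection procedure.

    ``e_min_n1_m`` and ``e_min_n_m`` are the expected set counts at first
    and final elimination, truncated at m; ``e_t`` the expected number of
    tenecteplase patients randomized in the selection phase; ``median_n``
    the median of min(N, m); ``mode_n`` the most frequent completed
    selection time (ties to the smallest).  ``_se`` fields are Monte-Carlo
    standard errors.
    """

    label: str
    reps: int
    p_cs: float
    p_cs_se: float
    p_incorrect: float
    p_no_winner: float
    p_no_winner_se: float
    e_min_n1_m: float
    e_min_n1_m_se: float
    e_min_n_m: float
    e_min_n_m_se: float
    median_n: float
    mode_n: int
    e_t: float
    e_t_se: float
    arm_selection_probs: Tuple[float, float, float]


def estimate_selection_ocs(
    x_marginals: Sequence[ProbTriple],
    reps: int,
    config: Optional[SelectionConfig] = None,
    seed: int = 0,
    best_index: int = 0,
    label: str = "",
) -> OCRow:
    """Estimate selection operating characteristics by simulation.

    Rapid responses are sampled i.i.d. per arm from the three marginals;
    ``best_index`` names the truly best arm (default the first listed).
    A correct selection requires a final elimination at or before the
    truncation point — correct picks by clinical criteria at truncation
    do not count.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    config = config or SelectionConfig()
    m = config.truncation_m
    xm = np.stack([ProbTriple.from_array(list(t)).as_array() for t in x_marginals])
    if xm.shape != (3, 3):
        raise ValueError("exactly three tenecteplase x-marginals required")
    xc = np.cumsum(xm, axis=1)[:, :2]
    lut = config.score_lut()

    parts: list[tuple[np.ndarray, np.ndarray, np.ndarray]] = []
    done = 0
    ci = 0
    while done < reps:
        b = min(_OC_BLOCK, reps - done)
        rng = substream(seed, "ocs", ci)
        u = rng.random((b, 3, m))
        X = (u > xc[:, 0][None, :, None]).astype(np.int8)
        X += u > xc[:, 1][None, :, None]
        del u
        res = simulate_selection_batch(lut[X], config)
        parts.append((res.n_first_elim, res.n_final, res.selected))
        done += b
        ci += 1
    n1 = np.concatenate([p[0] for p in parts])
    nf = np.concatenate([p[1] for p in parts])
    selected = np.concatenate([p[2] for p in parts])

    minn1 = np.where(n1 > 0, n1, m)
    minn = np.where(nf > 0, nf, m)
    t = 2 * minn + minn1
    completed = nf > 0

    def _mean_se(a: np.ndarray) -> tuple[float, float]:
        return float(a.mean()), float(a.std(ddof=1) / np.sqrt(reps))

    def _prop_se(p: float) -> float:
        return float(np.sqrt(p * (1.0 - p) / reps))

    p_cs = float(np.mean((selected == best_index) & completed))
    p_nw = float(np.mean(~completed))
    e_n1, se_n1 = _mean_se(minn1.astype(float))
    e_n, se_n = _mean_se(minn.astype(float))
    e_t, se_t = _mean_se(t.astype(float))
    mode_n = int(np.bincount(nf[completed]).argmax()) if completed.any() else m
    arm_probs = tuple(
        float(np.mean((selected == j) & completed)) for j in range(3)
    )
    return OCRow(
        label=label,
        reps=reps,
        p_cs=p_cs,
        p_cs_se=_prop_se(p_cs),
        p_incorrect=float(np.mean((selected != best_index) & completed)),
        p_no_winner=p_nw,
        p_no_winner_se=_prop_se(p_nw),
        e_min_n1_m=e_n1,
        e_min_n1_m_se=se_n1,
        e_min_n_m=e_n,
        e_min_n_m_se=se_n,
        median_n=float(np.median(minn)),
        mode_n=mode_n,
        e_t=e_t,
        e_t_se=se_t,
        arm_selection_probs=arm_probs,  # type: ignore[arg-type]
    )


# ---------------------------------------------------------------------------
# Single-trial wrappers
# ---------------------------------------------------------------------------


def _selection_result_from_batch(
    sel: SelectionBatch, i: int, config: SelectionConfig
) -> SelectionResult:
    m = config.truncation_m
    n1 = int(sel.n_first_elim[i]) or None
    n = int(sel.n_final[i]) or None
    return SelectionResult(
        selected=TNK_ARMS[int(sel.selected[i])] if n is not None else None,
        n_first_elim=n1,
        n_final=n,
        truncated=n is None,
        tnk_patients=int(sel.tnk_patients(m)[i]),
        survivors_at_truncation=(
            ()
            if n is not None
            else tuple(a for j, a in enumerate(TNK_ARMS) if sel.survivors[i, j])
        ),
    )


def _rejections_dict(res: _BatchResult, i: int) -> dict:
    return {
        e: {d: bool(res.rej[(e, d)][i]) for d in _DIRECTIONS} for e in _ENDPOINTS
    }


def simulate_full_trial(
    scheme: DistributionScheme,
    sel_cfg: Optional[SelectionConfig] = None,
    gs_cfg: Optional[GSConfig] = None,
    p2_cfg: Optional[Phase2Config] = None,
    rng=None,
) -> TrialResult:
    """Simulate one complete group-sequential trial under ``scheme``."""
    sel_cfg = sel_cfg or SelectionConfig()
    gs_cfg = gs_cfg or GSConfig()
    p2_cfg = p2_cfg or Phase2Config()
    rng = as_generator(rng)
    res = _simulate_trial_batch(
        scheme, 1, sel_cfg, gs_cfg, p2_cfg, "gs", rng, collect_details=True
    )
    d = res.details
    assert d is not None
    stage = int(res.stage[0])
    selection = _selection_result_from_batch(res.selection, 0, sel_cfg)

    if stage == _NO_WINNER:
        decision = Phase2Decision(status=UNPROMISING, scenario=None)
    else:
        a1 = int(d["a1"][0])
        tnk = ArmSummary(
            n_rapid=a1,
            ich_count=int(d["ich_t"][0]),
            n_rankin=a1,
            poor_count=int(d["poor_t"][0]),
            neither_count=a1 - int(d["poor_t"][0]) - int(d["good_t"][0]),
            good_count=int(d["good_t"][0]),
        )
        rtpa = ArmSummary(
            n_rapid=a1,
            ich_count=int(d["ich_r"][0]),
            n_rankin=a1,
            poor_count=int(d["poor_r"][0]),
            neither_count=a1 - int(d["poor_r"][0]) - int(d["good_r"][0]),
            good_count=int(d["good_r"][0]),
        )
        sig = frozenset(
            e for e, f in (("poor", d["rej1_poor"]), ("good", d["rej1_good"])) if f[0]
        )
        if stage == _I1:
            decision = Phase2Decision(
                status=STOP_SIGNIFICANT,
                scenario=classify_scenario(tnk, rtpa, p2_cfg.ich_scenario_threshold),
                significant_endpoints=sig,
            )
        else:
            decision = Phase2Decision(
                status=PROMISING if bool(d["prom1"][0]) else UNPROMISING,
                scenario=int(d["scen1"][0]),
                significant_endpoints=sig,
            )

    holm = None
    if res.reached_terminal[0]:
        holm = frozenset(
            e
            for e, f in (("poor", res.holm_poor), ("good", res.holm_good))
            if f[0]
        )
    return TrialResult(
        stop_stage=STAGE_NAMES[stage],
        selection=selection,
        decision=decision,
        rejections=_rejections_dict(res, 0),
        any_type1=bool(res.any_type1[0]),
        holm_rejected=holm,
    )


def simulate_fss_trial(
    scheme: DistributionScheme,
    sel_cfg: Optional[SelectionConfig] = None,
    gs_cfg: Optional[GSConfig] = None,
    rng=None,
) -> TrialResult:
    """Simulate one fixed-sample-size trial: selection, then a single
    terminal analysis at the full per-arm size with no futility or
    interim examination.  Truncation without a winner forces a uniform
    random selection among the survivors."""
    sel_cfg = sel_cfg or SelectionConfig()
    gs_cfg = gs_cfg or GSConfig()
    rng = as_generator(rng)
    res = _simulate_trial_batch(
        scheme, 1, sel_cfg, gs_cfg, Phase2Config(), "fss", rng
    )
    selection = _selection_result_from_batch(res.selection, 0, sel_cfg)
    holm = frozenset(
        e for e, f in (("poor", res.holm_poor), ("good", res.holm_good)) if f[0]
    )
    return TrialResult(
        stop_stage=STAGE_NAMES[_TERMINAL],
        selection=selection,
        decision=None,
        rejections=_rejections_dict(res, 0),
        any_type1=bool(res.any_type1[0]),
        holm_rejected=holm,
    )


# ---------------------------------------------------------------------------
# Type I error study
# ---------------------------------------------------------------------------

_STATS_COLUMNS = (
    "Mean",
    "Median",
    "Maximum",
    "Minimum",
    "Lower quartile",
    "Upper quartile",
    "Range",
    "Std Dev.",
)


@dataclass
class TypeISummary:
    """Per-scheme type I error rates plus descriptive statistics.

    ``per_scheme`` has one row per scheme with per-endpoint, either-
    endpoint, and signed-tail rejection rates; ``stats`` summarizes the
    poor / good / either rates across schemes.
    """

    per_scheme: pd.DataFrame
    stats: pd.DataFrame
    mode: str
    reps_per_scheme: int

    @property
    def mean_either(self) -> float:
        return float(self.stats.loc["either", "Mean"])

    @property
    def max_either(self) -> float:
        return float(self.stats.loc["either", "Maximum"])


def _describe(per_scheme: pd.DataFrame, variables: Sequence[str]) -> pd.DataFrame:
    rows = {}
    for v in variables:
        s = per_scheme[v]
        rows[v] = {
            "Mean": s.mean(),
            "Median": s.median(),
            "Maximum": s.max(),
            "Minimum": s.min(),
            "Lower quartile": s.quantile(0.25),
            "Upper quartile": s.quantile(0.75),
            "Range": s.max() - s.min(),
            "Std Dev.": s.std(ddof=1),
        }
    return pd.DataFrame.from_dict(rows, orient="index", columns=list(_STATS_COLUMNS))


def estimate_type1_errors(
    schemes: Sequence[DistributionScheme],
    reps_per_scheme: int,
    mode: str = "gs",
    sel_cfg: Optional[SelectionConfig] = None,
    gs_cfg: Optional[GSConfig] = None,
    p2_cfg: Optional[Phase2Config] = None,
    seed: int = 0,
) -> TypeISummary:
    """Estimate experiment-wise type I error rates over a null ensemble.

    For each scheme, the fraction of replications with a poor-endpoint
    rejection, a good-endpoint rejection, either (at least one type I
    error), and each signed tail.  Replications run in fixed-size blocks
    with one named substream per (scheme index, block), so results are
    deterministic in ``seed`` and independent of scheme processing order.
    """
    chunk = _BLOCK
    if mode not in ("gs", "fss"):
        raise ValueError(f"unknown mode {mode!r}")
    if reps_per_scheme < 1:
        raise ValueError("reps_per_scheme must be >= 1 (no data)")
    if not schemes:
        raise ValueError("at least one scheme required")
    sel_cfg = sel_cfg or SelectionConfig()
    gs_cfg = gs_cfg or GSConfig()
    p2_cfg = p2_cfg or Phase2Config()

    rows = []
    for si, scheme in enumerate(schemes):
        if not scheme.is_null:
            raise ValueError(f"scheme {si} is not null; type I error undefined")
        counts = {k: 0 for k in _FLAG_KEYS}
        either_n = 0
        poor_n = 0
        good_n = 0
        stop_p2_n = 0
        done = 0
        ci = 0
        while done < reps_per_scheme:
            b = min(chunk, reps_per_scheme - done)
            rng = substream(seed, "type1", mode, si, ci)
            res = _simulate_trial_batch(scheme, b, sel_cfg, gs_cfg, p2_cfg, mode, rng)
            for k in _FLAG_KEYS:
                counts[k] += int(res.rej[k].sum())
            poor_any = res.rej[("poor", "tnk_better")] | res.rej[("poor", "tnk_worse")]
            good_any = res.rej[("good", "tnk_better")] | res.rej[("good", "tnk_worse")]
            poor_n += int(poor_any.sum())
            good_n += int(good_any.sum())
            either_n += int((poor_any | good_any).sum())
            stop_p2_n += int((res.stage <= _NO_WINNER).sum())
            done += b
            ci += 1
        n = float(reps_per_scheme)
        rows.append(
            {
                "scheme": si,
                "poor": poor_n / n,
                "good": good_n / n,
                "either": either_n / n,
                "poor_tnk_better": counts[("poor", "tnk_better")] / n,
                "poor_tnk_worse": counts[("poor", "tnk_worse")] / n,
                "good_tnk_better": counts[("good", "tnk_better")] / n,
                "good_tnk_worse": counts[("good", "tnk_worse")] / n,
                "phase2_stop": stop_p2_n / n,
            }
        )
    per_scheme = pd.DataFrame(rows)
    stats = _describe(per_scheme, ["poor", "good", "either"])
    return TypeISummary(
        per_scheme=per_scheme,
        stats=stats,
        mode=mode,
        reps_per_scheme=reps_per_scheme,
    )
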