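"""Result tables and deterministic fixtures.

Writers render the two standard summaries — selection operating
characteristics (one row per characteristic, one column per scheme) and
type I error descriptive statistics — to CSV or JSON with fixed column
order and fixed precision (4 decimals for rates, 1 for expectations), so
a rerun from the same config and seed is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence, Union

import pandas as pd

from .engine import OCRow, TypeISummary
from .outcomes import ARMS, ArmLabel, CondMatrix, DistributionScheme, ProbTriple
from .schemes import table1_scheme

__all__ = [
    "oc_table",
    "type1_table",
    "write_results",
    "make_fixture_schemes",
    "LEAST_FAVORABLE_CONFIGS",
]

_OC_ROWS = (
    ("P[cs]", "p_cs", 4),
    ("E[min(N(1),m)]", "e_min_n1_m", 1),
    ("E[min(N,m)]", "e_min_n_m", 1),
    ("Median[N]", "median_n", 1),
    ("Mode[N]", "mode_n", 1),
    ("E[T]", "e_t", 1),
    ("P[no winner]", "p_no_winner", 4),
)


def oc_table(rows: Sequence[OCRow]) -> pd.DataFrame:
    """Selection operating characteristics, one column per scheme."""
    if not rows:
        raise ValueError("no rows to write")
    cols = {}
    for i, r in enumerate(rows):
        label = r.label or f"scheme{i + 1}"
        cols[label] = [round(float(getattr(r, attr)), nd) for _, attr, nd in _OC_ROWS]
    return pd.DataFrame(cols, index=[name for name, _, _ in _OC_ROWS])


def type1_table(summary: TypeISummary) -> pd.DataFrame:
    """Descriptive statistics of the per-scheme error rates (4 decimals)."""
    return summary.stats.round(4)


def write_results(
    obj: Union[Sequence[OCRow], TypeISummary, pd.DataFrame],
    path: Union[str, Path],
    format: str = None,
) -> None:
    """Write a result table as CSV or JSON (format inferred from suffix)."""
    path = Path(path)
    if format is None:
        format = "json" if path.suffix.lower() == ".json" else "csv"
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}")

    if isinstance(obj, TypeISummary):
        frame = type1_table(obj)
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        frame = oc_table(obj)

    if format == "csv":
        frame.to_csv(path, index=True, encoding="utf-8")
    else:
        payload = {idx: row.to_dict() for idx, row in frame.iterrows()}
        path.write_text(json.dumps(payload, indent=1))


#: The five least-favorable configurations of the selection study, as
#: (best, inferior, inferior) pairs of (P[MNI], P[ICH]).
LEAST_FAVORABLE_CONFIGS = (
    ((0.36, 0.06), (0.16, 0.06), (0.16, 0.06)),
    ((0.36, 0.06), (0.16, 0.02), (0.16, 0.02)),
    ((0.31, 0.06), (0.21, 0.06), (0.21, 0.06)),
    ((0.31, 0.06), (0.21, 0.02), (0.21, 0.02)),
    ((0.26, 0.06), (0.26, 0.06), (0.26, 0.06)),
)

_RTPA_X = ProbTriple(0.06, 0.68, 0.26)
_Y_REF = ProbTriple(0.40, 0.25, 0.35)


def _independence_scheme(
    x_by_arm: dict[ArmLabel, ProbTriple], y: ProbTriple
) -> DistributionScheme:
    cond = CondMatrix((y, y, y))
    return DistributionScheme(
        x_marginal=x_by_arm,
        y_marginal={a: y for a in ARMS},
        conditional={a: cond for a in ARMS},
        is_null=True,
    )


def make_fixture_schemes() -> list[DistributionScheme]:
    """Deterministic, seed-free null schemes for tests and demos.

    The first five carry the least-favorable rapid-response
    configurations with an independence conditional and a common Rankin
    marginal; then a degenerate-Rankin scheme (all mass on the middle
    category) and a safety-imbalance scheme in which the tenecteplase
    arms have a much higher ICH probability than rt-PA.
    """
    out = []
    for best, inf1, inf2 in LEAST_FAVORABLE_CONFIGS:
        x = dict(table1_scheme(best, inf1, inf2))
        x[ArmLabel.D] = _RTPA_X
        out.append(_independence_scheme(x, _Y_REF))

    degenerate_y = ProbTriple(0.0, 1.0, 0.0)
    x = dict(table1_scheme(*LEAST_FAVORABLE_CONFIGS[4]))
    x[ArmLabel.D] = _RTPA_X
    out.append(_independence_scheme(x, degenerate_y))

    risky_x = ProbTriple(0.30, 0.44, 0.26)
    safe_x = ProbTriple(0.01, 0.73, 0.26)
    out.append(
        _independence_scheme(
            {
                ArmLabel.A: risky_x,
                ArmLabel.B: risky_x,
                ArmLabel.C: risky_x,
                ArmLabel.D: safe_x,
            },
            _Y_REF,
        )
    )
    return out
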