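"""Decision-behaviour metrics: influence of AI, practice variation, advice distance.

The influence (weight-on-advice) metric follows the judge-advisor-system
tradition: with initial prescription P, AI-advised dose A and final
prescription F,

    I = (F - P) / (A - P)

so I = 0 means the advice was ignored and I = 1 means it was adopted.  The
metric is undefined when the advice (approximately) equals the initial
estimate; such trials are excluded from influence analyses and counted in QC.

Practice variation measures how much of an outlier a prescriber is: the
absolute distance from their pre-reveal dose to the group-mean pre-reveal
dose for the same scenario and drug (the mean includes the prescriber's own
dose; a leave-one-out variant is available).  Advice distance |F - A| is the
complementary adherence metric on the dose scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from clingaze.io import RATING_COLUMNS

#: dose-scale tolerance below which advice == initial estimate is degenerate
DEFAULT_EPSILON = {"fluid": 1.0, "vasopressor": 0.01}

BEHAVIOUR_COLUMNS = [
    "participant_id", "scenario_id", "condition", "drug",
    "influence_raw", "influence_clamped", "influence_defined",
    "practice_variation", "advice_distance",
]


@dataclass(frozen=True)
class Influence:
    raw: float          # NaN when undefined
    clamped: float      # winsorized to [0, 1]; NaN when undefined
    defined: bool


def influence_of_ai(
    initial: float, final: float, advice: float,
    epsilon: float = 0.0, clamp: bool = True,
) -> Influence:
    """Weight-on-advice I = (final - initial) / (advice - initial).

    Undefined (``defined=False``, NaN values) when |advice - initial| <=
    epsilon.  With ``clamp`` the headline value is winsorized to [0, 1];
    the raw value is always retained.
    """
    for v in (initial, final, advice):
        if not np.isfinite(v) or v < 0:
            raise ValueError("doses must be finite and non-negative")
    denom = advice - initial
    if abs(denom) <= epsilon:
        return Influence(float("nan"), float("nan"), False)
    raw = (final - initial) / denom + 0.0  # normalize signed zero
    clamped = min(max(raw, 0.0), 1.0) if clamp else raw
    return Influence(raw, clamped, True)


def practice_variation(doses: dict[str, float]) -> dict[str, float]:
    """Absolute distance of each prescriber's dose from the group mean.

    ``doses`` maps participant -> pre-reveal dose for one scenario x drug.
    The mean is over all participants, the prescriber included.
    """
    if len(doses) < 2:
        raise ValueError("practice variation needs at least 2 participants")
    mean = float(np.mean(list(doses.values())))
    return {p: abs(d - mean) for p, d in doses.items()}


def advice_distance(final: float, advice: float) -> float:
    """|final - advice| on the dose scale (lower = more adherent)."""
    if not (np.isfinite(final) and np.isfinite(advice)):
        raise ValueError("doses must be finite")
    return abs(final - advice)


def compute_behaviour(
    trials: pd.DataFrame,
    epsilon: dict[str, float] | None = None,
    clamp: bool = True,
    leave_one_out: bool = False,
) -> pd.DataFrame:
    """Behaviour metrics for every trial x drug row of a trials table."""
    epsilon = DEFAULT_EPSILON if epsilon is None else epsilon
    df = trials.copy()

    grp = df.groupby(["scenario_id", "drug"])["initial_dose"]
    mean = grp.transform("mean")
    if leave_one_out:
        n = grp.transform("count")
        if (n < 2).any():
            raise ValueError("leave-one-out variation needs >= 2 participants per group")
        mean = (mean * n - df["initial_dose"]) / (n - 1)
    elif (grp.transform("count") < 2).any():
        raise ValueError("practice variation needs >= 2 participants per scenario x drug")
    variation = (df["initial_dose"] - mean).abs()

    rows = []
    for i, rec in df.iterrows():
        eps = epsilon.get(rec["drug"], 0.0)
        inf = influence_of_ai(
            rec["initial_dose"], rec["final_dose"], rec["ai_dose"],
            epsilon=eps, clamp=clamp,
        )
        rows.append((
            rec["participant_id"], rec["scenario_id"], rec["condition"], rec["drug"],
            inf.raw, inf.clamped, inf.defined,
            float(variation.loc[i]),
            advice_distance(rec["final_dose"], rec["ai_dose"]),
        ))
    return pd.DataFrame(rows, columns=BEHAVIOUR_COLUMNS)


def join_behaviour_attention(
    behaviour: pd.DataFrame,
    attention: pd.DataFrame,
    trials: pd.DataFrame,
) -> tuple[pd.DataFrame, dict]:
    """One analysis row per participant x scenario x drug.

    Attaches AI-screen and explanation-panel attention metrics (fixation
    counts, blink rates, gaze proportions) and the post-hoc usefulness
    ratings to each behaviour row.  Missing values propagate; nothing is
    imputed.  Keys present on only one side are listed in the QC dict.
    """
    keys = ["participant_id", "scenario_id"]
    wide = attention.pivot_table(
        index=keys,
        columns="roi_id",
        values=["n_fixations", "blink_rate_bpm", "gaze_time_ms",
                "actual_gaze_proportion", "actual_to_chance_ratio"],
        aggfunc="first",
    )
    wide.columns = [f"{metric}__{roi}" for metric, roi in wide.columns]
    wide = wide.reset_index()

    ratings = trials[keys + ["drug"] + RATING_COLUMNS].drop_duplicates(keys + ["drug"])
    out = behaviour.merge(ratings, on=keys + ["drug"], how="left")
    out = out.merge(wide, on=keys, how="left", indicator=True)

    b_keys = set(map(tuple, behaviour[keys].drop_duplicates().itertuples(index=False)))
    a_keys = set(map(tuple, attention[keys].drop_duplicates().itertuples(index=False)))
    qc = {
        "behaviour_only_keys": sorted(b_keys - a_keys),
        "attention_only_keys": sorted(a_keys - b_keys),
    }
    out = out.drop(columns="_merge")
    return out, qc
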