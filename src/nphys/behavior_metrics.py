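"""Closed-form behavior statistics: Y-maze alternation, EPM percentages,
and gait footfall distances.

Y-maze spontaneous alternation counts sliding triads of three distinct
consecutive arm entries: ``alternation% = triads / (entries - 2) * 100``,
with the theoretical chance level ``100 * (n-1)/n * (n-2)/n`` (about 22%
for three arms). EPM percentages are dwell times divided by the trial
length (300 s). Gait metrics are means of labeled paw-pair distances
(A: left fore, B: left hind, C: right fore, D: right hind).
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

EPM_TRIAL_SECONDS = 300.0
ARM_LABELS = ("A", "B", "C")
# Paw-label mapping chosen so the metric formulas are anatomically
# coherent: AB and CD are ipsilateral fore-hind pairs (FP-HP distance),
# AC and BD are left-right pairs (stance width).
PAW_LABELS = ("A", "B", "C", "D")   # A: LF, B: LH, C: RF, D: RH


def alternation_percent(entries: str | list[str]) -> float:
    """Spontaneous alternation percentage of an arm-entry sequence.

    A spontaneous alternation is a window of three consecutive entries
    visiting three distinct arms; windows overlap, so the denominator is
    (number of entries - 2).
    """
    seq = list(entries)
    if len(seq) < 3:
        raise ValueError("need at least 3 arm entries")
    triads = sum(len({seq[i], seq[i + 1], seq[i + 2]}) == 3
                 for i in range(len(seq) - 2))
    return 100.0 * triads / (len(seq) - 2)


def chance_alternation(n_arms: int = 3) -> float:
    """Theoretical chance alternation%: 100 * (n-1)/n * (n-2)/n.

    For a three-arm maze this is the product 1 x 2/3 x 1/3, about 22%:
    after any entry, the second arm must differ (2 of 3 under uniform
    arm choice) and the third must differ from both (1 of 3).
    """
    if n_arms < 3:
        raise ValueError("need at least 3 arms")
    return 100.0 * (n_arms - 1) * (n_arms - 2) / n_arms**2


def simulate_chance_alternation(n_draws: int, *, n_arms: int = 3,
                                seed: int = 0) -> float:
    """Monte-Carlo estimate of the chance triad-success rate (percent).

    Draws independent uniform triads of arm entries and scores the
    fraction with three distinct arms — the model behind the closed-form
    chance level.
    """
    rng = np.random.default_rng(seed)
    arms = rng.integers(0, n_arms, size=(n_draws, 3))
    distinct = (arms[:, 0] != arms[:, 1]) & (arms[:, 0] != arms[:, 2]) \
        & (arms[:, 1] != arms[:, 2])
    return 100.0 * float(distinct.mean())


def epm_percentages(open_s: float, closed_s: float,
                    trial_s: float = EPM_TRIAL_SECONDS) -> dict:
    """Percent time in open and closed arms of the elevated plus maze.

    Each percentage is dwell time divided by the trial length (300 s);
    the remainder is the center area.
    """
    if open_s < 0 or closed_s < 0:
        raise ValueError("dwell times must be nonnegative")
    if open_s + closed_s > trial_s + 1e-9:
        raise ValueError("dwell times exceed the trial length")
    return {"open_pct": 100.0 * open_s / trial_s,
            "closed_pct": 100.0 * closed_s / trial_s,
            "center_pct": 100.0 * (trial_s - open_s - closed_s) / trial_s}


# ---------------------------------------------------------------------
# gait
# ---------------------------------------------------------------------

def footfall_distances(footfalls: pd.DataFrame) -> dict[str, float]:
    """Mean pairwise paw distances from a labeled footfall table.

    ``footfalls`` has columns ``step_index, paw_label, x_cm, y_cm``.
    Cross-paw distances (AB, CD, AC, BD) are measured within each step
    cycle and averaged over cycles; same-paw distances (AA..DD) are
    stride lengths between consecutive placements of that paw.
    """
    pos = {(int(r.step_index), r.paw_label): np.array([r.x_cm, r.y_cm])
           for r in footfalls.itertuples()}
    cycles = sorted({i for i, _ in pos})
    dists: dict[str, float] = {}
    for p, q in itertools.combinations(PAW_LABELS, 2):
        d = [np.linalg.norm(pos[(i, p)] - pos[(i, q)]) for i in cycles
             if (i, p) in pos and (i, q) in pos]
        if d:
            dists[p + q] = float(np.mean(d))
    for p in PAW_LABELS:
        steps = [pos[(i, p)] for i in cycles if (i, p) in pos]
        if len(steps) >= 2:
            d = [np.linalg.norm(b - a) for a, b in zip(steps, steps[1:])]
            dists[p + p] = float(np.mean(d))
    return dists


def gait_metrics(footfalls: pd.DataFrame | dict[str, float]) -> dict:
    """Gait summary: FP-HP distance, step length, stance width,
    alternation coefficient.

    fp_hp = mean(AB, CD); step_length = mean(AA, BB, CC, DD);
    stance_width = mean(AC, BD); alternation_coefficient = AB/BD
    (None when BD is 0).
    """
    d = footfalls if isinstance(footfalls, dict) \
        else footfall_distances(footfalls)
    need = ["AB", "CD", "AC", "BD", "AA", "BB", "CC", "DD"]
    missing = [k for k in need if k not in d]
    if missing:
        raise ValueError(f"missing pairwise distances: {missing}")
    coeff = d["AB"] / d["BD"] if d["BD"] != 0 else None
    return {"fp_hp_distance": float(np.mean([d["AB"], d["CD"]])),
            "step_length": float(np.mean([d[p * 2] for p in PAW_LABELS])),
            "stance_width": float(np.mean([d["AC"], d["BD"]])),
            "alternation_coefficient": coeff}


# ---------------------------------------------------------------------
# tabular wrappers
# ---------------------------------------------------------------------

def ymaze_table(df: pd.DataFrame) -> pd.DataFrame:
    """Per-subject alternation% from a `subject,session,entries` table."""
    rows = [{"subject": r.subject, "session": r.session,
             "n_entries": len(str(r.entries)),
             "alternation_pct": alternation_percent(str(r.entries))}
            for r in df.itertuples()]
    return pd.DataFrame(rows)


def epm_table(df: pd.DataFrame,
              trial_s: float = EPM_TRIAL_SECONDS) -> pd.DataFrame:
    rows = []
    for r in df.itertuples():
        pct = epm_percentages(r.open_s, r.closed_s, trial_s)
        rows.append({"subject": r.subject, **pct,
                     "total_entries": getattr(r, "total_entries", None)})
    return pd.DataFrame(rows)


def gait_table(footfalls: pd.DataFrame) -> pd.DataFrame:
    rows = []
    for subject, grp in footfalls.groupby("subject"):
        rows.append({"subject": subject, **gait_metrics(grp)})
    return pd.DataFrame(rows)
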