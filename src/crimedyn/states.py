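"""Assign person-wave panel records to the five model states.

Input panels are long-format DataFrames with columns
``person_id, wave, age, sex, race, offended, arrested`` (flags 0/1).
State assignment uses each person's full observed history:

1. arrested this wave                                      -> ``A``
2. never arrested, offended this wave                      -> ``C1``
3. never arrested, inactive this wave                      -> ``X``
4. arrest history, offended this wave                      -> ``C2``
5. arrest history, inactive, streak < 3 years              -> ``R``
6. arrest history, inactive for >= 3 consecutive years     -> ``X``

"Inactive" means neither offended nor arrested in that year.  For early
waves where a full 3-year lookback is unavailable, only the available
history is used (so a person arrested at wave 1 cannot reach the
rehabilitated ``X`` before wave 4).  Waves with missing flags are
excluded (never imputed) and counted in the returned diagnostics.
"""

from __future__ import annotations

import logging
from collections.abc import Sequence

import numpy as np
import pandas as pd

from .model import ADMISSIBLE_ARROWS, STATES, TransitionParameters

__all__ = [
    "PANEL_COLUMNS",
    "assign_state",
    "assign_states",
    "build_transitions",
    "transition_indicators",
    "EmpiricalMatrix",
    "empirical_matrix",
]

logger = logging.getLogger(__name__)

PANEL_COLUMNS = ("person_id", "wave", "age", "sex", "race", "offended", "arrested")

_STATE_INDEX = {s: i for i, s in enumerate(STATES)}


def _states_for_person(offended: Sequence[int], arrested: Sequence[int]):
    """States, ever-arrested flags and inactive streaks for one person.

    ``offended`` and ``arrested`` are wave-ordered 0/1 flags.
    Returns (states, ever_arrested, streaks, n_late_reoffend) where
    ``n_late_reoffend`` counts waves where offending resumed after a
    completed 3-year inactive window (a rare, history-inconsistent
    pattern in self-report data).
    """
    states: list[str] = []
    evers: list[int] = []
    streaks: list[int] = []
    ever = False
    streak = 0
    n_late = 0
    for off, arr in zip(offended, arrested):
        off = int(off)
        arr = int(arr)
        inactive = (off == 0 and arr == 0)
        if ever and streak >= 3 and off == 1:
            n_late += 1
        streak = streak + 1 if inactive else 0
        ever = ever or arr == 1
        if arr == 1:
            state = "A"
        elif not ever:
            state = "C1" if off == 1 else "X"
        elif off == 1:
            state = "C2"
        else:
            state = "R" if streak < 3 else "X"
        states.append(state)
        evers.append(int(ever))
        streaks.append(streak)
    return states, evers, streaks, n_late


def assign_state(offended: Sequence[int], arrested: Sequence[int]) -> str:
    """State at the final wave of one person's flag history."""
    if len(offended) == 0 or len(offended) != len(arrested):
        raise ValueError("offense and arrest histories must be nonempty and equal-length")
    return _states_for_person(offended, arrested)[0][-1]


def assign_states(panel: pd.DataFrame) -> pd.DataFrame:
    """Per-person-wave state assignments for a whole panel.

    Returns a DataFrame with columns
    ``person_id, wave, state, ever_arrested, inactive_streak``, sorted
    by person and wave.  Records with missing offense or arrest flags
    are excluded and logged; counts are exposed via ``result.attrs``:

    - ``n_excluded_missing``: person-waves dropped for missing flags
    - ``n_late_reoffend``: offenses resuming after a completed 3-year
      inactive window
    """
    missing = [c for c in ("person_id", "wave", "offended", "arrested")
               if c not in panel.columns]
    if missing:
        raise ValueError(f"panel is missing required column(s): {missing}")
    df = panel.sort_values(["person_id", "wave"], kind="stable")
    bad = df["offended"].isna() | df["arrested"].isna()
    n_excluded = int(bad.sum())
    if n_excluded:
        logger.warning("excluding %d person-wave(s) with missing flags", n_excluded)
        df = df.loc[~bad]
    dup = df.duplicated(["person_id", "wave"])
    if dup.any():
        raise ValueError(f"duplicate (person_id, wave) pairs: {int(dup.sum())}")

    df = df.reset_index(drop=True)
    off = df["offended"].to_numpy(dtype=int)
    arr = df["arrested"].to_numpy(dtype=int)
    pid = df["person_id"].to_numpy()
    n = len(df)

    ever = df.groupby("person_id", sort=False)["arrested"].cummax().to_numpy(dtype=bool)
    # inactive streak: distance to the last active wave (or person start)
    pos = np.arange(n)
    active = (off == 1) | (arr == 1)
    is_start = np.empty(n, dtype=bool)
    if n:
        is_start[0] = True
        is_start[1:] = pid[1:] != pid[:-1]
    barrier = np.where(active, pos, -1)
    barrier[is_start & ~active] = pos[is_start & ~active] - 1
    last_active = np.maximum.accumulate(barrier) if n else barrier
    streak = pos - last_active

    state = np.empty(n, dtype=object)
    state[arr == 1] = "A"
    never = ~ever
    state[never & (off == 1)] = "C1"
    state[never & (off == 0)] = "X"
    prior = ever & (arr == 0)
    state[prior & (off == 1)] = "C2"
    state[prior & (off == 0) & (streak < 3)] = "R"
    state[prior & (off == 0) & (streak >= 3)] = "X"

    # diagnostics: offending resumed after a completed 3-year inactive window
    prev_streak = np.zeros(n, dtype=int)
    prev_ever = np.zeros(n, dtype=bool)
    if n > 1:
        prev_streak[1:] = streak[:-1]
        prev_ever[1:] = ever[:-1]
    prev_streak[is_start] = 0
    prev_ever[is_start] = False
    n_late_total = int((prev_ever & (prev_streak >= 3) & (off == 1)).sum())

    result = pd.DataFrame({
        "person_id": pid,
        "wave": df["wave"].to_numpy(),
        "state": state,
        "ever_arrested": ever.astype(int),
        "inactive_streak": streak,
    })
    if n_late_total:
        logger.info("%d wave(s) resumed offending after a 3-year inactive window",
                    n_late_total)
    result.attrs["n_excluded_missing"] = n_excluded
    result.attrs["n_late_reoffend"] = n_late_total
    return result


def build_transitions(states: pd.DataFrame) -> pd.DataFrame:
    """Wave-to-wave transition outcomes from assigned states.

    One row per person per *consecutive* wave pair, with columns
    ``person_id, from_wave, from_state, to_state, transition``.  Pairs
    separated by a wave gap are skipped and counted
    (``attrs["n_gap_skipped"]``); observed pairs that do not lie on an
    admissible arrow are rejected and counted
    (``attrs["n_inadmissible"]``).
    """
    df = states.sort_values(["person_id", "wave"], kind="stable")
    same_person = df["person_id"].to_numpy()[1:] == df["person_id"].to_numpy()[:-1]
    wave = df["wave"].to_numpy()
    consecutive = wave[1:] == wave[:-1] + 1
    paired = same_person & consecutive
    n_gaps = int((same_person & ~consecutive).sum())
    if n_gaps:
        logger.warning("skipping %d wave pair(s) with gaps", n_gaps)

    from_rows = df.iloc[:-1][paired]
    to_rows = df.iloc[1:][paired]
    out = pd.DataFrame({
        "person_id": from_rows["person_id"].to_numpy(),
        "from_wave": from_rows["wave"].to_numpy(),
        "from_state": from_rows["state"].to_numpy(),
        "to_state": to_rows["state"].to_numpy(),
    })
    admissible = [
        (f, t) in ADMISSIBLE_ARROWS
        for f, t in zip(out["from_state"], out["to_state"])
    ]
    admissible = np.asarray(admissible, dtype=bool)
    n_bad = int((~admissible).sum())
    if n_bad:
        logger.warning("rejecting %d inadmissible observed transition(s)", n_bad)
        out = out.loc[admissible].reset_index(drop=True)
    out["transition"] = out["from_state"] + "->" + out["to_state"]
    out.attrs["n_gap_skipped"] = n_gaps
    out.attrs["n_inadmissible"] = n_bad
    return out


def transition_indicators(transitions: pd.DataFrame) -> pd.DataFrame:
    """One-hot columns for the 16 admissible arrows (exactly one 1 per row)."""
    arrows = sorted(f"{f}->{t}" for f, t in ADMISSIBLE_ARROWS)
    onehot = pd.DataFrame(
        {a: (transitions["transition"] == a).astype(int) for a in arrows}
    )
    return pd.concat(
        [transitions[["person_id", "from_wave"]].reset_index(drop=True), onehot],
        axis=1,
    )


class EmpiricalMatrix:
    """Row-normalized empirical transition matrix with origin counts.

    ``matrix`` rows for unobserved origin states are NaN and listed in
    ``undefined_rows``; converting such a matrix to
    :class:`TransitionParameters` is refused.
    """

    def __init__(self, matrix: np.ndarray, row_counts: np.ndarray):
        self.matrix = matrix
        self.row_counts = row_counts
        self.undefined_rows = tuple(
            STATES[i] for i in range(5) if row_counts[i] == 0
        )

    def to_params(self, label: str | None = None) -> TransitionParameters:
        if self.undefined_rows:
            raise ValueError(
                f"origin state(s) {self.undefined_rows} have no observations; "
                "equilibrium computation refused"
            )
        from .model import params_from_matrix

        return params_from_matrix(self.matrix, label=label)

    def __repr__(self) -> str:  # pragma: no cover
        return (f"EmpiricalMatrix(n={int(self.row_counts.sum())}, "
                f"undefined={self.undefined_rows})")


def empirical_matrix(transitions: pd.DataFrame,
                     panel: pd.DataFrame | None = None,
                     sex: str | None = None,
                     race: str | None = None) -> EmpiricalMatrix:
    """Count-based transition matrix, optionally for one sex/race subgroup.

    Subgroup filtering requires ``panel`` (for the demographic columns);
    demographics are taken as time-invariant per person.  Rows sum to 1
    exactly by construction; structural zeros hold because inadmissible
    pairs never enter ``transitions``.
    """
    df = transitions
    if sex is not None or race is not None:
        if panel is None:
            raise ValueError("subgroup filtering requires the panel DataFrame")
        demo = panel.drop_duplicates("person_id").set_index("person_id")
        keep = pd.Series(True, index=demo.index)
        if sex is not None:
            keep &= demo["sex"] == sex
        if race is not None:
            keep &= demo["race"] == race
        df = df[df["person_id"].isin(demo.index[keep])]

    counts = np.zeros((5, 5))
    for (f, t), n in df.groupby(["from_state", "to_state"]).size().items():
        counts[_STATE_INDEX[f], _STATE_INDEX[t]] = n
    row_counts = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        matrix = counts / row_counts[:, None]
    matrix[row_counts == 0] = np.nan
    return EmpiricalMatrix(matrix, row_counts)
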