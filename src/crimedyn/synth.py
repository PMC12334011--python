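"""Synthetic longitudinal panels with the structure the analysis assumes.

Two generating modes:

``markov``
    The latent state sequence is exactly the five-state chain defined by
    the configured :class:`~crimedyn.model.TransitionParameters` (all 11
    rates free, including R->X).  This tests the dynamical-model half of
    the pipeline; state assignment applied to the observables is *not*
    guaranteed to round-trip, because the chain's R->X flow ignores the
    3-year-window definition.

``history``
    R->X is never drawn from its configured rate; instead rehabilitation
    occurs deterministically when the inactive streak reaches 3 years,
    and an ever-arrested person in X who resumes offending moves to C2
    (not C1).  The R->X rate becomes emergent
    (:func:`emergent_rehab_rate`) and state assignment round-trips
    exactly on the observables.

Observables per person-wave: ``arrested`` = (latent state == A);
``offended`` = 1 in C1/C2, Bernoulli(p_offend_given_a) in A, 0 in X/R.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections.abc import Mapping

import numpy as np
import pandas as pd

from .model import STATES, ParameterError, TransitionParameters, make_matrix

__all__ = ["SynthConfig", "generate_panel", "emergent_rehab_rate"]

_X, _C1, _A, _R, _C2 = range(5)
_CRIMEWARD = np.array([False, True, True, False, True])  # C1, A, C2

#: Round 1 full-sample state mix (X, C1, A, R, C2).
DEFAULT_INITIAL = (0.855, 0.079, 0.041, 0.013, 0.012)

DEFAULT_RACE_PROBS = {"Black": 0.26, "White": 0.519, "Hispanic": 0.212}


@dataclass
class SynthConfig:
    """Configuration for :func:`generate_panel`."""

    n_persons: int
    params: TransitionParameters | Mapping
    n_waves: int = 7
    p_man: float = 0.51
    race_probs: Mapping = field(default_factory=lambda: dict(DEFAULT_RACE_PROBS))
    age_low: int = 12
    age_high: int = 17
    random_intercept_sd: float = 0.0
    age_slope: float = 0.0        # per-year (age-16) shift on crime-ward logits
    age_curvature: float = 0.0    # per-year^2 (age-16)^2 shift
    p_offend_given_a: float = 0.7
    initial_distribution: tuple = DEFAULT_INITIAL
    mode: str = "markov"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_persons <= 0 or self.n_waves <= 0:
            raise ValueError("n_persons and n_waves must be positive")
        if self.mode not in ("markov", "history"):
            raise ValueError(f"mode must be 'markov' or 'history', got {self.mode!r}")
        if not (0 <= self.p_man <= 1 and 0 <= self.p_offend_given_a <= 1):
            raise ValueError("probabilities must lie in [0, 1]")
        if self.random_intercept_sd < 0:
            raise ValueError("random_intercept_sd must be >= 0")
        init = np.asarray(self.initial_distribution, dtype=float)
        if init.shape != (5,) or np.any(init < 0) or init.sum() <= 0:
            raise ValueError("initial_distribution must be 5 nonnegative fractions")

    def params_for(self, sex: str, race: str) -> TransitionParameters:
        if isinstance(self.params, TransitionParameters):
            return self.params
        try:
            return self.params[(sex, race)]
        except KeyError:
            raise KeyError(
                f"no transition parameters configured for subgroup ({sex}, {race})"
            ) from None


def _row_for(params: TransitionParameters, state: int, mode: str,
             ever: bool) -> np.ndarray:
    """Base destination probabilities for one (state, history) cell."""
    row = make_matrix(params)[state].copy()
    if mode == "history":
        if state == _R:
            # rehabilitation is emergent, not drawn: reallocate eps_rx to stay
            row[_X] = 0.0
            row[_R] = 1.0 - params.alpha_r2 - params.alpha_ra
        elif state == _X and ever:
            # a rehabilitated person cannot re-enter C1 (it requires no
            # arrest history) and X->C2 is not an admissible arrow, so the
            # no-arrest onset flow is reallocated to staying in X; re-entry
            # into crime for this group happens only through X->A
            row[_X] += row[_C1]
            row[_C1] = 0.0
    return row


def _sample_destinations(row: np.ndarray, shift: np.ndarray,
                         rng: np.random.Generator) -> np.ndarray:
    """Draw destinations for persons sharing a base row.

    ``shift`` (one value per person) perturbs the logits of the
    crime-ward destinations (C1, A, C2) with a shared unit loading,
    followed by softmax renormalization over the row's support.
    """
    support = np.nonzero(row > 0)[0]
    n = shift.shape[0]
    if np.all(shift == 0) or support.size == 1:
        cum = np.cumsum(row[support])
        draws = np.searchsorted(cum, rng.random(n) * cum[-1], side="right")
        return support[np.minimum(draws, support.size - 1)]
    logits = np.log(row[support])[None, :] + np.where(
        _CRIMEWARD[support][None, :], shift[:, None], 0.0
    )
    logits -= logits.max(axis=1, keepdims=True)
    probs = np.exp(logits)
    probs /= probs.sum(axis=1, keepdims=True)
    cum = np.cumsum(probs, axis=1)
    u = rng.random(n)
    idx = (cum < u[:, None]).sum(axis=1)
    return support[np.minimum(idx, support.size - 1)]


def generate_panel(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a panel of observables plus the latent state truth.

    Returns ``(panel, truth)``: the panel has columns
    ``person_id, wave, age, sex, race, offended, arrested``; the truth
    has ``person_id, wave, state, ever_arrested, inactive_streak``.
    Identical configs (including seed) reproduce identical output.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_persons

    sex = np.where(rng.random(n) < config.p_man, "man", "woman")
    races = list(config.race_probs)
    rp = np.asarray([config.race_probs[r] for r in races], dtype=float)
    race = np.asarray(races)[rng.choice(len(races), size=n, p=rp / rp.sum())]
    age0 = rng.integers(config.age_low, config.age_high + 1, size=n)
    u = (rng.normal(0.0, config.random_intercept_sd, size=n)
         if config.random_intercept_sd > 0 else np.zeros(n))

    init = np.asarray(config.initial_distribution, dtype=float)
    if config.mode == "history":
        # R/C2 presuppose an unobserved pre-panel arrest; start in X/C1/A
        init = init.copy()
        init[[_R, _C2]] = 0.0
    init = init / init.sum()
    state = rng.choice(5, size=n, p=init)

    ever = np.isin(state, [_A, _R, _C2])
    streak = np.zeros(n, dtype=int)

    # subgroup cells share a parameter set
    if isinstance(config.params, TransitionParameters):
        cell_of = np.zeros(n, dtype=int)
        cell_params = [config.params]
    else:
        cells = sorted({(s, r) for s, r in zip(sex, race)})
        cell_index = {c: i for i, c in enumerate(cells)}
        cell_of = np.asarray([cell_index[(s, r)] for s, r in zip(sex, race)])
        cell_params = [config.params_for(s, r) for s, r in cells]
    for p in cell_params:
        if min(p.stay_probabilities().values()) < 0:
            raise ParameterError("configured parameters imply a negative stay probability")

    states_out = np.empty((config.n_waves, n), dtype=int)
    offended_out = np.zeros((config.n_waves, n), dtype=int)
    arrested_out = np.zeros((config.n_waves, n), dtype=int)
    ever_out = np.empty((config.n_waves, n), dtype=int)
    streak_out = np.empty((config.n_waves, n), dtype=int)

    for w in range(config.n_waves):
        if w > 0:
            nxt = np.empty(n, dtype=int)
            age_c = (age0 + w - 16).astype(float)
            shift_all = u + config.age_slope * age_c + config.age_curvature * age_c ** 2
            for ci in range(len(cell_params)):
                for s in range(5):
                    for ev in (False, True):
                        mask = (cell_of == ci) & (state == s) & (ever == ev)
                        if not mask.any():
                            continue
                        row = _row_for(cell_params[ci], s, config.mode, ev)
                        nxt[mask] = _sample_destinations(row, shift_all[mask], rng)
            if config.mode == "history":
                # a second consecutive inactive year in R completes the window
                done = (state == _R) & (nxt == _R) & (streak >= 2)
                nxt[done] = _X
            state = nxt

        arrested = (state == _A).astype(int)
        offended = np.isin(state, [_C1, _C2]).astype(int)
        in_a = state == _A
        if in_a.any():
            offended[in_a] = (rng.random(int(in_a.sum()))
                              < config.p_offend_given_a).astype(int)
        inactive = (offended == 0) & (arrested == 0)
        streak = np.where(inactive, streak + 1, 0)
        ever = ever | (arrested == 1)

        states_out[w] = state
        offended_out[w] = offended
        arrested_out[w] = arrested
        ever_out[w] = ever.astype(int)
        streak_out[w] = streak

    person_id = np.repeat(np.arange(1, n + 1), config.n_waves)
    wave = np.tile(np.arange(1, config.n_waves + 1), n)
    order = lambda m: m.T.reshape(-1)  # noqa: E731  (wave-major -> person-major)
    panel = pd.DataFrame({
        "person_id": person_id,
        "wave": wave,
        "age": np.repeat(age0, config.n_waves) + np.tile(np.arange(config.n_waves), n),
        "sex": np.repeat(sex, config.n_waves),
        "race": np.repeat(race, config.n_waves),
        "offended": order(offended_out),
        "arrested": order(arrested_out),
    })
    truth = pd.DataFrame({
        "person_id": person_id,
        "wave": wave,
        "state": np.asarray(STATES)[order(states_out)],
        "ever_arrested": order(ever_out),
        "inactive_streak": order(streak_out),
    })
    return panel, truth


def emergent_rehab_rate(config_or_params) -> float:
    """Implied rehabilitation rate of history mode.

    The probability that a person entering R completes the 3-year
    inactive window before recidivating: two further consecutive
    inactive years, each survived with probability
    ``1 - alpha_r2 - alpha_ra``.
    """
    p = (config_or_params.params
         if isinstance(config_or_params, SynthConfig) else config_or_params)
    if not isinstance(p, TransitionParameters):
        raise TypeError("expected a SynthConfig with a single TransitionParameters "
                        "or a TransitionParameters instance")
    survive = 1.0 - p.alpha_r2 - p.alpha_ra
    return survive ** 2
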