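"""Five-state linear compartmental model of criminal involvement.

States, in fixed order everywhere (vectors, matrices, files):

==========  =====================================================
``X``       criminally inactive, no recent arrest history
            (never involved, or rehabilitated after >= 3
            inactive years)
``C1``      criminally active, never arrested
``A``       arrested within the last year
``R``       inactive within the last year, but active within the
            last three years, with an arrest history
``C2``      criminally active with a past (not current) arrest
==========  =====================================================

The dynamics are a discrete-time (annual) row-stochastic chain on these
five states with structural zeros: ``X`` and ``C1`` cannot reach
``R``/``C2`` in one step (those require a prior arrest), ``A`` and
``C2`` cannot reach ``X`` or ``C1`` in one step, and no previously
arrested state can ever return to ``C1``.

Eleven flow rates are free; the five stay probabilities are their
per-row complements and are never stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "STATES",
    "PARAM_NAMES",
    "StateVector",
    "TransitionParameters",
    "EquilibriumResult",
    "ParameterError",
    "DegenerateEquilibriumError",
    "make_matrix",
    "validate_matrix",
    "params_from_matrix",
    "step",
    "simulate",
    "equilibrium_closed_form",
    "equilibrium_solve",
]

#: Canonical state ordering.
STATES = ("X", "C1", "A", "R", "C2")

#: Canonical arrow names for the 11 free transition parameters.
PARAM_NAMES = (
    "X->C1",
    "X->A",
    "C1->X",
    "C1->A",
    "A->C2",
    "A->R",
    "C2->A",
    "C2->R",
    "R->C2",
    "R->A",
    "R->X",
)

# arrow name -> dataclass attribute
_ARROW_TO_ATTR = {
    "X->C1": "alpha_x1",
    "X->A": "alpha_xa",
    "C1->X": "beta_1x",
    "C1->A": "gamma_1a",
    "A->C2": "zeta_a2",
    "A->R": "beta_ar",
    "C2->A": "gamma_2a",
    "C2->R": "beta_2r",
    "R->C2": "alpha_r2",
    "R->A": "alpha_ra",
    "R->X": "epsilon_rx",
}
_ATTR_TO_ARROW = {v: k for k, v in _ARROW_TO_ATTR.items()}

#: admissible (from, to) arrows including the five stays
ADMISSIBLE_ARROWS = frozenset(
    [("X", "X"), ("X", "C1"), ("X", "A"),
     ("C1", "X"), ("C1", "C1"), ("C1", "A"),
     ("A", "A"), ("A", "R"), ("A", "C2"),
     ("R", "X"), ("R", "A"), ("R", "R"), ("R", "C2"),
     ("C2", "A"), ("C2", "R"), ("C2", "C2")]
)


class ParameterError(ValueError):
    """Invalid transition-parameter configuration."""


class DegenerateEquilibriumError(ArithmeticError):
    """The closed-form equilibrium denominator is zero (degenerate chain)."""


@dataclass(frozen=True)
class StateVector:
    """Population fractions in the five states at one time step.

    Components are normalized to sum to 1 on construction; a vector of
    all zeros is rejected.
    """

    x: float
    c1: float
    a: float
    r: float
    c2: float
    t: int = 0

    def __post_init__(self) -> None:
        vals = (self.x, self.c1, self.a, self.r, self.c2)
        if any(v < -1e-12 or not math.isfinite(v) for v in vals):
            raise ValueError(f"state components must be finite and >= 0, got {vals}")
        total = sum(vals)
        if total <= 0:
            raise ValueError("state components sum to zero; cannot normalize")
        if abs(total - 1.0) > 1e-9:
            object.__setattr__(self, "x", self.x / total)
            object.__setattr__(self, "c1", self.c1 / total)
            object.__setattr__(self, "a", self.a / total)
            object.__setattr__(self, "r", self.r / total)
            object.__setattr__(self, "c2", self.c2 / total)

    @classmethod
    def from_array(cls, arr, t: int = 0) -> "StateVector":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (5,):
            raise ValueError(f"expected 5 components, got shape {arr.shape}")
        return cls(*arr, t=t)

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.c1, self.a, self.r, self.c2])

    def as_dict(self) -> dict:
        return dict(zip(STATES, self.as_array()))


@dataclass(frozen=True)
class TransitionParameters:
    """The 11 free per-year flow rates; stay probabilities are derived.

    Attribute names follow the flow they govern (``alpha_x1`` is the
    X->C1 onset rate, etc.); arrow-string access is available through
    :meth:`value` and :meth:`from_dict` using the canonical names in
    :data:`PARAM_NAMES`.
    """

    alpha_x1: float  # X->C1 onset
    alpha_xa: float  # X->A onset with same-year arrest
    beta_1x: float   # C1->X desistance, never arrested
    gamma_1a: float  # C1->A first arrest
    zeta_a2: float   # A->C2 continued offending after arrest
    beta_ar: float   # A->R desistance after arrest
    gamma_2a: float  # C2->A re-arrest
    beta_2r: float   # C2->R desistance with arrest history
    alpha_r2: float  # R->C2 recidivism without arrest
    alpha_ra: float  # R->A recidivism with same-year arrest
    epsilon_rx: float  # R->X rehabilitation (3 inactive years)
    label: str | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        for f in fields(self):
            if f.name == "label":
                continue
            v = getattr(self, f.name)
            if not (0.0 <= v <= 1.0) or not math.isfinite(v):
                raise ParameterError(
                    f"parameter {_ATTR_TO_ARROW[f.name]} = {v!r} outside [0, 1]"
                )
        for state, sigma in self.stay_probabilities().items():
            if sigma < -1e-12:
                raise ParameterError(
                    f"outflows from state {state} sum to {1 - sigma:.6g} > 1 "
                    f"(stay probability would be negative)"
                )

    # -- stay probabilities ------------------------------------------------
    @property
    def sigma_xx(self) -> float:
        return 1.0 - self.alpha_x1 - self.alpha_xa

    @property
    def sigma_11(self) -> float:
        return 1.0 - self.beta_1x - self.gamma_1a

    @property
    def sigma_aa(self) -> float:
        return 1.0 - self.zeta_a2 - self.beta_ar

    @property
    def sigma_22(self) -> float:
        return 1.0 - self.gamma_2a - self.beta_2r

    @property
    def sigma_rr(self) -> float:
        return 1.0 - self.alpha_r2 - self.alpha_ra - self.epsilon_rx

    def stay_probabilities(self) -> dict:
        return {
            "X": self.sigma_xx,
            "C1": self.sigma_11,
            "A": self.sigma_aa,
            "C2": self.sigma_22,
            "R": self.sigma_rr,
        }

    # -- arrow-name access -------------------------------------------------
    def value(self, name: str) -> float:
        """Value of a free parameter by its arrow name (e.g. ``"X->A"``)."""
        try:
            return getattr(self, _ARROW_TO_ATTR[name])
        except KeyError:
            raise KeyError(
                f"unknown parameter {name!r}; expected one of {list(PARAM_NAMES)}"
            ) from None

    def replace(self, name: str, value: float) -> "TransitionParameters":
        """A copy with the named free parameter set to ``value``.

        The source state's stay probability absorbs the change; all
        other free parameters are untouched.
        """
        if name not in _ARROW_TO_ATTR:
            raise KeyError(
                f"unknown parameter {name!r}; expected one of {list(PARAM_NAMES)}"
            )
        return replace(self, **{_ARROW_TO_ATTR[name]: value})

    def as_dict(self) -> dict:
        d = {arrow: getattr(self, attr) for arrow, attr in _ARROW_TO_ATTR.items()}
        if self.label is not None:
            d["label"] = self.label
        return d

    @classmethod
    def from_dict(cls, d: dict, label: str | None = None) -> "TransitionParameters":
        missing = [k for k in PARAM_NAMES if k not in d]
        if missing:
            raise ParameterError(f"missing parameter key(s): {missing}")
        kwargs = {_ARROW_TO_ATTR[k]: float(d[k]) for k in PARAM_NAMES}
        return cls(label=d.get("label", label), **kwargs)

    def as_array(self) -> np.ndarray:
        """The 11 free parameters in :data:`PARAM_NAMES` order."""
        return np.array([self.value(n) for n in PARAM_NAMES])

    @classmethod
    def from_array(cls, arr, label: str | None = None) -> "TransitionParameters":
        arr = np.asarray(arr, dtype=float)
        if arr.shape != (11,):
            raise ValueError(f"expected 11 parameters, got shape {arr.shape}")
        return cls.from_dict(dict(zip(PARAM_NAMES, arr)), label=label)

    def is_interior(self, eps: float = 0.0) -> bool:
        """All free parameters strictly inside (0, 1) and all stays > 0."""
        vals = self.as_array()
        if not np.all((vals > eps) & (vals < 1 - eps)):
            return False
        return all(s > eps for s in self.stay_probabilities().values())


@dataclass(frozen=True)
class EquilibriumResult:
    """Stationary distribution of the chain plus diagnostics."""

    state_star: StateVector
    x_star: float
    crime_rate: float
    denominator_d: float
    n_steps_to_converge: int | str
    unique: bool = True


def make_matrix(params: TransitionParameters) -> np.ndarray:
    """Row-stochastic 5x5 transition matrix in (X, C1, A, R, C2) order."""
    p = params
    return np.array([
        [p.sigma_xx, p.alpha_x1, p.alpha_xa, 0.0, 0.0],
        [p.beta_1x, p.sigma_11, p.gamma_1a, 0.0, 0.0],
        [0.0, 0.0, p.sigma_aa, p.beta_ar, p.zeta_a2],
        [p.epsilon_rx, 0.0, p.alpha_ra, p.sigma_rr, p.alpha_r2],
        [0.0, 0.0, p.gamma_2a, p.beta_2r, p.sigma_22],
    ])


# mask of structurally-zero cells (row = source, col = destination)
_STRUCTURAL_ZEROS = np.array([
    [0, 0, 0, 1, 1],
    [0, 0, 0, 1, 1],
    [1, 1, 0, 0, 0],
    [0, 1, 0, 0, 0],
    [1, 1, 0, 0, 0],
], dtype=bool)


def validate_matrix(matrix: np.ndarray, atol: float = 1e-9) -> None:
    """Raise :class:`ParameterError` unless rows are stochastic and the
    structural zeros hold exactly."""
    m = np.asarray(matrix, dtype=float)
    if m.shape != (5, 5):
        raise ParameterError(f"transition matrix must be 5x5, got {m.shape}")
    if np.any(m < -atol) or np.any(m > 1 + atol):
        raise ParameterError("transition probabilities must lie in [0, 1]")
    rowsums = m.sum(axis=1)
    bad = np.nonzero(np.abs(rowsums - 1) > atol)[0]
    if bad.size:
        raise ParameterError(
            f"rows {[STATES[i] for i in bad]} are not stochastic "
            f"(sums {rowsums[bad]})"
        )
    if np.any(m[_STRUCTURAL_ZEROS] != 0):
        raise ParameterError("structurally-zero cells must be exactly 0")


def params_from_matrix(matrix: np.ndarray, label: str | None = None) -> TransitionParameters:
    """Recover the 11 free parameters from a valid transition matrix."""
    validate_matrix(matrix)
    m = np.asarray(matrix, dtype=float)
    idx = {s: i for i, s in enumerate(STATES)}
    d = {name: m[idx[name.split("->")[0]], idx[name.split("->")[1]]]
         for name in PARAM_NAMES}
    return TransitionParameters.from_dict(d, label=label)


def step(state: StateVector, params: TransitionParameters) -> StateVector:
    """One annual update: left-multiply the state row vector by the matrix."""
    nxt = state.as_array() @ make_matrix(params)
    return StateVector.from_array(nxt, t=state.t + 1)


def simulate(state0: StateVector, params: TransitionParameters,
             n_steps: int) -> list[StateVector]:
    """Trajectory ``[state0, step(state0), ...]`` of length ``n_steps + 1``."""
    if n_steps < 0:
        raise ValueError("n_steps must be >= 0")
    matrix = make_matrix(params)
    out = [state0]
    vec = state0.as_array()
    for k in range(n_steps):
        vec = vec @ matrix
        out.append(StateVector.from_array(vec, t=state0.t + k + 1))
    return out


def _x_star_and_d(p: TransitionParameters) -> tuple[float, float]:
    """Closed-form equilibrium X component and its denominator D."""
    ax1, axa = p.alpha_x1, p.alpha_xa
    b1x, g1a = p.beta_1x, p.gamma_1a
    za2, bar = p.zeta_a2, p.beta_ar
    g2a, b2r = p.gamma_2a, p.beta_2r
    ar2, ara, erx = p.alpha_r2, p.alpha_ra, p.epsilon_rx

    num = erx * (b1x + g1a) * (g2a * bar + b2r * (bar + za2))
    d = (
        ax1 * (
            erx * g1a * g2a + erx * g2a * bar + g1a * g2a * bar
            + g1a * g2a * ara + erx * g1a * za2 + g1a * ara * za2
            + ar2 * g1a * (g2a + bar + za2)
            + b2r * (erx * (g1a + bar + za2) + g1a * (bar + ara + za2))
        )
        + (b1x + g1a) * (
            erx * (g2a * (bar + axa) + axa * za2)
            + axa * (g2a * (bar + ara) + ara * za2 + ar2 * (g2a + bar + za2))
            + b2r * (erx * (bar + axa + za2) + axa * (bar + ara + za2))
        )
    )
    if d == 0:
        raise DegenerateEquilibriumError(
            "equilibrium denominator D = 0: degenerate parameterization "
            "(e.g. no flow out of the crime states)"
        )
    return num / d, d


def equilibrium_closed_form(params: TransitionParameters) -> EquilibriumResult:
    """Equilibrium by the closed-form expression for X*.

    The remaining components are recovered from the per-state balance
    relations (a well-posed 4x4 linear system once X* is fixed).
    """
    x_star, d = _x_star_and_d(params)
    p = params
    # balance relations at equilibrium, unknowns (c1, a, r, c2):
    #   (b1x+g1a) c1                                 = ax1 x
    #   (bar+za2) a  - g1a c1 - ara r - g2a c2       = axa x
    #   (ar2+ara+erx) r - bar a - b2r c2             = 0
    #   (g2a+b2r) c2 - za2 a - ar2 r                 = 0
    lhs = np.array([
        [p.beta_1x + p.gamma_1a, 0.0, 0.0, 0.0],
        [-p.gamma_1a, p.beta_ar + p.zeta_a2, -p.alpha_ra, -p.gamma_2a],
        [0.0, -p.beta_ar, p.alpha_r2 + p.alpha_ra + p.epsilon_rx, -p.beta_2r],
        [0.0, -p.zeta_a2, -p.alpha_r2, p.gamma_2a + p.beta_2r],
    ])
    rhs = np.array([p.alpha_x1 * x_star, p.alpha_xa * x_star, 0.0, 0.0])
    try:
        c1, a, r, c2 = np.linalg.solve(lhs, rhs)
    except np.linalg.LinAlgError as exc:
        raise DegenerateEquilibriumError(
            f"balance relations are singular: {exc}"
        ) from exc
    state = StateVector(x_star, c1, a, r, c2)
    return EquilibriumResult(
        state_star=state,
        x_star=x_star,
        crime_rate=1.0 - x_star,
        denominator_d=d,
        n_steps_to_converge="closed-form",
    )


def equilibrium_solve(params: TransitionParameters) -> EquilibriumResult:
    """Equilibrium as the normalized stationary distribution of the chain.

    Independent of the closed form: solves the null space of
    ``P.T - I``.  If the stationary distribution is not unique (a
    reducible chain from boundary parameters) the result is flagged
    ``unique=False`` and the distribution reachable from a strictly
    positive start is returned.
    """
    matrix = make_matrix(params)
    validate_matrix(matrix)
    kernel_dim = int(np.sum(np.linalg.svd(matrix.T - np.eye(5), compute_uv=False) < 1e-10))
    if kernel_dim > 1:
        # reducible: power-iterate from a uniform (strictly positive) start
        vec = np.full(5, 0.2)
        for n in range(100_000):
            nxt = vec @ matrix
            if np.abs(nxt - vec).sum() < 1e-14:
                vec = nxt
                break
            vec = nxt
        state = StateVector.from_array(vec / vec.sum())
        unique = False
        n_conv: int | str = n + 1
    else:
        lhs = np.vstack([matrix.T - np.eye(5), np.ones(5)])
        rhs = np.zeros(6)
        rhs[-1] = 1.0
        vec, *_ = np.linalg.lstsq(lhs, rhs, rcond=None)
        vec = np.clip(vec, 0.0, None)
        state = StateVector.from_array(vec / vec.sum())
        unique = True
        n_conv = "null-space"
    try:
        _, d = _x_star_and_d(params)
    except DegenerateEquilibriumError:
        d = 0.0
    return EquilibriumResult(
        state_star=state,
        x_star=state.x,
        crime_rate=1.0 - state.x,
        denominator_d=d,
        n_steps_to_converge=n_conv,
        unique=unique,
    )


def equilibrium_iterate(state0: StateVector, params: TransitionParameters,
                        max_steps: int = 300, tol: float = 1e-12) -> EquilibriumResult:
    """Equilibrium by fixed-point iteration from ``state0``.

    Stops when the L1 change per step falls below ``tol`` or after
    ``max_steps`` steps, whichever comes first (the 300-step protocol).
    """
    matrix = make_matrix(params)
    vec = state0.as_array()
    n = 0
    for n in range(1, max_steps + 1):
        nxt = vec @ matrix
        delta = np.abs(nxt - vec).sum()
        vec = nxt
        if delta < tol:
            break
    try:
        _, d = _x_star_and_d(params)
    except DegenerateEquilibriumError:
        d = 0.0
    state = StateVector.from_array(vec, t=state0.t + n)
    return EquilibriumResult(
        state_star=state,
        x_star=state.x,
        crime_rate=1.0 - state.x,
        denominator_d=d,
        n_steps_to_converge=n,
    )
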