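"""Between-group transition-rate gaps and their equilibrium consequences.

Group A is conventionally the disadvantaged group (e.g. Black men) and
group B the comparison group (e.g. White men).  Relative differences
default to (A - B) / B; the reversed convention (B - A) / A is exposed
as an option.  Equilibrium gaps are measured on the law-abiding
fraction X*; the complementary crime-rate gap has the same magnitude
with opposite sign.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import PARAM_NAMES, ParameterError, TransitionParameters
from .sensitivity import x_star

__all__ = [
    "DisparityReport",
    "EqualizationResult",
    "gap_table",
    "equalize_one",
    "gap_reduction_elasticity",
    "equalization_table",
    "full_report",
]


@dataclass(frozen=True)
class DisparityReport:
    """Per-parameter gaps plus the equilibrium gap between two groups."""

    table: pd.DataFrame          # parameter, value_a, value_b, abs/rel diffs, flags
    x_star_a: float
    x_star_b: float
    gap: float                   # x_star_a - x_star_b
    crime_rate_gap: float        # equal magnitude, opposite sign
    max_abs_parameter: str
    max_rel_parameter: str | None


def gap_table(params_a: TransitionParameters, params_b: TransitionParameters,
              relative: str = "a_minus_b_over_b") -> DisparityReport:
    """Absolute and relative per-parameter differences between two groups.

    ``relative`` selects the denominator convention:
    ``"a_minus_b_over_b"`` (default) or ``"b_minus_a_over_a"``.
    A relative difference with a zero denominator is reported as missing
    (NaN), never as infinity.
    """
    if relative not in ("a_minus_b_over_b", "b_minus_a_over_a"):
        raise ValueError(f"unknown relative-difference convention {relative!r}")
    va = params_a.as_array()
    vb = params_b.as_array()
    abs_diff = va - vb
    if relative == "a_minus_b_over_b":
        num, den = abs_diff, vb
    else:
        num, den = -abs_diff, va
    rel_diff = np.where(den != 0, num / np.where(den != 0, den, 1.0), np.nan)

    abs_rank = np.abs(abs_diff)
    rel_rank = np.where(np.isnan(rel_diff), -np.inf, np.abs(rel_diff))
    i_abs = int(np.argmax(abs_rank))
    i_rel = int(np.argmax(rel_rank))
    table = pd.DataFrame({
        "parameter": list(PARAM_NAMES),
        "value_a": va,
        "value_b": vb,
        "abs_diff": abs_diff,
        "rel_diff": rel_diff,
        "is_max_abs": [i == i_abs for i in range(len(PARAM_NAMES))],
        "is_max_rel": [i == i_rel for i in range(len(PARAM_NAMES))],
    })
    xa = x_star(params_a)
    xb = x_star(params_b)
    return DisparityReport(
        table=table,
        x_star_a=xa,
        x_star_b=xb,
        gap=xa - xb,
        crime_rate_gap=-(xa - xb),
        max_abs_parameter=PARAM_NAMES[i_abs],
        max_rel_parameter=PARAM_NAMES[i_rel] if np.isfinite(rel_rank[i_rel]) else None,
    )


@dataclass(frozen=True)
class EqualizationResult:
    """Equilibrium gap before and after one single-parameter substitution."""

    parameter: str
    baseline_gap: float          # x_star_a - x_star_b, untouched
    gap_a_to_b: float            # gap after setting A's parameter to B's value
    gap_b_to_a: float            # gap after setting B's parameter to A's value

    @property
    def reduction_a_to_b(self) -> float:
        """Percent reduction in |gap| when A adopts B's value."""
        return _pct_reduction(self.baseline_gap, self.gap_a_to_b)

    @property
    def reduction_b_to_a(self) -> float:
        return _pct_reduction(self.baseline_gap, self.gap_b_to_a)


def _pct_reduction(before: float, after: float) -> float:
    if before == 0:
        return 0.0
    return 100.0 * (abs(before) - abs(after)) / abs(before)


def equalize_one(params_a: TransitionParameters, params_b: TransitionParameters,
                 name: str) -> EqualizationResult:
    """Close one parameter's gap completely, in both directions."""
    baseline = x_star(params_a) - x_star(params_b)
    try:
        a_swapped = params_a.replace(name, params_b.value(name))
        b_swapped = params_b.replace(name, params_a.value(name))
    except ParameterError as exc:
        raise ParameterError(
            f"substituting {name} makes a parameter set invalid: {exc}"
        ) from exc
    return EqualizationResult(
        parameter=name,
        baseline_gap=baseline,
        gap_a_to_b=x_star(a_swapped) - x_star(params_b),
        gap_b_to_a=x_star(params_a) - x_star(b_swapped),
    )


def gap_reduction_elasticity(params_a: TransitionParameters,
                             params_b: TransitionParameters,
                             name: str, fraction: float) -> float:
    """Percent reduction in |X* gap| from shrinking one parameter gap.

    Moves A's named parameter toward B's value by
    ``fraction * (value_a - value_b)`` and recomputes both equilibria.
    ``fraction=1`` reproduces :func:`equalize_one` (A-to-B direction).
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    va = params_a.value(name)
    vb = params_b.value(name)
    moved = params_a.replace(name, va - fraction * (va - vb))
    before = x_star(params_a) - x_star(params_b)
    after = x_star(moved) - x_star(params_b)
    return _pct_reduction(before, after)


def equalization_table(params_a: TransitionParameters,
                       params_b: TransitionParameters,
                       fraction: float = 0.01) -> pd.DataFrame:
    """All 11 single-parameter equalizations plus the small-shrink elasticity."""
    rows = []
    for name in PARAM_NAMES:
        eq = equalize_one(params_a, params_b, name)
        rows.append({
            "parameter": name,
            "baseline_gap": eq.baseline_gap,
            "gap_after_a_to_b": eq.gap_a_to_b,
            "reduction_a_to_b_pct": eq.reduction_a_to_b,
            "gap_after_b_to_a": eq.gap_b_to_a,
            "reduction_b_to_a_pct": eq.reduction_b_to_a,
            f"reduction_fraction_{fraction}_pct":
                gap_reduction_elasticity(params_a, params_b, name, fraction),
        })
    return pd.DataFrame(rows)


def full_report(params_a: TransitionParameters, params_b: TransitionParameters,
                fraction: float = 0.01,
                relative: str = "a_minus_b_over_b") -> pd.DataFrame:
    """Gap table merged with equalization outcomes, one row per parameter."""
    gaps = gap_table(params_a, params_b, relative=relative)
    eqs = equalization_table(params_a, params_b, fraction=fraction)
    return gaps.table.merge(eqs, on="parameter")
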