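"""File formats and packaged parameter fixtures.

Transition parameters travel as JSON objects with the 11 arrow keys
(``"X->C1"`` ... ``"R->X"``) and an optional ``"label"``; stay
probabilities are never stored.  Printed full-row tables (stays
included, 3-decimal rounding) use a ``{"rows": {...}}`` JSON layout and
are renormalized on load, with a logged warning when a raw row sum
deviates from 1 by more than 0.02.

State distributions travel as JSON objects or single-row CSVs with
columns X, C1, A, R, C2.
"""

from __future__ import annotations

import json
import logging
from importlib import resources
from pathlib import Path

import pandas as pd

from .model import PARAM_NAMES, STATES, ParameterError, StateVector, TransitionParameters

__all__ = [
    "ParameterFileError",
    "load_params",
    "save_params",
    "params_from_printed_rows",
    "load_state_distribution",
    "save_state_distribution",
    "list_fixtures",
    "load_fixture_params",
    "load_fixture_state",
]

logger = logging.getLogger(__name__)

_ROW_SUM_WARN = 0.02


class ParameterFileError(ParameterError):
    """A parameter file is malformed; the message names the field."""


def params_from_printed_rows(rows: dict, label: str | None = None) -> TransitionParameters:
    """Build parameters from full printed rows that include stays.

    ``rows`` maps each source state to a ``{destination: probability}``
    dict.  Each row is renormalized to sum to 1 (printed tables are
    rounded to 3 decimals); a deviation larger than 0.02 is logged as a
    warning rather than hidden.
    """
    free = {}
    for source in STATES:
        if source not in rows:
            raise ParameterFileError(f"printed rows are missing source state {source!r}")
        row = rows[source]
        total = sum(row.values())
        if total <= 0:
            raise ParameterFileError(f"row {source} has nonpositive total {total}")
        if abs(total - 1.0) > _ROW_SUM_WARN:
            logger.warning("printed row %s sums to %.3f; renormalizing", source, total)
        for dest, value in row.items():
            arrow = f"{source}->{dest}"
            if arrow in PARAM_NAMES:
                free[arrow] = value / total
            elif dest != source:
                raise ParameterFileError(f"row {source} contains inadmissible arrow {arrow}")
    return TransitionParameters.from_dict(free, label=label)


def load_params(path) -> TransitionParameters:
    """Load a transition-parameter JSON file (arrow keys or printed rows)."""
    path = Path(path)
    with open(path) as fh:
        data = json.load(fh)
    if not isinstance(data, dict):
        raise ParameterFileError(f"{path}: expected a JSON object")
    label = data.get("label")
    if "rows" in data:
        return params_from_printed_rows(data["rows"], label=label)
    missing = [k for k in PARAM_NAMES if k not in data]
    if missing:
        raise ParameterFileError(f"{path}: missing parameter key(s) {missing}")
    for k in PARAM_NAMES:
        v = data[k]
        if not isinstance(v, (int, float)) or not (0.0 <= v <= 1.0):
            raise ParameterFileError(f"{path}: value for {k!r} must be in [0, 1], got {v!r}")
    try:
        return TransitionParameters.from_dict(data, label=label)
    except ParameterError as exc:
        raise ParameterFileError(f"{path}: {exc}") from exc


def save_params(params: TransitionParameters, path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        json.dump(params.as_dict(), fh, indent=2)
        fh.write("\n")


def load_state_distribution(path) -> StateVector:
    """Load a state distribution from JSON or single-row CSV."""
    path = Path(path)
    if path.suffix.lower() == ".csv":
        df = pd.read_csv(path)
        missing = [s for s in STATES if s not in df.columns]
        if missing:
            raise ParameterFileError(f"{path}: missing state column(s) {missing}")
        row = df.iloc[0]
        return StateVector(*[float(row[s]) for s in STATES])
    with open(path) as fh:
        data = json.load(fh)
    missing = [s for s in STATES if s not in data]
    if missing:
        raise ParameterFileError(f"{path}: missing state key(s) {missing}")
    return StateVector(*[float(data[s]) for s in STATES])


def save_state_distribution(state: StateVector, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".csv":
        pd.DataFrame([state.as_dict()]).to_csv(path, index=False)
    else:
        with open(path, "w") as fh:
            json.dump(state.as_dict(), fh, indent=2)
            fh.write("\n")


# -- packaged fixtures -----------------------------------------------------

def _fixture_dir():
    return resources.files("crimedyn") / "fixtures"


def list_fixtures() -> list[str]:
    return sorted(p.name for p in _fixture_dir().iterdir() if p.name.endswith(".json"))


def load_fixture_params(name: str) -> TransitionParameters:
    """Load a packaged parameter fixture, e.g. ``"table5_black_men"``."""
    ref = _fixture_dir() / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_params(path)


def load_fixture_state(name: str) -> StateVector:
    """Load a packaged initial-distribution fixture."""
    ref = _fixture_dir() / f"{name}.json"
    with resources.as_file(ref) as path:
        return load_state_distribution(path)
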