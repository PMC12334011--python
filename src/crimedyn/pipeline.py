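"""End-to-end pipeline: assign -> estimate -> equilibrium -> sensitivity
(-> disparity when two subgroups are requested), with a machine-readable
run manifest."""

from __future__ import annotations

import json
import logging
import platform
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .disparity import full_report
from .estimation import fit_all_transitions, params_from_subgroup_table, subgroup_table
from .io import save_params
from .model import StateVector, TransitionParameters, equilibrium_iterate
from .sensitivity import sensitivity_report
from .states import assign_states, build_transitions, empirical_matrix

__all__ = ["RunConfig", "PipelineError", "run_pipeline"]

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage and cause."""


@dataclass
class RunConfig:
    """Configuration for :func:`run_pipeline`.

    ``subgroups`` lists the (sex, race) cells to analyze; with exactly
    two, a disparity report comparing the first against the second is
    produced.  An empty list analyzes the pooled panel.
    """

    panel_path: str
    output_dir: str
    subgroups: list = field(default_factory=list)
    estimation_method: str = "empirical"   # or "random-intercept"
    max_steps: int = 300
    tol: float = 1e-12
    seed: int = 0
    force: bool = False

    def __post_init__(self) -> None:
        if self.estimation_method not in ("empirical", "random-intercept"):
            raise ValueError(
                f"estimation_method must be 'empirical' or 'random-intercept', "
                f"got {self.estimation_method!r}"
            )
        cells = []
        for cell in self.subgroups:
            if len(cell) != 2:
                raise ValueError(f"subgroup cells must be (sex, race) pairs, got {cell!r}")
            cells.append(tuple(cell))
        self.subgroups = cells


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the manifest (also written to disk)."""
    import pandas as pd

    panel_path = Path(config.panel_path)
    if not panel_path.exists():
        raise FileNotFoundError(f"panel file not found: {panel_path}")
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "inputs": {"panel": str(panel_path)},
        "seed": config.seed,
        "estimation_method": config.estimation_method,
        "subgroups": [list(c) for c in config.subgroups],
        "versions": {
            "crimedyn": __version__,
            "python": platform.python_version(),
        },
        "stages": [],
        "warnings": [],
        "outputs": {},
    }

    def _write(name: str, writer) -> None:
        path = outdir / name
        if path.exists() and not config.force:
            raise PipelineError(
                f"output {path} exists; pass force=True to overwrite"
            )
        writer(path)
        manifest["outputs"][name] = str(path)

    def _stage(name: str, fn):
        try:
            result = fn()
        except Exception as exc:
            manifest["stages"].append({"name": name, "status": "failed",
                                       "error": str(exc)})
            _write_manifest()
            raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        manifest["stages"].append({"name": name, "status": "completed"})
        return result

    def _write_manifest():
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, default=str)
            fh.write("\n")

    panel = pd.read_csv(panel_path)

    # 1. assign
    def do_assign():
        states = assign_states(panel)
        manifest["warnings"].extend(
            f"assign: {k} = {v}" for k, v in states.attrs.items() if v
        )
        _write("states.csv", lambda p: states.to_csv(p, index=False))
        return states

    states = _stage("assign", do_assign)

    # 2. transitions
    def do_transitions():
        trans = build_transitions(states)
        manifest["warnings"].extend(
            f"transitions: {k} = {v}" for k, v in trans.attrs.items() if v
        )
        _write("transitions.csv", lambda p: trans.to_csv(p, index=False))
        return trans

    transitions = _stage("transitions", do_transitions)

    # 3. estimate (per requested subgroup, or pooled)
    cells = config.subgroups or [None]

    def do_estimate():
        params_by_cell = {}
        if config.estimation_method == "random-intercept":
            fits = fit_all_transitions(transitions, panel)
            table = subgroup_table(fits, panel, ci="none", seed=config.seed)
            _write("subgroup_probabilities.csv",
                   lambda p: table.to_csv(p, index=False))
            for cell in cells:
                if cell is None:
                    raise PipelineError(
                        "random-intercept estimation requires explicit subgroups"
                    )
                sex, race = cell
                params_by_cell[cell] = params_from_subgroup_table(table, sex, race)
        else:
            for cell in cells:
                if cell is None:
                    emp = empirical_matrix(transitions)
                    key = "pooled"
                else:
                    emp = empirical_matrix(transitions, panel,
                                           sex=cell[0], race=cell[1])
                    key = f"{cell[1]}_{cell[0]}"
                params_by_cell[cell] = emp.to_params(label=key)
        for cell, params in params_by_cell.items():
            key = "pooled" if cell is None else f"{cell[1]}_{cell[0]}"
            _write(f"params_{key}.json", lambda p, pr=params: save_params(pr, p))
        return params_by_cell

    params_by_cell = _stage("estimate", do_estimate)

    # 4. equilibrium
    def do_equilibrium():
        results = {}
        for cell, params in params_by_cell.items():
            key = "pooled" if cell is None else f"{cell[1]}_{cell[0]}"
            start = StateVector(0.2, 0.2, 0.2, 0.2, 0.2)
            eq = equilibrium_iterate(start, params, max_steps=config.max_steps,
                                     tol=config.tol)
            results[key] = {
                "state_star": eq.state_star.as_dict(),
                "x_star": eq.x_star,
                "crime_rate": eq.crime_rate,
                "n_steps": eq.n_steps_to_converge,
            }
        _write("equilibrium.json", lambda p: Path(p).write_text(
            json.dumps(results, indent=2) + "\n"))
        return results

    _stage("equilibrium", do_equilibrium)

    # 5. sensitivity
    def do_sensitivity():
        frames = []
        for cell, params in params_by_cell.items():
            key = "pooled" if cell is None else f"{cell[1]}_{cell[0]}"
            rep = sensitivity_report(params).to_frame()
            rep.insert(0, "group", key)
            frames.append(rep)
        merged = pd.concat(frames, ignore_index=True)
        _write("sensitivity.csv", lambda p: merged.to_csv(p, index=False))
        return merged

    _stage("sensitivity", do_sensitivity)

    # 6. disparity (only with exactly two subgroups)
    if len(config.subgroups) == 2:
        def do_disparity():
            a, b = config.subgroups
            rep = full_report(params_by_cell[a], params_by_cell[b])
            _write("disparity.csv", lambda p: rep.to_csv(p, index=False))
            return rep

        _stage("disparity", do_disparity)

    _write_manifest()
    manifest["outputs"]["manifest.json"] = str(outdir / "manifest.json")
    return manifest
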