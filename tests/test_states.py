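import numpy as np
import pandas as pd
import pytest

from crimedyn.model import make_matrix
from crimedyn.states import (
    assign_state,
    assign_states,
    build_transitions,
    empirical_matrix,
    transition_indicators,
    _states_for_person,
)
from crimedyn.synth import SynthConfig, generate_panel


def panel_row(pid, wave, off, arr, age=15, sex="man", race="White"):
    return {"person_id": pid, "wave": wave, "age": age, "sex": sex,
            "race": race, "offended": off, "arrested": arr}


class TestAssignState:
    def test_offended_never_arrested_is_c1(self):
        assert assign_state([1], [0]) == "C1"

    def test_arrest_overrides_offense(self):
        assert assign_state([1], [1]) == "A"

    def test_inactive_never_arrested_is_x(self):
        assert assign_state([0, 0], [0, 0]) == "X"

    def test_three_inactive_years_after_arrest_rehabilitates(self):
        off = [0, 0, 0, 0]
        arr = [1, 0, 0, 0]
        states, *_ = _states_for_person(off, arr)
        assert states == ["A", "R", "R", "X"]

    def test_two_inactive_years_still_r(self):
        states, *_ = _states_for_person([0, 0, 0], [1, 0, 0])
        assert states == ["A", "R", "R"]

    def test_reoffense_with_history_is_c2(self):
        states, *_ = _states_for_person([0, 1], [1, 0])
        assert states == ["A", "C2"]

    def test_late_reoffense_reenters_c2(self):
        # offense after a completed 3-year window: back to C2, counted
        off = [0, 0, 0, 0, 1]
        arr = [1, 0, 0, 0, 0]
        states, _, _, n_late = _states_for_person(off, arr)
        assert states[-2:] == ["X", "C2"]
        assert n_late == 1

    def test_early_wave_lookback_uses_available_history(self):
        # arrested at wave 1: rehabilitated X impossible before wave 4
        states, *_ = _states_for_person([0, 0, 0], [1, 0, 0])
        assert "X" not in states

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            assign_state([], [])


class TestAssignStates:
    def test_missing_flags_excluded_and_counted(self):
        panel = pd.DataFrame([
            panel_row(1, 1, 0, 0),
            panel_row(1, 2, None, 0),
            panel_row(1, 3, 1, 0),
        ])
        out = assign_states(panel)
        assert len(out) == 2
        assert out.attrs["n_excluded_missing"] == 1

    def test_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(0)
        rows = []
        for p in range(200):
            for w in range(1, 8):
                rows.append(panel_row(p, w, int(rng.random() < 0.3),
                                      int(rng.random() < 0.1)))
        out = assign_states(pd.DataFrame(rows))
        assert len(out) == 200 * 7
        assert out["state"].isin(["X", "C1", "A", "R", "C2"]).all()

    def test_a_iff_arrested(self):
        rng = np.random.default_rng(1)
        rows = [panel_row(p, w, int(rng.random() < 0.3), int(rng.random() < 0.2))
                for p in range(100) for w in range(1, 8)]
        panel = pd.DataFrame(rows)
        out = assign_states(panel).merge(panel, on=["person_id", "wave"])
        assert ((out["state"] == "A") == (out["arrested"] == 1)).all()

    def test_matches_scalar_scan_oracle(self):
        rng = np.random.default_rng(2)
        rows, expected = [], []
        for p in range(300):
            off = rng.integers(0, 2, 7)
            arr = (rng.random(7) < 0.25).astype(int)
            states, evers, streaks, _ = _states_for_person(off, arr)
            for w in range(7):
                rows.append(panel_row(p, w + 1, off[w], arr[w]))
                expected.append((states[w], evers[w], streaks[w]))
        out = assign_states(pd.DataFrame(rows))
        exp = pd.DataFrame(expected, columns=["state", "ever", "streak"])
        assert (out["state"].to_numpy() == exp["state"].to_numpy()).all()
        assert (out["ever_arrested"].to_numpy() == exp["ever"].to_numpy()).all()
        assert (out["inactive_streak"].to_numpy() == exp["streak"].to_numpy()).all()

    def test_duplicate_person_wave_rejected(self):
        panel = pd.DataFrame([panel_row(1, 1, 0, 0), panel_row(1, 1, 1, 0)])
        with pytest.raises(ValueError):
            assign_states(panel)


class TestBuildTransitions:
    def test_x_to_c1(self):
        panel = pd.DataFrame([panel_row(1, 1, 0, 0), panel_row(1, 2, 1, 0)])
        trans = build_transitions(assign_states(panel))
        assert list(trans["transition"]) == ["X->C1"]

    def test_stay_in_a(self):
        panel = pd.DataFrame([panel_row(1, 1, 0, 1), panel_row(1, 2, 0, 1)])
        trans = build_transitions(assign_states(panel))
        assert list(trans["transition"]) == ["A->A"]

    def test_counting_oracle_six_per_person(self, black_men):
        n = 150
        panel, _ = generate_panel(
            SynthConfig(n_persons=n, params=black_men, mode="history", seed=9))
        trans = build_transitions(assign_states(panel))
        assert len(trans) == 6 * n

    def test_wave_gap_skipped(self):
        panel = pd.DataFrame([
            panel_row(1, 1, 0, 0), panel_row(1, 3, 0, 0),
        ])
        trans = build_transitions(assign_states(panel))
        assert len(trans) == 0
        assert trans.attrs["n_gap_skipped"] == 1

    def test_inadmissible_pair_rejected(self):
        states = pd.DataFrame({
            "person_id": [1, 1], "wave": [1, 2],
            "state": ["X", "C2"],  # impossible in one step
            "ever_arrested": [0, 1], "inactive_streak": [1, 0],
        })
        trans = build_transitions(states)
        assert len(trans) == 0
        assert trans.attrs["n_inadmissible"] == 1

    def test_indicator_frame_one_hot(self, black_men):
        panel, _ = generate_panel(
            SynthConfig(n_persons=50, params=black_men, mode="history", seed=3))
        trans = build_transitions(assign_states(panel))
        ind = transition_indicators(trans)
        arrow_cols = [c for c in ind.columns if "->" in c]
        assert len(arrow_cols) == 16
        assert (ind[arrow_cols].sum(axis=1) == 1).all()


class TestEmpiricalMatrix:
    def test_direct_count_oracle(self):
        # 9 of 10 X-origin pairs stay, 1 moves to C1
        rows = []
        for p in range(10):
            rows.append(panel_row(p, 1, 0, 0))
            rows.append(panel_row(p, 2, int(p == 0), 0))
        emp = empirical_matrix(build_transitions(assign_states(pd.DataFrame(rows))))
        assert emp.matrix[0] == pytest.approx([0.9, 0.1, 0, 0, 0])

    def test_single_person_always_x(self):
        panel = pd.DataFrame([panel_row(1, w, 0, 0) for w in range(1, 4)])
        emp = empirical_matrix(build_transitions(assign_states(panel)))
        assert emp.matrix[0] == pytest.approx([1, 0, 0, 0, 0])
        assert set(emp.undefined_rows) == {"C1", "A", "R", "C2"}
        with pytest.raises(ValueError, match="refused"):
            emp.to_params()

    def test_rows_sum_to_one(self, black_men):
        _, truth = generate_panel(
            SynthConfig(n_persons=2000, params=black_men, mode="markov", seed=21))
        emp = empirical_matrix(build_transitions(truth))
        assert emp.matrix.sum(axis=1) == pytest.approx(np.ones(5))

    def test_recovers_generating_rates_within_3se(self, black_men):
        _, truth = generate_panel(
            SynthConfig(n_persons=20_000, params=black_men, mode="markov", seed=4))
        emp = empirical_matrix(build_transitions(truth))
        expected = make_matrix(black_men)
        for i in range(5):
            n = emp.row_counts[i]
            for j in range(5):
                se = np.sqrt(expected[i, j] * (1 - expected[i, j]) / n)
                assert abs(emp.matrix[i, j] - expected[i, j]) <= 3 * max(se, 1e-12)

    def test_subgroup_filter(self, black_men, white_men):
        cfg = SynthConfig(
            n_persons=600,
            params={("man", "Black"): black_men, ("man", "White"): white_men,
                    ("woman", "Black"): black_men, ("woman", "White"): white_men,
                    ("man", "Hispanic"): white_men, ("woman", "Hispanic"): white_men},
            mode="markov", seed=12)
        panel, truth = generate_panel(cfg)
        trans = build_transitions(truth)
        sub = empirical_matrix(trans, panel, sex="man", race="Black")
        keep = panel.drop_duplicates("person_id")
        n_bm = ((keep["sex"] == "man") & (keep["race"] == "Black")).sum()
        assert sub.row_counts.sum() == 6 * n_bm

    def test_subgroup_filter_requires_panel(self, black_men):
        _, truth = generate_panel(
            SynthConfig(n_persons=50, params=black_men, mode="markov", seed=5))
        trans = build_transitions(truth)
        with pytest.raises(ValueError):
            empirical_matrix(trans, sex="man")
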