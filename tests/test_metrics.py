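import math

import numpy as np
import pandas as pd
import pytest

from scentforage import (
    SimulationConfig,
    coefficient_of_variation,
    pollen_transfer,
    run_simulation,
    summarize,
)
from scentforage.engine import SimulationResult


def make_events(rows):
    return pd.DataFrame(rows, columns=["step", "pollinator_id", "flower_id", "accepted", "nectar_gained"])


def brute_force_carryover(events, window=None):
    """Independent oracle: per-visit suffix enumeration, then per-flower means."""
    acc = events[events["accepted"] == 1].sort_values("step", kind="stable")
    per_flower = {}
    for pid in acc["pollinator_id"].unique():
        seq = acc[acc["pollinator_id"] == pid]
        visits = list(zip(seq["step"], seq["flower_id"]))
        for i, (t, f) in enumerate(visits):
            later = [
                g for (t2, g) in visits[i + 1 :]
                if g != f and (window is None or t2 <= t + window)
            ]
            per_flower.setdefault(f, []).append(len(set(later)))
    return {f: float(np.mean(c)) for f, c in per_flower.items()}


class TestCV:
    @pytest.mark.parametrize(
        "values, expected",
        [
            ([5, 5, 5], 0.0),
            ([1, 3], math.sqrt(2) / 2),
            ([2, 4, 6, 8], 0.5163977794943222),
        ],
    )
    def test_hand_computed_examples(self, values, expected):
        assert coefficient_of_variation(values) == pytest.approx(expected)

    def test_degenerate_inputs_are_missing_not_errors(self):
        assert math.isnan(coefficient_of_variation([4.2]))
        assert math.isnan(coefficient_of_variation([0.0, 0.0]))
        assert math.isnan(coefficient_of_variation([]))


class TestPollenTransfer:
    def test_single_pollinator_chain(self):
        events = make_events([(0, 0, 10, 1, 1.0), (7, 0, 11, 1, 0.5), (14, 0, 12, 1, 0.2)])
        carry = pollen_transfer(events)
        assert carry.to_dict() == {10: 2.0, 11: 1.0, 12: 0.0}

    def test_repeat_visits_average_per_flower(self):
        # visits A, B, A, C: first A sees {B, C}, B sees {A, C}, second A {C}, C {}
        events = make_events(
            [(0, 0, 0, 1, 1), (6, 0, 1, 1, 1), (12, 0, 0, 1, 1), (18, 0, 2, 1, 1)]
        )
        carry = pollen_transfer(events)
        assert carry[0] == pytest.approx(1.5)
        assert carry[1] == pytest.approx(2.0)
        assert carry[2] == pytest.approx(0.0)

    def test_single_visit_run(self):
        carry = pollen_transfer(make_events([(3, 1, 7, 1, 0.4)]))
        assert carry.to_dict() == {7: 0.0}

    def test_rejected_events_are_ignored(self):
        events = make_events([(0, 0, 0, 1, 1), (2, 0, 1, 0, 0.0), (6, 0, 2, 1, 1)])
        assert pollen_transfer(events).to_dict() == {0: 1.0, 2: 0.0}

    def test_empty_log(self):
        assert pollen_transfer(make_events([])).empty

    @pytest.mark.parametrize("window", [None, 50])
    def test_against_brute_force_on_random_logs(self, window):
        rng = np.random.default_rng(5)
        rows = []
        t = {p: 0 for p in range(4)}
        for _ in range(120):
            p = int(rng.integers(4))
            t[p] += int(rng.integers(1, 12))
            rows.append((t[p], p, int(rng.integers(8)), int(rng.random() < 0.8), 0.1))
        events = make_events(rows)
        expected = brute_force_carryover(events, window)
        got = pollen_transfer(events, carryover_window=window).to_dict()
        assert got == pytest.approx(expected)

    def test_wide_window_equals_no_window(self):
        rng = np.random.default_rng(11)
        rows = [(i * 7, int(rng.integers(3)), int(rng.integers(6)), 1, 0.2) for i in range(60)]
        events = make_events(rows)
        pd.testing.assert_series_equal(
            pollen_transfer(events), pollen_transfer(events, carryover_window=10**9)
        )


def toy_result():
    """3 pollinators, 4 flowers, 6 accepted + 1 rejected events; all aggregates
    hand-checkable."""
    config = SimulationConfig(size_map=20, n_steps=100, seed=1)
    events = make_events(
        [
            (1, 0, 0, 1, 1.0),
            (8, 0, 1, 1, 0.5),
            (10, 1, 2, 1, 1.0),
            (15, 0, 2, 0, 0.0),
            (20, 1, 0, 1, 0.25),
            (30, 0, 3, 1, 0.75),
            (40, 2, 1, 1, 0.1),
        ]
    )
    per_pollinator = pd.DataFrame(
        {"id": [0, 1, 2], "nectar_collected": [2.25, 1.25, 0.1], "visits": [3, 2, 1]}
    )
    per_flower = pd.DataFrame(
        {
            "id": [0, 1, 2, 3],
            "x": [1.0, 2, 3, 4],
            "y": [1.0, 1, 1, 1],
            "nectar": [0.2, 0.15, 0.3, 0.05],
            "scent": [0.8, 0.85, 0.7, 0.95],
            "visit_count": [2, 2, 1, 1],
        }
    )
    return SimulationResult(config, 1, per_pollinator, per_flower, events, total_refill=0.0)


class TestSummarize:
    def test_toy_fixture_matches_hand_calculation(self):
        m = summarize(toy_result())
        assert m.mean_nectar_collected == pytest.approx(np.mean([2.25, 1.25, 0.1]))
        assert m.cv_nectar_collected == pytest.approx(
            np.std([2.25, 1.25, 0.1], ddof=1) / np.mean([2.25, 1.25, 0.1])
        )
        assert m.mean_nectar_per_visit == pytest.approx(3.6 / 6)
        assert m.mean_nectar_remaining == pytest.approx(0.175)
        assert m.mean_visits_per_flower == pytest.approx(1.5)
        # carryover: p0 visits 0,1,3 -> 0:{1,3}=2, 1:{3}=1, 3:{}=0; p1 visits 2,0 -> 2:{0}=1, 0:{}=0; p2: 1:{}=0
        # flower 0 mean (2+0)/2=1, flower 1 mean (1+0)/2=0.5, flower 2: 1, flower 3: 0
        assert m.mean_pollen_transfer == pytest.approx(np.mean([1.0, 0.5, 1.0, 0.0]))

    def test_summary_is_invariant_to_id_relabeling(self):
        base = toy_result()
        relabeled = toy_result()
        fmap = {0: 3, 1: 2, 2: 1, 3: 0}
        pmap = {0: 2, 1: 0, 2: 1}
        relabeled.events["flower_id"] = relabeled.events["flower_id"].map(fmap)
        relabeled.events["pollinator_id"] = relabeled.events["pollinator_id"].map(pmap)
        relabeled.per_flower["id"] = relabeled.per_flower["id"].map(fmap)
        relabeled.per_pollinator["id"] = relabeled.per_pollinator["id"].map(pmap)
        assert summarize(base).to_dict() == pytest.approx(summarize(relabeled).to_dict())

    def test_no_pollinators_reports_missing_visit_metrics(self):
        cfg = SimulationConfig(size_map=20, pollinator_ratio=0.0, n_steps=20)
        m = summarize(run_simulation(cfg))
        assert m.mean_nectar_remaining == 1.0
        assert m.mean_visits_per_flower == 0.0
        assert math.isnan(m.mean_nectar_per_visit)
        assert math.isnan(m.mean_pollen_transfer)

    def test_visit_identity_on_a_real_run(self, tiny_config):
        result = run_simulation(tiny_config)
        m = summarize(result)
        total_accepted = int((result.events["accepted"] == 1).sum())
        assert m.mean_visits_per_flower * result.n_flowers == pytest.approx(total_accepted)
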