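import numpy as np
import pandas as pd
import pytest

from volleymine import (
    build_feature_matrix,
    build_score_map,
    generate_season,
    targets_from_dataset,
)
from volleymine.core_data import SeasonDataset, canonicalize


def make_tiny_season(shift_days: int = 0) -> SeasonDataset:
    """A small handcrafted two-player season for golden-value tests.

    Six calendar weeks with a one-week holiday (days 14-20), one match on
    the last day.  All dates can be shifted by a constant for
    translation-invariance checks.
    """
    d0 = pd.Timestamp("2018-05-07") + pd.Timedelta(days=shift_days)

    def day(i):
        return d0 + pd.Timedelta(days=i)

    n_days = 42
    phases = ["prep1"] * 14 + ["holiday"] * 7 + ["prep2"] * 14 + ["comp2"] * 7
    calendar = pd.DataFrame({"date": [day(i) for i in range(n_days)], "phase": phases})

    roster = pd.DataFrame([
        {"player_id": "A", "position": "outside_hitter", "exercise": "back_squat", "one_rm_kg": 150.0},
        {"player_id": "A", "position": "outside_hitter", "exercise": "bench_press", "one_rm_kg": 100.0},
        {"player_id": "B", "position": "libero", "exercise": "back_squat", "one_rm_kg": 120.0},
    ])
    sessions = pd.DataFrame([
        {"player_id": "A", "date": day(35), "session_type": "volleyball", "duration_min": 60.0, "rpe": 5.0},
        {"player_id": "A", "date": day(37), "session_type": "strength", "duration_min": 40.0, "rpe": 6.0},
        {"player_id": "A", "date": day(40), "session_type": "volleyball", "duration_min": 100.0, "rpe": 4.0},
        {"player_id": "B", "date": day(36), "session_type": "volleyball", "duration_min": 90.0, "rpe": 7.0},
    ])
    jumps = pd.DataFrame([
        {"player_id": "A", "date": day(35), "height_cm": 40.0, "source": "training"},
        {"player_id": "A", "date": day(35), "height_cm": 55.0, "source": "training"},
        {"player_id": "A", "date": day(35), "height_cm": 70.0, "source": "training"},
        {"player_id": "A", "date": day(38), "height_cm": 50.0, "source": "training"},
        {"player_id": "A", "date": day(40), "height_cm": 66.0, "source": "training"},
        {"player_id": "B", "date": day(36), "height_cm": 45.0, "source": "training"},
    ])
    strength = pd.DataFrame([
        {"player_id": "A", "date": day(37), "exercise": "back_squat", "body_region": "lower_body",
         "reps": 5, "weight_kg": 120.0, "weight_pct_1rm": 0.8},
        {"player_id": "A", "date": day(37), "exercise": "bench_press", "body_region": "upper_body",
         "reps": 8, "weight_kg": 80.0, "weight_pct_1rm": 0.8},
    ])
    wellness = pd.DataFrame([
        {"player_id": "A", "date": day(39), "fatigue": 6, "sleep_quality": 7, "hours_slept": 7, "mood": 8},
        {"player_id": "A", "date": day(40), "fatigue": 5, "sleep_quality": 8, "hours_slept": 6, "mood": 7},
        {"player_id": "B", "date": day(40), "fatigue": 4, "sleep_quality": 6, "hours_slept": 8, "mood": 9},
    ])
    actions = pd.DataFrame([
        {"player_id": "A", "match_id": "M01", "match_date": day(41), "action_type": "attack", "rating": "#"},
        {"player_id": "A", "match_id": "M01", "match_date": day(41), "action_type": "attack", "rating": "#"},
        {"player_id": "A", "match_id": "M01", "match_date": day(41), "action_type": "attack", "rating": "="},
        {"player_id": "B", "match_id": "M01", "match_date": day(41), "action_type": "pass", "rating": "+"},
        {"player_id": "B", "match_id": "M01", "match_date": day(41), "action_type": "pass", "rating": "#"},
    ])
    return canonicalize(SeasonDataset(roster=roster, sessions=sessions, jumps=jumps,
                                      strength=strength, wellness=wellness,
                                      actions=actions, calendar=calendar))


def make_uniform_score_map():
    """Score map where '#'=10, '='=0 and intermediate ratings spread evenly
    along each action type's own worst-to-best rating order."""
    from volleymine.scoring import rating_order

    rows = []
    for action in ("attack", "pass", "block", "serve"):
        for k, r in enumerate(rating_order(action)):
            rows.append({"action_type": action, "rating": r, "n_total": 10, "n_won": 2 * k})
    return build_score_map(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def tiny_season():
    return make_tiny_season()


@pytest.fixture(scope="session")
def season_and_matrix():
    """One generated season with targets and the full feature matrix,
    shared across tests (read-only)."""
    dataset, historic = generate_season(seed=11)
    score_map = build_score_map(historic)
    targets = targets_from_dataset(dataset, score_map)
    matrix = build_feature_matrix(dataset, targets)
    return dataset, historic, score_map, targets, matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
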