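"""Synthetic season generator with plantable ground-truth subgroup effects.

Generates monitoring data with the structure the analysis assumes: a
24-week international season (5-week preparation, 3-week competition,
3-week holiday with no data collection, 10-week preparation, 3-week
competition), 17 players covering all five positions, about 6.1 +/- 2.4
training sessions per player-week, 31 matches, and per-position match
participation calibrated so a season yields roughly 122 attack, 87 pass,
58 block and 35 serve performance records.

Action ratings are drawn from per-action categorical distributions whose
mean mapped scores sit near the observed levels for elite men's volleyball
(attack about 6.8, serve 3.3, block 2.7, pass 8.6 on the 0-10 scale).  The
generator also emits a surrogate historical-outcomes table (rally-win
counts per action type and rating) from which the rating-score map is
rebuilt downstream, so the full scoring path is exercised.

Null seasons carry no association between training-load features and
performance targets by construction: per-row performance fluctuations are
drawn independently of the training process, and there is no per-player
performance baseline (targets are exchangeable within an action type,
the premise of the swap-randomization null).  Ground-truth effects are
planted by re-drawing the ratings of rows that satisfy a feature
condition, shifting their expected mean score by a requested amount.
"""

from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core_data import SeasonDataset, canonicalize, validate_season
from .features import DEFAULT_CONFIG, FeatureConfig, build_feature_matrix
from .scoring import RELEVANT_ACTIONS, RatingScoreMap, match_performance, rating_order

# -- rating-generation parameters per action type ---------------------------
# win_prob: historical probability that an action with this rating wins the
# rally (defines the surrogate score map, x10); base_prob: how often the
# scout assigns each rating.  Keys follow the worst->best rating order of
# the action type.  Calibrated so mean mapped scores land near the observed
# per-action levels.

_ACTION_PARAMS: dict[str, dict[str, dict[str, float]]] = {
    "attack": {
        "win_prob": {"=": 0.02, "/": 0.10, "-": 0.25, "!": 0.40, "+": 0.60, "#": 0.98},
        "base_prob": {"=": 0.08, "/": 0.02, "-": 0.10, "!": 0.13, "+": 0.15, "#": 0.52},
    },
    "pass": {
        "win_prob": {"=": 0.05, "/": 0.20, "-": 0.50, "!": 0.70, "+": 0.85, "#": 0.97},
        "base_prob": {"=": 0.02, "/": 0.02, "-": 0.05, "!": 0.09, "+": 0.24, "#": 0.58},
    },
    "block": {
        "win_prob": {"=": 0.02, "/": 0.08, "-": 0.15, "!": 0.30, "+": 0.55, "#": 0.95},
        "base_prob": {"=": 0.25, "/": 0.20, "-": 0.18, "!": 0.14, "+": 0.11, "#": 0.12},
    },
    "serve": {
        "win_prob": {"=": 0.02, "-": 0.18, "!": 0.30, "+": 0.45, "/": 0.70, "#": 0.99},
        "base_prob": {"=": 0.12, "-": 0.25, "!": 0.30, "+": 0.22, "/": 0.06, "#": 0.05},
    },
}

#: SD of the per-row latent performance fluctuation (score units);
#: calibrated so per-row target SDs land near the observed per-action
#: spreads (attack ~1.7, pass ~0.9, block ~1.5, serve ~0.9)
_ROW_NOISE_SD = {"attack": 1.25, "pass": 0.7, "block": 0.75, "serve": 0.7}
#: mean number of actions per participating (player, match, action) row
_ACTIONS_PER_ROW = {"attack": 9.0, "pass": 12.0, "block": 5.0, "serve": 8.0}

_EXERCISES = {
    # exercise -> (body region, mean 1-RM kg, sd)
    "back_squat": ("lower_body", 140.0, 15.0),
    "leg_press": ("lower_body", 220.0, 25.0),
    "deadlift": ("full_body", 160.0, 20.0),
    "power_clean": ("full_body", 90.0, 10.0),
    "bench_press": ("upper_body", 100.0, 12.0),
    "shoulder_press": ("upper_body", 60.0, 8.0),
}


@dataclass(frozen=True)
class SeasonConfig:
    """Generator parameters; the defaults are the study conditions."""

    n_players: int = 17
    position_counts: dict[str, int] = field(default_factory=lambda: {
        "setter": 3, "outside_hitter": 5, "middle_blocker": 4, "opposite": 3, "libero": 2,
    })
    phase_weeks: tuple[int, int, int, int, int] = (5, 3, 3, 10, 3)  # prep1, comp1, holiday, prep2, comp2
    start_date: str = "2018-05-07"  # a Monday
    sessions_per_week_mean: float = 6.1
    sessions_per_week_sd: float = 2.4
    strength_session_frac: float = 0.33
    n_matches: int = 31
    #: per-action probability that an eligible player produces records in a
    #: match; calibrated to ~122/87/58/35 attack/pass/block/serve rows
    participation: dict[str, float] = field(default_factory=lambda: {
        "attack": 122 / (31 * 12), "pass": 87 / (31 * 5),
        "block": 58 / (31 * 4), "serve": 35 / (31 * 3),
    })
    jump_height_log_mean: float = float(np.log(54.0))
    jump_height_log_sd: float = 0.20
    jumps_per_session_mean: float = 55.0
    wellness_mu: float = 7.0
    wellness_phi: float = 0.6
    wellness_sd: float = 1.3

    def validate(self) -> None:
        if sum(self.position_counts.values()) != self.n_players:
            raise ValueError("position_counts must sum to n_players")
        if min(self.position_counts.values()) < 1:
            raise ValueError("every position needs at least one player")
        if len(self.phase_weeks) != 5 or sum(self.phase_weeks) != 24:
            raise ValueError("phase weeks must be five phases summing to 24")
        for a in RELEVANT_ACTIONS:
            if not 0 < self.participation[a] <= 1:
                raise ValueError(f"participation[{a}] must lie in (0, 1]")


DEFAULT_SEASON_CONFIG = SeasonConfig()


@dataclass(frozen=True)
class PlantedEffect:
    """A ground-truth subgroup effect to inject into a generated season.

    The threshold may be given directly or as a quantile of the observed
    feature values (``threshold_quantile``); ``shift`` is the desired
    change, in score units, of the mean target for rows satisfying
    ``feature direction threshold``.
    """

    feature: str
    action_type: str
    shift: float
    direction: str = ">="            # '>=' or '<='
    threshold: float | None = None
    threshold_quantile: float | None = None


@dataclass
class PlantedEffectResult:
    effect: PlantedEffect
    threshold: float
    affected: pd.DataFrame          # (player_id, match_id) keys of shifted rows
    size_fraction: float


def _stream(seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng([int(seed) % 2**31, zlib.crc32(name.encode())])


def _tilt_probs(base: np.ndarray, scores: np.ndarray, delta: float) -> np.ndarray:
    """Exponentially tilt a categorical score distribution so its mean
    moves by ``delta`` (clipped to the attainable open interval)."""
    mean0 = float(base @ scores)
    target = float(np.clip(mean0 + delta, scores.min() + 0.05, scores.max() - 0.05))

    def mean_at(lam: float) -> float:
        w = base * np.exp(lam * (scores - scores.mean()))
        w /= w.sum()
        return float(w @ scores)

    lo, hi = -12.0, 12.0
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if mean_at(mid) < target:
            lo = mid
        else:
            hi = mid
    lam = 0.5 * (lo + hi)
    w = base * np.exp(lam * (scores - scores.mean()))
    return w / w.sum()


def _draw_row_ratings(rng: np.random.Generator, action: str, n: int, delta: float) -> list[str]:
    order = list(rating_order(action))
    params = _ACTION_PARAMS[action]
    base = np.array([params["base_prob"][r] for r in order])
    scores = np.array([10.0 * params["win_prob"][r] for r in order])
    probs = _tilt_probs(base, scores, delta)
    return list(rng.choice(order, size=n, p=probs))


def expected_score(action: str, delta: float = 0.0) -> float:
    """Expected mapped score of one action under the generator's rating law."""
    order = list(rating_order(action))
    params = _ACTION_PARAMS[action]
    base = np.array([params["base_prob"][r] for r in order])
    scores = np.array([10.0 * params["win_prob"][r] for r in order])
    if delta == 0.0:
        return float(base @ scores)
    return float(_tilt_probs(base, scores, delta) @ scores)


def _build_calendar(config: SeasonConfig) -> pd.DataFrame:
    d0 = pd.Timestamp(config.start_date)
    phases = ("prep1", "comp1", "holiday", "prep2", "comp2")
    rows = []
    day = d0
    for phase, weeks in zip(phases, config.phase_weeks):
        for _ in range(weeks * 7):
            rows.append({"date": day, "phase": phase})
            day += pd.Timedelta(days=1)
    return pd.DataFrame(rows)


def _match_days(calendar: pd.DataFrame, config: SeasonConfig, rng: np.random.Generator) -> list[pd.Timestamp]:
    cal = calendar.copy()
    cal["week"] = (cal["date"] - cal["date"].min()).dt.days // 7
    comp_days = cal.loc[cal["phase"].isin(["comp1", "comp2"]), "date"].to_numpy()
    # friendlies in preparation, skipping the first two ramp-up weeks
    prep_days = cal.loc[cal["phase"].isin(["prep1", "prep2"]) & (cal["week"] >= 2), "date"].to_numpy()
    n_friendly = min(int(round(config.n_matches * 17 / 31)), len(prep_days))
    n_comp = min(config.n_matches - n_friendly, len(comp_days))
    if n_comp + n_friendly < config.n_matches:
        raise ValueError("calendar has too few eligible days for the requested matches")
    days = list(rng.choice(comp_days, size=n_comp, replace=False))
    days += list(rng.choice(prep_days, size=n_friendly, replace=False))
    return sorted(pd.Timestamp(d) for d in days)


def generate_season(
    config: SeasonConfig = DEFAULT_SEASON_CONFIG,
    seed: int = 0,
) -> tuple[SeasonDataset, pd.DataFrame]:
    """Generate one season and its surrogate historical-outcomes table.

    Fully reproducible given ``(config, seed)``.  Returns the validated
    :class:`~volleymine.core_data.SeasonDataset` and a DataFrame
    ``(action_type, rating, n_total, n_won)`` for
    :func:`~volleymine.scoring.build_score_map`.
    """
    config.validate()
    calendar = _build_calendar(config)
    d0 = calendar["date"].min()
    holiday = set(calendar.loc[calendar["phase"] == "holiday", "date"])

    # roster ---------------------------------------------------------------
    rng = _stream(seed, "roster")
    players, positions = [], []
    i = 1
    for pos, cnt in config.position_counts.items():
        for _ in range(cnt):
            players.append(f"P{i:02d}")
            positions.append(pos)
            i += 1
    roster_rows = []
    for pid, pos in zip(players, positions):
        for ex, (region, mu, sd) in _EXERCISES.items():
            rm = float(np.round(max(rng.normal(mu, sd), 20.0), 1))
            roster_rows.append({"player_id": pid, "position": pos, "exercise": ex, "one_rm_kg": rm})
    roster = pd.DataFrame(roster_rows)
    one_rm = roster.set_index(["player_id", "exercise"])["one_rm_kg"]

    match_days = _match_days(calendar, config, _stream(seed, "matches"))
    match_ids = [f"M{k + 1:02d}" for k in range(len(match_days))]

    # match participation and actions --------------------------------------
    rng = _stream(seed, "actions")
    pos_of = dict(zip(players, positions))
    action_rows = []
    played: dict[tuple[str, str], set[str]] = {}
    for mid, mdate in zip(match_ids, match_days):
        in_match: set[str] = set()
        for action, rel_pos in RELEVANT_ACTIONS.items():
            for pid in players:
                if pos_of[pid] not in rel_pos:
                    continue
                if rng.random() >= config.participation[action]:
                    continue
                in_match.add(pid)
                n = 1 + rng.poisson(_ACTIONS_PER_ROW[action] - 1.0)
                delta = rng.normal(0.0, _ROW_NOISE_SD[action])
                for r in _draw_row_ratings(rng, action, n, delta):
                    action_rows.append({"player_id": pid, "match_id": mid, "match_date": mdate,
                                        "action_type": action, "rating": r})
        # occasional position-irrelevant rows (setters attacking) exercise
        # the downstream relevance filter
        for pid in players:
            if pos_of[pid] == "setter" and pid in in_match and rng.random() < 0.2:
                for r in _draw_row_ratings(rng, "attack", 1 + rng.poisson(1.0), 0.0):
                    action_rows.append({"player_id": pid, "match_id": mid, "match_date": mdate,
                                        "action_type": "attack", "rating": r})
        played[(mid, str(mdate.date()))] = in_match
    actions = pd.DataFrame(action_rows)

    # training sessions ----------------------------------------------------
    rng = _stream(seed, "sessions")
    cal = calendar.copy()
    cal["week"] = (cal["date"] - d0).dt.days // 7
    week_days = {w: list(g["date"]) for w, g in cal[cal["phase"] != "holiday"].groupby("week")}
    match_day_set = set(match_days)
    session_rows = []
    for pid in players:
        for w, days in week_days.items():
            free = [d for d in days if d not in match_day_set]
            n = int(np.round(max(rng.normal(config.sessions_per_week_mean, config.sessions_per_week_sd), 0.0)))
            n = min(n, 2 * len(free))
            chosen = rng.choice(len(free), size=n, replace=True) if free else []
            for di in np.sort(chosen):
                d = free[int(di)]
                if rng.random() < config.strength_session_frac:
                    stype, dur, rpe = "strength", rng.normal(60, 10), rng.normal(6.5, 1.3)
                else:
                    stype, dur, rpe = "volleyball", rng.normal(100, 20), rng.normal(6.0, 1.5)
                session_rows.append({"player_id": pid, "date": d, "session_type": stype,
                                     "duration_min": float(np.round(max(dur, 20.0))),
                                     "rpe": float(np.clip(np.round(rpe * 2) / 2, 0.5, 10.0))})
    for (mid, mdate_s), in_match in played.items():
        mdate = pd.Timestamp(mdate_s)
        for pid in sorted(in_match):
            session_rows.append({"player_id": pid, "date": mdate, "session_type": "match",
                                 "duration_min": float(np.round(max(rng.normal(110, 20), 60.0))),
                                 "rpe": float(np.clip(np.round(rng.normal(8.0, 1.0) * 2) / 2, 0.5, 10.0))})
    sessions = pd.DataFrame(session_rows)

    # jumps: every volleyball session / match produces individual jumps ----
    rng = _stream(seed, "jumps")
    vb = sessions[sessions["session_type"].isin(["volleyball", "match"])].reset_index(drop=True)
    n_per = rng.poisson(config.jumps_per_session_mean, size=len(vb))
    total = int(n_per.sum())
    heights = np.maximum(np.round(np.exp(rng.normal(
        config.jump_height_log_mean, config.jump_height_log_sd, total)), 1), 5.0)
    jumps = pd.DataFrame({
        "player_id": np.repeat(vb["player_id"].to_numpy(), n_per),
        "date": np.repeat(vb["date"].to_numpy(), n_per),
        "height_cm": heights,
        "source": np.repeat(np.where(vb["session_type"] == "match", "match", "training"), n_per),
    })

    # strength sets ---------------------------------------------------------
    rng = _stream(seed, "strength")
    one_rm_lookup = one_rm.to_dict()
    ex_names = list(_EXERCISES)
    st_pid, st_date, st_ex = [], [], []
    for row in sessions[sessions["session_type"] == "strength"].itertuples():
        for ex in rng.choice(ex_names, size=rng.integers(3, 6), replace=False):
            n_sets = int(rng.integers(3, 6))
            st_pid += [row.player_id] * n_sets
            st_date += [row.date] * n_sets
            st_ex += [ex] * n_sets
    n_sets_total = len(st_pid)
    pct = np.clip(rng.normal(0.80, 0.08, n_sets_total), 0.30, 1.05)
    rm_arr = np.array([one_rm_lookup[(p, e)] for p, e in zip(st_pid, st_ex)])
    kg = np.round(pct * rm_arr, 1)
    strength = pd.DataFrame({
        "player_id": st_pid, "date": st_date, "exercise": st_ex,
        "body_region": [_EXERCISES[e][0] for e in st_ex],
        "reps": rng.integers(3, 11, n_sets_total),
        "weight_kg": kg, "weight_pct_1rm": np.round(kg / rm_arr, 4),
    })

    # wellness: AR(1) Likert process on all non-holiday days ----------------
    rng = _stream(seed, "wellness")
    items = ("fatigue", "sleep_quality", "hours_slept", "mood")
    all_days = [d for d in calendar["date"] if d not in holiday]
    n_days = len(all_days)
    from scipy.signal import lfilter
    frames = {"player_id": np.repeat(players, n_days),
              "date": np.tile(np.array(all_days, dtype="datetime64[ns]"), len(players))}
    for it in items:
        eps = rng.normal(0, config.wellness_sd, size=(len(players), n_days))
        eps[:, 0] = rng.normal(0, 1.0, size=len(players))  # initial deviation
        dev = lfilter([1.0], [1.0, -config.wellness_phi], eps, axis=1)
        frames[it] = np.clip(np.round(config.wellness_mu + dev), 1, 10).astype(int).ravel()
    wellness = pd.DataFrame(frames)

    # surrogate historical outcomes ----------------------------------------
    rng = _stream(seed, "historic")
    hist_rows = []
    for action, params in _ACTION_PARAMS.items():
        for r, p in params["win_prob"].items():
            n_total = int(rng.integers(5000, 20000))
            n_won = int(rng.binomial(n_total, p))
            hist_rows.append({"action_type": action, "rating": r, "n_total": n_total, "n_won": n_won})
    historic = pd.DataFrame(hist_rows)

    dataset = canonicalize(SeasonDataset(
        roster=roster, sessions=sessions, jumps=jumps, strength=strength,
        wellness=wellness, actions=actions, calendar=calendar,
    ))
    validate_season(dataset)
    return dataset, historic


def plant_effects(
    dataset: SeasonDataset,
    effects: list[PlantedEffect],
    seed: int,
    score_map: RatingScoreMap,
    feature_config: FeatureConfig = DEFAULT_CONFIG,
) -> tuple[SeasonDataset, list[PlantedEffectResult]]:
    """Inject ground-truth subgroup effects by re-drawing action ratings.

    For every row of the affected action type satisfying the condition,
    the ratings are re-drawn from a tilted distribution whose expected
    mapped score is shifted by ``effect.shift`` (plus the usual per-row
    fluctuation), so the whole scoring path remains exercised.  Returns
    the modified dataset and per-effect bookkeeping (resolved threshold,
    affected rows, size fraction).  An empty effect list returns the
    dataset unchanged.
    """
    if not effects:
        return dataset, []
    ds = dataset.copy()
    results = []
    rng = _stream(seed, "plant")
    for eff in effects:
        targets = match_performance(ds.actions, score_map, ds.roster)
        targets = targets[targets["action_type"] == eff.action_type].reset_index(drop=True)
        matrix = build_feature_matrix(ds, targets, feature_config)
        if eff.feature not in matrix.columns:
            raise KeyError(f"planted feature {eff.feature!r} not in the feature catalogue")
        v = matrix[eff.feature].to_numpy(dtype=float)
        if eff.threshold is not None:
            thr = float(eff.threshold)
        elif eff.threshold_quantile is not None:
            thr = float(np.nanquantile(v, eff.threshold_quantile))
        else:
            raise ValueError("effect needs a threshold or a threshold_quantile")
        if eff.direction == ">=":
            mask = v >= thr
        elif eff.direction == "<=":
            mask = v <= thr
        else:
            raise ValueError(f"direction must be '>=' or '<=', got {eff.direction!r}")
        mask &= ~np.isnan(v)
        frac = float(mask.mean()) if len(mask) else 0.0
        if not 0.10 <= frac <= 0.90:
            warnings.warn(
                f"planted condition {eff.feature} {eff.direction} {thr:g} covers "
                f"{frac:.1%} of rows; outside the recoverable 10-90% size range",
                stacklevel=2,
            )
        affected = matrix.loc[mask, ["player_id", "match_id"]].reset_index(drop=True)
        keys = set(map(tuple, affected.to_numpy()))
        act = ds.actions
        sel = (act["action_type"] == eff.action_type) & np.array(
            [(p, m) in keys for p, m in zip(act["player_id"], act["match_id"])]
        )
        grp_keys = act.loc[sel].groupby(["player_id", "match_id"]).groups
        new_ratings = act["rating"].copy()
        for _, idx in grp_keys.items():
            delta = eff.shift + rng.normal(0.0, _ROW_NOISE_SD[eff.action_type])
            new_ratings.loc[idx] = _draw_row_ratings(rng, eff.action_type, len(idx), delta)
        ds.actions = act.assign(rating=new_ratings)
        results.append(PlantedEffectResult(effect=eff, threshold=thr,
                                           affected=affected, size_fraction=frac))
    return canonicalize(ds), results
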