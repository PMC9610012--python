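"""Windowed training-load and wellness predictors for performance targets.

Every performance-target row (player, match, action type) receives
predictors built in three steps: pick a monitored variable (daily jump
counts, jump height, per-set strength weights, wellness items, session
loads), restrict it to a look-back window of 7, 14 or 28 days ending the
day before the match, and apply an aggregate (first quartile, mean, third
quartile, standard deviation; additionally the sum for jump counts and
absolute-kilogram strength weights).

With the default configuration this yields exactly 237 predictors:

* 72 jump predictors — daily mean jump height (4 aggregates x 3 windows)
  plus daily jump counts in four categories: all, low (< 50 cm), average
  (50-65 cm) and high (> 65 cm) jumps (4 x 5 aggregates x 3 windows);
* 81 strength predictors — per-set weights by body region (lower, upper,
  full body) in absolute kg (3 x 5 x 3) and as a fraction of the player's
  1-RM (3 x 4 x 3, no sum);
* 48 wellness predictors — fatigue, sleep quality, hours-slept rating and
  mood (4 x 4 x 3);
* 27 load predictors — windowed training load (sum of session RPE x
  duration), monotony (mean/SD of daily load) and strain (load x
  monotony) for volleyball-specific sessions (incl. matches), strength
  sessions, and all sessions (3 x 3 x 3);
* 9 session-count predictors (3 session categories x 3 windows);

plus five one-hot player-position indicator columns.

Conventions: windows are half-open, ``[match_date - w, match_date)``, so
match-day activity never leaks into its own predictors; days with no
recorded activity contribute zero to count and load series but nothing to
per-event series (jump heights, set weights); holiday days, when no data
are collected, are missing for every variable; the standard deviation uses
the n-1 denominator and quartiles use linear interpolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core_data import POSITIONS, SeasonDataset

WINDOWS = (7, 14, 28)
#: the four aggregates applied to every variable; 'sum' only where documented
BASE_AGGS = ("firstquantile", "avg", "thirdquantile", "std")
SUM_AGGS = BASE_AGGS + ("sum",)

POSITION_COLUMNS = tuple(f"Position_{p}" for p in POSITIONS)
KEY_COLUMNS = ("player_id", "match_id", "match_date", "action_type")

_JUMP_COUNT_VARS = ("Jumps_all", "Jumps_below50", "Jumps_50to65", "Jumps_above65")
_KG_VARS = {"lower_body": "LowerWeight", "upper_body": "UpperWeight", "full_body": "FullbodyWeight"}
_PCT_VARS = {"lower_body": "WeightPrct_Lowerbody", "upper_body": "WeightPrct_Upperbody",
             "full_body": "WeightPrct_Fullbody"}
_WELLNESS_VARS = {"fatigue": "Fatigue", "sleep_quality": "SleepQuality",
                  "hours_slept": "HoursSlept", "mood": "Mood"}
#: session categories -> raw session types pooled into them; matches are
#: recorded like volleyball-specific sessions, so they count as volleyball
SESSION_CATEGORIES = {
    "Volleyball": ("volleyball", "match"),
    "Strength": ("strength",),
    "All": ("volleyball", "match", "strength"),
}


@dataclass(frozen=True)
class FeatureConfig:
    """Tunable construction parameters (defaults reproduce the 237-column build)."""

    windows: tuple[int, ...] = WINDOWS
    jump_low_cm: float = 50.0   # below -> low jump
    jump_high_cm: float = 65.0  # above -> high jump; [low, high] -> average


DEFAULT_CONFIG = FeatureConfig()


# ---------------------------------------------------------------------------
# elementary load metrics
# ---------------------------------------------------------------------------

def session_load(rpe: float, duration_min: float) -> float:
    """Session training load: CR10 RPE times session duration in minutes."""
    if not 0 <= rpe <= 10:
        raise ValueError(f"RPE must lie in [0, 10], got {rpe}")
    if duration_min < 0:
        raise ValueError(f"duration must be >= 0, got {duration_min}")
    return rpe * duration_min


def monotony(daily_loads) -> float:
    """Day-to-day load uniformity: mean(daily load) / SD(daily load).

    Days with no session enter as load 0; the SD uses the n-1 denominator.
    Undefined (NaN, never infinity) for fewer than two observed days or a
    constant series.
    """
    x = np.asarray(daily_loads, dtype=float)
    x = x[~np.isnan(x)]
    if x.size < 2:
        return float("nan")
    sd = x.std(ddof=1)
    if sd == 0:
        return float("nan")
    return float(x.mean() / sd)


def strain(window_total_load: float, monotony_value: float) -> float:
    """Training strain: total windowed load times monotony (NaN propagates)."""
    if np.isnan(monotony_value) or np.isnan(window_total_load):
        return float("nan")
    return float(window_total_load * monotony_value)


# ---------------------------------------------------------------------------
# daily / per-event series
# ---------------------------------------------------------------------------

#: documented catalogue of series names accepted by :func:`daily_series`
SERIES_CATALOGUE = (
    "jumps_all", "jumps_low", "jumps_average", "jumps_high", "jump_height_mean",
    "wellness_fatigue", "wellness_sleep_quality", "wellness_hours_slept", "wellness_mood",
    "load_volleyball", "load_strength", "load_all",
    "sessions_volleyball", "sessions_strength", "sessions_all",
    "strength_kg_lower_body", "strength_kg_upper_body", "strength_kg_full_body",
    "strength_pct_lower_body", "strength_pct_upper_body", "strength_pct_full_body",
)


class _PlayerArrays:
    """Per-player day-indexed arrays over the season span (fast path)."""

    __slots__ = ("counts", "height_mean", "wellness", "loads", "n_sessions",
                 "events_kg", "events_pct")

    def __init__(self, T: int, holiday_mask: np.ndarray):
        nan_days = np.where(holiday_mask, np.nan, 0.0)
        self.counts = {v: nan_days.copy() for v in _JUMP_COUNT_VARS}
        self.height_mean = np.full(T, np.nan)
        self.wellness = {v: np.full(T, np.nan) for v in _WELLNESS_VARS.values()}
        self.loads = {c: nan_days.copy() for c in SESSION_CATEGORIES}
        self.n_sessions = {c: nan_days.copy() for c in SESSION_CATEGORIES}
        self.events_kg = {}   # region var name -> (day_idx sorted, values)
        self.events_pct = {}


def _season_span(dataset: SeasonDataset):
    cal = dataset.calendar
    if not len(cal):
        raise ValueError("dataset has an empty calendar")
    d0 = cal["date"].min()
    T = (cal["date"].max() - d0).days + 1
    covered = np.zeros(T, dtype=bool)
    covered[((cal["date"] - d0).dt.days).to_numpy()] = True
    holiday = np.zeros(T, dtype=bool)
    hol_days = cal.loc[cal["phase"] == "holiday", "date"]
    if len(hol_days):
        holiday[((hol_days - d0).dt.days).to_numpy()] = True
    holiday |= ~covered  # days absent from the calendar: nothing collected
    return d0, T, holiday


def _player_arrays(dataset: SeasonDataset, config: FeatureConfig) -> dict[str, _PlayerArrays]:
    d0, T, holiday = _season_span(dataset)
    players = list(dataset.roster["player_id"].drop_duplicates())
    arrs = {p: _PlayerArrays(T, holiday) for p in players}

    jmp = dataset.jumps
    if len(jmp):
        day = ((jmp["date"] - d0).dt.days).to_numpy()
        h = jmp["height_cm"].to_numpy(dtype=float)
        low = h < config.jump_low_cm
        high = h > config.jump_high_cm
        cats = {"Jumps_all": np.ones_like(low), "Jumps_below50": low,
                "Jumps_50to65": ~low & ~high, "Jumps_above65": high}
        for pid, grp in jmp.groupby("player_id"):
            idx = grp.index
            dsel = day[jmp.index.get_indexer(idx)]
            a = arrs[pid]
            for var, mask in cats.items():
                msel = mask[jmp.index.get_indexer(idx)]
                np.add.at(a.counts[var], dsel[msel.astype(bool)], 1.0)
            hsum = np.zeros(T)
            hcnt = np.zeros(T)
            np.add.at(hsum, dsel, h[jmp.index.get_indexer(idx)])
            np.add.at(hcnt, dsel, 1.0)
            with np.errstate(invalid="ignore"):
                a.height_mean = np.where(hcnt > 0, hsum / np.maximum(hcnt, 1), np.nan)

    wel = dataset.wellness
    if len(wel):
        day = ((wel["date"] - d0).dt.days).to_numpy()
        for pid, grp in wel.groupby("player_id"):
            sel = wel.index.get_indexer(grp.index)
            a = arrs[pid]
            for raw, var in _WELLNESS_VARS.items():
                a.wellness[var][day[sel]] = wel[raw].to_numpy(dtype=float)[sel]

    ses = dataset.sessions
    if len(ses):
        day = ((ses["date"] - d0).dt.days).to_numpy()
        load = (ses["rpe"] * ses["duration_min"]).to_numpy(dtype=float)
        stype = ses["session_type"].to_numpy()
        for pid, grp in ses.groupby("player_id"):
            sel = ses.index.get_indexer(grp.index)
            a = arrs[pid]
            for cat, types in SESSION_CATEGORIES.items():
                m = np.isin(stype[sel], types)
                np.add.at(a.loads[cat], day[sel][m], load[sel][m])
                np.add.at(a.n_sessions[cat], day[sel][m], 1.0)

    stg = dataset.strength
    if len(stg):
        day = ((stg["date"] - d0).dt.days).to_numpy()
        kg = stg["weight_kg"].to_numpy(dtype=float)
        pct = stg["weight_pct_1rm"].to_numpy(dtype=float)
        region = stg["body_region"].to_numpy()
        for pid, grp in stg.groupby("player_id"):
            sel = stg.index.get_indexer(grp.index)
            a = arrs[pid]
            for reg, var in _KG_VARS.items():
                m = region[sel] == reg
                order = np.argsort(day[sel][m], kind="stable")
                a.events_kg[var] = (day[sel][m][order], kg[sel][m][order])
                a.events_pct[_PCT_VARS[reg]] = (day[sel][m][order], pct[sel][m][order])
    return arrs


def daily_series(dataset: SeasonDataset, variable: str, player: str,
                 config: FeatureConfig = DEFAULT_CONFIG) -> pd.Series:
    """Date-indexed series of one monitored variable for one player.

    Count and load variables are zero on activity-free days; per-event
    variables (jump height means, set weights) are missing on days without
    events; holiday days are missing for every variable.  ``strength_*``
    names return the per-set observations (non-unique date index).
    """
    if variable not in SERIES_CATALOGUE:
        raise KeyError(f"unknown series {variable!r}; catalogue: {SERIES_CATALOGUE}")
    arrs = _player_arrays(dataset, config)
    if player not in arrs:
        raise KeyError(f"player {player!r} not in roster")
    a = arrs[player]
    d0, T, _ = _season_span(dataset)
    dates = pd.date_range(d0, periods=T, freq="D")

    if variable.startswith("strength_"):
        kind, reg = variable.removeprefix("strength_").split("_", 1)
        var = (_KG_VARS if kind == "kg" else _PCT_VARS)[reg]
        days, vals = (a.events_kg if kind == "kg" else a.events_pct).get(var, (np.array([], int), np.array([])))
        return pd.Series(vals, index=pd.DatetimeIndex(d0 + pd.to_timedelta(days, "D")), name=variable)

    mapping = {
        "jumps_all": a.counts["Jumps_all"], "jumps_low": a.counts["Jumps_below50"],
        "jumps_average": a.counts["Jumps_50to65"], "jumps_high": a.counts["Jumps_above65"],
        "jump_height_mean": a.height_mean,
        "load_volleyball": a.loads["Volleyball"], "load_strength": a.loads["Strength"],
        "load_all": a.loads["All"],
        "sessions_volleyball": a.n_sessions["Volleyball"],
        "sessions_strength": a.n_sessions["Strength"], "sessions_all": a.n_sessions["All"],
        "wellness_fatigue": a.wellness["Fatigue"], "wellness_sleep_quality": a.wellness["SleepQuality"],
        "wellness_hours_slept": a.wellness["HoursSlept"], "wellness_mood": a.wellness["Mood"],
    }
    return pd.Series(mapping[variable], index=dates, name=variable)


_AGG_FUNCS = {
    "firstquantile": lambda x: float(np.percentile(x, 25)),
    "avg": lambda x: float(np.mean(x)),
    "thirdquantile": lambda x: float(np.percentile(x, 75)),
    "std": lambda x: float(np.std(x, ddof=1)) if x.size > 1 else float("nan"),
    "sum": lambda x: float(np.sum(x)),
}


def window_aggregate(series: pd.Series, window_days: int, aggregate: str,
                     match_date) -> float:
    """Aggregate a series over ``[match_date - window, match_date)``.

    Missing values are excluded pairwise; an all-missing window is missing.
    """
    if aggregate not in _AGG_FUNCS:
        raise KeyError(f"unknown aggregate {aggregate!r}")
    match_date = pd.Timestamp(match_date)
    lo = match_date - pd.Timedelta(days=window_days)
    vals = series[(series.index >= lo) & (series.index < match_date)].to_numpy(dtype=float)
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return float("nan")
    return _AGG_FUNCS[aggregate](vals)


# ---------------------------------------------------------------------------
# feature-matrix assembly
# ---------------------------------------------------------------------------

def feature_columns(config: FeatureConfig = DEFAULT_CONFIG) -> list[str]:
    """Predictor column names, in build order (237 under the defaults)."""
    cols: list[str] = []
    W = config.windows
    for agg in BASE_AGGS:
        for w in W:
            cols.append(f"JumpHeight_{agg}{w}")
    for var in _JUMP_COUNT_VARS:
        for agg in SUM_AGGS:
            for w in W:
                cols.append(f"{var}_{agg}{w}")
    for var in _KG_VARS.values():
        for agg in SUM_AGGS:
            for w in W:
                cols.append(f"{var}_{agg}{w}")
    for var in _PCT_VARS.values():
        for agg in BASE_AGGS:
            for w in W:
                cols.append(f"{var}_{agg}{w}")
    for var in _WELLNESS_VARS.values():
        for agg in BASE_AGGS:
            for w in W:
                cols.append(f"{var}_{agg}{w}")
    for cat in SESSION_CATEGORIES:
        for w in W:
            cols.append(f"Load_{cat}_sum{w}")
            cols.append(f"Monotony_{cat}_{w}")
            cols.append(f"Strain_{cat}_{w}")
    for cat in SESSION_CATEGORIES:
        for w in W:
            cols.append(f"Sessions_{cat}_sum{w}")
    return cols


def feature_families(config: FeatureConfig = DEFAULT_CONFIG) -> dict[str, list[str]]:
    """Predictor names grouped into the five documented families."""
    cols = feature_columns(config)
    fam = {"jumps": [], "strength": [], "wellness": [], "load_metrics": [], "session_counts": []}
    for c in cols:
        if c.startswith(("JumpHeight", "Jumps_")):
            fam["jumps"].append(c)
        elif c.startswith(("LowerWeight", "UpperWeight", "FullbodyWeight", "WeightPrct")):
            fam["strength"].append(c)
        elif c.startswith(("Fatigue", "SleepQuality", "HoursSlept", "Mood")):
            fam["wellness"].append(c)
        elif c.startswith(("Load_", "Monotony_", "Strain_")):
            fam["load_metrics"].append(c)
        else:
            fam["session_counts"].append(c)
    return fam


def _window_stats(vals: np.ndarray, aggs) -> list[float]:
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        return [float("nan")] * len(aggs)
    return [_AGG_FUNCS[a](vals) for a in aggs]


def build_feature_matrix(dataset: SeasonDataset, targets: pd.DataFrame,
                         config: FeatureConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """One row per performance target with all predictors attached.

    Returns a DataFrame with the key columns (player_id, match_id,
    match_date, action_type), the predictor columns of
    :func:`feature_columns`, the five position indicators, ``n_actions``
    and the numeric ``target`` score.
    """
    cols = feature_columns(config)
    if config != DEFAULT_CONFIG and len(cols) != 237:
        warnings.warn(
            f"non-default feature configuration yields {len(cols)} predictors; "
            "column-count parity with the reference 237-predictor build is broken",
            stacklevel=2,
        )
    if not len(targets):
        empty = pd.DataFrame(columns=list(KEY_COLUMNS) + cols + list(POSITION_COLUMNS) + ["n_actions", "target"])
        return empty

    arrs = _player_arrays(dataset, config)
    d0, T, _ = _season_span(dataset)
    positions = dataset.positions()

    daily_sum_vars = list(_JUMP_COUNT_VARS)
    pair_cache: dict[tuple[str, pd.Timestamp], np.ndarray] = {}

    nan_aggs = {a: float("nan") for a in SUM_AGGS}

    def all_aggs(raw: np.ndarray) -> dict[str, float]:
        x = raw[~np.isnan(raw)]
        if x.size == 0:
            return nan_aggs
        q1, q3 = np.percentile(x, (25, 75))
        return {"firstquantile": float(q1), "avg": float(x.mean()),
                "thirdquantile": float(q3),
                "std": float(x.std(ddof=1)) if x.size > 1 else float("nan"),
                "sum": float(x.sum())}

    def pair_features(pid: str, mdate: pd.Timestamp) -> np.ndarray:
        a = arrs[pid]
        m = (mdate - d0).days
        vals: dict[str, float] = {}
        for w in config.windows:
            lo, hi = max(m - w, 0), max(min(m, T), 0)
            st = all_aggs(a.height_mean[lo:hi])
            for agg in BASE_AGGS:
                vals[f"JumpHeight_{agg}{w}"] = st[agg]
            for var in daily_sum_vars:
                st = all_aggs(a.counts[var][lo:hi])
                for agg in SUM_AGGS:
                    vals[f"{var}_{agg}{w}"] = st[agg]
            for var in _KG_VARS.values():
                days, v = a.events_kg.get(var, (np.array([], int), np.array([])))
                i, j = np.searchsorted(days, [m - w, m])
                st = all_aggs(v[i:j])
                for agg in SUM_AGGS:
                    vals[f"{var}_{agg}{w}"] = st[agg]
            for var in _PCT_VARS.values():
                days, v = a.events_pct.get(var, (np.array([], int), np.array([])))
                i, j = np.searchsorted(days, [m - w, m])
                st = all_aggs(v[i:j])
                for agg in BASE_AGGS:
                    vals[f"{var}_{agg}{w}"] = st[agg]
            for var in _WELLNESS_VARS.values():
                st = all_aggs(a.wellness[var][lo:hi])
                for agg in BASE_AGGS:
                    vals[f"{var}_{agg}{w}"] = st[agg]
            for cat in SESSION_CATEGORIES:
                daily = a.loads[cat][lo:hi]
                valid = daily[~np.isnan(daily)]
                total = float(valid.sum()) if valid.size else float("nan")
                mono = monotony(daily)
                vals[f"Load_{cat}_sum{w}"] = total
                vals[f"Monotony_{cat}_{w}"] = mono
                vals[f"Strain_{cat}_{w}"] = strain(total, mono) if valid.size else float("nan")
                ns = a.n_sessions[cat][lo:hi]
                nsv = ns[~np.isnan(ns)]
                vals[f"Sessions_{cat}_sum{w}"] = float(nsv.sum()) if nsv.size else float("nan")
        return np.array([vals[c] for c in cols])

    rows = []
    for t in targets.itertuples():
        key = (t.player_id, t.match_date)
        if key not in pair_cache:
            pair_cache[key] = pair_features(*key)
        rows.append(pair_cache[key])

    mat = pd.DataFrame(np.vstack(rows), columns=cols)
    for c in KEY_COLUMNS:
        mat.insert(list(KEY_COLUMNS).index(c), c, targets[c].to_numpy())
    pos = targets["player_id"].map(positions)
    for p, col in zip(POSITIONS, POSITION_COLUMNS):
        mat[col] = (pos == p).astype(float).to_numpy()
    mat["n_actions"] = targets["n_actions"].to_numpy()
    mat["target"] = targets["score"].to_numpy()
    return mat


def predictor_columns(matrix: pd.DataFrame, include_positions: bool = True) -> list[str]:
    """Predictor column names present in a built matrix."""
    skip = set(KEY_COLUMNS) | {"n_actions", "target"}
    cols = [c for c in matrix.columns if c not in skip]
    if not include_positions:
        cols = [c for c in cols if c not in POSITION_COLUMNS]
    return cols
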