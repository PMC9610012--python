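"""Domain tables, CSV persistence and validation for season monitoring data.

A season is stored as seven plain CSV tables (ISO-8601 dates throughout):

``roster.csv``
    Long form: one row per (player, exercise) with the player's position and
    the one-repetition maximum (1-RM) for that exercise.  Players without
    any strength 1-RM appear once with empty exercise columns.
``sessions.csv``
    One row per training session or match: type, duration (minutes) and the
    CR10 rating of perceived exertion.
``jumps.csv``
    One row per jump (height in cm), with a flag for whether the jump was
    recorded in training or in a match.
``strength.csv``
    One row per strength-training set: exercise, body region, repetitions,
    absolute weight (kg) and weight as a fraction of the player's 1-RM.
``wellness.csv``
    One row per (player, morning): fatigue, sleep quality, hours-slept
    rating and mood, each on a 1-10 Likert scale.
``actions.csv``
    One row per annotated match action with its six-level scout rating.
``calendar.csv``
    One row per season day with its phase label; holiday days must carry no
    activity of any kind.

The six-level action rating uses the symbols '=' (worst) ... '#' (best);
the minus rating is stored as ASCII ``-`` on disk and in memory (a Unicode
minus on input is canonicalised).
"""

from __future__ import annotations

from dataclasses import dataclass, fields
from pathlib import Path

import numpy as np
import pandas as pd

POSITIONS = ("setter", "outside_hitter", "middle_blocker", "opposite", "libero")
SESSION_TYPES = ("volleyball", "strength", "match")
BODY_REGIONS = ("full_body", "lower_body", "upper_body")
ACTION_TYPES = ("attack", "block", "attack_reception", "freeball", "pass", "serve", "set")
RATINGS = ("=", "/", "-", "!", "+", "#")
PHASES = ("prep1", "comp1", "holiday", "prep2", "comp2")
JUMP_SOURCES = ("training", "match")

#: canonical column order per table
TABLE_COLUMNS = {
    "roster": ["player_id", "position", "exercise", "one_rm_kg"],
    "sessions": ["player_id", "date", "session_type", "duration_min", "rpe"],
    "jumps": ["player_id", "date", "height_cm", "source"],
    "strength": [
        "player_id", "date", "exercise", "body_region",
        "reps", "weight_kg", "weight_pct_1rm",
    ],
    "wellness": ["player_id", "date", "fatigue", "sleep_quality", "hours_slept", "mood"],
    "actions": ["player_id", "match_id", "match_date", "action_type", "rating"],
    "calendar": ["date", "phase"],
}

_DATE_COLS = {
    "sessions": "date", "jumps": "date", "strength": "date",
    "wellness": "date", "actions": "match_date", "calendar": "date",
}

_SORT_KEYS = {
    "roster": ["player_id", "exercise"],
    "sessions": ["player_id", "date", "session_type", "duration_min", "rpe"],
    "jumps": ["player_id", "date", "height_cm"],
    "strength": ["player_id", "date", "exercise", "weight_kg", "reps"],
    "wellness": ["player_id", "date"],
    "actions": ["player_id", "match_date", "match_id", "action_type", "rating"],
    "calendar": ["date"],
}


class SeasonLoadError(RuntimeError):
    """A season table could not be read (missing file, unreadable CSV)."""


class SeasonValidationError(ValueError):
    """One or more rows violate a documented invariant.

    The message lists every violation as ``table[row]: rule``.
    """

    def __init__(self, violations: list[str]):
        self.violations = list(violations)
        super().__init__(
            f"{len(self.violations)} validation error(s):\n  " + "\n  ".join(self.violations)
        )


@dataclass
class SeasonDataset:
    """All raw season tables, already validated, as pandas DataFrames."""

    roster: pd.DataFrame
    sessions: pd.DataFrame
    jumps: pd.DataFrame
    strength: pd.DataFrame
    wellness: pd.DataFrame
    actions: pd.DataFrame
    calendar: pd.DataFrame

    def positions(self) -> pd.Series:
        """player_id -> position (one entry per player)."""
        return self.roster.drop_duplicates("player_id").set_index("player_id")["position"]

    def one_rm(self) -> pd.Series:
        """(player_id, exercise) -> 1-RM in kg."""
        r = self.roster.dropna(subset=["exercise"])
        return r.set_index(["player_id", "exercise"])["one_rm_kg"]

    def copy(self) -> "SeasonDataset":
        return SeasonDataset(**{f.name: getattr(self, f.name).copy() for f in fields(self)})


def _canonical(df: pd.DataFrame, table: str) -> pd.DataFrame:
    df = df.loc[:, TABLE_COLUMNS[table]]
    df = df.sort_values(_SORT_KEYS[table], kind="mergesort").reset_index(drop=True)
    return df


def canonicalize(dataset: SeasonDataset) -> SeasonDataset:
    """Fixed column order and deterministic (player_id, date, ...) row sort."""
    out = {}
    for f in fields(SeasonDataset):
        df = getattr(dataset, f.name).copy()
        if f.name == "actions":
            df["rating"] = df["rating"].replace("−", "-")
        out[f.name] = _canonical(df, f.name)
    return SeasonDataset(**out)


def _check(violations, table, mask, rule):
    for idx in np.flatnonzero(np.asarray(mask)):
        violations.append(f"{table}[row {idx}]: {rule}")


def validate_season(dataset: SeasonDataset) -> None:
    """Check every per-table invariant plus cross-table integrity.

    Raises :class:`SeasonValidationError` listing each offending row and the
    rule it breaks; malformed values never pass silently.
    """
    v: list[str] = []
    ros, ses, jmp, stg, wel, act, cal = (
        dataset.roster, dataset.sessions, dataset.jumps, dataset.strength,
        dataset.wellness, dataset.actions, dataset.calendar,
    )

    _check(v, "roster", ~ros["position"].isin(POSITIONS), "position must be one of " + ", ".join(POSITIONS))
    has_rm = ros["one_rm_kg"].notna()
    _check(v, "roster", has_rm & ~(ros["one_rm_kg"] > 0), "1-RM must be > 0")
    multi_pos = ros.groupby("player_id")["position"].nunique() > 1
    for pid in multi_pos[multi_pos].index:
        v.append(f"roster[player {pid}]: player listed with more than one position")

    _check(v, "sessions", ~ses["session_type"].isin(SESSION_TYPES), "unknown session_type")
    _check(v, "sessions", ~(ses["duration_min"] >= 0), "duration must be >= 0 minutes")
    _check(v, "sessions", ~ses["rpe"].between(0, 10), "RPE must lie in [0, 10] (CR10 scale)")

    _check(v, "jumps", ~(jmp["height_cm"] > 0), "jump height must be > 0 cm")
    _check(v, "jumps", ~jmp["source"].isin(JUMP_SOURCES), "jump source must be training or match")

    _check(v, "strength", ~stg["body_region"].isin(BODY_REGIONS), "unknown body_region")
    _check(v, "strength", ~((stg["reps"] >= 1) & (stg["reps"] % 1 == 0)), "reps must be an integer >= 1")
    _check(v, "strength", ~(stg["weight_kg"] >= 0), "weight_kg must be >= 0")
    _check(v, "strength", ~(stg["weight_pct_1rm"] >= 0), "weight_pct_1rm must be >= 0")
    one_rm = dataset.one_rm()
    if len(stg):
        keys = pd.MultiIndex.from_frame(stg[["player_id", "exercise"]])
        known = keys.isin(one_rm.index)
        rm = pd.Series(np.nan, index=stg.index)
        rm[known] = one_rm.reindex(keys[known]).to_numpy()
        expected = stg["weight_kg"] / rm
        bad = known & ~np.isclose(stg["weight_pct_1rm"], expected, rtol=5e-3, atol=5e-4)
        _check(v, "strength", bad, "weight_pct_1rm must equal weight_kg / 1-RM for that exercise")

    for col in ("fatigue", "sleep_quality", "hours_slept", "mood"):
        _check(v, "wellness", ~(wel[col].between(1, 10) & (wel[col] % 1 == 0)),
               f"{col} must be an integer Likert value in [1, 10]")

    _check(v, "actions", ~act["action_type"].isin(ACTION_TYPES), "unknown action_type")
    _check(v, "actions", ~act["rating"].isin(RATINGS), "rating must be one of " + " ".join(RATINGS))

    _check(v, "calendar", ~cal["phase"].isin(PHASES), "unknown phase label")
    dup_days = cal["date"].duplicated()
    _check(v, "calendar", dup_days, "duplicate calendar day")

    # referential integrity: player ids resolve, event dates lie on calendar days
    players = set(ros["player_id"])
    cal_days = set(cal["date"])
    holidays = set(cal.loc[cal["phase"] == "holiday", "date"])
    for table, df in (("sessions", ses), ("jumps", jmp), ("strength", stg), ("wellness", wel), ("actions", act)):
        _check(v, table, ~df["player_id"].isin(players), "player_id not present in roster")
        dcol = _DATE_COLS[table]
        _check(v, table, ~df[dcol].isin(cal_days), "date outside the season calendar")
        _check(v, table, df[dcol].isin(holidays), "activity recorded on a holiday day (no data are collected)")

    if v:
        raise SeasonValidationError(v)


def write_season(dataset: SeasonDataset, dir_path: str | Path) -> list[Path]:
    """Write the seven tables as CSV; deterministic order, so repeated
    writes of the same dataset are byte-identical."""
    dir_path = Path(dir_path)
    dir_path.mkdir(parents=True, exist_ok=True)
    ds = canonicalize(dataset)
    written = []
    for f in fields(SeasonDataset):
        df = getattr(ds, f.name).copy()
        dcol = _DATE_COLS.get(f.name)
        if dcol is not None and len(df):
            df[dcol] = pd.to_datetime(df[dcol]).dt.strftime("%Y-%m-%d")
        path = dir_path / f"{f.name}.csv"
        df.to_csv(path, index=False, lineterminator="\n")
        written.append(path)
    return written


def load_season(dir_path: str | Path, validate: bool = True) -> SeasonDataset:
    """Read a season directory written by :func:`write_season`.

    Raises :class:`SeasonLoadError` if a table file is missing and
    :class:`SeasonValidationError` on any invariant breach.
    """
    dir_path = Path(dir_path)
    tables = {}
    dtypes = {
        "player_id": str, "position": str, "exercise": str, "session_type": str,
        "source": str, "body_region": str, "match_id": str, "action_type": str,
        "rating": str, "phase": str,
    }
    for f in fields(SeasonDataset):
        path = dir_path / f"{f.name}.csv"
        if not path.exists():
            raise SeasonLoadError(f"missing season table '{f.name}' (expected {path})")
        cols = TABLE_COLUMNS[f.name]
        try:
            df = pd.read_csv(path, dtype={k: t for k, t in dtypes.items() if k in cols},
                             keep_default_na=True)
        except Exception as exc:  # pragma: no cover - unreadable CSV
            raise SeasonLoadError(f"could not read table '{f.name}': {exc}") from exc
        missing = [c for c in cols if c not in df.columns]
        if missing:
            raise SeasonLoadError(f"table '{f.name}' lacks required column(s) {missing}")
        dcol = _DATE_COLS.get(f.name)
        if dcol is not None:
            df[dcol] = pd.to_datetime(df[dcol])
        tables[f.name] = df
    ds = canonicalize(SeasonDataset(**tables))
    if validate:
        validate_season(ds)
    return ds


def empty_season() -> SeasonDataset:
    """A valid dataset with all tables empty (header-only CSVs on disk)."""
    tables = {}
    for name, cols in TABLE_COLUMNS.items():
        df = pd.DataFrame({c: pd.Series(dtype=object) for c in cols})
        dcol = _DATE_COLS.get(name)
        if dcol is not None:
            df[dcol] = pd.to_datetime(df[dcol])
        for c in ("one_rm_kg", "duration_min", "rpe", "height_cm", "reps",
                  "weight_kg", "weight_pct_1rm", "fatigue", "sleep_quality",
                  "hours_slept", "mood"):
            if c in df.columns:
                df[c] = df[c].astype(float)
        tables[name] = df
    return SeasonDataset(**tables)
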