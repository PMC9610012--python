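"""Rating-to-score transformation and per-match performance targets.

A video scout grades every match action on a six-symbol ordinal scale,
'=' (action loses the point) through '#' (action wins the point).  Grades
are made numeric by looking up, in a historical database of international
matches, the empirical probability that an action with that grade leads to
winning the rally, scaled to [0, 10]:

    score(action_type, rating) = 10 * n_won / n_total

Match performance of a player for one action type is then the arithmetic
mean of the scores of all their actions of that type in that match.  Only
the action types relevant for a player's position produce a target row:
serves for setters; attacks for outside hitters, middle blockers and
opposites; blocks for middle blockers; passes for liberos and opposites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd

from .core_data import RATINGS, SeasonDataset

#: rating order worst -> best; the serve scale uses '/' as second-highest
DEFAULT_RATING_ORDER = ("=", "/", "-", "!", "+", "#")
SERVE_RATING_ORDER = ("=", "-", "!", "+", "/", "#")

#: action types that yield a performance target, and the positions for
#: which each is relevant
RELEVANT_ACTIONS: dict[str, tuple[str, ...]] = {
    "serve": ("setter",),
    "attack": ("outside_hitter", "middle_blocker", "opposite"),
    "block": ("middle_blocker",),
    "pass": ("libero", "opposite"),
}

OFFENSE_ACTIONS = ("attack", "serve")
DEFENSE_ACTIONS = ("pass", "block")


def rating_order(action_type: str) -> tuple[str, ...]:
    """Rating symbols ordered worst -> best for the given action type."""
    if action_type == "serve":
        return SERVE_RATING_ORDER
    if action_type in RELEVANT_ACTIONS or action_type in ("attack_reception", "freeball", "set"):
        return DEFAULT_RATING_ORDER
    raise ValueError(f"unknown action type: {action_type!r}")


@dataclass(frozen=True)
class RatingScoreMap:
    """(action_type, rating) -> score in [0, 10] derived from rally-win rates."""

    scores: dict[tuple[str, str], float]

    def score(self, action_type: str, rating: str) -> float:
        rating = "-" if rating == "−" else rating
        try:
            return self.scores[(action_type, rating)]
        except KeyError:
            raise KeyError(
                f"no score for action {action_type!r} with rating {rating!r}"
            ) from None

    def action_types(self) -> list[str]:
        return sorted({a for a, _ in self.scores})

    def to_frame(self) -> pd.DataFrame:
        rows = [{"action_type": a, "rating": r, "score": s} for (a, r), s in sorted(self.scores.items())]
        return pd.DataFrame(rows, columns=["action_type", "rating", "score"])


def build_score_map(historic_outcomes: pd.DataFrame) -> RatingScoreMap:
    """Derive the rating-score map from historical rally outcomes.

    Parameters
    ----------
    historic_outcomes
        Table with columns ``action_type, rating, n_total, n_won``; one row
        per (action type, rating) cell, counting historical occurrences and
        how many led to winning the point.

    Every action type present must have all six rating cells with
    ``n_total >= 1``; absent cells are an error, never imputed.  A score
    map that is non-monotone in the rating order (possible in small
    historical samples) triggers a warning but is returned as-is.
    """
    df = historic_outcomes.copy()
    df["rating"] = df["rating"].replace("−", "-")
    bad = df[(df["n_won"] > df["n_total"]) | (df["n_total"] < 1)]
    if len(bad):
        raise ValueError(
            "historic outcomes need n_total >= 1 and n_won <= n_total; offending cells: "
            + ", ".join(f"({r.action_type}, {r.rating})" for r in bad.itertuples())
        )
    scores: dict[tuple[str, str], float] = {}
    for action, grp in df.groupby("action_type"):
        present = set(grp["rating"])
        missing = [r for r in RATINGS if r not in present]
        if missing:
            raise ValueError(f"action {action!r} lacks historical cells for rating(s) {missing}")
        for row in grp.itertuples():
            scores[(action, row.rating)] = 10.0 * row.n_won / row.n_total
        order = rating_order(action)
        vals = [scores[(action, r)] for r in order]
        if any(b < a for a, b in zip(vals, vals[1:])):
            warnings.warn(
                f"score map for {action!r} is not monotone in the rating order "
                f"(empirical win rates: {dict(zip(order, vals))})",
                stacklevel=2,
            )
    return RatingScoreMap(scores)


def match_performance(
    actions: pd.DataFrame,
    score_map: RatingScoreMap,
    roster: pd.DataFrame,
) -> pd.DataFrame:
    """Per-(player, match, action type) mean rating-score targets.

    Only position-relevant action types are retained (see
    :data:`RELEVANT_ACTIONS`); a player-match with no action of a relevant
    type yields no row.  Columns: ``player_id, match_id, match_date,
    action_type, score, n_actions``.
    """
    cols = ["player_id", "match_id", "match_date", "action_type", "score", "n_actions"]
    if not len(actions):
        return pd.DataFrame(columns=cols)
    act = actions.copy()
    act["rating"] = act["rating"].replace("−", "-")
    positions = roster.drop_duplicates("player_id").set_index("player_id")["position"]
    act["position"] = act["player_id"].map(positions)

    keep = pd.Series(False, index=act.index)
    for action, pos in RELEVANT_ACTIONS.items():
        keep |= (act["action_type"] == action) & act["position"].isin(pos)
    act = act[keep]
    if not len(act):
        return pd.DataFrame(columns=cols)

    act["score"] = [score_map.score(a, r) for a, r in zip(act["action_type"], act["rating"])]
    out = (
        act.groupby(["player_id", "match_id", "match_date", "action_type"], as_index=False)
        .agg(score=("score", "mean"), n_actions=("score", "size"))
    )
    out = out.sort_values(["player_id", "match_date", "match_id", "action_type"], kind="mergesort")
    return out.reset_index(drop=True)[cols]


def targets_from_dataset(dataset: SeasonDataset, score_map: RatingScoreMap) -> pd.DataFrame:
    """Convenience wrapper: performance targets for a full season dataset."""
    return match_performance(dataset.actions, score_map, dataset.roster)
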