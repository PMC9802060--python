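"""Cohort construction: eligibility rules and index/pre/post season assignment.

For each player the *primary* severe lower-extremity injury (first severe
event in the groin/hip/thigh, knee or ankle region) defines the index
season.  Missed games spilling into the following season remain part of the
index season.  The pre-injury season is the season immediately preceding the
index season; year 1 (post1) is the first season played after return to
sport, and year 2 (post2) is the season immediately after post1 when played.

Eligibility requires: age 18+ at injury, at least three distinct seasons
played inside the study window, play in the pre-injury season, no more than
a Minor injury (<= 3 games missed) in the pre-injury season, and no
time-loss reinjury with onset within 14 calendar days of return to sport.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .classify import LOWER_EXTREMITY_REGIONS, Severity

LE_REGION_VALUES = tuple(r.value for r in LOWER_EXTREMITY_REGIONS)

EXCLUSION_REASONS = (
    "under_3_seasons",
    "under_18",
    "no_prior_season_play",
    "prior_season_injury_gt_minor",
    "reinjury_within_14d",
    "no_post_season_play",
)

#: Study window defaults: seasons ending 2008-2019, extraction cutoff.
DEFAULT_SEASON_MIN = 2008
DEFAULT_SEASON_MAX = 2019
REINJURY_WINDOW_DAYS = 14  # inclusive
PRIOR_SEASON_MAX_GAMES_MISSED = 3  # at most a Minor injury allowed pre-injury
MIN_SEASONS_PLAYED = 3


def _season_order(season_id: str) -> int:
    return int(season_id)


@dataclass
class SeasonAssignment:
    index_season: str
    pre_season: str
    post1_season: str | None
    post2_season: str | None
    index_event: pd.Series


def assign_seasons(
    player_events: pd.DataFrame, player_games: pd.DataFrame
) -> SeasonAssignment | None:
    """Assign index/pre/post seasons from a player's events and game log.

    Returns ``None`` when the player has no severe lower-extremity event.
    The index event is the first (by onset) severe LE event; if its missed
    games spill into the next season the index season does not shift.
    """
    severe = player_events[
        (player_events["severity"] == Severity.SEVERE.value)
        & (player_events["body_region"].isin(LE_REGION_VALUES))
    ]
    if severe.empty:
        return None
    index_event = severe.sort_values("onset_date").iloc[0]
    index_season = str(index_event["season_id"])
    pre_season = str(_season_order(index_season) - 1)

    played_seasons = sorted({str(s) for s in player_games["season_id"]}, key=_season_order)

    post1: str | None = None
    if index_event["return_observed"]:
        return_date = index_event["return_date"]
        return_rows = player_games[player_games["game_date"] == return_date]
        return_season = (
            str(return_rows["season_id"].iloc[0]) if not return_rows.empty else None
        )
        if return_season is not None and return_season != index_season:
            post1 = return_season
        else:
            later = [s for s in played_seasons if _season_order(s) > _season_order(index_season)]
            post1 = later[0] if later else None

    post2: str | None = None
    if post1 is not None:
        candidate = str(_season_order(post1) + 1)
        if candidate in played_seasons:
            post2 = candidate

    return SeasonAssignment(index_season, pre_season, post1, post2, index_event)


def check_eligibility(
    assignment: SeasonAssignment,
    player_events: pd.DataFrame,
    player_games: pd.DataFrame,
    birth_date: pd.Timestamp | None,
    season_min: int = DEFAULT_SEASON_MIN,
    season_max: int = DEFAULT_SEASON_MAX,
) -> tuple[bool, list[str]]:
    """Evaluate the five eligibility rules; returns (eligible, reason codes)."""
    reasons: list[str] = []
    index_event = assignment.index_event

    seasons_in_window = {
        str(s)
        for s in player_games["season_id"]
        if season_min <= _season_order(str(s)) <= season_max
    }
    if len(seasons_in_window) < MIN_SEASONS_PLAYED:
        reasons.append("under_3_seasons")

    if birth_date is not None and not pd.isna(birth_date):
        age = (index_event["onset_date"] - birth_date).days / 365.25
        if age < 18.0:
            reasons.append("under_18")

    if assignment.pre_season not in set(map(str, player_games["season_id"])):
        reasons.append("no_prior_season_play")
    else:
        prior = player_events[
            (player_events["season_id"].astype(str) == assignment.pre_season)
            & (player_events["games_missed"] > PRIOR_SEASON_MAX_GAMES_MISSED)
            & (player_events["event_id"] != index_event["event_id"])
        ]
        if not prior.empty:
            reasons.append("prior_season_injury_gt_minor")

    if index_event["return_observed"]:
        return_date = index_event["return_date"]
        others = player_events[player_events["event_id"] != index_event["event_id"]]
        deltas = (others["onset_date"] - return_date).dt.days
        if ((deltas >= 1) & (deltas <= REINJURY_WINDOW_DAYS)).any():
            reasons.append("reinjury_within_14d")

    if assignment.post1_season is None:
        reasons.append("no_post_season_play")

    return (len(reasons) == 0, reasons)


def build_cohort(
    events: pd.DataFrame,
    game_records: pd.DataFrame,
    roster_metadata: pd.DataFrame | None = None,
    season_min: int = DEFAULT_SEASON_MIN,
    season_max: int = DEFAULT_SEASON_MAX,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Build the study cohort from classified events and game logs.

    Returns (cohort, exclusion log, strata counts).  The strata counts hold,
    overall and per lower-extremity region, the number of severely injured
    players, the number who played a first post-injury season, and the
    number who played a second — the denominators of the prevalence tables.
    Missing roster metadata leaves covariates absent (complete-case handling
    happens in the adjusted models), it does not exclude a player.
    """
    roster = (
        roster_metadata.set_index("player_id")
        if roster_metadata is not None and not roster_metadata.empty
        else pd.DataFrame()
    )
    games_by_player = dict(tuple(game_records.groupby("player_id")))
    events_by_player = dict(tuple(events.groupby("player_id")))

    cohort_rows: list[dict] = []
    exclusion_rows: list[dict] = []
    strata: dict[str, dict[str, int]] = {
        key: {"severe": 0, "post1": 0, "post2": 0}
        for key in ("overall",) + LE_REGION_VALUES
    }

    for pid, pevents in events_by_player.items():
        pgames = games_by_player.get(pid)
        if pgames is None or pgames.empty:
            continue
        assignment = assign_seasons(pevents, pgames)
        if assignment is None:
            continue
        if not (season_min <= _season_order(assignment.index_season) <= season_max):
            continue
        index_event = assignment.index_event
        region = str(index_event["body_region"])

        birth_date = None
        height = weight = np.nan
        position = None
        if not roster.empty and pid in roster.index:
            meta = roster.loc[pid]
            birth_date = pd.to_datetime(meta.get("birth_date"), errors="coerce")
            height = pd.to_numeric(meta.get("height_cm"), errors="coerce")
            weight = pd.to_numeric(meta.get("weight_kg"), errors="coerce")
            position = meta.get("position")

        eligible, reasons = check_eligibility(
            assignment, pevents, pgames, birth_date, season_min, season_max
        )
        if not eligible:
            exclusion_rows.append(
                {"player_id": pid, "reasons": ";".join(reasons), "body_region": region}
            )
            continue

        strata["overall"]["severe"] += 1
        strata[region]["severe"] += 1
        strata["overall"]["post1"] += 1
        strata[region]["post1"] += 1
        if assignment.post2_season is not None:
            strata["overall"]["post2"] += 1
            strata[region]["post2"] += 1

        age = (
            float((index_event["onset_date"] - birth_date).days / 365.25)
            if birth_date is not None and not pd.isna(birth_date)
            else np.nan
        )
        bmi = (
            float(weight / (height / 100.0) ** 2)
            if np.isfinite(height) and np.isfinite(weight)
            else np.nan
        )
        seasons_at_injury = len(
            {
                str(s)
                for s in pgames["season_id"]
                if _season_order(str(s)) <= _season_order(assignment.index_season)
            }
        )
        cohort_rows.append(
            {
                "player_id": pid,
                "index_season": assignment.index_season,
                "pre_season": assignment.pre_season,
                "post1_season": assignment.post1_season,
                "post2_season": assignment.post2_season,
                "index_event_id": index_event["event_id"],
                "onset_date": index_event["onset_date"],
                "return_date": index_event["return_date"],
                "games_missed": int(index_event["games_missed"]),
                "days_to_return": index_event["days_to_return"],
                "body_region": region,
                "severity": index_event["severity"],
                "age_at_injury": age,
                "seasons_played_at_injury": seasons_at_injury,
                "position": position,
                "bmi": bmi,
                "injury_year": _season_order(assignment.index_season),
            }
        )

    # severely injured but ineligible players still count toward the severe
    # denominator: the flow is severe -> eligible/post1 -> post2
    for row in exclusion_rows:
        strata["overall"]["severe"] += 1
        if row["body_region"] in strata:
            strata[row["body_region"]]["severe"] += 1

    cohort = pd.DataFrame(cohort_rows)
    if not cohort.empty:
        cohort = cohort.sort_values("player_id").reset_index(drop=True)
    exclusions = pd.DataFrame(exclusion_rows, columns=["player_id", "reasons", "body_region"])
    return cohort, exclusions, strata
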