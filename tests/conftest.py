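from __future__ import annotations

import pandas as pd
import pytest

from courtside.synthetic import SyntheticConfig, generate_league


@pytest.fixture(scope="session")
def tiny_league():
    """4 teams, 20-game seasons, 2 seasons; high hazard so events exist."""
    config = SyntheticConfig(
        n_teams=4,
        games_per_team=20,
        n_seasons=2,
        roster_size=5,
        injury_hazard=0.03,
        seed=7,
        first_season_end_year=2010,
    )
    return config, generate_league(config)


@pytest.fixture(scope="session")
def mid_league():
    """A league large enough for cohort/performance statistics."""
    config = SyntheticConfig(
        n_teams=8,
        games_per_team=82,
        n_seasons=5,
        roster_size=8,
        injury_hazard=0.006,
        seed=11,
        first_season_end_year=2009,
    )
    return config, generate_league(config)


def make_event(
    player_id,
    season_id,
    onset,
    games_missed,
    severity,
    body_region,
    return_date=None,
    note="",
):
    """Hand-built classified injury-event row for cohort tests."""
    onset = pd.Timestamp(onset)
    ret = pd.Timestamp(return_date) if return_date is not None else pd.NaT
    return {
        "event_id": f"{player_id}:{onset.date()}",
        "player_id": player_id,
        "team_id": "TA",
        "season_id": str(season_id),
        "onset_date": onset,
        "return_date": ret,
        "games_missed": games_missed,
        "days_to_return": float((ret - onset).days) if return_date is not None else float("nan"),
        "return_observed": return_date is not None,
        "note": note,
        "severity": severity,
        "body_region": body_region,
    }


def make_games(player_id, season_dates, team_id="TA"):
    """Minimal game-log rows: one row per (season, date)."""
    rows = []
    for season_id, dates in season_dates.items():
        for d in dates:
            rows.append(
                {
                    "player_id": player_id,
                    "season_id": str(season_id),
                    "game_date": pd.Timestamp(d),
                    "team_id": team_id,
                    "started": True,
                    "minutes": 30.0,
                    "points": 10,
                    "rebounds": 4,
                    "field_goals_attempted": 9,
                }
            )
    return rows
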