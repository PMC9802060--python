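"""Reader validation, game-level linkage semantics, and cross-source agreement."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from courtside.classify import annotate_events
from courtside.errors import AgreementUndefinedError, DuplicateKeyError, SchemaError
from courtside.ingest import (
    agreement,
    link_injury_events,
    read_events,
    read_game_logs,
    read_transactions,
    write_events,
)

TXN_HEADER = "date,player_id,team_id,event_kind,note\n"
GAME_HEADER = (
    "player_id,season_id,game_date,team_id,started,minutes,points,rebounds,"
    "field_goals_attempted\n"
)


def test_empty_transaction_file_gives_empty_list(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(TXN_HEADER)
    df, issues = read_transactions(path)
    assert df.empty and not issues


def test_three_row_fixture_parses_in_date_order(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(
        TXN_HEADER
        + "2012-01-05,P1,TA,deactivate,sore knee\n"
        + "2012-01-02,P2,TA,activate,\n"
        + "2012-01-03,P3,TB,other,traded\n"
    )
    df, issues = read_transactions(path)
    assert len(df) == 3 and not issues
    assert list(df["player_id"]) == ["P2", "P3", "P1"]
    assert df["date"].is_monotonic_increasing


def test_impossible_month_flagged_and_excluded(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text(TXN_HEADER + "2019-13-01,P1,TA,deactivate,sore knee\n")
    df, issues = read_transactions(path)
    assert df.empty
    assert len(issues) == 1 and issues[0].excluded and issues[0].field == "date"


def test_missing_column_error_names_the_column(tmp_path):
    path = tmp_path / "t.csv"
    path.write_text("date,player_id,team_id,note\n")
    with pytest.raises(SchemaError, match="event_kind"):
        read_transactions(path)


def test_duplicate_player_date_rows_raise(tmp_path):
    path = tmp_path / "g.csv"
    row = "P1,2012,2012-01-05,TA,true,30,12,3,9\n"
    path.write_text(GAME_HEADER + row + row)
    with pytest.raises(DuplicateKeyError, match="P1"):
        read_game_logs(path)


def test_minutes_over_sixty_flagged_not_dropped(tmp_path):
    path = tmp_path / "g.csv"
    path.write_text(GAME_HEADER + "P1,2012,2012-01-05,TA,true,61,12,3,9\n")
    df, issues = read_game_logs(path)
    assert len(df) == 1
    assert any(i.field == "minutes" and not i.excluded for i in issues)


def test_game_log_round_trips_through_writer(tmp_path, tiny_league):
    _, league = tiny_league
    from courtside.synthetic import write_league

    paths = write_league(league, tmp_path)
    df, issues = read_game_logs(paths["games"])
    assert not issues
    pd.testing.assert_frame_equal(
        df.reset_index(drop=True).sort_values(["player_id", "game_date"]).reset_index(drop=True),
        league.games.sort_values(["player_id", "game_date"]).reset_index(drop=True),
        check_dtype=False,
    )


def _toy_league(played_games: list[int], deactivate_after: int | None, n_games: int = 5):
    """One team, one player, daily games; returns (txns, games, schedule)."""
    dates = pd.date_range("2012-01-01", periods=n_games, freq="D")
    schedule = pd.DataFrame(
        {"team_id": "TA", "season_id": "2012", "game_date": dates}
    )
    games = pd.DataFrame(
        {
            "player_id": "P1",
            "season_id": "2012",
            "game_date": dates[[g - 1 for g in played_games]],
            "team_id": "TA",
            "started": True,
            "minutes": 30.0,
            "points": 10,
            "rebounds": 3,
            "field_goals_attempted": 8,
        }
    )
    if deactivate_after is None:
        txns = pd.DataFrame(columns=["date", "player_id", "team_id", "event_kind", "note"])
        txns["date"] = pd.to_datetime(txns["date"])
    else:
        txns = pd.DataFrame(
            {
                "date": [dates[deactivate_after]],  # first missed game date
                "player_id": "P1",
                "team_id": "TA",
                "event_kind": "deactivate",
                "note": "sprained right ankle",
            }
        )
    return txns, games, schedule


def test_five_game_toy_example_links_one_event():
    txns, games, schedule = _toy_league(played_games=[1, 2, 5], deactivate_after=2)
    events, report = link_injury_events(txns, games, schedule)
    assert len(events) == 1
    event = events.iloc[0]
    assert event["onset_date"] == pd.Timestamp("2012-01-03")
    assert event["return_date"] == pd.Timestamp("2012-01-05")
    assert event["games_missed"] == 2
    assert event["days_to_return"] == 2
    assert report.missing_recovery == 0


def test_player_playing_every_game_yields_no_event():
    txns, games, schedule = _toy_league(played_games=[1, 2, 3, 4, 5], deactivate_after=None)
    events, _ = link_injury_events(txns, games, schedule)
    assert events.empty


def test_never_returning_player_flagged_missing_recovery():
    txns, games, schedule = _toy_league(played_games=[1, 2], deactivate_after=2)
    events, report = link_injury_events(txns, games, schedule)
    assert len(events) == 1
    event = events.iloc[0]
    assert event["games_missed"] == 3  # remaining team games
    assert pd.isna(event["return_date"]) and not event["return_observed"]
    assert report.missing_recovery == 1


def test_deactivation_without_missed_game_produces_no_event():
    # deactivated on the game-2 date but plays every game
    txns, games, schedule = _toy_league(played_games=[1, 2, 3, 4, 5], deactivate_after=1)
    events, report = link_injury_events(txns, games, schedule)
    assert events.empty
    assert report.deactivate_without_missed_game == 1


def test_transaction_player_absent_from_game_logs_reported():
    txns, games, schedule = _toy_league(played_games=[1, 2, 5], deactivate_after=2)
    txns = pd.concat(
        [
            txns,
            pd.DataFrame(
                {
                    "date": [pd.Timestamp("2012-01-02")],
                    "player_id": "GHOST",
                    "team_id": "TA",
                    "event_kind": "deactivate",
                    "note": "knee",
                }
            ),
        ]
    )
    events, report = link_injury_events(txns, games, schedule)
    assert report.players_without_game_logs == 1
    assert set(events["player_id"]) == {"P1"}


def test_events_round_trip_and_relink_idempotence(tmp_path, tiny_league):
    _, league = tiny_league
    events, _ = link_injury_events(league.transactions, league.games, league.schedule)
    path = tmp_path / "events.csv"
    write_events(events, path)
    back = read_events(path)
    pd.testing.assert_frame_equal(back, events, check_dtype=False)


def _agreement_frame(rows):
    df = pd.DataFrame(
        rows, columns=["player_id", "onset_date", "games_missed", "body_region"]
    )
    df["onset_date"] = pd.to_datetime(df["onset_date"])
    return df


def test_agreement_identical_sets_is_100():
    a = _agreement_frame([("P1", "2012-01-03", 4, "knee"), ("P2", "2012-02-01", 2, "ankle")])
    result = agreement(a, a.copy())
    assert (result.pct_exact_date, result.pct_missed_games, result.pct_injury_site) == (
        100.0,
        100.0,
        100.0,
    )


def test_agreement_single_region_difference_is_50():
    a = _agreement_frame([("P1", "2012-01-03", 4, "knee"), ("P2", "2012-02-01", 2, "ankle")])
    b = _agreement_frame([("P1", "2012-01-03", 4, "knee"), ("P2", "2012-02-01", 2, "knee")])
    result = agreement(a, b)
    assert result.pct_injury_site == 50.0
    assert result.pct_exact_date == 100.0 and result.pct_missed_games == 100.0


def test_agreement_partial_exact_dates():
    rows_a, rows_b = [], []
    for i in range(10):
        onset = pd.Timestamp("2012-01-01") + pd.Timedelta(days=10 * i)
        rows_a.append((f"P{i}", onset, 3, "knee"))
        shifted = onset if i < 4 else onset + pd.Timedelta(days=2)
        rows_b.append((f"P{i}", shifted, 3, "knee"))
    result = agreement(_agreement_frame(rows_a), _agreement_frame(rows_b))
    assert result.pct_exact_date == 40.0
    assert result.n_matched == 10


def test_agreement_empty_input_is_an_error():
    a = _agreement_frame([("P1", "2012-01-03", 4, "knee")])
    empty = _agreement_frame([])
    with pytest.raises(AgreementUndefinedError):
        agreement(a, empty)


def test_no_player_event_overlap(mid_league):
    _, league = mid_league
    events, _ = link_injury_events(league.transactions, league.games, league.schedule)
    events = annotate_events(events)
    for pid, grp in events.groupby("player_id"):
        grp = grp.sort_values("onset_date")
        prev_return = None
        for row in grp.itertuples():
            if prev_return is not None:
                assert row.onset_date > prev_return
            if row.return_observed:
                prev_return = row.return_date
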