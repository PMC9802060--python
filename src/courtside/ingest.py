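"""Reading, validation and game-level linkage of transaction and game logs.

The linkage step turns a dated roster-transaction log (deactivations with
free-text injury notes) and per-player box scores into time-loss injury
events at individual-game resolution: an event is a maximal run of
consecutively missed team games that begins at a deactivate transaction.
Because practice dates are unobservable, injury onset is dated at the first
*missed* team game and recovery at the first game *played* afterwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import AgreementUndefinedError, DuplicateKeyError, SchemaError

TRANSACTION_COLUMNS = ["date", "player_id", "team_id", "event_kind", "note"]
GAME_COLUMNS = [
    "player_id",
    "season_id",
    "game_date",
    "team_id",
    "started",
    "minutes",
    "points",
    "rebounds",
    "field_goals_attempted",
]
SCHEDULE_COLUMNS = ["team_id", "season_id", "game_date"]

EVENT_COLUMNS = [
    "event_id",
    "player_id",
    "team_id",
    "season_id",
    "onset_date",
    "return_date",
    "games_missed",
    "days_to_return",
    "return_observed",
    "note",
]

_EVENT_KINDS = {"deactivate", "activate", "other"}


@dataclass
class RowIssue:
    """One malformed or suspicious input row, reported rather than dropped silently."""

    row: int
    field: str
    problem: str
    value: str
    excluded: bool


@dataclass
class ValidationReport:
    """Counts of records flagged during linkage, mirroring internal validity checks."""

    unparseable_dates: int = 0
    missing_recovery: int = 0
    negative_recovery: int = 0
    deactivate_without_missed_game: int = 0
    activation_without_deactivation: int = 0
    players_without_game_logs: int = 0
    trade_windows_flagged: int = 0
    excluded_event_ids: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "unparseable_dates": self.unparseable_dates,
            "missing_recovery": self.missing_recovery,
            "negative_recovery": self.negative_recovery,
            "deactivate_without_missed_game": self.deactivate_without_missed_game,
            "activation_without_deactivation": self.activation_without_deactivation,
            "players_without_game_logs": self.players_without_game_logs,
            "trade_windows_flagged": self.trade_windows_flagged,
            "excluded_event_ids": list(self.excluded_event_ids),
        }


def _require_columns(df: pd.DataFrame, columns: list[str], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} file is missing required column(s): {', '.join(missing)}")


def _parse_dates(
    df: pd.DataFrame, column: str, issues: list[RowIssue]
) -> tuple[pd.DataFrame, pd.Series]:
    parsed = pd.to_datetime(df[column], format="%Y-%m-%d", errors="coerce")
    bad = parsed.isna() & df[column].notna() | df[column].isna()
    for idx in df.index[bad]:
        issues.append(
            RowIssue(
                row=int(idx),
                field=column,
                problem="unparseable ISO date",
                value=str(df.loc[idx, column]),
                excluded=True,
            )
        )
    return df.loc[~bad].copy(), parsed.loc[~bad]


def read_transactions(path: str | Path) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Read a transaction CSV: date, player_id, team_id, event_kind, note.

    Rows with unparseable dates are excluded and reported as issues; rows
    with an unrecognised event kind are coerced to ``other`` and flagged.
    The result is sorted by date (stable).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, TRANSACTION_COLUMNS, "transaction")
    issues: list[RowIssue] = []
    df, parsed = _parse_dates(df, "date", issues)
    df["date"] = parsed
    kinds = df["event_kind"].str.strip().str.lower()
    bad_kind = ~kinds.isin(_EVENT_KINDS)
    for idx in df.index[bad_kind]:
        issues.append(
            RowIssue(
                row=int(idx),
                field="event_kind",
                problem="unknown event kind, coerced to 'other'",
                value=str(df.loc[idx, "event_kind"]),
                excluded=False,
            )
        )
    df["event_kind"] = kinds.where(~bad_kind, "other")
    df = df.sort_values("date", kind="stable").reset_index(drop=True)
    return df[TRANSACTION_COLUMNS], issues


def read_game_logs(path: str | Path) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Read a game-log CSV (one row per player-game).

    Duplicate (player_id, game_date) keys are a format error.  Minutes above
    60 are flagged but retained; negative or unparseable numeric fields are
    flagged and excluded.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, GAME_COLUMNS, "game-log")
    issues: list[RowIssue] = []
    df, parsed = _parse_dates(df, "game_date", issues)
    df["game_date"] = parsed

    dup = df.duplicated(subset=["player_id", "game_date"], keep=False)
    if dup.any():
        keys = (
            df.loc[dup, ["player_id", "game_date"]]
            .drop_duplicates()
            .apply(lambda r: f"({r.player_id}, {r.game_date.date()})", axis=1)
            .tolist()
        )
        raise DuplicateKeyError(
            "duplicate player-date rows in game log: " + ", ".join(keys[:20])
        )

    df["started"] = df["started"].str.strip().str.lower().isin({"true", "1", "t", "yes"})
    keep = pd.Series(True, index=df.index)
    for col in ["minutes", "points", "rebounds", "field_goals_attempted"]:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = values.isna() | (values < 0)
        for idx in df.index[bad]:
            issues.append(
                RowIssue(int(idx), col, "negative or non-numeric value", str(df.loc[idx, col]), True)
            )
        keep &= ~bad
        df[col] = values
    over = df["minutes"] > 60
    for idx in df.index[over & keep]:
        issues.append(RowIssue(int(idx), "minutes", "minutes exceed 60", str(df.loc[idx, "minutes"]), False))
    df = df.loc[keep].copy()
    for col in ["points", "rebounds", "field_goals_attempted"]:
        df[col] = df[col].astype(int)
    df = df.sort_values(["game_date", "player_id"], kind="stable").reset_index(drop=True)
    return df[GAME_COLUMNS], issues


def read_schedule(path: str | Path) -> tuple[pd.DataFrame, list[RowIssue]]:
    """Read a schedule CSV: team_id, season_id, game_date."""
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    _require_columns(df, SCHEDULE_COLUMNS, "schedule")
    issues: list[RowIssue] = []
    df, parsed = _parse_dates(df, "game_date", issues)
    df["game_date"] = parsed
    dup = df.duplicated(subset=["team_id", "game_date"], keep=False)
    if dup.any():
        raise DuplicateKeyError("duplicate team-date rows in schedule")
    df = df.sort_values(["team_id", "game_date"], kind="stable").reset_index(drop=True)
    return df[SCHEDULE_COLUMNS], issues


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    out = events.copy()
    for col in ("onset_date", "return_date"):
        if col in out.columns:
            out[col] = pd.to_datetime(out[col]).dt.strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"player_id": str, "team_id": str, "season_id": str})
    for col in ("onset_date", "return_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d", errors="coerce")
    df["note"] = df["note"].fillna("")
    return df


def link_injury_events(
    transactions: pd.DataFrame,
    game_records: pd.DataFrame,
    team_schedule: pd.DataFrame,
) -> tuple[pd.DataFrame, ValidationReport]:
    """Link transactions and box scores into time-loss injury events.

    For each player, the relevant schedule is the union of the schedules of
    every (team, season) the player appeared in.  A maximal run of missed
    team games produces one event when a deactivate transaction points into
    it (the first scheduled game on/after the transaction date is part of
    the run); runs with no deactivation (rest, coach decisions) produce no
    event.  Events whose player never plays again are retained but flagged
    ``return_observed = False`` and counted as missing recovery.
    """
    report = ValidationReport()

    sched_by_ts: dict[tuple[str, str], list] = {
        (str(team), str(season)): grp["game_date"].sort_values().tolist()
        for (team, season), grp in team_schedule.groupby(["team_id", "season_id"])
    }
    season_of_date: dict[tuple[str, pd.Timestamp], str] = {}

    games_by_player = dict(tuple(game_records.groupby("player_id")))
    deact = transactions[transactions["event_kind"] == "deactivate"]
    act = transactions[transactions["event_kind"] == "activate"]
    deact_by_player = dict(tuple(deact.groupby("player_id")))
    act_by_player = dict(tuple(act.groupby("player_id")))

    txn_players = set(transactions["player_id"])
    log_players = set(game_records["player_id"])
    report.players_without_game_logs = len(txn_players - log_players)

    rows: list[dict] = []
    for pid, pgames in games_by_player.items():
        pairs = pgames[["team_id", "season_id"]].drop_duplicates()
        seasons_teams: dict[str, list[str]] = {}
        for team, season in pairs.itertuples(index=False):
            seasons_teams.setdefault(str(season), []).append(str(team))
        entries: list[tuple[pd.Timestamp, str, str]] = []  # (date, season, team)
        for season, teams in seasons_teams.items():
            if len(teams) > 1:
                report.trade_windows_flagged += 1
            seen: set[pd.Timestamp] = set()
            for team in teams:
                for d in sched_by_ts.get((team, season), []):
                    if d not in seen:
                        seen.add(d)
                        entries.append((d, season, team))
        entries.sort(key=lambda e: e[0])
        if not entries:
            continue
        sched_dates = [e[0] for e in entries]
        played = set(pgames["game_date"])
        played_mask = np.array([d in played for d in sched_dates])

        # maximal runs of consecutively missed team games
        runs: list[tuple[int, int]] = []
        i = 0
        n = len(sched_dates)
        while i < n:
            if not played_mask[i]:
                j = i
                while j + 1 < n and not played_mask[j + 1]:
                    j += 1
                runs.append((i, j))
                i = j + 1
            else:
                i += 1
        run_of_index: dict[int, int] = {}
        for run_idx, (a, b) in enumerate(runs):
            for k in range(a, b + 1):
                run_of_index[k] = run_idx

        claimed: dict[int, str] = {}  # run index -> note of first claiming deactivation
        pdeact = deact_by_player.get(pid)
        if pdeact is not None:
            dates_arr = np.array(sched_dates, dtype="datetime64[ns]")
            for txn in pdeact.itertuples():
                pos = int(np.searchsorted(dates_arr, np.datetime64(txn.date)))
                if pos >= n or played_mask[pos]:
                    report.deactivate_without_missed_game += 1
                    continue
                run_idx = run_of_index[pos]
                if run_idx not in claimed:
                    claimed[run_idx] = str(txn.note)

        pact = act_by_player.get(pid)
        if pact is not None:
            deact_dates = (
                sorted(pdeact["date"].tolist()) if pdeact is not None else []
            )
            for txn in pact.itertuples():
                if not any(d <= txn.date for d in deact_dates):
                    report.activation_without_deactivation += 1

        for run_idx, note in sorted(claimed.items()):
            a, b = runs[run_idx]
            onset_date, onset_season, onset_team = entries[a]
            games_missed = b - a + 1
            if b + 1 < n:
                return_date = sched_dates[b + 1]
                return_observed = True
                days = int((return_date - onset_date).days)
                if days < 0:  # defensive: impossible under sorted schedules
                    report.negative_recovery += 1
                    report.excluded_event_ids.append(f"{pid}:{onset_date.date()}")
                    continue
            else:
                return_date = pd.NaT
                return_observed = False
                days = np.nan
                report.missing_recovery += 1
            rows.append(
                {
                    "event_id": f"{pid}:{onset_date.date()}",
                    "player_id": pid,
                    "team_id": onset_team,
                    "season_id": onset_season,
                    "onset_date": onset_date,
                    "return_date": return_date,
                    "games_missed": games_missed,
                    "days_to_return": days,
                    "return_observed": return_observed,
                    "note": note,
                }
            )

    events = pd.DataFrame(rows, columns=EVENT_COLUMNS)
    if not events.empty:
        events = events.sort_values(["player_id", "onset_date"], kind="stable").reset_index(
            drop=True
        )
    return events, report


@dataclass
class AgreementResult:
    pct_exact_date: float
    pct_missed_games: float
    pct_injury_site: float
    n_matched: int
    n_unmatched_a: int
    n_unmatched_b: int


def agreement(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    date_tolerance_days: int = 30,
) -> AgreementResult:
    """Cross-source agreement between two injury-event sets.

    Events are paired per player by greedy nearest onset within the
    tolerance; each percentage is matched-and-equal over matched, in
    [0, 100].  Both inputs must carry a ``body_region`` column for the
    injury-site comparison.  Empty input on either side is an error.
    """
    if events_a.empty or events_b.empty:
        raise AgreementUndefinedError("agreement is undefined for an empty event set")
    for frame, name in ((events_a, "events_a"), (events_b, "events_b")):
        if "body_region" not in frame.columns:
            raise SchemaError(f"{name} lacks a body_region column (run classification first)")

    matched: list[tuple[pd.Series, pd.Series]] = []
    used_b: set[int] = set()
    b_by_player = dict(tuple(events_b.groupby("player_id")))
    n_unmatched_a = 0
    tol = pd.Timedelta(days=date_tolerance_days)
    for _, ev_a in events_a.iterrows():
        candidates = b_by_player.get(ev_a["player_id"])
        best_idx, best_delta = None, None
        if candidates is not None:
            for idx, ev_b in candidates.iterrows():
                if idx in used_b:
                    continue
                delta = abs(ev_b["onset_date"] - ev_a["onset_date"])
                if delta <= tol and (best_delta is None or delta < best_delta):
                    best_idx, best_delta = idx, delta
        if best_idx is None:
            n_unmatched_a += 1
        else:
            used_b.add(best_idx)
            matched.append((ev_a, events_b.loc[best_idx]))
    n_unmatched_b = len(events_b) - len(used_b)
    if not matched:
        raise AgreementUndefinedError(
            "no event pairs matched within the date tolerance; agreement undefined"
        )
    n = len(matched)
    exact = sum(a["onset_date"] == b["onset_date"] for a, b in matched)
    games = sum(a["games_missed"] == b["games_missed"] for a, b in matched)
    site = sum(a["body_region"] == b["body_region"] for a, b in matched)
    return AgreementResult(
        pct_exact_date=100.0 * exact / n,
        pct_missed_games=100.0 * games / n,
        pct_injury_site=100.0 * site / n,
        n_matched=n,
        n_unmatched_a=n_unmatched_a,
        n_unmatched_b=n_unmatched_b,
    )
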