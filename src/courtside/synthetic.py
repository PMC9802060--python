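"""Synthetic professional-basketball league generator with known ground truth.

The generator emulates the two tabular sources the downstream pipeline
ingests — a dated roster transaction log with free-text injury notes, and
per-player per-game box scores — plus a team schedule and roster metadata.
Every injected injury is recorded in a :class:`GroundTruth` object so that
linkage, classification, cohort construction and the regression analyses can
all be validated end to end without any real data.

Model sketch (all choices documented in the methods note):

* Each season has ``games_per_team`` league-wide game dates, daily from a
  season anchor; every team plays every date.  Opponent pairings carry no
  statistical information downstream and are not materialised.
* Per-player baseline minutes/game are drawn once from a truncated normal
  (league mean 25.8, SD 8.1); per-game minutes are Gamma around the baseline
  (exact mean, positive support).  Points, rebounds and field-goal attempts
  are Poisson with per-minute rates anchored at 0.434, 0.140 and 0.38.
* Each played game carries a per-game injury hazard.  An injury draws a
  severity band, a games-missed count inside the band, a body region and a
  keyworded free-text note; the player then misses that many consecutive
  team games.  Deactivate/activate transactions are dated at the first
  missed game and the return game.
* A player's first severe injury is the primary injury: subsequent seasons
  apply multiplicative performance decrements, and the player may drop out
  of the league entirely at each later season start.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from datetime import date, timedelta
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .classify import BodyRegion, Severity, classify_severity
from .errors import ConfigError

_SEVERITY_GM_DRAW = {
    # severity -> inclusive (low, high) range for the games-missed draw
    Severity.SLIGHT.value: (1, 1),
    Severity.MINOR.value: (2, 3),
    Severity.MODERATE.value: (4, 13),
    # capped at 54 so a severe injury spilling into the next season always
    # returns within it when one exists (82-game seasons)
    Severity.SEVERE.value: (14, 54),
}

_NONSEVERE_REGION_MIX = {
    "ankle": 0.25,
    "knee": 0.20,
    "groin/hip/thigh": 0.20,
    "other": 0.30,
    "unknown": 0.05,
}

_NOTE_TEMPLATES = {
    "knee": [
        "sore left knee",
        "right knee sprain",
        "torn acl",
        "meniscus tear",
        "patellar tendinitis",
    ],
    "groin/hip/thigh": [
        "strained groin",
        "hip flexor strain",
        "left thigh contusion",
        "hamstring strain",
        "sore quad",
    ],
    "ankle": [
        "sprained right ankle",
        "left ankle soreness",
        "achilles tendinitis",
    ],
    "other": [
        "lower back spasms",
        "sore shoulder",
        "sprained wrist",
        "illness",
        "bruised rib",
    ],
    "unknown": ["", "day-to-day"],
}

_POSITIONS = ("guard", "forward", "center")
_POSITION_PROBS = (0.39, 0.41, 0.20)


def _check_prob(name: str, value: float) -> None:
    if not (0.0 <= value <= 1.0):
        raise ConfigError(f"{name} must be a probability in [0, 1]; got {value!r}")


def _check_mix(name: str, mix: Mapping[str, float], allowed: set[str]) -> None:
    if set(mix) - allowed:
        raise ConfigError(f"{name} has unknown categories: {sorted(set(mix) - allowed)}")
    for key, p in mix.items():
        _check_prob(f"{name}[{key!r}]", p)
    if abs(sum(mix.values()) - 1.0) > 1e-9:
        raise ConfigError(f"{name} must sum to 1 within 1e-9; got {sum(mix.values())!r}")


@dataclass
class SyntheticConfig:
    """Parameters of the synthetic league.

    Defaults emulate the study conditions: 30 teams, 82-game seasons,
    league-mean 25.8 minutes/game (SD 8.1 across players), 0.434 points and
    0.140 rebounds per minute, a severe-injury region mix of 20/57/23%
    (groin-hip-thigh / knee / ankle), post-injury decrements of 0.7 (year 1)
    and 0.85 (year 2), and a 33% per-season league-dropout probability after
    a severe injury.
    """

    n_teams: int = 30
    games_per_team: int = 82
    n_seasons: int = 5
    roster_size: int = 15
    injury_hazard: float = 0.005
    severity_mix: Mapping[str, float] = field(
        default_factory=lambda: {"Slight": 0.45, "Minor": 0.30, "Moderate": 0.17, "Severe": 0.08}
    )
    severe_region_mix: Mapping[str, float] = field(
        default_factory=lambda: {"groin/hip/thigh": 0.20, "knee": 0.57, "ankle": 0.23}
    )
    decrement_y1: float = 0.70
    decrement_y2: float = 0.85
    dropout_prob: float = 0.33
    seed: int = 0
    # distributional anchors (league means / rates)
    first_season_end_year: int = 2009
    minutes_mean: float = 25.8
    minutes_between_sd: float = 8.1
    minutes_game_sd: float = 3.0
    points_per_minute: float = 0.434
    rebounds_per_minute: float = 0.140
    fga_per_minute: float = 0.38

    def __post_init__(self) -> None:
        for name in ("n_teams", "games_per_team", "n_seasons", "roster_size"):
            value = getattr(self, name)
            if not isinstance(value, (int, np.integer)) or value <= 0:
                raise ConfigError(f"{name} must be a positive integer; got {value!r}")
        _check_prob("injury_hazard", self.injury_hazard)
        _check_prob("dropout_prob", self.dropout_prob)
        _check_mix("severity_mix", self.severity_mix, {s.value for s in Severity})
        _check_mix(
            "severe_region_mix",
            self.severe_region_mix,
            {"groin/hip/thigh", "knee", "ankle"},
        )
        for name in ("decrement_y1", "decrement_y2"):
            value = getattr(self, name)
            if not (0.0 < value <= 1.5):
                raise ConfigError(f"{name} must lie in (0, 1.5]; got {value!r}")
        if self.minutes_mean <= 0 or self.minutes_between_sd <= 0 or self.minutes_game_sd <= 0:
            raise ConfigError("minutes parameters must be positive")


@dataclass
class PlayerBaseline:
    minutes_mean: float
    points_rate: float
    rebounds_rate: float
    fga_rate: float


@dataclass
class InjectedInjury:
    """One injected injury, with the *realized* (observable) games missed.

    ``intended_games_missed`` is the drawn duration; ``games_missed`` is the
    number of team games actually missed within the simulated horizon (they
    differ only when an injury runs into the end of the last season, in
    which case ``return_date`` is absent).  ``severity`` is classified from
    the realized count.
    """

    player_id: str
    team_id: str
    season_id: str
    onset_round: int
    onset_date: str
    games_missed: int
    intended_games_missed: int
    return_date: str | None
    region: str
    severity: str
    intended_severity: str
    note: str


@dataclass
class GroundTruth:
    baselines: dict[str, PlayerBaseline]
    injuries: list[InjectedInjury]
    primary_severe_season: dict[str, str]
    dropout_season: dict[str, str]
    decrement_y1: float
    decrement_y2: float
    n_hazard_draws: int

    def to_json(self, path: str | Path) -> None:
        payload = {
            "baselines": {k: dataclasses.asdict(v) for k, v in self.baselines.items()},
            "injuries": [dataclasses.asdict(e) for e in self.injuries],
            "primary_severe_season": self.primary_severe_season,
            "dropout_season": self.dropout_season,
            "decrement_y1": self.decrement_y1,
            "decrement_y2": self.decrement_y2,
            "n_hazard_draws": self.n_hazard_draws,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        payload = json.loads(Path(path).read_text())
        return cls(
            baselines={k: PlayerBaseline(**v) for k, v in payload["baselines"].items()},
            injuries=[InjectedInjury(**e) for e in payload["injuries"]],
            primary_severe_season=payload["primary_severe_season"],
            dropout_season=payload["dropout_season"],
            decrement_y1=payload["decrement_y1"],
            decrement_y2=payload["decrement_y2"],
            n_hazard_draws=payload["n_hazard_draws"],
        )


@dataclass
class League:
    schedule: pd.DataFrame
    games: pd.DataFrame
    transactions: pd.DataFrame
    roster: pd.DataFrame
    ground_truth: GroundTruth

    def __iter__(self):
        return iter((self.schedule, self.games, self.transactions, self.ground_truth))


def season_ids(config: SyntheticConfig) -> list[str]:
    return [str(config.first_season_end_year + s) for s in range(config.n_seasons)]


def _season_dates(config: SyntheticConfig) -> tuple[list[date], np.ndarray, list[str]]:
    """Flattened game dates across seasons, with parallel season indices."""
    dates: list[date] = []
    season_idx: list[int] = []
    labels = season_ids(config)
    for s in range(config.n_seasons):
        anchor = date(config.first_season_end_year + s - 1, 11, 1)
        for g in range(config.games_per_team):
            dates.append(anchor + timedelta(days=g))
            season_idx.append(s)
    return dates, np.asarray(season_idx), labels


def draw_minutes(mean: float, rng: np.random.Generator, game_sd: float = 3.0) -> float:
    """Per-game minutes: Gamma with the given mean and SD (exact mean)."""
    if mean <= 0:
        return 0.0
    shape = (mean / game_sd) ** 2
    scale = game_sd**2 / mean
    return float(min(rng.gamma(shape, scale), 60.0))


def draw_box_score(
    player_baseline: PlayerBaseline,
    minutes_played: float,
    decrement: float = 1.0,
    rng: np.random.Generator | None = None,
) -> tuple[int, int, int]:
    """Draw (points, rebounds, field_goals_attempted) for one game.

    Counts are Poisson with expectation ``rate × minutes × decrement``.
    Zero minutes yields all zeros; negative minutes is an input error.
    """
    if minutes_played < 0:
        raise ConfigError(f"minutes_played must be nonnegative; got {minutes_played!r}")
    if decrement <= 0:
        raise ConfigError(f"decrement must be positive; got {decrement!r}")
    if minutes_played == 0:
        return (0, 0, 0)
    if rng is None:
        rng = np.random.default_rng()
    scale = minutes_played * decrement
    points = int(rng.poisson(player_baseline.points_rate * scale))
    rebounds = int(rng.poisson(player_baseline.rebounds_rate * scale))
    fga = int(rng.poisson(player_baseline.fga_rate * scale))
    return (points, rebounds, fga)


def _draw_baselines(config: SyntheticConfig, player_ids: list[str], rng) -> dict[str, PlayerBaseline]:
    n = len(player_ids)
    lo, hi = 10.0, 44.0
    a = (lo - config.minutes_mean) / config.minutes_between_sd
    b = (hi - config.minutes_mean) / config.minutes_between_sd
    mins = stats.truncnorm.rvs(
        a, b, loc=config.minutes_mean, scale=config.minutes_between_sd, size=n, random_state=rng
    )
    pts = np.clip(rng.normal(config.points_per_minute, 0.10, size=n), 0.05, None)
    reb = np.clip(rng.normal(config.rebounds_per_minute, 0.04, size=n), 0.01, None)
    fga = np.clip(rng.normal(config.fga_per_minute, 0.08, size=n), 0.05, None)
    return {
        pid: PlayerBaseline(float(m), float(p), float(r), float(f))
        for pid, m, p, r, f in zip(player_ids, mins, pts, reb, fga)
    }


def _draw_roster(config: SyntheticConfig, players: list[tuple[str, str]], rng) -> pd.DataFrame:
    anchor = date(config.first_season_end_year - 1, 11, 1)
    rows = []
    for team_id, player_id in players:
        age = rng.uniform(19.0, 34.0)
        birth = anchor - timedelta(days=int(age * 365.25))
        height = float(np.clip(rng.normal(200.0, 8.0), 175.0, 226.0))
        bmi = float(np.clip(rng.normal(25.1, 1.7), 20.0, 32.0))
        weight = bmi * (height / 100.0) ** 2
        position = rng.choice(_POSITIONS, p=_POSITION_PROBS)
        rows.append(
            {
                "player_id": player_id,
                "birth_date": birth.isoformat(),
                "height_cm": round(height, 1),
                "weight_kg": round(weight, 1),
                "position": str(position),
            }
        )
    return pd.DataFrame(rows)


def _draw_injury(config: SyntheticConfig, rng) -> tuple[str, str, int, str]:
    """Draw (severity, region, intended games missed, note) for a new injury."""
    sev_labels = list(config.severity_mix)
    severity = str(rng.choice(sev_labels, p=[config.severity_mix[k] for k in sev_labels]))
    if severity == Severity.SEVERE.value:
        reg_labels = list(config.severe_region_mix)
        region = str(
            rng.choice(reg_labels, p=[config.severe_region_mix[k] for k in reg_labels])
        )
    else:
        reg_labels = list(_NONSEVERE_REGION_MIX)
        region = str(rng.choice(reg_labels, p=[_NONSEVERE_REGION_MIX[k] for k in reg_labels]))
    lo, hi = _SEVERITY_GM_DRAW[severity]
    games_missed = int(rng.integers(lo, hi + 1))
    note = str(rng.choice(_NOTE_TEMPLATES[region]))
    return severity, region, games_missed, note


def generate_league(config: SyntheticConfig) -> League:
    """Simulate a league and return schedule, box scores, transactions,
    roster metadata and the injected ground truth.

    The output is a pure function of ``config`` (including its seed): the
    same configuration yields byte-identical CSV files from
    :func:`write_league`.
    """
    rng = np.random.default_rng(config.seed)
    teams = [f"T{t:02d}" for t in range(config.n_teams)]
    players = [
        (team, f"{team}P{j:02d}") for team in teams for j in range(config.roster_size)
    ]
    player_ids = [pid for _, pid in players]
    player_team = dict((pid, team) for team, pid in players)
    starter = {pid: int(pid[-2:]) < 5 for pid in player_ids}

    dates, season_idx, labels = _season_dates(config)
    n_rounds = len(dates)

    baselines = _draw_baselines(config, player_ids, rng)
    roster = _draw_roster(config, players, rng)

    schedule_rows = [
        {"team_id": team, "season_id": labels[season_idx[r]], "game_date": dates[r].isoformat()}
        for team in teams
        for r in range(n_rounds)
    ]
    schedule = pd.DataFrame(schedule_rows)

    game_rows: list[dict] = []
    txn_rows: list[dict] = []
    injuries: list[InjectedInjury] = []
    primary_severe_season: dict[str, str] = {}
    dropout_season: dict[str, str] = {}
    n_hazard_draws = 0

    for pid in player_ids:
        team = player_team[pid]
        base = baselines[pid]
        injured_remaining = 0
        pending: InjectedInjury | None = None
        primary_index: int | None = None  # season index of first severe injury
        return_season: int | None = None  # season index of primary-injury return
        dropped = False
        current_season = -1

        for r in range(n_rounds):
            s = int(season_idx[r])
            if s != current_season:
                current_season = s
                if (
                    not dropped
                    and return_season is not None
                    and s > return_season
                    and injured_remaining == 0
                    and pending is None
                    and rng.random() < config.dropout_prob
                ):
                    dropped = True
                    dropout_season[pid] = labels[s]
            if dropped:
                continue
            if injured_remaining > 0:
                injured_remaining -= 1
                continue
            if pending is not None:
                # first game back after the injury gap
                pending.return_date = dates[r].isoformat()
                txn_rows.append(
                    {
                        "date": dates[r].isoformat(),
                        "player_id": pid,
                        "team_id": team,
                        "event_kind": "activate",
                        "note": "activated from injured list",
                    }
                )
                if (
                    pending.intended_severity == Severity.SEVERE.value
                    and primary_index is not None
                    and return_season is None
                ):
                    return_season = s
                pending = None

            offset = 0 if primary_index is None else s - primary_index
            if offset <= 0:
                factor = 1.0
            elif offset == 1:
                factor = config.decrement_y1
            else:
                factor = config.decrement_y2

            minutes = round(draw_minutes(base.minutes_mean * factor, rng, config.minutes_game_sd), 1)
            points, rebounds, fga = draw_box_score(base, minutes, factor, rng)
            game_rows.append(
                {
                    "player_id": pid,
                    "season_id": labels[s],
                    "game_date": dates[r].isoformat(),
                    "team_id": team,
                    "started": starter[pid],
                    "minutes": minutes,
                    "points": points,
                    "rebounds": rebounds,
                    "field_goals_attempted": fga,
                }
            )

            n_hazard_draws += 1
            if rng.random() < config.injury_hazard:
                severity, region, gm_intended, note = _draw_injury(config, rng)
                gm_realized = min(gm_intended, n_rounds - (r + 1))
                if gm_realized < 1:
                    continue  # injury at the final game: no observable time loss
                onset_round = r + 1
                onset_season = labels[int(season_idx[onset_round])]
                returns = onset_round + gm_realized < n_rounds and gm_realized == gm_intended
                event = InjectedInjury(
                    player_id=pid,
                    team_id=team,
                    season_id=onset_season,
                    onset_round=onset_round,
                    onset_date=dates[onset_round].isoformat(),
                    games_missed=gm_realized,
                    intended_games_missed=gm_intended,
                    return_date=None,
                    region=region,
                    severity=classify_severity(gm_realized).value,
                    intended_severity=severity,
                    note=note,
                )
                injuries.append(event)
                txn_rows.append(
                    {
                        "date": dates[onset_round].isoformat(),
                        "player_id": pid,
                        "team_id": team,
                        "event_kind": "deactivate",
                        "note": note,
                    }
                )
                injured_remaining = gm_realized
                if returns:
                    pending = event
                if severity == Severity.SEVERE.value and primary_index is None:
                    primary_index = int(season_idx[onset_round])
                    primary_severe_season[pid] = labels[primary_index]
            # occasional non-injury roster noise
            elif rng.random() < 0.0005:
                txn_rows.append(
                    {
                        "date": dates[r].isoformat(),
                        "player_id": pid,
                        "team_id": team,
                        "event_kind": "other",
                        "note": "signed contract extension",
                    }
                )

    games = pd.DataFrame(
        game_rows,
        columns=[
            "player_id",
            "season_id",
            "game_date",
            "team_id",
            "started",
            "minutes",
            "points",
            "rebounds",
            "field_goals_attempted",
        ],
    ).sort_values(["game_date", "team_id", "player_id"], kind="stable").reset_index(drop=True)
    transactions = pd.DataFrame(
        txn_rows, columns=["date", "player_id", "team_id", "event_kind", "note"]
    ).sort_values(["date", "player_id"], kind="stable").reset_index(drop=True)

    # in-memory frames carry real datetimes, matching what the CSV readers produce
    schedule["game_date"] = pd.to_datetime(schedule["game_date"])
    games["game_date"] = pd.to_datetime(games["game_date"])
    transactions["date"] = pd.to_datetime(transactions["date"])

    ground_truth = GroundTruth(
        baselines=baselines,
        injuries=injuries,
        primary_severe_season=primary_severe_season,
        dropout_season=dropout_season,
        decrement_y1=config.decrement_y1,
        decrement_y2=config.decrement_y2,
        n_hazard_draws=n_hazard_draws,
    )
    return League(schedule, games, transactions, roster, ground_truth)


def write_league(league: League, out_dir: str | Path) -> dict[str, Path]:
    """Write the league bundle as the CSV dialects the ingest stage reads."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "schedule": out / "schedule.csv",
        "games": out / "games.csv",
        "transactions": out / "transactions.csv",
        "roster": out / "roster.csv",
        "ground_truth": out / "ground_truth.json",
    }
    schedule = league.schedule.copy()
    schedule["game_date"] = schedule["game_date"].dt.strftime("%Y-%m-%d")
    games = league.games.copy()
    games["game_date"] = games["game_date"].dt.strftime("%Y-%m-%d")
    transactions = league.transactions.copy()
    transactions["date"] = transactions["date"].dt.strftime("%Y-%m-%d")
    schedule.to_csv(paths["schedule"], index=False)
    games.to_csv(paths["games"], index=False)
    transactions.to_csv(paths["transactions"], index=False)
    league.roster.to_csv(paths["roster"], index=False)
    league.ground_truth.to_json(paths["ground_truth"])
    return paths


def simulate_pre_post_cohort(
    n_players: int,
    decrement: float,
    games: int = 82,
    rng: np.random.Generator | int | None = None,
    minutes_mean: float = 25.8,
    minutes_between_sd: float = 8.1,
    minutes_game_sd: float = 3.0,
) -> pd.DataFrame:
    """Draw paired pre/post season minutes totals for a synthetic cohort.

    Uses the same two-level minutes model as :func:`generate_league`, drawn
    at season resolution: a season total of iid per-game Gammas is itself
    Gamma, so totals are drawn exactly.  The post season applies the
    multiplicative ``decrement`` to each player's baseline mean, mirroring a
    post-injury season.  Intended for parameter-recovery studies of the
    post-on-pre regression slope.
    """
    if n_players < 3:
        raise ConfigError("n_players must be at least 3")
    if decrement <= 0:
        raise ConfigError("decrement must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    lo, hi = 10.0, 44.0
    a = (lo - minutes_mean) / minutes_between_sd
    b = (hi - minutes_mean) / minutes_between_sd
    means = stats.truncnorm.rvs(
        a, b, loc=minutes_mean, scale=minutes_between_sd, size=n_players, random_state=rng
    )

    def season_total(m: np.ndarray) -> np.ndarray:
        shape = games * (m / minutes_game_sd) ** 2
        scale = minutes_game_sd**2 / m
        return rng.gamma(shape, scale)

    pre = season_total(means)
    post = season_total(means * decrement)
    return pd.DataFrame(
        {
            "player_id": [f"P{i:04d}" for i in range(n_players)],
            "baseline_minutes_mean": means,
            "pre_minutes": pre,
            "post_minutes": post,
        }
    )
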