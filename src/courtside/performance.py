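"""Season performance aggregates, return-to-performance classification, and
prevalence estimation with Wald confidence intervals.

"Return to preinjury performance" has no parameter-free operational
definition in the surveillance literature; the default rule here is
meet-or-exceed (post-season value >= pre-season value), with an optional
relative tolerance tau (post >= (1 - tau) * pre).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .classify import LOWER_EXTREMITY_REGIONS
from .errors import ConfigError

#: Metrics reported in the prevalence and descriptive tables.
DEFAULT_METRICS = (
    "games_played",
    "games_started",
    "minutes_total",
    "minutes_per_game",
    "points_total",
    "points_per_game",
    "rebounds_total",
    "rebounds_per_game",
)

METRIC_LABELS = {
    "games_played": "Games played",
    "games_started": "Games started",
    "minutes_total": "Season minutes played",
    "minutes_per_game": "Minutes played per game",
    "points_total": "Season points",
    "points_per_game": "Points per game",
    "rebounds_total": "Season rebounds",
    "rebounds_per_game": "Rebounds per game",
    "fga_total": "Season field goals attempted",
}


@dataclass
class SeasonPerformance:
    player_id: str
    season_id: str
    games_played: int
    games_started: int
    minutes_total: float
    points_total: int
    rebounds_total: int
    fga_total: int

    @property
    def minutes_per_game(self) -> float:
        return self.minutes_total / self.games_played

    @property
    def points_per_game(self) -> float:
        return self.points_total / self.games_played

    @property
    def rebounds_per_game(self) -> float:
        return self.rebounds_total / self.games_played

    @property
    def athlete_game_exposures(self) -> int:
        return self.games_played

    def metric(self, name: str) -> float:
        if name not in DEFAULT_METRICS and name != "fga_total":
            raise ConfigError(f"unknown metric {name!r}")
        return float(getattr(self, name))


def aggregate_seasons(game_records: pd.DataFrame) -> pd.DataFrame:
    """Per-(player, season) totals and per-game rates from box-score lines."""
    grouped = game_records.groupby(["player_id", "season_id"], as_index=False).agg(
        games_played=("game_date", "size"),
        games_started=("started", "sum"),
        minutes_total=("minutes", "sum"),
        points_total=("points", "sum"),
        rebounds_total=("rebounds", "sum"),
        fga_total=("field_goals_attempted", "sum"),
    )
    grouped["games_started"] = grouped["games_started"].astype(int)
    grouped["minutes_per_game"] = grouped["minutes_total"] / grouped["games_played"]
    grouped["points_per_game"] = grouped["points_total"] / grouped["games_played"]
    grouped["rebounds_per_game"] = grouped["rebounds_total"] / grouped["games_played"]
    grouped["season_id"] = grouped["season_id"].astype(str)
    return grouped


def season_aggregates(
    game_records: pd.DataFrame, player_id: str, season_id: str
) -> SeasonPerformance:
    """Aggregate one player-season; absent (zero games) is an error."""
    rows = game_records[
        (game_records["player_id"] == player_id)
        & (game_records["season_id"].astype(str) == str(season_id))
    ]
    if rows.empty:
        raise ConfigError(f"player {player_id!r} has no games in season {season_id!r}")
    return SeasonPerformance(
        player_id=player_id,
        season_id=str(season_id),
        games_played=len(rows),
        games_started=int(rows["started"].sum()),
        minutes_total=float(rows["minutes"].sum()),
        points_total=int(rows["points"].sum()),
        rebounds_total=int(rows["rebounds"].sum()),
        fga_total=int(rows["field_goals_attempted"].sum()),
    )


@dataclass(frozen=True)
class ReturnRule:
    """post >= (1 - tolerance) * pre; tolerance 0 is strict meet-or-exceed."""

    tolerance: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.tolerance < 1.0):
            raise ConfigError(f"tolerance must lie in [0, 1); got {self.tolerance!r}")


def _metric_value(perf, metric: str) -> float:
    if isinstance(perf, SeasonPerformance):
        return perf.metric(metric)
    if metric not in perf:
        raise ConfigError(f"unknown metric {metric!r}")
    return float(perf[metric])


def reached_preinjury(pre, post, metric: str, rule: ReturnRule = ReturnRule()) -> bool:
    """Did the post-injury season reach the pre-injury level on this metric?"""
    pre_value = _metric_value(pre, metric)
    post_value = _metric_value(post, metric)
    return bool(post_value >= (1.0 - rule.tolerance) * pre_value)


@dataclass
class PrevalenceEstimate:
    numerator: int
    denominator: int
    proportion: float
    ci_low: float
    ci_high: float
    metric: str = ""
    year: int = 0
    stratum: str = "overall"


def prevalence_ci(
    numerator: int, denominator: int, level: float = 0.95
) -> PrevalenceEstimate:
    """Binomial proportion with a Wald (normal-approximation) interval.

    p +/- z * sqrt(p(1-p)/n), clipped to [0, 1].  Reporting as integer
    percentages (half away from zero) is done in the rendering layer.
    """
    if denominator < 1:
        raise ConfigError("denominator must be at least 1")
    if not (0 <= numerator <= denominator):
        raise ConfigError("numerator must lie in [0, denominator]")
    p = numerator / denominator
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * math.sqrt(p * (1.0 - p) / denominator)
    return PrevalenceEstimate(
        numerator=int(numerator),
        denominator=int(denominator),
        proportion=p,
        ci_low=max(0.0, p - half),
        ci_high=min(1.0, p + half),
    )


def _cohort_season(row: pd.Series, year: int) -> str | None:
    if year == 0:
        return row["pre_season"]
    if year == 1:
        return row["post1_season"]
    if year == 2:
        return row["post2_season"]
    raise ConfigError(f"year must be 0 (pre), 1 or 2; got {year!r}")


def _lookup(aggregates: pd.DataFrame, player_id: str, season_id: str | None):
    if season_id is None:
        return None
    rows = aggregates[
        (aggregates["player_id"] == player_id)
        & (aggregates["season_id"] == str(season_id))
    ]
    return rows.iloc[0] if not rows.empty else None


def descriptive_table(
    cohort: pd.DataFrame,
    aggregates: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
) -> pd.DataFrame:
    """Mean (SD) of each metric for the pre, post1 and post2 seasons.

    SDs use the sample (n-1) convention.  The post2 column is computed on
    complete cases only (players with a second post-injury season).
    """
    if cohort.empty:
        raise ConfigError("descriptive_table requires a nonempty cohort")
    rows = []
    for period, year in (("pre", 0), ("post1", 1), ("post2", 2)):
        values: dict[str, list[float]] = {m: [] for m in metrics}
        for _, entry in cohort.iterrows():
            perf = _lookup(aggregates, entry["player_id"], _cohort_season(entry, year))
            if perf is None:
                continue
            for m in metrics:
                values[m].append(float(perf[m]))
        for m in metrics:
            arr = np.asarray(values[m], dtype=float)
            rows.append(
                {
                    "metric": m,
                    "period": period,
                    "n": len(arr),
                    "mean": float(arr.mean()) if len(arr) else np.nan,
                    "sd": float(arr.std(ddof=1)) if len(arr) > 1 else (0.0 if len(arr) else np.nan),
                }
            )
    return pd.DataFrame(rows)


def prevalence_table(
    cohort: pd.DataFrame,
    aggregates: pd.DataFrame,
    metrics: tuple[str, ...] = DEFAULT_METRICS,
    years: tuple[int, ...] = (1, 2),
    rule: ReturnRule = ReturnRule(),
    level: float = 0.95,
) -> pd.DataFrame:
    """Return-to-preinjury prevalence per (stratum x metric x year).

    Strata are overall plus each lower-extremity region; denominators are
    the cohort members with the relevant post season played (the strata
    counts).  Empty strata yield a flagged row without an estimate.
    """
    strata = [("overall", cohort)] + [
        (region.value, cohort[cohort["body_region"] == region.value])
        for region in LOWER_EXTREMITY_REGIONS
    ]
    rows = []
    for year in years:
        for name, sub in strata:
            season_col = "post1_season" if year == 1 else "post2_season"
            present = sub[sub[season_col].notna()] if not sub.empty else sub
            for metric in metrics:
                num = 0
                den = 0
                for _, entry in present.iterrows():
                    pre = _lookup(aggregates, entry["player_id"], entry["pre_season"])
                    post = _lookup(aggregates, entry["player_id"], entry[season_col])
                    if pre is None or post is None:
                        continue
                    den += 1
                    if reached_preinjury(pre, post, metric, rule):
                        num += 1
                if den == 0:
                    rows.append(
                        {
                            "stratum": name,
                            "metric": metric,
                            "year": year,
                            "numerator": 0,
                            "denominator": 0,
                            "proportion": np.nan,
                            "ci_low": np.nan,
                            "ci_high": np.nan,
                        }
                    )
                    continue
                est = prevalence_ci(num, den, level)
                rows.append(
                    {
                        "stratum": name,
                        "metric": metric,
                        "year": year,
                        "numerator": est.numerator,
                        "denominator": est.denominator,
                        "proportion": est.proportion,
                        "ci_low": est.ci_low,
                        "ci_high": est.ci_high,
                    }
                )
    return pd.DataFrame(rows)
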