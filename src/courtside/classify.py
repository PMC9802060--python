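"""Severity and body-region classification of time-loss injury events.

Severity follows the standard consensus bands on competitive games missed:
Slight (1 game), Minor (2-3), Moderate (4-13), Severe (14 or more).  Body
region is assigned from free-text transaction notes with a keyword lexicon;
coding is regional ("to the nearest body part"), not diagnosis-level.
"""

from __future__ import annotations

import re
from enum import Enum
from importlib import resources
from pathlib import Path

import pandas as pd

from .errors import ConfigError, SchemaError


class Severity(str, Enum):
    SLIGHT = "Slight"
    MINOR = "Minor"
    MODERATE = "Moderate"
    SEVERE = "Severe"


class BodyRegion(str, Enum):
    GROIN_HIP_THIGH = "groin/hip/thigh"
    KNEE = "knee"
    ANKLE = "ankle"
    OTHER = "other"
    UNKNOWN = "unknown"


#: Severity bands as (low, high) inclusive ranges over games missed.
#: Together they partition the positive integers.
SEVERITY_BANDS: dict[Severity, tuple[int, float]] = {
    Severity.SLIGHT: (1, 1),
    Severity.MINOR: (2, 3),
    Severity.MODERATE: (4, 13),
    Severity.SEVERE: (14, float("inf")),
}

#: The three lower-extremity regions under study.
LOWER_EXTREMITY_REGIONS = (
    BodyRegion.GROIN_HIP_THIGH,
    BodyRegion.KNEE,
    BodyRegion.ANKLE,
)

SEVERITY_ORDER = [Severity.SLIGHT, Severity.MINOR, Severity.MODERATE, Severity.SEVERE]


def classify_severity(games_missed: int) -> Severity:
    """Map a games-missed count to its severity band.

    Raises :class:`ConfigError` for counts below 1, which violate the
    time-loss injury definition (at least one competitive game missed).
    """
    gm = int(games_missed)
    if gm != games_missed or gm < 1:
        raise ConfigError(
            f"games_missed must be a positive integer (time-loss definition); got {games_missed!r}"
        )
    for severity, (lo, hi) in SEVERITY_BANDS.items():
        if lo <= gm <= hi:
            return severity
    raise AssertionError("severity bands must partition the positive integers")


def load_region_lexicon(path: str | Path | None = None) -> dict[str, BodyRegion]:
    """Load a keyword->region lexicon from a tab-separated file.

    ``None`` loads the default lexicon shipped with the package.  Lines
    starting with ``#`` and blank lines are ignored.
    """
    if path is None:
        text = (
            resources.files("courtside").joinpath("data/region_lexicon.tsv").read_text()
        )
    else:
        text = Path(path).read_text()
    lexicon: dict[str, BodyRegion] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise SchemaError(f"lexicon line {lineno}: expected 'keyword<TAB>region', got {line!r}")
        keyword, region = parts[0].strip().lower(), parts[1].strip()
        try:
            region_enum = BodyRegion(region)
        except ValueError as exc:
            raise SchemaError(f"lexicon line {lineno}: unknown region {region!r}") from exc
        if keyword in lexicon and lexicon[keyword] is not region_enum:
            raise SchemaError(f"lexicon keyword {keyword!r} maps to two regions")
        lexicon[keyword] = region_enum
    return lexicon


_DEFAULT_LEXICON: dict[str, BodyRegion] | None = None


def _default_lexicon() -> dict[str, BodyRegion]:
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = load_region_lexicon(None)
    return _DEFAULT_LEXICON


def map_body_region(note: str, lexicon: dict[str, BodyRegion] | None = None) -> BodyRegion:
    """Assign a body region from a free-text injury note.

    Matching is case-insensitive on whole words (``"quad"`` does not match
    inside ``"quadriceps"``); when several keywords hit, the earliest
    occurrence in the note wins, ties broken by longer keyword.  A note with
    no keyword hit — including an empty note — maps to ``unknown``.
    """
    if lexicon is None:
        lexicon = _default_lexicon()
    if note is None:
        return BodyRegion.UNKNOWN
    text = str(note).lower()
    if not text.strip():
        return BodyRegion.UNKNOWN
    best: tuple[int, int, BodyRegion] | None = None  # (position, -len, region)
    for keyword, region in lexicon.items():
        pattern = r"(?<![a-z])" + re.escape(keyword) + r"(?![a-z])"
        match = re.search(pattern, text)
        if match is not None:
            key = (match.start(), -len(keyword), region)
            if best is None or key[:2] < best[:2]:
                best = key
    return best[2] if best is not None else BodyRegion.UNKNOWN


def annotate_events(
    events: pd.DataFrame, lexicon: dict[str, BodyRegion] | None = None
) -> pd.DataFrame:
    """Add ``severity`` and ``body_region`` columns to a linked event table."""
    out = events.copy()
    out["severity"] = [classify_severity(gm).value for gm in out["games_missed"]]
    out["body_region"] = [map_body_region(note, lexicon).value for note in out["note"]]
    return out


def season_windows_from_schedule(schedule: pd.DataFrame) -> pd.DataFrame:
    """Derive regular-season windows (first/last game date) from a schedule."""
    grouped = schedule.groupby("season_id")["game_date"]
    windows = grouped.agg(start_date="min", end_date="max").reset_index()
    return windows.sort_values("season_id").reset_index(drop=True)


def filter_regular_season(
    events: pd.DataFrame, season_windows: pd.DataFrame
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Keep events whose onset lies inside a regular-season window.

    Windows are closed on both ends.  Returns the surviving events and a
    count of exclusions by reason (``off_season``, ``unknown_season``).
    """
    windows = {
        str(row.season_id): (row.start_date, row.end_date)
        for row in season_windows.itertuples()
    }
    keep: list[bool] = []
    excluded = {"off_season": 0, "unknown_season": 0}
    for row in events.itertuples():
        window = windows.get(str(row.season_id))
        if window is None:
            excluded["unknown_season"] += 1
            keep.append(False)
        elif window[0] <= row.onset_date <= window[1]:
            keep.append(True)
        else:
            excluded["off_season"] += 1
            keep.append(False)
    kept = events.loc[keep].reset_index(drop=True)
    return kept, excluded
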