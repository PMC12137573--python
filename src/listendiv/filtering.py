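"""Inclusion rules for streams, users and areas.

Pure, order-documented table transforms: drop sub-30-second events, keep
users with at least 100 events and at most 10 distinct locations, assign
each user the area of their modal location, keep areas with at least 200
users, then draw an equal number of unique songs per user so no listener is
over-represented.  A ``FilterReport`` accounts for every removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FilterReport",
    "filter_streams",
    "filter_users",
    "assign_home_location",
    "filter_areas",
    "sample_user_streams",
    "run_filter_pipeline",
]


@dataclass
class FilterReport:
    """Per-rule removal accounting across the filter pipeline."""

    n_streams_in: int = 0
    n_streams_out: int = 0
    n_users_in: int = 0
    n_users_out: int = 0
    n_areas_in: int = 0
    n_areas_out: int = 0
    removals: dict = field(default_factory=dict)
    sampling_shortfalls: int = 0

    def record(self, rule: str, removed: int) -> None:
        self.removals[rule] = self.removals.get(rule, 0) + int(removed)

    def to_dict(self) -> dict:
        return {
            "n_streams_in": self.n_streams_in,
            "n_streams_out": self.n_streams_out,
            "n_users_in": self.n_users_in,
            "n_users_out": self.n_users_out,
            "n_areas_in": self.n_areas_in,
            "n_areas_out": self.n_areas_out,
            "removals": dict(self.removals),
            "sampling_shortfalls": self.sampling_shortfalls,
        }


def filter_streams(
    streams: pd.DataFrame,
    min_duration_s: float = 30.0,
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Keep events played for at least ``min_duration_s`` seconds, and drop
    mobile-network events when an ``is_mobile_network`` column is present
    (their geolocation is unreliable)."""
    n_in = len(streams)
    keep = streams["duration_s"] >= min_duration_s
    if "is_mobile_network" in streams.columns:
        keep &= ~streams["is_mobile_network"].astype(bool)
    out = streams[keep]
    if report is not None:
        report.record("stream_duration_or_network", n_in - len(out))
    return out


def filter_users(
    streams: pd.DataFrame,
    min_streams: int = 100,
    max_locations: int = 10,
    report: FilterReport | None = None,
) -> pd.Index:
    """Users with at least ``min_streams`` events and at most
    ``max_locations`` distinct locations (non-travellers).  Bounds are
    inclusive: 100 events / 10 locations pass."""
    g = streams.groupby("user_id", observed=True)
    n_events = g.size()
    n_locs = g["location_id"].nunique()
    keep = (n_events >= min_streams) & (n_locs <= max_locations)
    if report is not None:
        report.record("user_too_few_streams", int((n_events < min_streams).sum()))
        report.record(
            "user_too_many_locations",
            int(((n_locs > max_locations) & (n_events >= min_streams)).sum()),
        )
    return keep.index[keep]


def assign_home_location(
    streams: pd.DataFrame, locations: pd.DataFrame
) -> pd.Series:
    """Home area per user: the area of the modal event location, ties
    broken by the lexicographically smallest area id.

    ``locations`` maps ``location_id -> area_id``.  Raises on an empty
    streams table (a user with zero events has no home).
    """
    if len(streams) == 0:
        raise ValueError("cannot assign home locations from an empty streams table")
    loc_to_area = locations.set_index("location_id")["area_id"]
    counts = (
        streams.assign(_area=streams["location_id"].map(loc_to_area))
        .dropna(subset=["_area"])
        .groupby(["user_id", "_area"], observed=True)
        .size()
        .reset_index(name="n")
        .sort_values(["user_id", "n", "_area"], ascending=[True, False, True])
    )
    home = counts.drop_duplicates("user_id").set_index("user_id")["_area"]
    home.name = "home_area"
    return home


def filter_areas(
    home: pd.Series, min_users: int = 200, report: FilterReport | None = None
) -> pd.Index:
    """Areas with at least ``min_users`` unique users (inclusive)."""
    per_area = home.value_counts()
    keep = per_area.index[per_area >= min_users]
    if report is not None:
        report.n_areas_in = int(per_area.size)
        report.n_areas_out = int(keep.size)
        report.record("area_too_few_users", int(per_area.size - keep.size))
    return pd.Index(sorted(keep))


def sample_user_streams(
    streams: pd.DataFrame,
    k: int = 100,
    seed: int | np.random.Generator = 0,
    unique: str = "songs",
    report: FilterReport | None = None,
) -> pd.DataFrame:
    """Draw ``k`` random unique streams per user.

    With ``unique='songs'`` (default) the sampled events have distinct
    song ids within each user: one random event is kept per distinct song,
    then ``k`` of those are drawn.  ``unique='events'`` samples ``k``
    distinct events regardless of song.  Users with fewer than ``k``
    available keep everything; the shortfall is recorded.
    """
    if unique not in {"songs", "events"}:
        raise ValueError("unique must be 'songs' or 'events'")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if len(streams) == 0:
        return streams.copy()
    perm = rng.permutation(len(streams))
    shuffled = streams.iloc[perm]
    if unique == "songs":
        shuffled = shuffled.drop_duplicates(["user_id", "song_id"])
    sampled = shuffled.groupby("user_id", observed=True, group_keys=False).head(k)
    if report is not None:
        per_user = sampled.groupby("user_id", observed=True).size()
        report.sampling_shortfalls += int((per_user < k).sum())
    return sampled.sort_index()


def run_filter_pipeline(
    streams: pd.DataFrame,
    locations: pd.DataFrame,
    min_duration_s: float = 30.0,
    min_streams: int = 100,
    max_locations: int = 10,
    min_users_per_area: int = 200,
    k: int = 100,
    seed: int = 0,
    unique: str = "songs",
) -> tuple[pd.DataFrame, pd.Series, FilterReport]:
    """The documented pipeline order: streams -> users -> home -> areas ->
    equal-depth sampling.

    Returns the sampled streams (with a ``home_area`` column), the per-user
    home-area series, and the filter report.
    """
    report = FilterReport(
        n_streams_in=len(streams), n_users_in=streams["user_id"].nunique()
    )
    s = filter_streams(streams, min_duration_s=min_duration_s, report=report)
    keep_users = filter_users(
        s, min_streams=min_streams, max_locations=max_locations, report=report
    )
    s = s[s["user_id"].isin(keep_users)]
    home = assign_home_location(s, locations)
    keep_areas = filter_areas(home, min_users=min_users_per_area, report=report)
    home = home[home.isin(keep_areas)]
    s = s[s["user_id"].isin(home.index)]
    sampled = sample_user_streams(s, k=k, seed=seed, unique=unique, report=report)
    sampled = sampled.merge(home.rename("home_area"), left_on="user_id", right_index=True)
    report.n_streams_out = len(sampled)
    report.n_users_out = sampled["user_id"].nunique()
    return sampled, home, report
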