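"""Simulation and run configuration objects.

``SimulationConfig`` encodes every generative assumption of the synthetic
listening-event generator: how area sizes, demographics, latent user tastes
and stream choices are produced, and how strongly each causal arrow of the
assumed demographic DAG acts.  Identical config + seed reproduces every
table bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import yaml

__all__ = [
    "LogLinear",
    "AgeCurve",
    "SimulationConfig",
    "DEFAULT_CONFOUNDING",
    "substream",
]

#: causal arrows of the demographic DAG whose strength the generator exposes.
#: ``size->x`` arrows act per decade of log10 population; ``x->wid`` act on
#: latent breadth per standard deviation of the (transformed) area covariate;
#: ``x->bid`` act on the log genre-mixture concentration per SD.
CONFOUNDING_KEYS = frozenset(
    [
        "size->age",
        "size->gender",
        "size->income",
        "size->education",
        "size->immigration",
        "size->venues",
        "size->sci",
        "age->bid",
        "gender->wid",
        "gender->bid",
        "income->wid",
        "income->bid",
        "education->wid",
        "education->bid",
        "immigration->wid",
        "immigration->bid",
        "venues->wid",
        "venues->bid",
        "sci->wid",
        "sci->bid",
        "algorithmic->wid",
        "algorithmic->bid",
    ]
)

#: a moderately confounded default: larger areas are younger, richer, more
#: educated, more international; those covariates in turn broaden individual
#: taste (wid arrows) and even out the local genre mixture (bid arrows).
DEFAULT_CONFOUNDING: Mapping[str, float] = {
    "size->age": -2.0,
    "size->income": 0.12,
    "size->education": 0.35,
    "size->immigration": 0.45,
    "size->venues": 0.6,
    "size->sci": 0.4,
    "gender->wid": 0.02,
    "income->wid": 0.05,
    "education->wid": 0.05,
    "immigration->wid": 0.04,
    "venues->wid": 0.03,
    "sci->wid": 0.04,
    "algorithmic->wid": -0.03,
    "income->bid": 0.30,
    "education->bid": 0.30,
    "immigration->bid": 0.18,
    "venues->bid": 0.18,
    "sci->bid": 0.18,
    "algorithmic->bid": -0.09,
}


@dataclass(frozen=True)
class LogLinear:
    """A monotone log-linear map ``x -> base + slope * log10(x)``."""

    base: float
    slope: float

    def __call__(self, x):
        return self.base + self.slope * np.log10(x)


@dataclass(frozen=True)
class AgeCurve:
    """Inverted-U age profile: a Gaussian bump centred at ``peak_age``."""

    peak_age: float = 28.0
    width: float = 10.0

    def __call__(self, age):
        return np.exp(-0.5 * ((np.asarray(age, dtype=float) - self.peak_age) / self.width) ** 2)


@dataclass(frozen=True)
class SimulationConfig:
    """All dials of the synthetic listening-data generator.

    Parameters
    ----------
    seed
        Root seed; every table draws from a named substream of it.
    n_areas, area_size_range
        Number of geographic areas and their (min, max) platform-user
        counts; sizes are log-spaced across the range.
    n_songs, n_genres, embed_dim
        Catalog size, number of genre clusters and the dimension of the
        ground-truth song vectors.
    zipf_exponent
        Skew of global song popularity (0 = uniform).
    taste_concentration_by_size
        Monotone map giving the log Dirichlet concentration of the area's
        genre mixture; the slope acts per decade of population and the base
        anchors the value at the centre of the size range.  Larger
        concentration = more even mixture = higher between-individual
        diversity, so a positive slope is the generator's BID-size dial.
    popularity_weight
        Weight of ln(popularity) in the song-choice utility (tempered by
        breadth together with the taste term).
    breadth_base, breadth_size_slope, direct_effect_wid
        Latent taste-breadth structural equation: breadth =
        breadth_base + (breadth_size_slope + direct_effect_wid) *
        (log10 population - centre) + age curve + demographic terms + noise.
        ``direct_effect_wid`` is the labelled dial for causal
        parameter-recovery runs; it enters identically to the slope.
    breadth_age_curve, breadth_age_amplitude
        Inverted-U age dependence of breadth (peak age, width, height).
    direct_effect_bid
        Extra slope added to ``taste_concentration_by_size.slope`` — the
        labelled direct size->BID dial for causal runs.
    confounding_coefficients
        Strength of each DAG arrow; see ``CONFOUNDING_KEYS``.  Missing keys
        mean zero.
    pct_algorithmic_slope
        Logit-scale slope of the area's algorithmic-stream share per decade
        of population (negative: metropolitan users rely less on
        recommendations).
    stream_count_mean, stream_count_shape
        Negative-binomial per-user stream counts (mean and shape r).
    short_duration_fraction, travel_fraction, traveller_user_fraction
        Fractions of sub-30-second events, of events logged away from the
        home location, and of heavy-traveller users (events scattered over
        >10 locations) — these exercise the inclusion filters downstream.
    """

    seed: int = 0
    n_areas: int = 30
    area_size_range: tuple[int, int] = (200, 2000)
    n_songs: int = 2000
    n_genres: int = 12
    embed_dim: int = 128
    zipf_exponent: float = 1.0
    taste_concentration_by_size: LogLinear = LogLinear(base=1.8, slope=0.0)
    breadth_base: float = 0.25
    breadth_size_slope: float = 0.0
    breadth_age_curve: AgeCurve = AgeCurve(28.0, 10.0)
    breadth_age_amplitude: float = 0.10
    breadth_noise_sd: float = 0.10
    direct_effect_bid: float = 0.0
    direct_effect_wid: float = 0.0
    confounding_coefficients: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_CONFOUNDING)
    )
    pct_algorithmic_slope: float = -0.3
    stream_count_mean: float = 150.0
    stream_count_shape: float = 50.0
    short_duration_fraction: float = 0.05
    travel_fraction: float = 0.02
    traveller_user_fraction: float = 0.01
    age_mean: float = 35.0
    age_sd: float = 14.0
    song_cluster_sd: float = 0.8
    user_centroid_sd: float = 0.6
    popularity_weight: float = 0.05
    n_foreign_areas: int = 20
    country: str = "FR"

    def __post_init__(self):
        # normalise nested fields supplied as plain tuples / dicts (YAML)
        tcs = self.taste_concentration_by_size
        if not isinstance(tcs, LogLinear):
            object.__setattr__(
                self,
                "taste_concentration_by_size",
                LogLinear(**tcs) if isinstance(tcs, Mapping) else LogLinear(*tcs),
            )
        bac = self.breadth_age_curve
        if not isinstance(bac, AgeCurve):
            object.__setattr__(
                self,
                "breadth_age_curve",
                AgeCurve(**bac) if isinstance(bac, Mapping) else AgeCurve(*bac),
            )
        object.__setattr__(self, "area_size_range", tuple(self.area_size_range))
        self.validate()

    def validate(self) -> None:
        if self.n_areas < 2:
            raise ValueError("n_areas must be >= 2")
        lo, hi = self.area_size_range
        if lo < 1 or hi < lo:
            raise ValueError("area_size_range must satisfy 1 <= min <= max")
        if self.zipf_exponent < 0:
            raise ValueError("zipf_exponent must be nonnegative")
        if self.embed_dim < 2:
            raise ValueError("embed_dim must be >= 2")
        if self.n_genres > self.n_songs:
            raise ValueError("n_genres may not exceed n_songs")
        unknown = set(self.confounding_coefficients) - CONFOUNDING_KEYS
        if unknown:
            raise ValueError(f"unknown confounding coefficient keys: {sorted(unknown)}")

    # -- structural helpers -------------------------------------------------

    @property
    def log10_size_centre(self) -> float:
        """Centre of the log10 population range; size effects are measured
        relative to this point so coefficients are range-independent."""
        lo, hi = self.area_size_range
        return 0.5 * (np.log10(lo) + np.log10(hi))

    def coeff(self, key: str) -> float:
        return float(self.confounding_coefficients.get(key, 0.0))

    # -- (de)serialisation --------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["taste_concentration_by_size"] = dataclasses.asdict(self.taste_concentration_by_size)
        d["breadth_age_curve"] = dataclasses.asdict(self.breadth_age_curve)
        d["area_size_range"] = list(self.area_size_range)
        d["confounding_coefficients"] = dict(self.confounding_coefficients)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls.from_dict(payload.get("simulation", payload))

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({"simulation": self.to_dict()}, fh, sort_keys=True)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=float)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def substream(seed: int, name: str) -> np.random.Generator:
    """A named, order-independent child RNG of ``seed``.

    Each table draws from its own substream so that, e.g., adding stream
    generation does not perturb the user draws.
    """
    digest = hashlib.sha256(name.encode()).digest()
    key = int.from_bytes(digest[:4], "big")
    return np.random.default_rng([int(seed), key])
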