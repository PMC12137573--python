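"""Synthetic listening-event generator.

Emulates the statistical structure the downstream analysis assumes about a
music-streaming population: area sizes spanning orders of magnitude, per-area
genre mixtures whose evenness grows with size, per-user latent taste
centroids and breadth with an inverted-U age profile, Zipf-skewed song
popularity, and demographic covariates confounded with area size along the
assumed DAG.  Every effect has a config dial so each downstream stage has a
parameter-recovery test; identical config + seed reproduces every table
bit-identically.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from listendiv.config import SimulationConfig, substream
from listendiv.embedding import SongEmbedding

__all__ = [
    "Catalog",
    "Population",
    "SocialConnectivity",
    "generate_catalog",
    "generate_population",
    "generate_streams",
    "sci_index",
    "international_sci",
]

#: start of the 4-week observation window
WINDOW_START = np.datetime64("2023-03-06T00:00:00")
WINDOW_SECONDS = 28 * 24 * 3600


@dataclass
class Catalog:
    """Song catalog with ground-truth genre-clustered vectors."""

    songs: pd.DataFrame  # song_id, artist_id, genre_id, popularity
    embedding: SongEmbedding  # ground-truth vectors
    genre_means: np.ndarray  # (n_genres, d) unit vectors


@dataclass
class SocialConnectivity:
    """Symmetric friendship-link counts between areas plus platform-user
    counts per area; substrate of the social-connectedness index."""

    area_ids: np.ndarray
    countries: np.ndarray
    users: np.ndarray
    connections: np.ndarray

    def __post_init__(self):
        self.connections = np.asarray(self.connections, dtype=float)
        if not np.allclose(self.connections, self.connections.T):
            raise ValueError("connections must be symmetric")
        if np.any(self.connections < 0):
            raise ValueError("connections must be nonnegative")
        self._index = pd.Index(self.area_ids)

    def loc(self, area_id) -> int:
        return self._index.get_loc(area_id)


@dataclass
class Population:
    """Areas, users (with latent taste state) and social connectivity."""

    areas: pd.DataFrame
    users: pd.DataFrame
    centroids: np.ndarray  # (n_users, d) latent taste centroids
    connectivity: SocialConnectivity
    locations: pd.DataFrame  # location_id -> area_id


def _zipf_weights(n: int, exponent: float) -> np.ndarray:
    w = np.arange(1, n + 1, dtype=float) ** (-exponent)
    return w / w.sum()


def _genre_means(config: SimulationConfig) -> np.ndarray:
    rng = substream(config.seed, "genre_means")
    m = rng.standard_normal((config.n_genres, config.embed_dim))
    return m / np.linalg.norm(m, axis=1, keepdims=True)


def generate_catalog(config: SimulationConfig) -> Catalog:
    """Songs with genre labels, artists, Zipf popularity and ground-truth
    vectors drawn from genre-specific Gaussians."""
    rng = substream(config.seed, "catalog")
    n, g = config.n_songs, config.n_genres
    genre_codes = rng.permutation(np.arange(n) % g)  # every genre occupied
    genre_means = _genre_means(config)
    # cluster scatter is expressed as a displacement *norm* relative to the
    # unit genre means, hence the 1/sqrt(d) per-coordinate scaling
    scatter = config.song_cluster_sd / np.sqrt(config.embed_dim)
    vectors = genre_means[genre_codes] + scatter * rng.standard_normal(
        (n, config.embed_dim)
    )
    # artists group ~4 songs within a genre
    order_within = np.zeros(n, dtype=int)
    for gc in range(g):
        mask = genre_codes == gc
        order_within[mask] = np.arange(mask.sum())
    songs = pd.DataFrame(
        {
            "song_id": [f"s{i:06d}" for i in range(n)],
            "artist_id": [
                f"ar{gc:03d}_{k // 4:04d}" for gc, k in zip(genre_codes, order_within)
            ],
            "genre_id": [f"g{gc:03d}" for gc in genre_codes],
            "popularity": _zipf_weights(n, config.zipf_exponent),
        }
    )
    emb = SongEmbedding(ids=songs["song_id"].to_numpy(), vectors=vectors)
    return Catalog(songs=songs, embedding=emb, genre_means=genre_means)


def _area_covariate_z(areas: pd.DataFrame) -> pd.DataFrame:
    """Standardised transformed area covariates used in the structural
    equations (and mirrored by the causal stage)."""
    raw = pd.DataFrame(
        {
            "age": areas["mean_age"],
            "income": np.log(areas["median_income"]),
            "education": areas["pct_degree"],
            "immigration": areas["pct_immigrant"],
            "venues": np.log1p(areas["venues"]),
            "sci": areas["sci_intl"],
            "algorithmic": areas["pct_algorithmic"],
        }
    )
    return (raw - raw.mean()) / raw.std(ddof=0).replace(0.0, 1.0)


def generate_population(config: SimulationConfig) -> Population:
    """Areas with size-confounded demographics, and users with latent taste
    centroids and breadth.

    Structural equations (z = log10 population - range centre):

    * each ``size->x`` confounding coefficient shifts covariate ``x`` per
      decade of population;
    * latent user breadth = breadth_base + (breadth_size_slope +
      direct_effect_wid) * z + age bump + gender term + sum of ``x->wid``
      terms (per SD of area covariate) + Gaussian noise;
    * log genre-mixture concentration = taste map(population) +
      direct_effect_bid * z + sum of ``x->bid`` terms + noise; the area
      mixture is Dirichlet with that concentration, so large concentration
      (big areas, positive slope) = even mixture = diverse repertoire.
    """
    rng = substream(config.seed, "areas")
    n_areas = config.n_areas
    lo, hi = config.area_size_range
    pops = np.round(np.logspace(np.log10(lo), np.log10(hi), n_areas)).astype(int)
    area_ids = np.array([f"A{i:03d}" for i in range(n_areas)])
    z = np.log10(pops) - config.log10_size_centre
    c = config.coeff

    median_income = np.exp(
        np.log(20_000.0) + c("size->income") * z + 0.25 * rng.standard_normal(n_areas)
    )
    pct_immigrant = expit(
        logit(0.08) + c("size->immigration") * z + 0.60 * rng.standard_normal(n_areas)
    )
    pct_degree = expit(
        logit(0.30) + c("size->education") * z + 0.50 * rng.standard_normal(n_areas)
    )
    venues = rng.poisson(
        np.exp(np.log(8.0) + c("size->venues") * z + 0.80 * rng.standard_normal(n_areas))
    )
    pct_algorithmic = expit(
        logit(0.30)
        + config.pct_algorithmic_slope * z
        + 0.30 * rng.standard_normal(n_areas)
    )

    connectivity = _generate_connectivity(config, area_ids, pops, z)
    sci_intl = international_sci(connectivity, home_country=config.country)

    areas = pd.DataFrame(
        {
            "area_id": area_ids,
            "country": config.country,
            "population": pops,
            "median_income": median_income,
            "pct_immigrant": pct_immigrant,
            "pct_degree": pct_degree,
            "venues": venues,
            "sci_intl": sci_intl.loc[area_ids].to_numpy(),
            "pct_algorithmic": pct_algorithmic,
        }
    )

    # users ------------------------------------------------------------
    urng = substream(config.seed, "users")
    n_users = int(pops.sum())
    area_idx = np.repeat(np.arange(n_areas), pops)
    age = np.clip(
        config.age_mean
        + c("size->age") * z[area_idx]
        + config.age_sd * urng.standard_normal(n_users),
        10.0,
        90.0,
    )
    p_male = np.clip(0.5 + c("size->gender") * z[area_idx], 0.05, 0.95)
    gender = np.where(urng.random(n_users) < p_male, "M", "F")
    areas["mean_age"] = pd.Series(age).groupby(area_idx).mean().to_numpy()
    zx = _area_covariate_z(areas)

    # genre mixtures
    log_kappa = (
        # the map's base anchors the log-concentration at the centre of the
        # size range; its slope acts per decade of population
        config.taste_concentration_by_size(pops / 10.0**config.log10_size_centre)
        + config.direct_effect_bid * z
        + sum(
            c(f"{k}->bid") * zx[k].to_numpy()
            for k in ("age", "income", "education", "immigration", "venues", "sci", "algorithmic")
            if c(f"{k}->bid") != 0.0
        )
        + 0.15 * urng.standard_normal(n_areas)
    )
    kappa = np.clip(np.exp(log_kappa), 0.05, 1e4)
    alphas = np.maximum(kappa / config.n_genres, 1e-3)
    # an analysis area pools several commune-scale communities; its mixture
    # is the average of a few Dirichlet draws, which tempers the draw noise
    # without changing how evenness scales with the concentration
    mixtures = np.vstack(
        [
            np.mean(
                urng.dirichlet(np.full(config.n_genres, a), size=4), axis=0
            )
            for a in alphas
        ]
    )

    taste_genre = np.empty(n_users, dtype=int)
    for a in range(n_areas):
        m = area_idx == a
        taste_genre[m] = urng.choice(config.n_genres, size=int(m.sum()), p=mixtures[a])
    genre_means = _genre_means(config)
    spread = config.user_centroid_sd / np.sqrt(config.embed_dim)
    centroids = genre_means[taste_genre] + spread * urng.standard_normal(
        (n_users, config.embed_dim)
    )

    # user-level covariates: income/education/immigration are commune-like
    # noisy proxies around the area aggregate (the analysis areas pool many
    # communes, so users within an area differ); algorithmic share is the
    # user's own propensity and drives their stream flags
    income_u = median_income[area_idx] * np.exp(0.40 * urng.standard_normal(n_users))
    education_u = expit(logit(pct_degree)[area_idx] + 0.8 * urng.standard_normal(n_users))
    immigration_u = expit(
        logit(pct_immigrant)[area_idx] + 0.8 * urng.standard_normal(n_users)
    )
    algorithmic_u = expit(
        logit(pct_algorithmic)[area_idx] + 0.6 * urng.standard_normal(n_users)
    )

    def _z(v):
        v = np.asarray(v, dtype=float)
        sd = v.std()
        return (v - v.mean()) / (sd if sd > 0 else 1.0)

    user_cov_z = {
        "income": _z(np.log(income_u)),
        "education": _z(education_u),
        "immigration": _z(immigration_u),
        "algorithmic": _z(algorithmic_u),
        "venues": zx["venues"].to_numpy()[area_idx],
        "sci": zx["sci"].to_numpy()[area_idx],
    }
    wid_terms = sum(
        c(f"{k}->wid") * user_cov_z[k]
        for k in ("income", "education", "immigration", "venues", "sci", "algorithmic")
        if c(f"{k}->wid") != 0.0
    )
    breadth = (
        config.breadth_base
        + (config.breadth_size_slope + config.direct_effect_wid) * z[area_idx]
        + config.breadth_age_amplitude * config.breadth_age_curve(age)
        + c("gender->wid") * (gender == "M")
        + wid_terms
        + config.breadth_noise_sd * urng.standard_normal(n_users)
    )
    breadth = np.maximum(breadth, 0.02)

    users = pd.DataFrame(
        {
            "user_id": [f"u{i:07d}" for i in range(n_users)],
            "home_area": area_ids[area_idx],
            "age": age,
            "gender": gender,
            "income": income_u,
            "education": education_u,
            "immigration": immigration_u,
            "algorithmic": algorithmic_u,
            "breadth": breadth,
            "taste_genre": taste_genre,
        }
    )
    locations = pd.DataFrame(
        {
            "location_id": [f"{a}-L{k}" for a in area_ids for k in range(3)],
            "area_id": np.repeat(area_ids, 3),
        }
    )
    return Population(
        areas=areas,
        users=users,
        centroids=centroids,
        connectivity=connectivity,
        locations=locations,
    )


def _generate_connectivity(
    config: SimulationConfig, area_ids, pops, z
) -> SocialConnectivity:
    """Synthetic symmetric friendship counts: a gravity baseline with a
    size-dependent boost of domestic-foreign links (the ``size->sci`` arrow)."""
    rng = substream(config.seed, "sci")
    n_f = config.n_foreign_areas
    f_ids = np.array([f"F{i:03d}" for i in range(n_f)])
    f_countries = np.array([f"ROW{i:02d}" for i in range(n_f)])
    f_users = np.exp(rng.uniform(np.log(1e3), np.log(1e5), size=n_f))
    ids = np.concatenate([area_ids, f_ids])
    countries = np.concatenate([np.full(len(area_ids), config.country), f_countries])
    mu = np.concatenate([pops.astype(float), f_users])
    n = len(ids)
    c_sci = config.coeff("size->sci")
    boost = np.zeros(n)
    # area-level shock: pair-level noise averages out over foreign partners,
    # so without it the summed index would be deterministic in size
    boost[: len(area_ids)] = c_sci * z + 0.55 * rng.standard_normal(len(area_ids))
    lam = 1e-4 * np.outer(mu, mu) * np.exp(
        boost[:, None] + boost[None, :] + 0.5 * rng.standard_normal((n, n))
    )
    upper = np.triu(rng.poisson(np.minimum(lam, 1e9)).astype(float), k=1)
    connections = upper + upper.T
    return SocialConnectivity(
        area_ids=ids, countries=countries, users=mu, connections=connections
    )


def sci_index(conn: SocialConnectivity, i, j) -> float:
    """Social-connectedness index between two areas:
    connections(i, j) / (users_i * users_j)."""
    ii, jj = conn.loc(i), conn.loc(j)
    mu_i, mu_j = conn.users[ii], conn.users[jj]
    if mu_i <= 0 or mu_j <= 0:
        raise ZeroDivisionError("SCI undefined for areas with zero users")
    return float(conn.connections[ii, jj] / (mu_i * mu_j))


def international_sci(conn: SocialConnectivity, home_country: str) -> pd.Series:
    """Per-area international connectedness: the SCI summed over all areas
    of other countries, normalised to a unit maximum and log-transformed."""
    home = conn.countries == home_country
    foreign = ~home
    if foreign.sum() == 0:
        raise ValueError("connectivity holds no foreign areas")
    mu = conn.users
    sci = conn.connections / np.outer(mu, mu)
    raw = sci[np.ix_(home, foreign)].sum(axis=1)
    norm = raw / max(raw.max(), 1e-300)
    return pd.Series(np.log(np.maximum(norm, 1e-12)), index=conn.area_ids[home])


def generate_streams(
    population: Population, catalog: Catalog, config: SimulationConfig
) -> pd.DataFrame:
    """Listening events from a popularity-times-taste choice model.

    Per user the stream count is negative-binomial; each event picks a song
    by softmax over the utility ``cos(centroid, song_vector) +
    popularity_weight * ln(popularity)`` at temperature ``breadth``:
    specialists (low breadth) concentrate on the songs maximising that
    utility, generalists spread out towards a uniform choice.  Tempering
    the popularity term together with the taste term keeps a generalist
    population diverse instead of collapsing it onto the global hits.
    A configured fraction of events carries sub-30-second durations or
    off-home locations, and a small share of users are heavy travellers —
    all to exercise the inclusion filters.
    """
    users = population.users
    n_users = len(users)
    if n_users == 0:
        return _empty_streams()
    rng = substream(config.seed, "streams")
    r = config.stream_count_shape
    p_nb = r / (r + config.stream_count_mean)
    counts = rng.negative_binomial(r, p_nb, size=n_users)

    song_vecs = catalog.embedding.vectors
    unit_songs = song_vecs / np.linalg.norm(song_vecs, axis=1, keepdims=True)
    cent = population.centroids
    unit_cent = cent / np.linalg.norm(cent, axis=1, keepdims=True)
    log_pop = np.log(catalog.songs["popularity"].to_numpy())
    tau = np.maximum(users["breadth"].to_numpy(), 1e-6)

    song_code_chunks: list[np.ndarray] = []
    user_idx_chunks: list[np.ndarray] = []
    chunk = 2048
    for start in range(0, n_users, chunk):
        stop = min(start + chunk, n_users)
        util = unit_cent[start:stop] @ unit_songs.T + config.popularity_weight * log_pop
        logits = util / tau[start:stop, None]
        logits -= logits.max(axis=1, keepdims=True)
        probs = np.exp(logits)
        probs /= probs.sum(axis=1, keepdims=True)
        for u in range(start, stop):
            if counts[u] == 0:
                continue
            cnt = rng.multinomial(counts[u], probs[u - start])
            nz = np.nonzero(cnt)[0]
            codes = np.repeat(nz, cnt[nz])
            song_code_chunks.append(rng.permutation(codes))
            user_idx_chunks.append(np.full(codes.size, u, dtype=np.int64))
    if not song_code_chunks:
        return _empty_streams()
    song_codes = np.concatenate(song_code_chunks)
    user_idx = np.concatenate(user_idx_chunks)
    n_events = song_codes.size

    # locations: a per-user main location in the home area, a travel-noise
    # fraction of events elsewhere, and a small share of heavy travellers
    area_ids = population.areas["area_id"].to_numpy()
    area_pos = pd.Index(area_ids).get_indexer(users["home_area"])
    main_loc = area_pos * 3 + rng.integers(0, 3, size=n_users)
    all_locs = population.locations["location_id"].to_numpy()
    loc_codes = main_loc[user_idx]
    travel = rng.random(n_events) < config.travel_fraction
    loc_codes = np.where(
        travel, rng.integers(0, len(all_locs), size=n_events), loc_codes
    )
    traveller = rng.random(n_users) < config.traveller_user_fraction
    trav_events = traveller[user_idx]
    if trav_events.any():
        loc_codes[trav_events] = rng.integers(0, len(all_locs), size=int(trav_events.sum()))

    durations = 30.0 + rng.lognormal(mean=4.8, sigma=0.5, size=n_events)
    short = rng.random(n_events) < config.short_duration_fraction
    durations[short] = rng.uniform(1.0, 29.0, size=int(short.sum()))

    if "algorithmic" in users.columns:
        algo_rate = users["algorithmic"].to_numpy()[user_idx]
    else:
        algo_rate = population.areas["pct_algorithmic"].to_numpy()[area_pos][user_idx]
    is_algorithmic = rng.random(n_events) < algo_rate
    ts = WINDOW_START + rng.integers(0, WINDOW_SECONDS, size=n_events).astype(
        "timedelta64[s]"
    )

    songs = catalog.songs
    streams = pd.DataFrame(
        {
            "user_id": users["user_id"].to_numpy()[user_idx],
            "song_id": songs["song_id"].to_numpy()[song_codes],
            "artist_id": songs["artist_id"].to_numpy()[song_codes],
            "genre_id": songs["genre_id"].to_numpy()[song_codes],
            "location_id": all_locs[loc_codes],
            "timestamp": ts,
            "duration_s": durations,
            "is_algorithmic": is_algorithmic,
        }
    )
    return streams.sort_values(["user_id", "timestamp"], kind="stable").reset_index(
        drop=True
    )


def _empty_streams() -> pd.DataFrame:
    return pd.DataFrame(
        {
            "user_id": pd.Series(dtype=object),
            "song_id": pd.Series(dtype=object),
            "artist_id": pd.Series(dtype=object),
            "genre_id": pd.Series(dtype=object),
            "location_id": pd.Series(dtype=object),
            "timestamp": pd.Series(dtype="datetime64[s]"),
            "duration_s": pd.Series(dtype=float),
            "is_algorithmic": pd.Series(dtype=bool),
        }
    )
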