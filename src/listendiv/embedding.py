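"""Song embeddings, user centroids, GS-score / WID, and user dispersion.

Songs are embedded by factorising a positive-PMI-transformed song-by-song
co-listening matrix with a truncated SVD, mirroring how streaming platforms
derive item vectors from user interactions.  A user's centroid is the mean
of the vectors of the songs they listened to; their Generalist-Specialist
score is the play-count-weighted mean cosine similarity between each
listened song and that centroid,

    GS(u) = (1 / sum_s w_s) * sum_s w_s * cos(s_vec, centroid)

so specialists (all listening in one region of the space) score near 1.
Within-individual diversity inverts and rescales it: WID = 100*(1 - GS),
clipped to [0, 100].  Area-level dispersion is the population variance of
cosine similarities between bootstrapped pairs of user vectors.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.linalg import svds

from listendiv.diversity import DiversityEstimate

__all__ = [
    "SongEmbedding",
    "UndefinedScoreError",
    "UnderSizeError",
    "build_song_embedding",
    "user_vectors",
    "gs_score",
    "wid_score",
    "wid_scores",
    "wid_bootstrap",
    "user_dispersion",
]


class UndefinedScoreError(ValueError):
    """GS-score is undefined (no embedded songs or zero-norm centroid)."""


class UnderSizeError(ValueError):
    """An area has fewer users than the equal-size bootstrap requires."""


@dataclass
class SongEmbedding:
    """Dense ``song_id -> d-vector`` map.

    ``disconnected`` flags songs that had no co-occurrence signal and were
    assigned zero vectors.
    """

    ids: np.ndarray
    vectors: np.ndarray
    disconnected: np.ndarray = field(default=None)

    def __post_init__(self):
        self.ids = np.asarray(self.ids)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 2 or len(self.ids) != self.vectors.shape[0]:
            raise ValueError("vectors must be (n_songs, d) aligned with ids")
        if not np.all(np.isfinite(self.vectors)):
            raise ValueError("embedding vectors must be finite")
        if self.disconnected is None:
            self.disconnected = ~np.any(self.vectors != 0.0, axis=1)
        self._index = pd.Index(self.ids)

    @property
    def d(self) -> int:
        return self.vectors.shape[1]

    def __len__(self) -> int:
        return len(self.ids)

    def __contains__(self, song_id) -> bool:
        return song_id in self._index

    def vector(self, song_id) -> np.ndarray:
        return self.vectors[self._index.get_loc(song_id)]

    def lookup(self, song_ids) -> tuple[np.ndarray, np.ndarray]:
        """Vectors for ``song_ids``; second return flags ids that are
        present with a nonzero vector."""
        locs = self._index.get_indexer(np.asarray(song_ids))
        ok = locs >= 0
        vecs = np.zeros((len(locs), self.d))
        vecs[ok] = self.vectors[locs[ok]]
        ok &= np.any(vecs != 0.0, axis=1)
        return vecs, ok

    # -- persistence: ids list + dense matrix -------------------------------

    def save(self, prefix, fmt: str = "npy") -> None:
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        pd.Series(self.ids).to_csv(prefix.with_suffix(".ids.txt"), index=False, header=False)
        if fmt == "npy":
            np.save(prefix.with_suffix(".vectors.npy"), self.vectors)
        elif fmt == "tsv":
            np.savetxt(prefix.with_suffix(".vectors.tsv"), self.vectors, delimiter="\t")
        else:
            raise ValueError("fmt must be 'npy' or 'tsv'")

    @classmethod
    def load(cls, prefix) -> "SongEmbedding":
        prefix = Path(prefix)
        ids = pd.read_csv(prefix.with_suffix(".ids.txt"), header=None)[0].to_numpy()
        npy = prefix.with_suffix(".vectors.npy")
        if npy.exists():
            vectors = np.load(npy)
        else:
            vectors = np.loadtxt(prefix.with_suffix(".vectors.tsv"), delimiter="\t")
        return cls(ids=ids, vectors=vectors)


def _ppmi(cooc: sp.csr_matrix) -> sp.csr_matrix:
    """Positive pointwise-mutual-information transform of a count matrix."""
    cooc = cooc.tocoo()
    total = cooc.sum()
    row_sums = np.asarray(cooc.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        pmi = np.log(cooc.data * total / (row_sums[cooc.row] * row_sums[cooc.col]))
    keep = pmi > 0
    out = sp.coo_matrix(
        (pmi[keep], (cooc.row[keep], cooc.col[keep])), shape=cooc.shape
    )
    return out.tocsr()


def build_song_embedding(
    streams: pd.DataFrame,
    d: int = 128,
    seed: int = 0,
    song_col: str = "song_id",
    user_col: str = "user_id",
) -> SongEmbedding:
    """Embed songs from within-user co-listening.

    Builds the symmetric song-by-song co-occurrence matrix (two songs
    co-occur when the same user listened to both), applies a positive-PMI
    transform, takes a truncated rank-``d`` SVD and scales rows by the
    square root of the singular values.  Songs with no co-occurrence get
    zero vectors and are flagged ``disconnected``.
    """
    song_ids = np.unique(streams[song_col].to_numpy())
    n_songs = song_ids.size
    if d >= n_songs:
        raise ValueError(f"embedding dimension d={d} must be < n_songs={n_songs}")
    song_codes = pd.Index(song_ids).get_indexer(streams[song_col])
    user_codes, users = pd.factorize(streams[user_col].to_numpy())
    # binary user-song incidence -> co-listening counts
    incidence = sp.csr_matrix(
        (np.ones(len(streams)), (user_codes, song_codes)),
        shape=(len(users), n_songs),
    )
    incidence.data[:] = 1.0
    incidence.sum_duplicates()
    incidence.data[:] = 1.0
    cooc = (incidence.T @ incidence).tocsr()
    cooc.setdiag(0)
    cooc.eliminate_zeros()
    ppmi = _ppmi(cooc)
    rng = np.random.default_rng(seed)
    v0 = rng.standard_normal(n_songs)
    u, s, _ = svds(ppmi.astype(float), k=d, v0=v0)
    order = np.argsort(s)[::-1]
    u, s = u[:, order], s[order]
    # deterministic sign: largest-magnitude loading of each component positive
    signs = np.sign(u[np.argmax(np.abs(u), axis=0), np.arange(d)])
    signs[signs == 0] = 1.0
    vectors = (u * signs) * np.sqrt(s)
    connected = np.asarray(cooc.sum(axis=1)).ravel() > 0
    vectors[~connected] = 0.0
    if not connected.all():
        warnings.warn(
            f"{int((~connected).sum())} songs had no co-occurrence; zero vectors assigned",
            stacklevel=2,
        )
    return SongEmbedding(ids=song_ids, vectors=vectors, disconnected=~connected)


def _song_counts(user_streams, song_col="song_id") -> pd.Series:
    if isinstance(user_streams, pd.Series):
        return user_streams
    if isinstance(user_streams, pd.DataFrame):
        return user_streams.groupby(song_col, observed=True).size()
    raise TypeError("user streams must be a DataFrame of events or a song->count Series")


def _centroid(vecs: np.ndarray, weights: np.ndarray, weighted: bool) -> np.ndarray:
    if weighted:
        return np.average(vecs, axis=0, weights=weights)
    return vecs.mean(axis=0)


def gs_score(
    user_streams,
    emb: SongEmbedding,
    weighted_centroid: bool = False,
) -> float:
    """Generalist-Specialist score of one user.

    The count-weighted mean cosine similarity between each listened song's
    vector and the user centroid.  The centroid is by default the unweighted
    mean over the distinct listened songs; ``weighted_centroid`` switches to
    a play-count-weighted mean.
    """
    counts = _song_counts(user_streams)
    vecs, ok = emb.lookup(counts.index.to_numpy())
    if not ok.any():
        raise UndefinedScoreError("user has no embedded songs with nonzero vectors")
    vecs, w = vecs[ok], counts.to_numpy(dtype=float)[ok]
    mu = _centroid(vecs, w, weighted_centroid)
    mu_norm = np.linalg.norm(mu)
    if mu_norm == 0.0:
        raise UndefinedScoreError("user centroid has zero norm")
    cos = (vecs @ mu) / (np.linalg.norm(vecs, axis=1) * mu_norm)
    return float(np.sum(w * cos) / np.sum(w))


def wid_score(gs: float) -> float:
    """Within-individual diversity on the 0-100 scale: 100*clip(1-GS, 0, 1)."""
    return float(100.0 * np.clip(1.0 - gs, 0.0, 1.0))


def user_vectors(
    streams: pd.DataFrame,
    emb: SongEmbedding,
    weighted: bool = False,
    song_col: str = "song_id",
    user_col: str = "user_id",
) -> tuple[np.ndarray, np.ndarray]:
    """Centroid vector per user: ``(user_ids, (n_users, d) matrix)``.

    Users with no embedded song are dropped.
    """
    counts = streams.groupby([user_col, song_col], observed=True).size()
    song_level = counts.index.get_level_values(song_col).to_numpy()
    vecs, ok = emb.lookup(song_level)
    user_level, users = pd.factorize(counts.index.get_level_values(user_col))
    w = counts.to_numpy(dtype=float) if weighted else np.ones(len(counts))
    w = w * ok
    sums = np.zeros((len(users), emb.d))
    np.add.at(sums, user_level, vecs * w[:, None])
    tot = np.bincount(user_level, weights=w, minlength=len(users))
    keep = tot > 0
    return np.asarray(users)[keep], sums[keep] / tot[keep, None]


def wid_scores(
    streams: pd.DataFrame,
    emb: SongEmbedding,
    organic_only: bool = True,
    weighted_centroid: bool = False,
) -> pd.DataFrame:
    """Per-user GS and WID scores from a streams table.

    Algorithmically recommended events are excluded by default: breadth is
    meant to reflect the user's own choices.
    """
    if organic_only and "is_algorithmic" in streams.columns:
        streams = streams[~streams["is_algorithmic"].astype(bool)]
    counts = streams.groupby(["user_id", "song_id"], observed=True).size()
    song_level = counts.index.get_level_values("song_id").to_numpy()
    vecs, ok = emb.lookup(song_level)
    user_level, users = pd.factorize(counts.index.get_level_values("user_id"))
    w_counts = counts.to_numpy(dtype=float)
    cw = (w_counts if weighted_centroid else np.ones_like(w_counts)) * ok
    n_users, dim = len(users), emb.d
    sums = np.zeros((n_users, dim))
    np.add.at(sums, user_level, vecs * cw[:, None])
    tot = np.bincount(user_level, weights=cw, minlength=n_users)
    with np.errstate(invalid="ignore", divide="ignore"):
        mu = sums / tot[:, None]
    mu_norm = np.linalg.norm(mu, axis=1)
    song_norm = np.linalg.norm(vecs, axis=1)
    denom = song_norm * mu_norm[user_level]
    with np.errstate(invalid="ignore", divide="ignore"):
        cos = np.einsum("ij,ij->i", vecs, mu[user_level]) / denom
    w = w_counts * ok
    cos = np.where(w > 0, cos, 0.0)
    gs_num = np.bincount(user_level, weights=w * cos, minlength=n_users)
    gs_den = np.bincount(user_level, weights=w, minlength=n_users)
    valid = (gs_den > 0) & (mu_norm > 0) & np.isfinite(mu_norm)
    gs = np.full(n_users, np.nan)
    gs[valid] = gs_num[valid] / gs_den[valid]
    out = pd.DataFrame({"user_id": np.asarray(users), "gs": gs})
    out["wid"] = 100.0 * np.clip(1.0 - out["gs"], 0.0, 1.0)
    return out.dropna(subset=["gs"]).reset_index(drop=True)


def wid_bootstrap(
    wid_values,
    n_users: int = 100,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> DiversityEstimate:
    """Equal-size bootstrap of an area's mean WID.

    Each replicate draws ``n_users`` distinct users without replacement and
    averages their WID scores.
    """
    wid_values = np.asarray(wid_values, dtype=float)
    if wid_values.size < n_users:
        raise UnderSizeError(
            f"area has {wid_values.size} users but the bootstrap draws {n_users}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.empty(n_reps)
    for r in range(n_reps):
        means[r] = wid_values[rng.choice(wid_values.size, n_users, replace=False)].mean()
    lo, hi = np.percentile(means, [2.5, 97.5])
    return DiversityEstimate(
        statistic="wid",
        q=None,
        mean=float(means.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        n_draw=n_users,
    )


def _sample_distinct_pairs(
    n: int, n_pairs: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Uniform sample of distinct unordered index pairs (i < j)."""
    n_comb = n * (n - 1) // 2
    if n_pairs >= n_comb:
        return np.triu_indices(n, k=1)
    keys = np.empty(0, dtype=np.int64)
    while keys.size < n_pairs:
        m = int(1.3 * (n_pairs - keys.size)) + 8
        a = rng.integers(0, n, size=m)
        b = rng.integers(0, n, size=m)
        ok = a != b
        lo, hi = np.minimum(a[ok], b[ok]), np.maximum(a[ok], b[ok])
        keys = np.unique(np.concatenate([keys, lo * n + hi]))
    keys = rng.permutation(keys)[:n_pairs]
    return keys // n, keys % n


def user_dispersion(
    vectors: np.ndarray,
    n_pairs: int = 1000,
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
) -> DiversityEstimate:
    """Dispersion of an area's users in the embedding space.

    Each replicate samples ``n_pairs`` distinct user pairs, computes their
    cosine similarities and returns the population variance (1/N) of those
    similarities; the estimate is the bootstrap mean with a percentile CI.
    High variance = heterogeneous local tastes.
    """
    vectors = np.asarray(vectors, dtype=float)
    if vectors.ndim != 2 or vectors.shape[0] < 2:
        raise ValueError("need at least two user vectors")
    norms = np.linalg.norm(vectors, axis=1)
    if np.any(norms == 0):
        raise ValueError("user vectors must be nonzero")
    unit = vectors / norms[:, None]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vals = np.empty(n_reps)
    for r in range(n_reps):
        i, j = _sample_distinct_pairs(unit.shape[0], n_pairs, rng)
        cos = np.einsum("ij,ij->i", unit[i], unit[j])
        vals[r] = cos.var(ddof=0)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return DiversityEstimate(
        statistic="dispersion",
        q=None,
        mean=float(vals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        n_draw=n_pairs,
    )
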