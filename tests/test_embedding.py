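"""Song embedding construction, GS-score/WID, and user dispersion."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import ortho_group, spearmanr

from listendiv import embedding as em
from listendiv.embedding import (
    SongEmbedding,
    UndefinedScoreError,
    UnderSizeError,
    build_song_embedding,
    gs_score,
    user_dispersion,
    user_vectors,
    wid_bootstrap,
    wid_score,
    wid_scores,
)
from oracles import dispersion_exhaustive_oracle


def _emb(vectors, ids=None):
    vectors = np.asarray(vectors, dtype=float)
    ids = ids or [f"s{i}" for i in range(len(vectors))]
    return SongEmbedding(ids=np.asarray(ids), vectors=vectors)


# ------------------------------------------------------------- build


def test_block_structure_cooccurrence():
    """Two songs only ever co-listened with each other end up closer to one
    another than to songs from a different co-listening block."""
    rows = []
    for u in range(20):
        rows += [(f"a{u}", "s0"), (f"a{u}", "s1")]
        rows += [(f"b{u}", "s2"), (f"b{u}", "s3"), (f"b{u}", "s4")]
    # one bridge user so the co-occurrence graph is connected
    rows += [("bridge", "s1"), ("bridge", "s2")]
    streams = pd.DataFrame(rows, columns=["user_id", "song_id"])
    emb = build_song_embedding(streams, d=3, seed=0)

    def cos(a, b):
        va, vb = emb.vector(a), emb.vector(b)
        return va @ vb / (np.linalg.norm(va) * np.linalg.norm(vb))

    assert cos("s0", "s1") > cos("s0", "s3")
    assert cos("s0", "s1") > cos("s0", "s4")


def test_embedding_recovers_genre_clusters(tiny_dataset):
    cat, _, streams = tiny_dataset
    emb = build_song_embedding(streams, d=16, seed=0)
    genre = cat.songs.set_index("song_id")["genre_id"]
    vecs = emb.vectors / np.linalg.norm(emb.vectors, axis=1, keepdims=True)
    labels = genre.loc[emb.ids].to_numpy()
    rng = np.random.default_rng(0)
    idx = rng.choice(len(vecs), size=(4000, 2))
    idx = idx[idx[:, 0] != idx[:, 1]]
    cos = np.einsum("ij,ij->i", vecs[idx[:, 0]], vecs[idx[:, 1]])
    same = labels[idx[:, 0]] == labels[idx[:, 1]]
    assert cos[same].mean() > cos[~same].mean() + 0.1


def test_embedding_dimension_bound():
    streams = pd.DataFrame(
        {"user_id": ["u"] * 4, "song_id": ["a", "b", "c", "d"]}
    )
    with pytest.raises(ValueError):
        build_song_embedding(streams, d=4)


def test_embedding_deterministic_and_flags_disconnected():
    rng = np.random.default_rng(2)
    streams = pd.DataFrame(
        {
            "user_id": rng.integers(0, 30, 400).astype(str),
            "song_id": rng.integers(0, 50, 400).astype(str),
        }
    )
    # a song listened by a user with no other songs: no co-occurrence
    lonely = pd.DataFrame({"user_id": ["hermit"], "song_id": ["zz_lonely"]})
    streams = pd.concat([streams, lonely], ignore_index=True)
    with pytest.warns(UserWarning, match="no co-occurrence"):
        e1 = build_song_embedding(streams, d=8, seed=5)
    with pytest.warns(UserWarning):
        e2 = build_song_embedding(streams.sample(frac=1, random_state=1), d=8, seed=5)
    assert e1.disconnected.sum() == 1
    np.testing.assert_allclose(e1.vectors, e2.vectors, atol=1e-8)
    assert np.all(e1.vector("zz_lonely") == 0.0)


def test_embedding_save_load_roundtrip(tmp_path):
    emb = _emb(np.arange(12.0).reshape(4, 3))
    for fmt in ("npy", "tsv"):
        emb.save(tmp_path / f"emb_{fmt}", fmt=fmt)
        back = SongEmbedding.load(tmp_path / f"emb_{fmt}")
        np.testing.assert_allclose(back.vectors, emb.vectors)
        assert list(back.ids) == list(emb.ids)


# ------------------------------------------------------------- GS / WID


def test_gs_score_identical_songs_is_one():
    emb = _emb([[1.0, 2.0], [1.0, 2.0], [0.0, 1.0]])
    counts = pd.Series({"s0": 5, "s1": 3})
    assert gs_score(counts, emb) == pytest.approx(1.0)
    assert wid_score(gs_score(counts, emb)) == pytest.approx(0.0)


def test_gs_score_orthogonal_pair():
    emb = _emb([[1.0, 0.0], [0.0, 1.0]])
    counts = pd.Series({"s0": 2, "s1": 2})
    assert gs_score(counts, emb) == pytest.approx(1 / np.sqrt(2), rel=1e-9)


def test_gs_score_weight_scale_invariance():
    rng = np.random.default_rng(0)
    emb = _emb(rng.standard_normal((6, 4)))
    counts = pd.Series({"s0": 1, "s2": 4, "s5": 2})
    assert gs_score(counts * 7, emb) == pytest.approx(gs_score(counts, emb), rel=1e-12)


def test_gs_score_errors():
    emb = _emb([[1.0, 0.0], [-1.0, 0.0]])
    with pytest.raises(UndefinedScoreError):
        gs_score(pd.Series({"s0": 1, "s1": 1}), emb)  # zero centroid
    with pytest.raises(UndefinedScoreError):
        gs_score(pd.Series({"unknown": 3}), emb)  # nothing embedded


@pytest.mark.parametrize(
    "gs, expected", [(1.0, 0.0), (0.5, 50.0), (-0.2, 100.0), (1.3, 0.0), (0.0, 100.0)]
)
def test_wid_score_normalisation(gs, expected):
    assert wid_score(gs) == pytest.approx(expected)


def test_wid_scores_table_matches_scalar_path():
    rng = np.random.default_rng(1)
    emb = _emb(rng.standard_normal((20, 6)))
    rows = []
    for u in range(8):
        songs = rng.choice(20, size=rng.integers(3, 9), replace=False)
        for s in songs:
            rows += [(f"u{u}", f"s{s}")] * rng.integers(1, 4)
    streams = pd.DataFrame(rows, columns=["user_id", "song_id"])
    table = wid_scores(streams, emb).set_index("user_id")
    for u, sub in streams.groupby("user_id"):
        gs = gs_score(sub.groupby("song_id").size(), emb)
        assert table.loc[u, "gs"] == pytest.approx(gs, rel=1e-9)
        assert table.loc[u, "wid"] == pytest.approx(wid_score(gs), rel=1e-9)


def test_wid_scores_excludes_algorithmic_streams():
    emb = _emb([[1.0, 0.0], [0.0, 1.0]])
    streams = pd.DataFrame(
        {
            "user_id": ["u"] * 4,
            "song_id": ["s0", "s0", "s1", "s1"],
            "is_algorithmic": [False, False, True, True],
        }
    )
    organic_only = wid_scores(streams, emb)
    assert organic_only["gs"].iloc[0] == pytest.approx(1.0)  # only s0 counted
    both = wid_scores(streams, emb, organic_only=False)
    assert both["gs"].iloc[0] == pytest.approx(1 / np.sqrt(2), rel=1e-9)


def test_wid_independent_of_stream_volume():
    """Scaling all play counts leaves WID unchanged (fixed proportions)."""
    rng = np.random.default_rng(4)
    emb = _emb(rng.standard_normal((10, 5)))
    counts = pd.Series({f"s{i}": c for i, c in enumerate([1, 2, 3, 4, 5])})
    assert wid_score(gs_score(counts * 20, emb)) == pytest.approx(
        wid_score(gs_score(counts, emb)), rel=1e-12
    )


def test_rotation_invariance_of_gs_and_dispersion(rng):
    vecs = rng.standard_normal((15, 8))
    emb = _emb(vecs)
    counts = pd.Series({f"s{i}": i + 1 for i in range(7)})
    base_gs = gs_score(counts, emb)
    q = ortho_group.rvs(8, random_state=3)
    emb_rot = _emb(vecs @ q)
    assert gs_score(counts, emb_rot) == pytest.approx(base_gs, rel=1e-9)
    users = rng.standard_normal((9, 8))
    d0 = user_dispersion(users, n_pairs=1000, n_reps=5, seed=1)
    d1 = user_dispersion(users @ q, n_pairs=1000, n_reps=5, seed=1)
    assert d1.mean == pytest.approx(d0.mean, rel=1e-9)


def test_generator_breadth_drives_wid(tiny_dataset):
    """Users configured with larger latent breadth score higher WID
    (rank correlation above 0.8 in the ground-truth space)."""
    cat, pop, streams = tiny_dataset
    keep = streams[streams["duration_s"] >= 30]
    table = wid_scores(keep, cat.embedding).merge(pop.users, on="user_id")
    rho = spearmanr(table["breadth"], table["wid"]).statistic
    assert rho > 0.8


# ------------------------------------------------------------- bootstraps


def test_wid_bootstrap_homogeneous_zero_width():
    est = wid_bootstrap(np.full(150, 42.0), n_users=100, n_reps=50, seed=0)
    assert est.mean == pytest.approx(42.0)
    assert est.ci_high - est.ci_low == pytest.approx(0.0)


def test_wid_bootstrap_all_users_equals_exact_mean():
    vals = np.arange(10.0)
    est = wid_bootstrap(vals, n_users=10, n_reps=20, seed=0)
    assert est.mean == pytest.approx(vals.mean())
    assert est.ci_low == pytest.approx(est.ci_high)


def test_wid_bootstrap_mean_and_seed():
    rng = np.random.default_rng(0)
    vals = rng.uniform(0, 100, 400)
    a = wid_bootstrap(vals, n_users=100, n_reps=400, seed=9)
    b = wid_bootstrap(vals, n_users=100, n_reps=400, seed=9)
    assert a == b
    # bootstrap mean of subsample means estimates the grand mean
    assert a.mean == pytest.approx(vals.mean(), abs=1.0)
    with pytest.raises(UnderSizeError):
        wid_bootstrap(vals[:50], n_users=100)


def test_dispersion_identical_vectors_zero():
    est = user_dispersion(np.tile([1.0, 2.0, 3.0], (6, 1)), n_pairs=10, n_reps=5)
    assert est.mean == pytest.approx(0.0, abs=1e-12)


def test_dispersion_two_orthogonal_clusters_exhaustive():
    """2+2 users in orthogonal clusters: pairwise cosines (1,1,0,0,0,0),
    population variance 2/9, frozen from the exhaustive-pair oracle."""
    vectors = np.array(
        [[1.0, 0.0], [1.0, 0.0], [0.0, 1.0], [0.0, 1.0]]
    )
    oracle = dispersion_exhaustive_oracle(vectors)
    assert oracle == pytest.approx(2.0 / 9.0, rel=1e-12)
    est = user_dispersion(vectors, n_pairs=6, n_reps=3, seed=0)  # all pairs
    assert est.mean == pytest.approx(oracle, rel=1e-12)
    assert est.ci_high - est.ci_low == pytest.approx(0.0, abs=1e-12)


def test_dispersion_matches_oracle_on_random_fixtures(rng):
    for n in (5, 8, 10):
        vectors = rng.standard_normal((n, 4))
        oracle = dispersion_exhaustive_oracle(vectors)
        est = user_dispersion(vectors, n_pairs=n * (n - 1) // 2, n_reps=2, seed=1)
        assert est.mean == pytest.approx(oracle, rel=1e-9)


def test_dispersion_grows_with_cluster_separation(rng):
    """Pulling two user clusters apart increases dispersion."""
    means = []
    base = rng.standard_normal((40, 6)) * 0.2
    direction = np.zeros(6)
    direction[0] = 1.0
    for sep in (0.3, 1.0, 3.0):
        cluster = np.where(np.arange(40)[:, None] < 20, sep, -sep) * direction
        vecs = 1.0 + base + cluster  # offset keeps cosines away from +-1
        means.append(user_dispersion(vecs, n_pairs=300, n_reps=30, seed=2).mean)
    assert means[0] < means[1] < means[2]


def test_dispersion_input_validation():
    with pytest.raises(ValueError):
        user_dispersion(np.ones((1, 3)))
    with pytest.raises(ValueError):
        user_dispersion(np.array([[1.0, 0.0], [0.0, 0.0]]))


def test_user_vectors_mean_of_distinct_songs():
    emb = _emb([[2.0, 0.0], [0.0, 2.0]])
    streams = pd.DataFrame(
        {"user_id": ["u"] * 3, "song_id": ["s0", "s0", "s1"]}
    )
    ids, vecs = user_vectors(streams, emb)
    np.testing.assert_allclose(vecs[0], [1.0, 1.0])  # unweighted over distinct
    ids, vecs = user_vectors(streams, emb, weighted=True)
    np.testing.assert_allclose(vecs[0], [4.0 / 3, 2.0 / 3])
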