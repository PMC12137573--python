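"""Between-individual diversity: Hill numbers and the equal-depth bootstrap.

The central statistic is the Hill number of order ``q``,

    qD = (sum_i p_i ** q) ** (1 / (1 - q)),       q != 1
    1D = exp(-sum_i p_i * ln p_i),                q == 1 (limit)

the "effective number of equally common categories" in a frequency vector.
An area's between-individual diversity (BID) is the bootstrap mean of the
Hill number over replicates that each draw the same number of events from
the area's pooled streams, so that differently sized areas are compared at
equal depth.  The Gini coefficient is provided as an alternative
concentration metric.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "DiversityEstimate",
    "UnderDepthError",
    "hill_number",
    "gini_coefficient",
    "bid_bootstrap",
]


class UnderDepthError(ValueError):
    """An area has fewer pooled events than the equal-depth draw requires."""


@dataclass(frozen=True)
class DiversityEstimate:
    """Bootstrap mean and 95% percentile CI of a diversity statistic."""

    statistic: str
    q: float | None
    mean: float
    ci_low: float
    ci_high: float
    n_reps: int
    n_draw: int

    def __post_init__(self):
        if self.n_reps < 1:
            raise ValueError("n_reps must be >= 1")
        if not (self.ci_low - 1e-9 <= self.mean <= self.ci_high + 1e-9):
            raise ValueError("mean must lie inside the CI")


def _abundances(counts) -> np.ndarray:
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 1 or counts.size == 0:
        raise ValueError("counts must be a non-empty 1-D vector")
    if np.any(counts < 0) or not np.all(np.isfinite(counts)):
        raise ValueError("counts must be finite and nonnegative")
    total = counts.sum()
    if total <= 0:
        raise ValueError("counts must have positive total")
    return counts / total


def hill_number(counts, q: float = 1.0) -> float:
    """Hill number (effective number of categories) of order ``q``.

    ``counts`` are raw abundances (they are normalised internally); zero
    counts contribute nothing.  ``q`` tunes sensitivity: q=0 is richness,
    q=1 the exponential of Shannon entropy, q=2 the inverse Simpson index.
    """
    if q < 0:
        raise ValueError("Hill order q must be nonnegative")
    p = _abundances(counts)
    p = p[p > 0]
    if q == 1.0:
        return float(np.exp(-np.sum(p * np.log(p))))
    if q == 0.0:
        return float(p.size)
    return float(np.sum(p**q) ** (1.0 / (1.0 - q)))


def gini_coefficient(counts) -> float:
    """Population Gini concentration of an abundance vector, in [0, 1).

    0 for a perfectly even vector; computed over the vector as passed, so
    explicit zero categories count as empty share-holders.
    """
    x = np.sort(np.asarray(counts, dtype=float))
    if x.size == 0:
        raise ValueError("counts must be non-empty")
    if np.any(x < 0):
        raise ValueError("counts must be nonnegative")
    total = x.sum()
    if total <= 0:
        raise ValueError("counts must have positive total")
    n = x.size
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * x) / (n * total) - (n + 1.0) / n)


def bid_bootstrap(
    area_streams: pd.DataFrame,
    group_key: str = "song_id",
    n_draw: int = 1000,
    n_reps: int = 1000,
    q: float = 1.0,
    seed: int | np.random.Generator = 0,
) -> DiversityEstimate:
    """Equal-depth bootstrap Hill-number estimate for one area.

    Each replicate draws ``n_draw`` events without replacement from the
    area's pooled streams, tabulates them by ``group_key`` (song, artist or
    genre) and computes the order-``q`` Hill number; the estimate is the
    mean over replicates with a 2.5/97.5-percentile CI.

    Raises
    ------
    UnderDepthError
        If the area holds fewer than ``n_draw`` events — such areas should
        have been removed upstream; silently rarefying would break the
        equal-depth contract.
    """
    if group_key not in area_streams.columns:
        raise KeyError(f"group_key {group_key!r} not in streams table")
    codes, _ = pd.factorize(area_streams[group_key].to_numpy(), sort=True)
    codes = np.sort(codes)  # canonical multiset order: row order cannot matter
    n = codes.size
    if n < n_draw:
        raise UnderDepthError(
            f"area has {n} events but the equal-depth draw needs {n_draw}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_cat = int(codes.max()) + 1
    vals = np.empty(n_reps)
    for r in range(n_reps):
        idx = rng.choice(n, size=n_draw, replace=False)
        vals[r] = hill_number(np.bincount(codes[idx], minlength=n_cat), q=q)
    lo, hi = np.percentile(vals, [2.5, 97.5])
    return DiversityEstimate(
        statistic=f"bid_{group_key}",
        q=q,
        mean=float(vals.mean()),
        ci_low=float(lo),
        ci_high=float(hi),
        n_reps=n_reps,
        n_draw=n_draw,
    )
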