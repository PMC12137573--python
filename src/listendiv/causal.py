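"""DAG-based causal adjustment of the diversity-size relationship.

The stage takes an assumed directed acyclic graph over population size,
demographics and a diversity outcome, derives its testable conditional
independencies and minimal adjustment sets, balances the three
population-size groups with generalised overlap (ATO) propensity weights,
checks covariate balance via standardised mean differences, and estimates
intercept-matched standardised effects with a user-resampling bootstrap.

Adjustment sets target the *direct* effect of the exposure as drawn: a set
``Z`` is valid when it contains no descendant of the outcome and blocks
every exposure-outcome path except the direct edge (the single-door
criterion); minimality means no proper subset is valid.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.preprocessing import PolynomialFeatures, StandardScaler

from listendiv.scaling import holm_adjust

__all__ = [
    "DAGModel",
    "Independence",
    "PropensityWeights",
    "EffectEstimate",
    "default_dag",
    "implied_independencies",
    "test_independencies",
    "minimal_adjustment_sets",
    "ato_weights",
    "smd_balance",
    "weighted_effect",
    "bootstrap_causal",
]

TREATMENT_LEVELS = ("small", "medium", "large")


@dataclass
class DAGModel:
    """A directed acyclic graph over named variables with a designated
    exposure and outcome."""

    graph: nx.DiGraph
    exposure: str
    outcome: str

    def __post_init__(self):
        if not nx.is_directed_acyclic_graph(self.graph):
            raise ValueError("graph must be acyclic")
        for node in (self.exposure, self.outcome):
            if node not in self.graph:
                raise ValueError(f"node {node!r} not in graph")

    @classmethod
    def from_edges(cls, edges, exposure: str, outcome: str) -> "DAGModel":
        g = nx.DiGraph()
        for e in edges:
            if isinstance(e, str):
                a, b = (part.strip() for part in e.split("->"))
            else:
                a, b = e
            g.add_edge(a, b)
        return cls(graph=g, exposure=exposure, outcome=outcome)

    @classmethod
    def from_file(cls, path, exposure: str, outcome: str) -> "DAGModel":
        lines = [
            ln.strip()
            for ln in Path(path).read_text().splitlines()
            if ln.strip() and not ln.strip().startswith("#")
        ]
        return cls.from_edges(lines, exposure=exposure, outcome=outcome)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)


def default_dag(outcome: str = "bid") -> DAGModel:
    """The package's assumed demographic DAG.

    Population size shapes the area's demographic composition (age, income,
    education, immigration, venues, international connections, algorithmic
    usage), each of which shapes diversity; age and gender additionally
    drive algorithmic usage; the bold edge of interest is the direct
    size -> outcome arrow.
    """
    demo = [
        "age",
        "income",
        "education",
        "immigration",
        "venues",
        "social_connections",
        "algorithmic_share",
    ]
    edges = [("population_size", d) for d in demo]
    edges += [(d, outcome) for d in demo + ["gender"]]
    edges += [
        ("age", "algorithmic_share"),
        ("gender", "algorithmic_share"),
        ("population_size", outcome),
    ]
    return DAGModel.from_edges(edges, exposure="population_size", outcome=outcome)


@dataclass(frozen=True)
class Independence:
    """A testable claim ``x independent of y given Z``."""

    x: str
    y: str
    given: frozenset

    def __str__(self):
        z = ", ".join(sorted(self.given)) or "{}"
        return f"{self.x} _||_ {self.y} | {z}"


def _as_digraph(dag) -> nx.DiGraph:
    g = dag.graph if isinstance(dag, DAGModel) else dag
    if not nx.is_directed_acyclic_graph(g):
        raise ValueError("input graph must be acyclic")
    return g


def implied_independencies(dag) -> list[Independence]:
    """The pairwise testable basis of the DAG's conditional independencies.

    For every non-adjacent ordered pair (u earlier, v later in a
    topological order): u is independent of v given the parents of v.  This
    basis implies, via the graphoid axioms, every independence the DAG
    encodes.
    """
    g = _as_digraph(dag)
    topo = list(nx.topological_sort(g))
    pos = {n: i for i, n in enumerate(topo)}
    claims = []
    for u, v in itertools.combinations(topo, 2):
        if g.has_edge(u, v) or g.has_edge(v, u):
            continue
        first, second = (u, v) if pos[u] < pos[v] else (v, u)
        claims.append(
            Independence(x=first, y=second, given=frozenset(g.predecessors(second)))
        )
    return claims


def partial_correlation(data: pd.DataFrame, x: str, y: str, given=()) -> tuple[float, float]:
    """Linear partial correlation of x and y given Z, with its two-tailed
    p-value (t distribution, df = n - 2 - |Z|)."""
    given = list(given)
    n = len(data)
    xv = data[x].to_numpy(dtype=float)
    yv = data[y].to_numpy(dtype=float)
    if given:
        Z = np.column_stack([np.ones(n), data[given].to_numpy(dtype=float)])
        xv = xv - Z @ np.linalg.lstsq(Z, xv, rcond=None)[0]
        yv = yv - Z @ np.linalg.lstsq(Z, yv, rcond=None)[0]
    else:
        xv = xv - xv.mean()
        yv = yv - yv.mean()
    denom = np.sqrt((xv**2).sum() * (yv**2).sum())
    r = 0.0 if denom == 0 else float((xv * yv).sum() / denom)
    df = n - 2 - len(given)
    if df <= 0:
        return r, np.nan
    r_clip = np.clip(r, -0.9999999, 0.9999999)
    t = r_clip * np.sqrt(df / (1.0 - r_clip**2))
    p = 2.0 * stats.t.sf(abs(t), df)
    return r, float(p)


def test_independencies(
    claims, data: pd.DataFrame, alpha: float = 0.05
) -> pd.DataFrame:
    """Test each implied independence by linear partial correlation; flags
    claims rejected at ``alpha`` after Holm adjustment."""
    rows = []
    for c in claims:
        r, p = partial_correlation(data, c.x, c.y, sorted(c.given))
        rows.append({"claim": str(c), "partial_r": r, "p": p})
    out = pd.DataFrame(rows)
    if len(out):
        out["p_holm"] = holm_adjust(out["p"].to_numpy())
        out["rejected"] = out["p_holm"] < alpha
    else:
        out["p_holm"] = pd.Series(dtype=float)
        out["rejected"] = pd.Series(dtype=bool)
    return out


def _is_valid_direct_adjustment(g: nx.DiGraph, x: str, y: str, z: frozenset) -> bool:
    if x in z or y in z:
        return False
    if z & nx.descendants(g, y):
        return False
    g2 = g.copy()
    if g2.has_edge(x, y):
        g2.remove_edge(x, y)
    return nx.is_d_separator(g2, {x}, {y}, set(z))


def minimal_adjustment_sets(dag: DAGModel, effect: str = "direct") -> list[frozenset]:
    """All minimal adjustment sets for the exposure-outcome effect.

    ``effect='direct'`` uses the single-door criterion (block every path but
    the direct edge); ``effect='total'`` the classic backdoor criterion.
    """
    g = _as_digraph(dag)
    x, y = dag.exposure, dag.outcome
    if effect == "direct":
        candidates = set(g.nodes) - {x, y} - nx.descendants(g, y)
        valid_fn = lambda z: _is_valid_direct_adjustment(g, x, y, z)
    elif effect == "total":
        candidates = set(g.nodes) - {x, y} - nx.descendants(g, x)
        g_back = g.copy()
        g_back.remove_edges_from(list(g.out_edges(x)))
        valid_fn = lambda z: nx.is_d_separator(g_back, {x}, {y}, set(z))
    else:
        raise ValueError("effect must be 'direct' or 'total'")
    candidates = sorted(candidates)
    valid: list[frozenset] = []
    for size in range(len(candidates) + 1):
        for combo in itertools.combinations(candidates, size):
            z = frozenset(combo)
            if any(v <= z for v in valid):
                continue  # a subset already works: z is not minimal
            if valid_fn(z):
                valid.append(z)
    return valid


@dataclass
class PropensityWeights:
    """Generalised overlap (ATO) weights for a multi-level treatment.

    With generalised propensity scores ``e_k(x)`` the weight of unit i in
    group Z_i is ``[sum_k 1/e_k(x_i)]^-1 / e_{Z_i}(x_i)`` (the matching-
    weights family), normalised to mean 1 within each treatment group.  In
    the binary case this reduces to the familiar overlap weights 1-e for
    the treated and e for the controls.
    """

    weights: np.ndarray
    propensities: pd.DataFrame  # one column per treatment level
    treatment: np.ndarray
    n_truncated: int = 0
    model: object = field(default=None, repr=False)


def ato_weights(
    covariates: pd.DataFrame,
    treatment,
    truncate_at: float = 1e-8,
    max_iter: int = 1000,
    poly_degree: int = 2,
) -> PropensityWeights:
    """Fit a multinomial-logit propensity model and return generalised
    overlap weights.

    ``covariates`` must be complete (complete-case analysis); propensities
    below ``truncate_at`` are clipped with a logged count.  The model uses a
    polynomial expansion of the standardised covariates (default quadratic
    with interactions): treatment here is a discretised continuous exposure,
    so the group-membership posterior is curved in the covariates and a
    purely linear logit leaves residual imbalance.
    """
    X = covariates.to_numpy(dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("covariates must be complete and finite")
    treatment = np.asarray(treatment)
    levels = [lv for lv in TREATMENT_LEVELS if lv in set(treatment)]
    if len(levels) < 2:
        levels = sorted(set(treatment))
    if len(levels) < 2:
        raise ValueError("treatment must have at least two levels")
    scaler = StandardScaler()
    Xs = scaler.fit_transform(X)
    if poly_degree > 1:
        Xs = PolynomialFeatures(poly_degree, include_bias=False).fit_transform(Xs)
    # C=inf: an unpenalised maximum-likelihood propensity model
    clf = LogisticRegression(C=np.inf, max_iter=max_iter)
    clf.fit(Xs, treatment)
    order = [list(clf.classes_).index(lv) for lv in levels]
    probs = clf.predict_proba(Xs)[:, order]
    n_trunc = int((probs < truncate_at).sum())
    if n_trunc:
        warnings.warn(
            f"{n_trunc} propensities below {truncate_at} were truncated", stacklevel=2
        )
        probs = np.clip(probs, truncate_at, None)
        probs = probs / probs.sum(axis=1, keepdims=True)
    inv_sum = (1.0 / probs).sum(axis=1)
    level_index = pd.Index(levels).get_indexer(treatment)
    e_own = probs[np.arange(len(treatment)), level_index]
    w = 1.0 / (inv_sum * e_own)
    for k, lv in enumerate(levels):
        mask = level_index == k
        w[mask] = w[mask] / w[mask].mean()
    return PropensityWeights(
        weights=w,
        propensities=pd.DataFrame(probs, columns=levels, index=covariates.index),
        treatment=treatment,
        n_truncated=n_trunc,
        model=clf,
    )


def smd_balance(
    covariates: pd.DataFrame,
    treatment,
    weights=None,
    threshold: float = 0.1,
) -> pd.DataFrame:
    """Pairwise standardised mean differences per covariate, unweighted and
    (when weights are given) weighted; denominators are the unweighted
    pooled standard deviations so before/after values are comparable."""
    treatment = np.asarray(treatment)
    levels = [lv for lv in TREATMENT_LEVELS if lv in set(treatment)] or sorted(
        set(treatment)
    )
    weights = np.ones(len(treatment)) if weights is None else np.asarray(weights, float)
    rows = []
    for col in covariates.columns:
        v = covariates[col].to_numpy(dtype=float)
        for a, b in itertools.combinations(levels, 2):
            ma, mb = treatment == a, treatment == b
            sd = np.sqrt(0.5 * (v[ma].var(ddof=1) + v[mb].var(ddof=1)))
            sd = sd if sd > 0 else 1.0
            smd_raw = (v[ma].mean() - v[mb].mean()) / sd
            wa, wb = weights[ma], weights[mb]
            smd_w = (np.average(v[ma], weights=wa) - np.average(v[mb], weights=wb)) / sd
            rows.append(
                {
                    "covariate": col,
                    "pair": f"{a}-{b}",
                    "smd_unweighted": smd_raw,
                    "smd_weighted": smd_w,
                    "balanced": abs(smd_w) < threshold,
                }
            )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class EffectEstimate:
    """One standardised, intercept-matched treatment contrast."""

    contrast: str  # e.g. "medium-small"
    adjusted: float
    unadjusted: float
    adjusted_ci: tuple = (np.nan, np.nan)
    unadjusted_ci: tuple = (np.nan, np.nan)
    intercept: float = 0.0  # shared small-group reference level

    def __post_init__(self):
        for est, ci in ((self.adjusted, self.adjusted_ci), (self.unadjusted, self.unadjusted_ci)):
            lo, hi = ci
            if np.isfinite(lo) and np.isfinite(hi) and not (lo - 1e-9 <= est <= hi + 1e-9):
                raise ValueError("estimate must lie inside its CI")


def weighted_effect(
    outcome,
    treatment,
    weights,
    standardise: bool = True,
    reference: str = "small",
) -> list[EffectEstimate]:
    """Adjusted (weighted) and unadjusted (unweighted) linear-model
    contrasts of the outcome across treatment groups.

    The outcome is Z-scored on the pooled sample (before weighting) when
    ``standardise``; both models are re-expressed with the reference
    ('small') group's fitted mean as the shared intercept, so contrasts are
    directly comparable between the adjusted and unadjusted lines.
    """
    y = np.asarray(outcome, dtype=float)
    treatment = np.asarray(treatment)
    weights = np.asarray(weights, dtype=float)
    levels = [lv for lv in TREATMENT_LEVELS if lv in set(treatment)] or sorted(
        set(treatment)
    )
    if reference not in levels:
        raise ValueError(f"reference level {reference!r} absent from treatment")
    for lv in levels:
        if (treatment == lv).sum() < 2:
            raise ValueError(f"treatment group {lv!r} has fewer than 2 units")
    if standardise:
        y = (y - y.mean()) / y.std(ddof=0)
    others = [lv for lv in levels if lv != reference]
    X = np.column_stack(
        [np.ones(y.size)] + [(treatment == lv).astype(float) for lv in others]
    )
    adj = sm.WLS(y, X, weights=weights).fit()
    unadj = sm.OLS(y, X).fit()
    out = []
    for k, lv in enumerate(others, start=1):
        out.append(
            EffectEstimate(
                contrast=f"{lv}-{reference}",
                adjusted=float(adj.params[k]),
                unadjusted=float(unadj.params[k]),
                intercept=float(adj.params[0]),
            )
        )
    return out


def bootstrap_causal(
    data: pd.DataFrame,
    covariate_cols,
    outcome_col: str,
    treatment_col: str = "size_group",
    n_reps: int = 200,
    seed: int | np.random.Generator = 0,
    standardise: bool = True,
    cluster_col: str | None = None,
) -> pd.DataFrame:
    """Bootstrap the whole weighting-and-estimation procedure.

    Each replicate resamples units with replacement, refits the propensity
    model, recomputes ATO weights and the adjusted/unadjusted contrasts;
    CIs are 2.5/97.5 percentiles.  Returns one row per contrast.

    For outcomes that are constant within a geographic area (the area's
    BID), pass ``cluster_col`` to resample whole areas instead of users so
    the CI reflects area-level noise.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    covariate_cols = list(covariate_cols)
    cluster_members = None
    if cluster_col is not None:
        cluster_members = [
            np.asarray(idx) for _, idx in data.groupby(cluster_col, observed=True).indices.items()
        ]

    def _fit(d: pd.DataFrame):
        pw = ato_weights(d[covariate_cols], d[treatment_col].to_numpy())
        return weighted_effect(
            d[outcome_col].to_numpy(),
            d[treatment_col].to_numpy(),
            pw.weights,
            standardise=standardise,
        )

    point = _fit(data)
    contrasts = [e.contrast for e in point]
    reps_adj = np.empty((n_reps, len(point)))
    reps_unadj = np.empty((n_reps, len(point)))
    n = len(data)
    for r in range(n_reps):
        if cluster_members is not None:
            picks = rng.integers(0, len(cluster_members), len(cluster_members))
            idx = np.concatenate([cluster_members[p] for p in picks])
        else:
            idx = rng.integers(0, n, n)
        try:
            ests = _fit(data.iloc[idx])
        except ValueError:
            reps_adj[r] = np.nan
            reps_unadj[r] = np.nan
            continue
        reps_adj[r] = [e.adjusted for e in ests]
        reps_unadj[r] = [e.unadjusted for e in ests]
    rows = []
    for k, est in enumerate(point):
        a_lo, a_hi = np.nanpercentile(reps_adj[:, k], [2.5, 97.5])
        u_lo, u_hi = np.nanpercentile(reps_unadj[:, k], [2.5, 97.5])
        rows.append(
            {
                "contrast": contrasts[k],
                "adjusted": est.adjusted,
                "adjusted_ci_low": float(min(a_lo, est.adjusted)),
                "adjusted_ci_high": float(max(a_hi, est.adjusted)),
                "unadjusted": est.unadjusted,
                "unadjusted_ci_low": float(min(u_lo, est.unadjusted)),
                "unadjusted_ci_high": float(max(u_hi, est.unadjusted)),
                "intercept": est.intercept,
                "n_reps": n_reps,
            }
        )
    return pd.DataFrame(rows)
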