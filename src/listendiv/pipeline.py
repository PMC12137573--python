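"""End-to-end orchestration: generate -> filter -> embed -> diversity ->
scaling -> causal, with file-based stage handoffs and a run manifest.

Every stage writes its outputs under the run directory so any stage can be
re-run or inspected in isolation; the manifest records the config hash,
seeds and row counts, and an identical re-run reproduces it.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from listendiv import causal as causal_mod
from listendiv import diversity as div_mod
from listendiv import embedding as emb_mod
from listendiv import filtering as filt_mod
from listendiv import scaling as scal_mod
from listendiv import synthetic as synth_mod
from listendiv.config import SimulationConfig

log = logging.getLogger("listendiv")

__all__ = ["RunConfig", "StageError", "run"]

ALL_STAGES = (
    "generate",
    "filter",
    "embed",
    "bid",
    "wid",
    "dispersion",
    "scaling",
    "causal",
)

#: DAG node -> causal-table column construction happens in causal_table();
#: the names coincide so adjustment sets select columns directly.
CAUSAL_COVARIATES = [
    "age",
    "gender",
    "income",
    "education",
    "immigration",
    "venues",
    "social_connections",
    "algorithmic_share",
]


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    out_dir: str = "runs/demo"
    stages: tuple = ALL_STAGES
    analysis_seed: int = 0
    # filtering
    min_duration_s: float = 30.0
    min_streams: int = 100
    max_locations: int = 10
    min_users_per_area: int = 200
    sample_k: int = 100
    unique: str = "songs"
    # diversity
    q: float = 1.0
    n_draw: int = 1000
    bid_reps: int = 1000
    group_key: str = "song_id"
    # embedding / wid / dispersion
    embed_d: int = 32
    wid_n_users: int = 100
    wid_reps: int = 1000
    dispersion_pairs: int = 500
    dispersion_reps: int = 500
    # scaling
    bin_width: int = 5
    age_traj_users: int = 100
    age_traj_reps: int = 500
    # causal
    causal_reps: int = 200
    causal_age_range: tuple = (18.0, 65.0)
    dag_path: str | None = None

    def __post_init__(self):
        if not isinstance(self.simulation, SimulationConfig):
            self.simulation = SimulationConfig.from_dict(self.simulation)
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["simulation"] = self.simulation.to_dict()
        d["stages"] = list(self.stages)
        d["causal_age_range"] = list(self.causal_age_range)
        return d


def causal_table(
    users: pd.DataFrame,
    areas: pd.DataFrame,
    bid_by_area: pd.Series,
    wid_by_user: pd.Series,
    age_range: tuple = (18.0, 65.0),
) -> pd.DataFrame:
    """Per-user analysis table for the causal stage.

    One row per complete-case user aged within ``age_range``: treatment is
    the area's population-size tercile, covariates are the user's age and
    gender plus the (transformed) demographics of their home area, outcomes
    are the area's BID and the user's WID.
    """
    a = areas.set_index("area_id")
    keep_cols = ["user_id", "home_area", "age", "gender"]
    user_level = {"income", "education", "immigration", "algorithmic"} <= set(
        users.columns
    )
    if user_level:
        keep_cols += ["income", "education", "immigration", "algorithmic"]
    t = users.loc[
        (users["age"] >= age_range[0]) & (users["age"] <= age_range[1]), keep_cols
    ].copy()
    t["gender"] = (t["gender"] == "M").astype(float)
    if user_level:
        # commune-like per-user proxies where available
        t["income"] = np.log(t["income"])
        t = t.rename(columns={"algorithmic": "algorithmic_share"})
    else:
        t["income"] = np.log(a["median_income"]).reindex(t["home_area"]).to_numpy()
        t["education"] = a["pct_degree"].reindex(t["home_area"]).to_numpy()
        t["immigration"] = a["pct_immigrant"].reindex(t["home_area"]).to_numpy()
        t["algorithmic_share"] = a["pct_algorithmic"].reindex(t["home_area"]).to_numpy()
    t["venues"] = np.log1p(a["venues"]).reindex(t["home_area"]).to_numpy()
    t["social_connections"] = a["sci_intl"].reindex(t["home_area"]).to_numpy()
    groups = scal_mod.population_quantile_groups(a["population"])
    t["size_group"] = groups.reindex(t["home_area"]).to_numpy()
    t["log10_population"] = np.log10(a["population"]).reindex(t["home_area"]).to_numpy()
    t["bid"] = bid_by_area.reindex(t["home_area"]).to_numpy()
    t["wid"] = wid_by_user.reindex(t["user_id"]).to_numpy()
    return t.dropna(subset=CAUSAL_COVARIATES + ["size_group"]).reset_index(drop=True)


def run(config: RunConfig) -> Path:
    """Execute the enabled stages in order; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim = config.simulation
    manifest: dict = {
        "config_hash": sim.config_hash(),
        "seed": sim.seed,
        "analysis_seed": config.analysis_seed,
        "stages": list(config.stages),
        "counts": {},
        "skipped": [lbl for lbl in ALL_STAGES if lbl not in config.stages],
    }
    state: dict = {}

    for stage in ALL_STAGES:
        if stage not in config.stages:
            log.info("stage %s disabled; skipping", stage)
            continue
        log.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, out, state, manifest)
        except StageError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage context
            raise StageError(stage, str(exc)) from exc

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    _write_summary(out, manifest)
    return out


# ---------------------------------------------------------------- stages


def _stage_generate(config: RunConfig, out: Path, state: dict, manifest: dict):
    sim = config.simulation
    catalog = synth_mod.generate_catalog(sim)
    pop = synth_mod.generate_population(sim)
    streams = synth_mod.generate_streams(pop, catalog, sim)
    catalog.songs.to_csv(out / "catalog.csv", index=False)
    pop.areas.to_csv(out / "areas.csv", index=False)
    pop.users.to_csv(out / "users.csv", index=False)
    pop.locations.to_csv(out / "locations.csv", index=False)
    streams.to_parquet(out / "streams.parquet", index=False)
    catalog.embedding.save(out / "truth_embedding")
    state.update(catalog=catalog, population=pop, streams=streams)
    manifest["counts"].update(
        n_areas=len(pop.areas), n_users=len(pop.users), n_streams=len(streams)
    )


def _load_streams(config: RunConfig, out: Path, state: dict):
    if "streams" not in state:
        path = out / "streams.parquet"
        if not path.exists():
            raise StageError("filter", f"input streams file not found: {path}")
        try:
            state["streams"] = pd.read_parquet(path)
        except Exception as exc:
            raise StageError("filter", f"could not read streams file {path}: {exc}")
        state["locations"] = pd.read_csv(out / "locations.csv")
    elif "locations" not in state:
        state["locations"] = state["population"].locations


def _stage_filter(config: RunConfig, out: Path, state: dict, manifest: dict):
    _load_streams(config, out, state)
    required = {"user_id", "song_id", "location_id", "duration_s"}
    missing = required - set(state["streams"].columns)
    if missing:
        raise StageError(
            "filter", f"streams table is missing columns {sorted(missing)}"
        )
    sampled, home, report = filt_mod.run_filter_pipeline(
        state["streams"],
        state["locations"],
        min_duration_s=config.min_duration_s,
        min_streams=config.min_streams,
        max_locations=config.max_locations,
        min_users_per_area=config.min_users_per_area,
        k=config.sample_k,
        seed=config.analysis_seed,
        unique=config.unique,
    )
    sampled.to_parquet(out / "filtered_streams.parquet", index=False)
    home.to_frame().to_csv(out / "homes.csv")
    with open(out / "filter_report.json", "w") as fh:
        json.dump(report.to_dict(), fh, indent=2)
    state.update(filtered=sampled, home=home, report=report)
    manifest["counts"].update(
        n_streams_filtered=len(sampled), n_users_filtered=home.size
    )


def _require(state: dict, key: str, stage: str, out: Path):
    if key in state:
        return state[key]
    loaders = {
        "filtered": lambda: pd.read_parquet(out / "filtered_streams.parquet"),
        "areas": lambda: pd.read_csv(out / "areas.csv"),
        "users": lambda: pd.read_csv(out / "users.csv"),
    }
    if key in loaders:
        try:
            state[key] = loaders[key]()
            return state[key]
        except Exception as exc:
            raise StageError(stage, f"missing prerequisite {key!r}: {exc}")
    raise StageError(stage, f"missing prerequisite {key!r}")


def _stage_embed(config: RunConfig, out: Path, state: dict, manifest: dict):
    filtered = _require(state, "filtered", "embed", out)
    emb = emb_mod.build_song_embedding(
        filtered, d=config.embed_d, seed=config.analysis_seed
    )
    emb.save(out / "embedding")
    state["embedding"] = emb
    manifest["counts"]["n_embedded_songs"] = int((~emb.disconnected).sum())


def _stage_bid(config: RunConfig, out: Path, state: dict, manifest: dict):
    filtered = _require(state, "filtered", "bid", out)
    rng = np.random.default_rng([config.analysis_seed, 11])
    rows = []
    for area, sub in filtered.groupby("home_area", observed=True):
        est = div_mod.bid_bootstrap(
            sub,
            group_key=config.group_key,
            n_draw=config.n_draw,
            n_reps=config.bid_reps,
            q=config.q,
            seed=rng,
        )
        rows.append(
            {
                "area_id": area,
                "statistic": est.statistic,
                "q": est.q,
                "mean": est.mean,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_reps": est.n_reps,
                "n_draw": est.n_draw,
            }
        )
    bid = pd.DataFrame(rows)
    bid.to_csv(out / "bid.csv", index=False)
    state["bid"] = bid
    manifest["counts"]["n_bid_areas"] = len(bid)


def _stage_wid(config: RunConfig, out: Path, state: dict, manifest: dict):
    filtered = _require(state, "filtered", "wid", out)
    emb = state.get("embedding")
    if emb is None:
        try:
            emb = emb_mod.SongEmbedding.load(out / "embedding")
        except Exception as exc:
            raise StageError("wid", f"no song embedding available: {exc}")
        state["embedding"] = emb
    scores = emb_mod.wid_scores(filtered, emb)
    homes = filtered.drop_duplicates("user_id").set_index("user_id")["home_area"]
    scores["home_area"] = homes.reindex(scores["user_id"]).to_numpy()
    scores.to_csv(out / "wid_users.csv", index=False)
    rng = np.random.default_rng([config.analysis_seed, 12])
    rows = []
    for area, sub in scores.groupby("home_area", observed=True):
        if len(sub) < config.wid_n_users:
            continue
        est = emb_mod.wid_bootstrap(
            sub["wid"].to_numpy(),
            n_users=config.wid_n_users,
            n_reps=config.wid_reps,
            seed=rng,
        )
        rows.append(
            {
                "area_id": area,
                "mean": est.mean,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
                "n_reps": est.n_reps,
                "n_draw": est.n_draw,
            }
        )
    wid = pd.DataFrame(rows)
    wid.to_csv(out / "wid.csv", index=False)
    state.update(wid_users=scores, wid=wid)
    manifest["counts"]["n_wid_users"] = len(scores)


def _stage_dispersion(config: RunConfig, out: Path, state: dict, manifest: dict):
    filtered = _require(state, "filtered", "dispersion", out)
    emb = state["embedding"]
    organic = (
        filtered[~filtered["is_algorithmic"].astype(bool)]
        if "is_algorithmic" in filtered.columns
        else filtered
    )
    uids, vecs = emb_mod.user_vectors(organic, emb)
    homes = filtered.drop_duplicates("user_id").set_index("user_id")["home_area"]
    area_of = homes.reindex(uids).to_numpy()
    rng = np.random.default_rng([config.analysis_seed, 13])
    rows = []
    for area in pd.unique(area_of):
        sel = vecs[area_of == area]
        if sel.shape[0] < 2:
            continue
        est = emb_mod.user_dispersion(
            sel,
            n_pairs=config.dispersion_pairs,
            n_reps=config.dispersion_reps,
            seed=rng,
        )
        rows.append(
            {
                "area_id": area,
                "mean": est.mean,
                "ci_low": est.ci_low,
                "ci_high": est.ci_high,
            }
        )
    disp = pd.DataFrame(rows)
    disp.to_csv(out / "dispersion.csv", index=False)
    state["dispersion"] = disp


def _stage_scaling(config: RunConfig, out: Path, state: dict, manifest: dict):
    areas = _require(state, "areas", "scaling", out)
    sizes = areas.set_index("area_id")["population"]
    log_pop = np.log10(sizes)
    pairs = {}
    for label in ("bid", "wid", "dispersion"):
        tbl = state.get(label)
        if tbl is None or tbl.empty:
            continue
        merged = tbl.set_index("area_id")["mean"].align(log_pop, join="inner")
        pairs[f"{label}~log10_population"] = (merged[1].to_numpy(), merged[0].to_numpy())
    corr = scal_mod.correlation_family(pairs) if pairs else pd.DataFrame()
    corr.to_csv(out / "scaling_correlations.csv", index=False)
    state["scaling_correlations"] = corr

    if "wid_users" in state:
        users = _require(state, "users", "scaling", out)
        merged = state["wid_users"].merge(
            users[["user_id", "age"]], on="user_id", how="inner"
        )
        try:
            traj, peak = scal_mod.age_trajectory(
                merged["age"],
                merged["wid"],
                bin_width=config.bin_width,
                n_users=config.age_traj_users,
                n_reps=config.age_traj_reps,
                seed=np.random.default_rng([config.analysis_seed, 14]),
            )
            traj.to_csv(out / "age_trajectory.csv", index=False)
            state["age_trajectory"] = traj
            manifest["counts"]["age_peak_bin"] = peak
        except ValueError:
            log.warning("age trajectory skipped: no bin holds enough users")

    # per-quantile demographic regressions on the area outcome table
    if "bid" in state and not state["bid"].empty:
        at = areas.set_index("area_id")
        tbl = pd.DataFrame(
            {
                "log_income": np.log(at["median_income"]),
                "pct_degree": at["pct_degree"],
                "pct_immigrant": at["pct_immigrant"],
                "log_venues": np.log1p(at["venues"]),
                "sci_intl": at["sci_intl"],
                "pct_algorithmic": at["pct_algorithmic"],
            }
        )
        tbl["size_group"] = scal_mod.population_quantile_groups(at["population"])
        outcomes = []
        for label in ("bid", "wid"):
            if label in state and not state[label].empty:
                tbl[label] = state[label].set_index("area_id")["mean"]
                outcomes.append(label)
        tbl = tbl.dropna()
        if outcomes and len(tbl) >= 10:
            r2 = scal_mod.quantile_regression_r2(
                tbl,
                outcome_cols=outcomes,
                covariate_cols=[
                    "log_income",
                    "pct_degree",
                    "pct_immigrant",
                    "log_venues",
                    "sci_intl",
                    "pct_algorithmic",
                ],
            )
            r2.to_csv(out / "quantile_r2.csv", index=False)
            state["quantile_r2"] = r2


def _stage_causal(config: RunConfig, out: Path, state: dict, manifest: dict):
    users = _require(state, "users", "causal", out)
    areas = _require(state, "areas", "causal", out)
    if "bid" not in state or "wid_users" not in state:
        raise StageError("causal", "bid and wid stages must run before causal")
    bid_by_area = state["bid"].set_index("area_id")["mean"]
    wid_by_user = state["wid_users"].set_index("user_id")["wid"]
    table = causal_table(
        users, areas, bid_by_area, wid_by_user, age_range=config.causal_age_range
    )
    table.to_csv(out / "causal_table.csv", index=False)
    results, balances = [], {}
    for outcome in ("bid", "wid"):
        dag = (
            causal_mod.DAGModel.from_file(
                config.dag_path, exposure="population_size", outcome=outcome
            )
            if config.dag_path
            else causal_mod.default_dag(outcome)
        )
        adj_sets = causal_mod.minimal_adjustment_sets(dag)
        adj = sorted(adj_sets[0]) if adj_sets else []
        sub = table.dropna(subset=[outcome])
        eff = causal_mod.bootstrap_causal(
            sub,
            covariate_cols=adj,
            outcome_col=outcome,
            n_reps=config.causal_reps,
            seed=np.random.default_rng([config.analysis_seed, 15]),
            # the area's BID is constant within the area: resample areas so
            # the CI carries area-level noise; WID varies per user
            cluster_col="home_area" if outcome == "bid" else None,
        )
        eff["outcome"] = outcome
        eff["adjustment_set"] = ",".join(adj)
        results.append(eff)
        pw = causal_mod.ato_weights(sub[adj], sub["size_group"].to_numpy())
        bal = causal_mod.smd_balance(
            sub[adj], sub["size_group"].to_numpy(), weights=pw.weights
        )
        balances[outcome] = bal.to_dict(orient="records")
    effects = pd.concat(results, ignore_index=True)
    effects.to_csv(out / "causal_effects.csv", index=False)
    with open(out / "balance_report.json", "w") as fh:
        json.dump(balances, fh, indent=2, default=str)
    state["causal_effects"] = effects
    manifest["counts"]["n_causal_users"] = len(table)


_STAGE_FUNCS = {
    "generate": _stage_generate,
    "filter": _stage_filter,
    "embed": _stage_embed,
    "bid": _stage_bid,
    "wid": _stage_wid,
    "dispersion": _stage_dispersion,
    "scaling": _stage_scaling,
    "causal": _stage_causal,
}


def _write_summary(out: Path, manifest: dict) -> None:
    lines = [
        "listendiv run summary",
        "=====================",
        f"config hash: {manifest['config_hash']}",
        f"generator seed: {manifest['seed']}; analysis seed: {manifest['analysis_seed']}",
        f"stages run: {', '.join(manifest['stages'])}",
    ]
    if manifest["skipped"]:
        lines.append(f"stages skipped: {', '.join(manifest['skipped'])}")
    for k, v in sorted(manifest["counts"].items()):
        lines.append(f"  {k}: {v}")
    (out / "summary.txt").write_text("\n".join(lines) + "\n")
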