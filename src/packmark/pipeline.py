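"""End-to-end pipeline: simulate -> territories -> three analyses -> reports.

``run_pipeline`` wires the stages together on synthetic data and writes
every intermediate and report to files, so a fixed seed reproduces the run
byte for byte.  Stage outputs are never mutated by later stages; each
report records the resolved configuration and its hash.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import covariates as cov
from . import follows as fl
from . import inference, selection, synthetic, territory

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    seed: int = 0
    n_packs: int = 3
    fixes_per_pack: int = 720
    fix_interval: float = 3.0
    n_follows_per_pack: int = 12
    window_days: tuple = (7, 14, 30)
    territory_level: float = 0.95
    core_level: float = 0.50
    availability_ratio: int = 15
    availability_window_days: int = 90
    interpolation_step_minutes: float = 1.0
    continuity_constant: float = 0.5
    k_folds: int = 10
    extent: float = 60_000.0

    def validate(self) -> None:
        if not 0 < self.core_level < self.territory_level < 1:
            raise ValueError("need 0 < core_level < territory_level < 1")
        if self.availability_ratio < 1:
            raise ValueError("availability_ratio must be >= 1")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_packs < 2:
            raise ValueError("n_packs must be >= 2")

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        if not path.exists():
            raise FileNotFoundError(f"config file not found: {path}")
        text = path.read_text()
        if path.suffix in {".yml", ".yaml"}:
            import yaml

            data = yaml.safe_load(text) or {}
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        if "window_days" in data:
            data["window_days"] = tuple(data["window_days"])
        config = cls(**data)
        config.validate()
        return config

    def hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _dump_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True, default=str))


def _avg_report(avg: selection.AveragedModel) -> dict:
    return {
        "n_members": len(avg.members),
        "aicc": avg.aicc_values,
        "delta_aicc": avg.delta,
        "weights": avg.weights,
        "beta": avg.beta,
        "member_terms": [list(m.terms) for m in avg.members],
    }


def _fit_candidates(fit_fn, design, candidate_set, **kw):
    """Fit every candidate model, skipping pathological members."""
    fits = []
    for terms in candidate_set:
        try:
            fits.append(fit_fn(design, terms, **kw))
        except (inference.SeparationError, np.linalg.LinAlgError):
            continue
    if not fits:
        raise RuntimeError("no candidate model could be fitted")
    return fits


def build_territories(config: RunConfig, fixes: pd.DataFrame, anchor=None) -> dict:
    """95% territory and core polygons per pack at the anchor time."""
    anchor = anchor or pd.to_datetime(fixes["timestamp"]).max()
    out = {}
    for pid in sorted(fixes["pack_id"].unique()):
        ud = territory.fit_ud(
            fixes, pid, anchor, window_days=config.availability_window_days
        )
        out[pid] = {
            "ud": ud,
            "territory": territory.isopleth(ud, config.territory_level),
            "core": territory.isopleth(ud, config.core_level),
        }
    return out


def _territory_kwargs(pid, terrs):
    return {
        "own_territory": terrs[pid]["territory"],
        "own_core": terrs[pid]["core"],
        "neighbor_territories": [
            terrs[q]["territory"] for q in sorted(terrs) if q != pid
        ],
    }


def analysis_rsf(config: RunConfig, sim, terrs, rng) -> dict:
    """Used/available RSF on all scent-mark locations (analysis 1)."""
    marks = sim.events[sim.events["behavior_class"] == "scent_mark"]
    frames = []
    for pid in sorted(marks["pack_id"].unique()):
        used = marks[marks["pack_id"] == pid][["x", "y"]].reset_index(drop=True)
        if len(used) == 0:
            continue
        avail = fl.sample_availability(
            used, terrs[pid]["territory"], ratio=config.availability_ratio,
            seed=rng,
        )
        pts = pd.concat([used, avail], ignore_index=True)
        cm = cov.sample_covariates(
            pts, sim.layers, **_territory_kwargs(pid, terrs)
        )
        df = cm.data
        df["response"] = [1] * len(used) + [0] * len(avail)
        df["weight"] = np.where(df["response"] == 1, 1.0, 100.0)
        df["pack_id"] = pid
        frames.append(df)
    design = pd.concat(frames, ignore_index=True)

    terms_to_std = [
        c for c in design.columns
        if c not in {"response", "weight", "pack_id", "residency"}
    ]
    cm = cov.standardize(cov.CovariateMatrix(design), columns=terms_to_std)
    design = cm.data
    screen = cov.collinearity_screen(
        cov.CovariateMatrix(design[terms_to_std + ["residency"]])
    )

    linear = list(selection.MANDATORY_TERMS) + [
        "n_neighbors", "neighbor_boundary_dist", "own_core_dist",
    ]
    interactions = [
        "dist_road:neighbor_boundary_dist",
        "dist_pan:neighbor_boundary_dist",
        "dist_road:own_core_dist",
        "dist_pan:own_core_dist",
    ]
    cand = selection.build_candidate_set(
        linear, interactions, screen_report=screen
    )
    fits = _fit_candidates(
        lambda d, t: inference.fit_rsf(d, t), design,
        [m for m in cand.models if m],  # null handled separately below
    )
    null_fit = inference.fit_rsf(design, [])
    avg = selection.average_models(fits)

    sweep = np.linspace(
        design["neighbor_boundary_dist"].min(),
        design["neighbor_boundary_dist"].max(), 25,
    )
    reference = {t: 0.0 for t in {p for m in avg.terms for p in m.split(":")}}
    curve = selection.log_rss_curve(
        avg, "neighbor_boundary_dist", sweep, reference
    )
    return {
        "design": design,
        "screen": screen,
        "candidates": cand,
        "averaged": avg,
        "null_aicc": selection.aicc(null_fit),
        "min_aicc": float(min(selection.aicc(f) for f in fits)),
        "log_rss_curve": curve,
        "standardization": {
            "center": {k: float(v) for k, v in cm.center.items()},
            "scale": {k: float(v) for k, v in cm.scale.items()},
        },
    }


def analysis_rpsf(config: RunConfig, sim, terrs) -> dict:
    """Used/unused scent-marking probability along follows (analysis 2)."""
    all_follows = fl.segment_follows(sim.events)
    design_pts = fl.label_used_unused(all_follows)
    frames = []
    for pid in sorted(design_pts["pack_id"].unique()):
        sub = design_pts[design_pts["pack_id"] == pid]
        cm = cov.sample_covariates(
            sub[["x", "y"]], sim.layers, **_territory_kwargs(pid, terrs)
        )
        df = cm.data
        for c in ("response", "pack_id", "follow_id",
                  "pack_size", "pup_presence", "pack_age"):
            df[c] = sub[c].to_numpy()
        frames.append(df)
    design = pd.concat(frames, ignore_index=True)
    design["pup_presence"] = design["pup_presence"].astype(float)

    terms_to_std = [
        c for c in design.columns
        if c not in {"response", "pack_id", "follow_id", "residency",
                     "pup_presence"}
        and design[c].std(ddof=1) > 0
    ]
    cm = cov.standardize(cov.CovariateMatrix(design), columns=terms_to_std)
    design = cm.data
    screen = cov.collinearity_screen(
        cov.CovariateMatrix(design[terms_to_std])
    )

    # with fixed pack-follow intercepts, follow-constant social terms are
    # absorbed by the intercepts and enter only through interactions
    linear = list(selection.MANDATORY_TERMS) + [
        "n_neighbors", "neighbor_boundary_dist", "own_core_dist",
    ]
    interactions = [
        "neighbor_boundary_dist:pack_size",
        "neighbor_boundary_dist:pup_presence",
        "dist_road:own_core_dist",
    ]
    cand = selection.build_candidate_set(
        linear, interactions, screen_report=screen, require_main_effects=False
    )
    fits = _fit_candidates(
        lambda d, t: inference.fit_rpsf(d, t), design,
        [m for m in cand.models if m],
    )
    avg = selection.average_models(fits)

    # in-sample AUC of the weight-averaged member probabilities
    pred = np.zeros(len(fits[0].extra["fitted"]))
    for w, f in zip(avg.weights, avg.members):
        pred += w * f.extra["fitted"]
    y = avg.members[0].extra["response"]
    auc_avg = selection.auc(pred, y)
    null_fit = inference.fit_rpsf(design, [])
    auc_null = selection.auc(null_fit.extra["fitted"], null_fit.extra["response"])
    return {
        "design": design,
        "screen": screen,
        "candidates": cand,
        "averaged": avg,
        "auc": auc_avg,
        "auc_null": auc_null,
    }


def analysis_tradeoff(config: RunConfig, sim, terrs, rng) -> dict:
    """Aggregated-follow marking-vs-hunting trade-off model (analysis 3)."""
    all_follows = fl.segment_follows(sim.events)
    frames = []
    for f in all_follows:
        agg = fl.aggregate_follow(
            f, sim.layers, _territory_kwargs(f.pack_id, terrs),
            c=config.continuity_constant,
        )
        frames.append(agg.as_row())
    af = pd.DataFrame(frames)
    af["pup_presence"] = af["pup_presence"].astype(float)

    delta_terms = ["delta_dist_road", "delta_dist_pan",
                   "delta_neighbor_boundary_dist"]
    social_terms = ["pack_size", "pack_age"]
    std_cols = [
        c for c in delta_terms + social_terms if af[c].std(ddof=1) > 0
    ]
    cm = cov.standardize(cov.CovariateMatrix(af), columns=std_cols)
    af = cm.data

    models = []
    base = tuple(delta_terms)
    for extra in [
        (), ("pack_size",), ("pack_age",), ("pack_size", "pack_age"),
        ("pack_size", "delta_neighbor_boundary_dist_bin:pack_size"),
        ("pack_age", "delta_neighbor_boundary_dist_bin:pack_age"),
    ]:
        models.append(base + extra)
    models.append(())  # null: intercept + pack effect only
    # drop models touching a degenerate (zero-variance) covariate
    models = [
        m for m in models
        if all(af[p].std(ddof=1) > 0 for t in m for p in t.split(":"))
    ]

    fitted = []
    for m in models:
        try:
            fitted.append((m, inference.fit_logratio(af, m)))
        except np.linalg.LinAlgError:
            continue
    if not fitted:
        raise RuntimeError("no trade-off model could be fitted")
    models = [m for m, _ in fitted]
    fits = [f for _, f in fitted]
    avg = selection.average_models(fits)
    cv = selection.kfold_cv_rmse(af, models, k=config.k_folds, seed=rng)
    t, p = selection.paired_t_test(
        cv["rmse_model"].to_numpy(), cv["rmse_baseline"].to_numpy()
    )
    # per-pack predicted ratio at the entering vs leaving contrast
    pack_rows = []
    for fit, w in zip(avg.members, avg.weights):
        for pid, b in fit.intercepts.items():
            pack_rows.append({"pack_id": pid, "weight": w, "blup": b})
    return {
        "af": af,
        "models": models,
        "averaged": avg,
        "cv": cv,
        "paired_t": {"t": t, "p": p},
        "mean_rmse_model": float(cv["rmse_model"].mean()),
        "mean_rmse_baseline": float(cv["rmse_baseline"].mean()),
        "pack_intercepts": pd.DataFrame(pack_rows),
    }


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the full synthetic pipeline and write a run directory.

    Returns the in-memory results dict; on disk the run directory holds
    the simulated inputs, territory GeoJSON, and one JSON report per
    analysis, all reproducible byte for byte under a fixed seed.
    """
    config.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    sim_config = synthetic.SimConfig(
        seed=config.seed,
        n_packs=config.n_packs,
        fixes_per_pack=config.fixes_per_pack,
        fix_interval=config.fix_interval,
        n_follows_per_pack=config.n_follows_per_pack,
        extent=config.extent,
    )
    stage = "simulate"
    try:
        sim = synthetic.simulate(sim_config)
        sim.write(outdir / "sim")

        stage = "territory"
        terrs = build_territories(config, sim.fixes)
        geojson = {
            "type": "FeatureCollection",
            "features": [
                terrs[p][k].to_geojson()
                for p in sorted(terrs) for k in ("territory", "core")
            ],
        }
        _dump_json(geojson, outdir / "territories.geojson")

        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=config.seed, spawn_key=(99,))
        )
        stage = "analysis_rsf"
        rsf = analysis_rsf(config, sim, terrs, rng)
        stage = "analysis_rpsf"
        rpsf = analysis_rpsf(config, sim, terrs)
        stage = "analysis_tradeoff"
        trade = analysis_tradeoff(config, sim, terrs, rng)
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    meta = {"config": asdict(config), "config_hash": config.hash()}
    _dump_json(
        {**meta, **_avg_report(rsf["averaged"]),
         "null_aicc": rsf["null_aicc"], "min_aicc": rsf["min_aicc"]},
        outdir / "rsf_report.json",
    )
    rsf["log_rss_curve"].to_csv(outdir / "rsf_log_rss_curve.csv", index=False)
    _dump_json(
        {**meta, **_avg_report(rpsf["averaged"]),
         "auc": rpsf["auc"], "auc_null": rpsf["auc_null"]},
        outdir / "rpsf_report.json",
    )
    _dump_json(
        {**meta, **_avg_report(trade["averaged"]),
         "mean_rmse_model": trade["mean_rmse_model"],
         "mean_rmse_baseline": trade["mean_rmse_baseline"],
         "paired_t": trade["paired_t"]},
        outdir / "tradeoff_report.json",
    )
    trade["cv"].to_csv(outdir / "tradeoff_cv.csv", index=False)
    trade["pack_intercepts"].to_csv(
        outdir / "tradeoff_pack_intercepts.csv", index=False
    )
    return {"sim": sim, "territories": terrs, "rsf": rsf, "rpsf": rpsf,
            "tradeoff": trade, "meta": meta}
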