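"""End-to-end orchestration: simulate/ingest → filter → scale → decompose
→ latent structure → anomalies → liver outcomes → kernel regression.

Each stage writes its artifacts (delimited matrices and tables, JSON
reports) under the run's output directory and appends a structured entry
(stage name, wall time, row/column counts in and out) to the manifest, so
filtering decisions and join drop-counts stay auditable.  A partial
failure leaves completed artifacts in place and records the failed stage.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import anomaly as anomaly_mod
from . import kmr as kmr_mod
from . import latent as latent_mod
from . import liver as liver_mod
from . import panel as panel_mod
from . import pcp as pcp_mod
from . import simulate as sim_mod

logger = logging.getLogger(__name__)

STAGES = ("simulate", "filter", "scale", "decompose", "latent",
          "anomalies", "outcomes", "kmr")


@dataclass
class RunConfig:
    """Declarative configuration of a full pipeline run."""

    output_dir: str = "expomix_run"
    seed: int = 0
    # either simulate…
    simulate: bool = True
    sim: sim_mod.MixtureSimConfig | None = None
    # …or ingest from files
    exposures_path: str | None = None
    lod_table_path: str | None = None
    detect_flags_path: str | None = None
    outcomes_path: str | None = None
    covariates_path: str | None = None

    detection_threshold: float = 0.5
    log1p_transform: bool = False
    pcp_lambda: float | None = None
    pcp_mu: float | None = None
    pcp_rank: int | None = 3
    n_components: int = 3
    anomaly_q_hi: float = 0.95
    anomaly_q_lo: float = 0.05
    anomaly_classifier: str = "percentile"   # or "lod_median"
    kmr_outcome: str = "fli"
    kmr_iters: int = 2000
    kmr_burn: int = 1000
    kmr_max_exposures: int = 12
    run_kmr: bool = True

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim_cfg = raw.pop("sim", None)
        cfg = cls(**raw)
        if sim_cfg:
            cfg.sim = sim_mod.MixtureSimConfig(**sim_cfg)
        return cfg

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


def validate_config(config: RunConfig) -> list[str]:
    """Return every violation at once (empty list = valid)."""
    findings = []
    if not (0 <= config.detection_threshold <= 1):
        findings.append(f"detection_threshold {config.detection_threshold} outside [0, 1]")
    if not (0 <= config.anomaly_q_lo < config.anomaly_q_hi <= 1):
        findings.append(
            f"anomaly quantiles (lo={config.anomaly_q_lo}, hi={config.anomaly_q_hi}) "
            "must satisfy 0 <= lo < hi <= 1")
    if config.anomaly_classifier not in ("percentile", "lod_median"):
        findings.append(f"unknown anomaly_classifier {config.anomaly_classifier!r}")
    if config.kmr_iters <= config.kmr_burn:
        findings.append("kmr_iters must exceed kmr_burn")
    if config.pcp_lambda is not None and config.pcp_lambda <= 0:
        findings.append("pcp_lambda must be positive")
    if config.pcp_mu is not None and config.pcp_mu <= 0:
        findings.append("pcp_mu must be positive")
    if not config.simulate:
        for name in ("exposures_path", "lod_table_path"):
            p = getattr(config, name)
            if p is None:
                findings.append(f"{name} is required when simulate is false")
            elif not Path(p).exists():
                findings.append(f"{name} does not exist: {p}")
        if config.sim is not None:
            findings.append("sim config given but simulate is false")
    else:
        try:
            (config.sim or sim_mod.MixtureSimConfig(seed=config.seed)).validate()
        except ValueError as exc:
            findings.append(f"simulation config invalid: {exc}")
    return findings


class PipelineError(RuntimeError):
    pass


def _config_hash(config: RunConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the run manifest (also written as JSON)."""
    findings = validate_config(config)
    if findings:
        raise PipelineError("invalid configuration: " + "; ".join(findings))

    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": _config_hash(config),
        "seed": config.seed,
        "stages": [],
        "status": "running",
    }

    def record(stage: str, t0: float, outputs: dict, **counts) -> None:
        manifest["stages"].append({
            "stage": stage, "wall_time_s": round(time.perf_counter() - t0, 3),
            "outputs": outputs, **counts,
        })

    state: dict = {}
    try:
        for stage in STAGES:
            t0 = time.perf_counter()
            outputs = _STAGE_FUNCS[stage](config, state, outdir)
            if outputs is None:
                continue
            record(stage, t0, outputs, **state.pop("_counts", {}))
        manifest["status"] = "ok"
    except Exception as exc:
        manifest["status"] = "failed"
        manifest["failed_stage"] = stage
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


# --------------------------------------------------------------------------
# stage implementations (each returns {artifact name: path})
# --------------------------------------------------------------------------

def _stage_simulate(config: RunConfig, state: dict, outdir: Path) -> dict:
    if config.simulate:
        cfg = config.sim or sim_mod.MixtureSimConfig(seed=config.seed)
        study = sim_mod.generate_exposure_matrix(cfg)
        study = sim_mod.generate_outcomes(study, cfg)
        paths = sim_mod.write_study(study, outdir / "input")
        state["panel"] = study.panel
        state["outcomes"] = study.outcomes
        state["covariates"] = study.covariates
        state["_counts"] = {"n_participants": study.panel.shape[0],
                            "n_analytes": study.panel.shape[1]}
        return paths
    pan = panel_mod.read_panel(config.exposures_path, config.lod_table_path,
                               detect_table=config.detect_flags_path)
    state["panel"] = pan
    state["outcomes"] = (pd.read_csv(config.outcomes_path).set_index("participant_id")
                         if config.outcomes_path else None)
    state["covariates"] = (pd.read_csv(config.covariates_path).set_index("participant_id")
                           if config.covariates_path else None)
    state["_counts"] = {"n_participants": pan.shape[0], "n_analytes": pan.shape[1]}
    return {"exposures": str(config.exposures_path)}


def _stage_filter(config: RunConfig, state: dict, outdir: Path) -> dict:
    pan = state["panel"]
    summaries = panel_mod.detection_frequency(pan, config.detection_threshold)
    df = pd.DataFrame([dataclasses.asdict(s) for s in summaries])
    path = outdir / "detection_summary.csv"
    df.to_csv(path, index=False)
    filtered = panel_mod.filter_by_detection(pan, config.detection_threshold)
    state["panel"] = filtered
    state["_counts"] = {"analytes_in": pan.shape[1], "analytes_out": filtered.shape[1]}
    return {"detection_summary": str(path)}


def _stage_scale(config: RunConfig, state: dict, outdir: Path) -> dict:
    pan = panel_mod.substitute_lod(state["panel"])
    values = pan.values
    if config.log1p_transform:
        values = np.log1p(values)
        pan = pan.copy()
        pan.values = values
        pan.lod = np.log1p(pan.lod)
    scaled, factors, lod_scaled = panel_mod.scale_columns(pan)
    state["panel_sub"] = pan
    state["X_scaled"] = scaled
    state["scale_factors"] = factors
    state["lod_scaled"] = lod_scaled
    path = outdir / "scaled_exposures.csv"
    scaled.to_csv(path, index_label="participant_id")
    fpath = outdir / "scale_factors.csv"
    factors.rename("sd").to_csv(fpath, index_label="analyte")
    return {"scaled_exposures": str(path), "scale_factors": str(fpath)}


def _stage_decompose(config: RunConfig, state: dict, outdir: Path) -> dict:
    pan = state["panel_sub"]
    X = state["X_scaled"].values
    n, p = X.shape
    params = pcp_mod.PCPParams(
        lam=config.pcp_lambda or pcp_mod.default_lambda(n, p),
        mu=config.pcp_mu or pcp_mod.default_mu(n, p),
        rank=config.pcp_rank,
    )
    res = pcp_mod.decompose(X, state["lod_scaled"].values,
                            pan.detect_flag.values, pan.missing_mask.values, params)
    state["pcp"] = res
    cols = pan.analytes
    ids = pan.participant_id
    lpath, spath = outdir / "L_lowrank.csv", outdir / "S_sparse.csv"
    pd.DataFrame(res.L, index=ids, columns=cols).to_csv(lpath, index_label="participant_id")
    pd.DataFrame(res.S, index=ids, columns=cols).to_csv(spath, index_label="participant_id")
    report = {
        "converged": bool(res.converged), "n_iter": int(res.n_iter),
        "lambda": res.params.lam, "mu": res.params.mu, "rank": res.params.rank,
        "objective_first": float(res.objective_trace[0]) if len(res.objective_trace) else None,
        "objective_last": float(res.objective_trace[-1]) if len(res.objective_trace) else None,
    }
    rpath = outdir / "pcp_report.json"
    rpath.write_text(json.dumps(report, indent=2))
    return {"L": str(lpath), "S": str(spath), "pcp_report": str(rpath)}


def _stage_latent(config: RunConfig, state: dict, outdir: Path) -> dict:
    pan = state["panel_sub"]
    res = state["pcp"]
    k = min(config.n_components, min(res.L.shape))
    lat = latent_mod.svd_loadings(res.L, k, analytes=pan.analytes)
    table = latent_mod.component_loadings(lat, list(range(1, k + 1)), pan.analyte_class)
    lpath = outdir / "component_loadings.csv"
    table.to_csv(lpath, index=False)
    comp = latent_mod.compare_raw_denoised(state["X_scaled"], res.L,
                                           classes=pan.analyte_class, columns=pan.analytes)
    rpath = outdir / "spearman_raw.csv"
    dpath = outdir / "spearman_denoised.csv"
    comp.raw_corr.to_csv(rpath)
    comp.denoised_corr.to_csv(dpath)
    state["latent"] = lat
    return {"component_loadings": str(lpath), "spearman_raw": str(rpath),
            "spearman_denoised": str(dpath)}


def _stage_anomalies(config: RunConfig, state: dict, outdir: Path) -> dict:
    pan = state["panel_sub"]
    res = state["pcp"]
    if config.anomaly_classifier == "percentile":
        R = anomaly_mod.residual_matrix(state["X_scaled"].values, res.L,
                                        pan.missing_mask.values)
        rescaled = anomaly_mod.rescale_sparse(res.S, R)
        # missing cells carry no observed deviation: exclude from thresholds
        rescaled = np.where(pan.missing_mask.values, np.nan, rescaled)
        grid = anomaly_mod.classify_events(rescaled, config.anomaly_q_hi, config.anomaly_q_lo)
        labels = grid.labels
        state["anomaly_grid"] = grid
    else:
        labels = anomaly_mod.tier_by_lod_median(pan)
    path = outdir / "anomaly_labels.csv"
    pd.DataFrame(labels, index=pan.participant_id, columns=pan.analytes) \
        .to_csv(path, index_label="participant_id")
    return {"anomaly_labels": str(path)}


def _stage_outcomes(config: RunConfig, state: dict, outdir: Path) -> dict:
    outcomes = state.get("outcomes")
    if outcomes is None:
        logger.info("no outcomes table; skipping liver stage")
        return {"skipped": "no outcomes table"}
    liver = liver_mod.add_fli(outcomes)
    model_table = liver_mod.assemble_outcomes(liver, state["X_scaled"], state["covariates"])
    state["model_table"] = model_table
    path = outdir / "modelling_table.csv"
    model_table.to_csv(path, index_label="participant_id")
    state["_counts"] = {"rows": len(model_table)}
    return {"modelling_table": str(path)}


def _stage_kmr(config: RunConfig, state: dict, outdir: Path) -> dict:
    table = state.get("model_table")
    if table is None or not config.run_kmr:
        return {"skipped": "kmr disabled or no modelling table"}
    exp_cols = [c for c in table.columns if c.startswith("exp_")][: config.kmr_max_exposures]
    cov_cols = [c for c in table.columns if c.startswith("cov_")]
    clean = table.dropna(subset=exp_cols + cov_cols + [config.kmr_outcome])
    model = kmr_mod.KMRModel(
        exposures=clean[exp_cols].values,
        covariates=clean[cov_cols].values,
        outcome=clean[config.kmr_outcome].values,
        exposure_names=exp_cols,
    )
    post = kmr_mod.fit(model, n_iter=config.kmr_iters, n_burn=config.kmr_burn,
                       seed=config.seed)
    state["kmr_posterior"] = post
    pips = kmr_mod.pip(post)
    ppath = outdir / "kmr_pips.csv"
    pd.DataFrame({"exposure": exp_cols, "pip": pips}).to_csv(ppath, index=False)
    rows = []
    for m in range(len(exp_cols)):
        eff = kmr_mod.univariate_effect(post, m)
        rows.append({"exposure": exp_cols[m], "estimate": eff.estimate,
                     "lower95": eff.lower95, "upper95": eff.upper95})
    epath = outdir / "kmr_univariate_effects.csv"
    pd.DataFrame(rows).to_csv(epath, index=False)
    overall = kmr_mod.overall_mixture_effect(post)
    opath = outdir / "kmr_overall_effect.csv"
    pd.DataFrame([{"context": e.context, "estimate": e.estimate,
                   "lower95": e.lower95, "upper95": e.upper95} for e in overall]) \
        .to_csv(opath, index=False)
    report = {"acceptance_rates": post.acceptance_rates,
              "n_iter": post.n_iter, "n_burn": post.n_burn, "outcome": config.kmr_outcome}
    rpath = outdir / "kmr_report.json"
    rpath.write_text(json.dumps(report, indent=2))
    return {"pips": str(ppath), "univariate_effects": str(epath),
            "overall_effect": str(opath), "kmr_report": str(rpath)}


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "filter": _stage_filter,
    "scale": _stage_scale,
    "decompose": _stage_decompose,
    "latent": _stage_latent,
    "anomalies": _stage_anomalies,
    "outcomes": _stage_outcomes,
    "kmr": _stage_kmr,
}
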