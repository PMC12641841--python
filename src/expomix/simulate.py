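"""Synthetic censored exposure panels and liver outcomes with known truth.

The generator emulates an NHANES-style biomonitoring panel: a non-negative
low-rank co-exposure structure organised in chemical-class blocks, sparse
individual exposure spikes, per-analyte left-censoring at fixed LODs, a
sprinkling of missing cells, and liver-marker outcomes driven by a known
smooth function ``h`` of a few active exposures plus linear covariate
effects and Gaussian noise.  Every downstream stage can therefore be tested
against stored ground truth (true L, true S, spike positions, true h).

The observed matrix is ``X = L + S + noise``; the panel the pipeline sees
is X with below-LOD cells censored (NaN sentinel + detection flag) and
missing cells blanked.  One global seed feeds a named sub-stream per stage
so exposures, censoring, missingness, covariates and outcomes can each be
regenerated independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .panel import ExposurePanel

# stage identifiers for seed sub-streams
_STAGES = {"loadings": 0, "spikes": 1, "noise": 2, "censor": 3, "missing": 4,
           "covariates": 5, "outcomes": 6, "fli": 7}

H_FORMS = ("linear", "quadratic", "sigmoidal", "product")

#: covariate generating distributions (single source of truth, see docs)
COVARIATE_SPEC = {
    "age": ("uniform", 20.0, 80.0),      # years
    "sex": ("bernoulli", 0.5),           # 1 = female
    "bmi": ("normal", 28.0, 5.0),        # kg/m², truncated below at 15
    "smoking": ("bernoulli", 0.2),       # 1 = current smoker
}

#: FLI input distributions: log-normal TG and GGT, waist coupled to BMI,
#: spanning both clinical FLI thresholds (<30 and ≥60) at these settings
FLI_INPUT_SPEC = {
    "triglycerides": ("lognormal", np.log(120.0), 0.45),  # mg/dL
    "ggt": ("lognormal", np.log(30.0), 0.55),             # U/L
}


@dataclass
class MixtureSimConfig:
    """Configuration of the synthetic mixture study.

    ``lod_quantiles`` may be a scalar (shared across analytes) or a
    length-``n_analytes`` sequence of per-analyte censoring proportions;
    LODs are set as those empirical quantiles of each generated column,
    so censoring fractions are controlled by construction.
    """

    n_participants: int = 500
    n_analytes: int = 20
    n_classes: int = 4
    true_rank: int = 3
    spike_fraction: float = 0.02
    spike_scale: float = 3.0
    lod_quantiles: float | Sequence[float] = 0.1
    missing_fraction: float = 0.0
    active_exposures: tuple[int, ...] = (0, 1)
    h_form: str = "linear"
    h_amplitude: float = 4.0
    covariate_effects: tuple[float, ...] = (0.02, 0.5, 0.05, 0.8)
    noise_sd: float = 1.0
    signed_spikes: bool = False
    class_strength: float = 2.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_participants <= 0 or self.n_analytes <= 0:
            raise ValueError("dimensions must be positive")
        if not (0 < self.true_rank < min(self.n_participants, self.n_analytes)):
            raise ValueError(
                f"true_rank={self.true_rank} must be in (0, min(n, p)={min(self.n_participants, self.n_analytes)})")
        if not (0 <= self.spike_fraction <= 1 and 0 <= self.missing_fraction <= 1):
            raise ValueError("spike_fraction and missing_fraction must be proportions")
        if self.spike_fraction + self.missing_fraction >= 1:
            raise ValueError("spike_fraction + missing_fraction must be < 1")
        q = np.broadcast_to(np.asarray(self.lod_quantiles, dtype=float), (self.n_analytes,))
        if np.any(q < 0) or np.any(q >= 1):
            raise ValueError("lod_quantiles must lie in [0, 1)")
        if self.h_form not in H_FORMS:
            raise ValueError(f"h_form must be one of {H_FORMS}")
        for m in self.active_exposures:
            if not (0 <= m < self.n_analytes):
                raise ValueError(f"active exposure index {m} out of range")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if len(self.covariate_effects) != len(COVARIATE_SPEC):
            raise ValueError(f"covariate_effects must have length {len(COVARIATE_SPEC)}")

    def rng(self, stage: str) -> np.random.Generator:
        """Named per-stage random sub-stream derived from the global seed."""
        return np.random.default_rng(np.random.SeedSequence(self.seed, spawn_key=(_STAGES[stage],)))


@dataclass
class SimulatedStudy:
    """A generated study: the observable panel plus its ground truth."""

    panel: ExposurePanel
    true_L: np.ndarray
    true_S: np.ndarray
    true_X: np.ndarray          # L + S + noise, pre-censoring, pre-missing
    censor_mask: np.ndarray     # True where measured value fell below LOD
    missing_mask: np.ndarray
    config: MixtureSimConfig
    covariates: pd.DataFrame | None = None
    outcomes: pd.DataFrame | None = None
    true_h_values: np.ndarray | None = None


OUTCOME_NAMES = ("ast", "alt", "ggt", "alp", "total_bilirubin")


def _class_labels(p: int, n_classes: int) -> np.ndarray:
    """Contiguous class blocks, as even as p allows."""
    sizes = np.full(n_classes, p // n_classes)
    sizes[: p % n_classes] += 1
    classes = ("metal", "PFAS", "phthalate", "PAH")
    labels = []
    for c, s in enumerate(sizes):
        labels.extend([classes[c % len(classes)] + ("" if c < len(classes) else f"_{c}")] * s)
    return np.asarray(labels)


def generate_exposure_matrix(config: MixtureSimConfig) -> SimulatedStudy:
    """Generate the censored exposure panel with stored ground truth.

    L = U·Vᵀ with folded-normal factors; analytes within a chemical class
    share a dominant factor (a class boost added to one column of V), which
    produces the block co-exposure structure.  Spikes are additive and
    positive by default, each of magnitude ``spike_scale`` × the column SD
    of L.  LODs are empirical ``lod_quantiles`` of each observed column.
    """
    config.validate()
    n, p, r = config.n_participants, config.n_analytes, config.true_rank

    rng = config.rng("loadings")
    U = np.abs(rng.normal(size=(n, r)))
    V = np.abs(rng.normal(size=(p, r)))
    labels = _class_labels(p, config.n_classes)
    class_ids = pd.factorize(labels)[0]
    for j in range(p):
        V[j, class_ids[j] % r] += config.class_strength
    L = U @ V.T

    S = np.zeros((n, p))
    n_spike = int(round(config.spike_fraction * n * p))
    if n_spike:
        rs = config.rng("spikes")
        flat = rs.choice(n * p, size=n_spike, replace=False)
        rows, cols = np.unravel_index(flat, (n, p))
        col_sd = L.std(axis=0, ddof=1)
        col_sd = np.where(col_sd > 0, col_sd, 1.0)
        mag = config.spike_scale * col_sd[cols]
        if config.signed_spikes:
            mag = mag * rs.choice([-1.0, 1.0], size=n_spike)
        S[rows, cols] = mag

    noise = np.zeros((n, p))
    if config.noise_sd > 0:
        noise = config.rng("noise").normal(scale=config.noise_sd, size=(n, p))

    X = L + S + noise

    q = np.broadcast_to(np.asarray(config.lod_quantiles, dtype=float), (p,)).copy()
    lod = np.array([np.quantile(X[:, j], q[j]) for j in range(p)])
    # LODs must be strictly positive even when the target quantile is 0
    lod = np.maximum(lod, 1e-9)
    censor_mask = X < lod[None, :]

    missing_mask = np.zeros((n, p), dtype=bool)
    if config.missing_fraction > 0:
        rm = config.rng("missing")
        n_miss = int(round(config.missing_fraction * n * p))
        flat = rm.choice(n * p, size=n_miss, replace=False)
        missing_mask[np.unravel_index(flat, (n, p))] = True

    observed = X.copy()
    observed[censor_mask] = np.nan   # sentinel: value known only to be < LOD
    observed[missing_mask] = np.nan
    detect_flag = ~censor_mask & ~missing_mask

    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
    analyte_names = [f"{labels[j]}_{j:02d}" for j in range(p)]
    units = np.where(np.char.startswith(labels.astype(str), "metal"), "ug/L", "ng/mL")

    panel = ExposurePanel(
        values=pd.DataFrame(observed, index=ids, columns=analyte_names),
        lod=pd.Series(lod, index=analyte_names),
        detect_flag=pd.DataFrame(detect_flag, index=ids, columns=analyte_names),
        missing_mask=pd.DataFrame(missing_mask, index=ids, columns=analyte_names),
        analyte_class=pd.Series(labels, index=analyte_names),
        units=pd.Series(units, index=analyte_names),
    )
    return SimulatedStudy(panel=panel, true_L=L, true_S=S, true_X=X,
                          censor_mask=censor_mask, missing_mask=missing_mask,
                          config=config)


def true_h(X: np.ndarray, config: MixtureSimConfig) -> np.ndarray:
    """Evaluate the generative exposure–response function h.

    h acts on the standardized (z-scored) columns of the true, uncensored
    exposure matrix, restricted to ``active_exposures``:

    - linear:     amplitude/k · Σ z_m
    - quadratic:  amplitude/k · Σ (z_m² − 1)
    - sigmoidal:  amplitude/k · Σ (2·expit(1.5 z_m) − 1)
    - product:    amplitude · z_a · z_b  (first two active exposures)
    """
    active = list(config.active_exposures)
    if not active:
        return np.zeros(X.shape[0])
    Z = (X[:, active] - X[:, active].mean(axis=0)) / X[:, active].std(axis=0, ddof=0)
    a = config.h_amplitude
    k = len(active)
    if config.h_form == "linear":
        return a / k * Z.sum(axis=1)
    if config.h_form == "quadratic":
        return a / k * (Z ** 2 - 1.0).sum(axis=1)
    if config.h_form == "sigmoidal":
        return a / k * (2.0 * expit(1.5 * Z) - 1.0).sum(axis=1)
    if config.h_form == "product":
        if len(active) < 2:
            raise ValueError("product h_form needs at least two active exposures")
        return a * Z[:, 0] * Z[:, 1]
    raise ValueError(config.h_form)


def generate_covariates(config: MixtureSimConfig) -> pd.DataFrame:
    rng = config.rng("covariates")
    n = config.n_participants
    cov = {}
    for name, spec in COVARIATE_SPEC.items():
        if spec[0] == "uniform":
            cov[name] = rng.uniform(spec[1], spec[2], size=n)
        elif spec[0] == "bernoulli":
            cov[name] = rng.binomial(1, spec[1], size=n).astype(float)
        elif spec[0] == "normal":
            cov[name] = np.maximum(rng.normal(spec[1], spec[2], size=n), 15.0)
    ids = pd.Index([f"P{i:05d}" for i in range(n)], name="participant_id")
    return pd.DataFrame(cov, index=ids)


def generate_outcomes(study: SimulatedStudy, config: MixtureSimConfig | None = None) -> SimulatedStudy:
    """Attach liver-marker outcomes Y = h(X_active) + Z·β + ε to a study.

    Each enzymatic marker (AST, ALT, GGT, ALP, total bilirubin analogues)
    receives the same systematic part h + Zβ with an independent Gaussian
    noise draw, so any single column satisfies the generative model while
    the panel of six mimics correlated liver markers.  FLI inputs
    (triglycerides, GGT, BMI, waist) are drawn from log-normal/normal
    ranges wide enough that the resulting index spans both clinical
    thresholds (<30, ≥60).
    """
    config = config or study.config
    config.validate()
    n = config.n_participants

    h = true_h(study.true_X, config)
    cov = generate_covariates(config)
    beta = np.asarray(config.covariate_effects, dtype=float)
    lin = cov.values @ beta

    rng = config.rng("outcomes")
    outcomes = {}
    for name in OUTCOME_NAMES:
        eps = rng.normal(scale=config.noise_sd, size=n) if config.noise_sd > 0 else 0.0
        outcomes[name] = h + lin + eps
    out = pd.DataFrame(outcomes, index=cov.index)

    rf = config.rng("fli")
    tg_spec = FLI_INPUT_SPEC["triglycerides"]
    ggt_spec = FLI_INPUT_SPEC["ggt"]
    out["triglycerides"] = rf.lognormal(tg_spec[1], tg_spec[2], size=n)
    out["ggt_fli"] = rf.lognormal(ggt_spec[1], ggt_spec[2], size=n)
    out["bmi"] = cov["bmi"].values
    out["waist"] = np.maximum(58.0 + 1.43 * cov["bmi"].values
                              + rf.normal(scale=8.0, size=n), 55.0)

    study.covariates = cov
    study.outcomes = out
    study.true_h_values = h
    return study


def write_study(study: SimulatedStudy, outdir) -> dict[str, str]:
    """Write the panel, flags, metadata, outcomes and a ground-truth sidecar."""
    import json
    from pathlib import Path

    from .panel import write_panel

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "exposures": str(outdir / "exposures.csv"),
        "lod_table": str(outdir / "lod_table.csv"),
        "detect_flags": str(outdir / "detect_flags.csv"),
        "truth": str(outdir / "ground_truth.json"),
    }
    write_panel(study.panel, paths["exposures"], paths["lod_table"])
    flags = study.panel.detect_flag.astype(int).where(~study.panel.missing_mask)
    flags.to_csv(paths["detect_flags"], index_label="participant_id")
    if study.outcomes is not None:
        paths["outcomes"] = str(outdir / "outcomes.csv")
        paths["covariates"] = str(outdir / "covariates.csv")
        study.outcomes.to_csv(paths["outcomes"], index_label="participant_id")
        study.covariates.to_csv(paths["covariates"], index_label="participant_id")
    truth = {
        "true_L": study.true_L.tolist(),
        "true_S": study.true_S.tolist(),
        "seed": study.config.seed,
        "true_rank": study.config.true_rank,
        "active_exposures": list(study.config.active_exposures),
        "h_form": study.config.h_form,
    }
    if study.true_h_values is not None:
        truth["true_h_values"] = study.true_h_values.tolist()
    with open(paths["truth"], "w") as fh:
        json.dump(truth, fh)
    return paths
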