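"""Fatty Liver Index and assembly of the liver-outcome modelling table.

The Fatty Liver Index (FLI) is a validated logistic score for hepatic
steatosis built from triglycerides, BMI, GGT and waist circumference
(Bedogni et al. 2006):

    A   = 0.953·ln(TG) + 0.139·BMI + 0.718·ln(GGT) + 0.053·waist − 15.745
    FLI = 100 · exp(A) / (1 + exp(A))

with TG in mg/dL, BMI in kg/m², GGT in U/L, waist in cm.  FLI ≥ 60
indicates a high probability of fatty liver; FLI < 30 suggests its
absence; [30, 60) is indeterminate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.special import expit

logger = logging.getLogger(__name__)

FLI_HIGH_CUTOFF = 60.0   # inclusive
FLI_LOW_CUTOFF = 30.0    # exclusive (below)

_COEF = {"tg": 0.953, "bmi": 0.139, "ggt": 0.718, "waist": 0.053}
_INTERCEPT = -15.745


def compute_fli(tg, bmi, ggt, waist):
    """Fatty Liver Index in [0, 100]; scalar or elementwise on arrays."""
    args = {"tg": tg, "bmi": bmi, "ggt": ggt, "waist": waist}
    for name, v in args.items():
        arr = np.asarray(v, dtype=float)
        if np.any(~(arr > 0)):
            raise ValueError(f"{name} must be strictly positive")
    a = (_COEF["tg"] * np.log(np.asarray(tg, float))
         + _COEF["bmi"] * np.asarray(bmi, float)
         + _COEF["ggt"] * np.log(np.asarray(ggt, float))
         + _COEF["waist"] * np.asarray(waist, float)
         + _INTERCEPT)
    fli = 100.0 * expit(a)
    return float(fli) if np.ndim(fli) == 0 else fli


def classify_fli(fli):
    """Band the score: ≥60 high, <30 low, otherwise indeterminate."""
    arr = np.asarray(fli, dtype=float)
    if np.any((arr < 0) | (arr > 100)):
        raise ValueError("FLI must lie in [0, 100]")
    bands = np.where(arr >= FLI_HIGH_CUTOFF, "high",
                     np.where(arr < FLI_LOW_CUTOFF, "low", "indeterminate"))
    return str(bands) if np.ndim(fli) == 0 else bands


def add_fli(outcomes: pd.DataFrame, tg_col: str = "triglycerides", bmi_col: str = "bmi",
            ggt_col: str = "ggt_fli", waist_col: str = "waist") -> pd.DataFrame:
    """Append ``fli`` and ``fli_band`` columns computed from the FLI inputs."""
    out = outcomes.copy()
    out["fli"] = compute_fli(out[tg_col], out[bmi_col], out[ggt_col], out[waist_col])
    out["fli_band"] = classify_fli(out["fli"].values)
    return out


def assemble_outcomes(liver: pd.DataFrame, exposures: pd.DataFrame,
                      covariates: pd.DataFrame) -> pd.DataFrame:
    """Inner-join outcomes, exposures and covariates on participant_id.

    Returns one row per participant present in all three tables, with
    exposure columns prefixed ``exp_`` and covariates ``cov_``.  Drop
    counts per source are logged; duplicate ids or an empty intersection
    are errors.
    """
    for name, df in (("liver", liver), ("exposures", exposures), ("covariates", covariates)):
        if df.index.has_duplicates:
            raise ValueError(f"duplicate participant_id in {name} table")
    shared = liver.index.intersection(exposures.index).intersection(covariates.index)
    if len(shared) == 0:
        raise ValueError("no participants shared across liver, exposure and covariate tables")
    for name, df in (("liver", liver), ("exposures", exposures), ("covariates", covariates)):
        dropped = len(df.index) - len(shared)
        if dropped:
            logger.info("assemble_outcomes: dropped %d participant(s) from %s", dropped, name)
    merged = pd.concat(
        [liver.loc[shared],
         exposures.loc[shared].add_prefix("exp_"),
         covariates.loc[shared].add_prefix("cov_")],
        axis=1,
    )
    return merged
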