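"""Exposure panels: censored concentration matrices with LOD metadata.

An :class:`ExposurePanel` holds a participants × analytes concentration
matrix together with per-analyte limits of detection (LOD), a detection
flag matrix (``True`` = measured at or above the LOD), a missingness mask,
chemical-class labels and units.  Cells below the LOD are *left-censored*:
we know only that the true concentration lies in ``[0, LOD)``.  Until
:func:`substitute_lod` is called explicitly, censored cells carry ``NaN``
as a sentinel — a censored value never silently becomes a number.

Missing and censored are distinct states throughout: a missing cell was
never measured; a censored cell was measured but fell below the assay's
quantification limit.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_CLASSES = ("metal", "PFAS", "phthalate", "PAH")


class PanelError(ValueError):
    """Raised when an exposure panel violates its contract."""


@dataclass
class ExposurePanel:
    """Participants × analytes concentration panel with censoring metadata.

    Attributes
    ----------
    values : pandas.DataFrame
        Concentrations, indexed by participant_id, one column per analyte.
        Censored (non-detect) cells hold ``NaN`` until LOD substitution;
        missing cells always hold ``NaN``.
    lod : pandas.Series
        Per-analyte limit of detection, strictly positive, same units as
        the analyte's column.
    detect_flag : pandas.DataFrame
        Boolean; ``True`` where the cell was measured at/above the LOD.
        ``False`` for censored cells and for missing cells.
    missing_mask : pandas.DataFrame
        Boolean; ``True`` where the cell was never measured.
    analyte_class : pandas.Series
        Chemical class per analyte (metal, PFAS, phthalate, PAH).
    units : pandas.Series
        Unit string per analyte (µg/L, ng/mL, ng/L ...).
    """

    values: pd.DataFrame
    lod: pd.Series
    detect_flag: pd.DataFrame
    missing_mask: pd.DataFrame
    analyte_class: pd.Series
    units: pd.Series
    lod_substituted: bool = field(default=False)

    def __post_init__(self) -> None:
        cols = list(self.values.columns)
        for name, obj in (("lod", self.lod), ("analyte_class", self.analyte_class),
                          ("units", self.units)):
            if list(obj.index) != cols:
                raise PanelError(f"{name} index does not match analyte columns")
        for name, df in (("detect_flag", self.detect_flag),
                         ("missing_mask", self.missing_mask)):
            if df.shape != self.values.shape:
                raise PanelError(f"{name} shape {df.shape} != values shape {self.values.shape}")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise PanelError(f"duplicate participant_id values: {dupes}")
        bad_lod = self.lod[~(self.lod > 0)]
        if len(bad_lod):
            raise PanelError(f"non-positive LOD for analytes: {list(bad_lod.index)}")
        neg = self.values.values < 0
        if np.any(neg & ~np.isnan(self.values.values)):
            i, j = np.argwhere(neg & ~np.isnan(self.values.values))[0]
            raise PanelError(
                f"negative concentration at participant {self.values.index[i]!r}, "
                f"analyte {cols[j]!r} — concentrations must be non-negative"
            )

    @property
    def analytes(self) -> list[str]:
        return list(self.values.columns)

    @property
    def participant_id(self) -> pd.Index:
        return self.values.index

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def censor_mask(self) -> pd.DataFrame:
        """Cells that were measured but fell below the LOD."""
        return ~self.detect_flag & ~self.missing_mask

    def copy(self) -> "ExposurePanel":
        return ExposurePanel(
            values=self.values.copy(), lod=self.lod.copy(),
            detect_flag=self.detect_flag.copy(), missing_mask=self.missing_mask.copy(),
            analyte_class=self.analyte_class.copy(), units=self.units.copy(),
            lod_substituted=self.lod_substituted,
        )

    def select_analytes(self, keep: list[str]) -> "ExposurePanel":
        return ExposurePanel(
            values=self.values[keep], lod=self.lod[keep],
            detect_flag=self.detect_flag[keep], missing_mask=self.missing_mask[keep],
            analyte_class=self.analyte_class[keep], units=self.units[keep],
            lod_substituted=self.lod_substituted,
        )


@dataclass
class DetectionSummary:
    """Detection frequency of one analyte and whether it clears the filter."""

    analyte: str
    n_measured: int
    frequency: float
    retained: bool


def read_panel(path, lod_table, detect_table=None,
               unit_map: dict[str, float] | None = None) -> ExposurePanel:
    """Read an exposure panel from delimited text.

    ``path`` is a CSV with a ``participant_id`` column plus one column per
    analyte; ``lod_table`` is a CSV with columns ``analyte, lod, units,
    class``.  Without a detection-flag file, a cell is a detect when its
    value is present and ≥ its analyte LOD, and empty cells are missing.
    With ``detect_table`` (same layout as the exposure file), each cell is
    coded 1 = detected, 0 = censored (below LOD), empty = never measured —
    this is how censored sentinels survive a round trip through text.

    Rows whose exposures are all missing are dropped (the count is logged).
    A present analyte without an LOD row, or a non-numeric cell, is a hard
    error.
    """
    raw = pd.read_csv(path)
    if "participant_id" not in raw.columns:
        raise PanelError("exposure file lacks a participant_id column")
    raw = raw.set_index("participant_id")
    meta = pd.read_csv(lod_table).set_index("analyte")

    missing_lod = [c for c in raw.columns if c not in meta.index]
    if missing_lod:
        raise PanelError(f"no LOD row for analyte(s): {missing_lod}")

    for col in raw.columns:
        coerced = pd.to_numeric(raw[col], errors="coerce")
        bad = coerced.isna() & raw[col].notna()
        if bad.any():
            row = raw.index[bad][0]
            raise PanelError(f"non-numeric cell at participant {row!r}, analyte {col!r}")
        raw[col] = coerced

    neg = raw.lt(0)
    if neg.any().any():
        col = neg.any().idxmax()
        row = raw.index[neg[col]][0]
        raise PanelError(f"negative concentration at participant {row!r}, "
                         f"analyte {col!r} — concentrations must be non-negative")

    if unit_map:
        for col, factor in unit_map.items():
            if col in raw.columns:
                raw[col] = raw[col] * factor
                meta.loc[col, "lod"] = meta.loc[col, "lod"] * factor

    lod = meta.loc[raw.columns, "lod"].astype(float)

    if detect_table is not None:
        flags = pd.read_csv(detect_table).set_index("participant_id")
        flags = flags.loc[raw.index, raw.columns]
        missing_mask = flags.isna()
        detect_flag = flags.fillna(0).astype(float).astype(bool)
    else:
        missing_mask = raw.isna()
        detect_flag = raw.ge(lod, axis=1).fillna(False)

    all_missing = missing_mask.all(axis=1)
    if all_missing.any():
        logger.info("dropping %d participant(s) with all-missing exposures", int(all_missing.sum()))
        keep = ~all_missing
        raw, missing_mask, detect_flag = raw.loc[keep], missing_mask.loc[keep], detect_flag.loc[keep]

    # measured-but-below-LOD cells become censored sentinels
    values = raw.where(detect_flag | missing_mask)

    return ExposurePanel(
        values=values, lod=lod,
        detect_flag=detect_flag.astype(bool), missing_mask=missing_mask.astype(bool),
        analyte_class=meta.loc[raw.columns, "class"].astype(str),
        units=meta.loc[raw.columns, "units"].astype(str),
    )


def read_xpt_panel(path, lod_table, analytes: list[str] | None = None,
                   id_column: str = "SEQN") -> ExposurePanel:
    """Read a SAS transport (XPT) laboratory file into an ExposurePanel.

    NHANES distributes laboratory tables as XPT with a SEQN participant key;
    below-LOD values arrive already substituted (LOD/√2), flagged by a
    companion comment column when available. Here detection is inferred
    against the LOD table, matching :func:`read_panel` semantics.
    """
    df = pd.read_sas(path, format="xport")
    if id_column not in df.columns:
        raise PanelError(f"XPT file lacks id column {id_column!r}")
    df = df.set_index(id_column)
    df.index.name = "participant_id"
    if analytes is not None:
        df = df[analytes]
    meta = pd.read_csv(lod_table).set_index("analyte")
    missing_lod = [c for c in df.columns if c not in meta.index]
    if missing_lod:
        raise PanelError(f"no LOD row for analyte(s): {missing_lod}")
    lod = meta.loc[df.columns, "lod"].astype(float)
    missing_mask = df.isna()
    detect_flag = df.ge(lod, axis=1).fillna(False)
    values = df.where(detect_flag | missing_mask)
    return ExposurePanel(
        values=values, lod=lod,
        detect_flag=detect_flag.astype(bool), missing_mask=missing_mask.astype(bool),
        analyte_class=meta.loc[df.columns, "class"].astype(str),
        units=meta.loc[df.columns, "units"].astype(str),
    )


def substitute_lod(panel: ExposurePanel) -> ExposurePanel:
    """Replace censored cells with LOD/√2 (standard NHANES convention).

    Detected cells and missing cells are untouched; the operation is a
    no-op on an already-substituted panel.
    """
    out = panel.copy()
    sub = panel.lod / math.sqrt(2.0)
    censored = panel.censor_mask()
    vals = out.values
    for j, col in enumerate(vals.columns):
        mask = censored[col].values
        if mask.any():
            vals.loc[mask, col] = sub[col]
    out.lod_substituted = True
    return out


def detection_frequency(panel: ExposurePanel, threshold: float = 0.5) -> list[DetectionSummary]:
    """Per-analyte detection frequency = detects / non-missing count.

    ``retained`` is True when frequency ≥ threshold (inclusive boundary:
    exactly 50 detects of 100 clears a 0.5 threshold).
    """
    out = []
    for col in panel.analytes:
        measured = (~panel.missing_mask[col]).sum()
        if measured == 0:
            raise PanelError(f"analyte {col!r} has no non-missing cells")
        detects = int(panel.detect_flag[col].sum())
        freq = detects / measured
        out.append(DetectionSummary(analyte=col, n_measured=int(measured),
                                    frequency=float(freq), retained=bool(freq >= threshold)))
    return out


def filter_by_detection(panel: ExposurePanel, threshold: float = 0.5) -> ExposurePanel:
    """Drop analytes detected in fewer than ``threshold`` of measured samples."""
    summaries = detection_frequency(panel, threshold)
    keep = [s.analyte for s in summaries if s.retained]
    dropped = [s.analyte for s in summaries if not s.retained]
    if not keep:
        raise PanelError("detection filter would exclude every analyte")
    if dropped:
        logger.info("detection filter (threshold %.2f) dropped %d analyte(s): %s",
                    threshold, len(dropped), dropped)
    return panel.select_analytes(keep)


def scale_columns(panel: ExposurePanel) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Divide each analyte column by its standard deviation.

    No centering is applied: mean-centering would make entries negative,
    which is incompatible with the non-negativity constraint on the
    low-rank component downstream.  The SD is computed over non-missing,
    non-censored-sentinel cells (i.e. over the numeric values currently
    stored).  LODs are rescaled by the same factors.

    Returns ``(scaled_values, scale_factors, scaled_lod)``.
    """
    factors = {}
    for col in panel.analytes:
        sd = panel.values[col].std(ddof=1)
        if not np.isfinite(sd) or sd <= 0:
            raise PanelError(f"analyte {col!r} has zero or undefined variance; cannot scale")
        factors[col] = sd
    factors = pd.Series(factors)
    scaled = panel.values / factors
    scaled_lod = panel.lod / factors
    return scaled, factors, scaled_lod


def descriptive_table(panel: ExposurePanel) -> pd.DataFrame:
    """Per-analyte n, arithmetic mean and SD after LOD/√2 substitution.

    Mirrors the descriptive summary typically reported for NHANES
    biomarker panels (sample size, mean, SD per analyte by class).
    """
    work = panel if panel.lod_substituted else substitute_lod(panel)
    rows = []
    for col in work.analytes:
        v = work.values[col].dropna()
        rows.append({
            "analyte": col, "class": work.analyte_class[col], "units": work.units[col],
            "n": int(len(v)), "mean": float(v.mean()), "sd": float(v.std(ddof=1)),
        })
    return pd.DataFrame(rows).set_index("analyte")


def write_panel(panel: ExposurePanel, values_path, lod_path) -> None:
    """Write the panel back to the delimited exposure + LOD metadata files."""
    panel.values.to_csv(values_path, index_label="participant_id")
    meta = pd.DataFrame({
        "analyte": panel.analytes,
        "lod": panel.lod.values,
        "units": panel.units.values,
        "class": panel.analyte_class.values,
    })
    meta.to_csv(lod_path, index=False)
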