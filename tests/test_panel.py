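"""Exposure panel I/O, LOD substitution, detection filtering, scaling."""

import math

import numpy as np
import pandas as pd
import pytest

from expomix import (PanelError, detection_frequency, filter_by_detection,
                     read_panel, scale_columns, substitute_lod)
from expomix.panel import ExposurePanel, descriptive_table


def _make_panel(values, lod, detect=None, missing=None, classes=None):
    values = pd.DataFrame(values)
    values.columns = [f"a{j}" for j in range(values.shape[1])]
    values.index = pd.Index([f"P{i}" for i in range(len(values))], name="participant_id")
    cols = values.columns
    lod = pd.Series(lod, index=cols, dtype=float)
    detect = (pd.DataFrame(True, index=values.index, columns=cols) if detect is None
              else pd.DataFrame(detect, index=values.index, columns=cols))
    missing = (pd.DataFrame(False, index=values.index, columns=cols) if missing is None
               else pd.DataFrame(missing, index=values.index, columns=cols))
    classes = pd.Series(classes or ["metal"] * len(cols), index=cols)
    return ExposurePanel(values=values, lod=lod, detect_flag=detect,
                         missing_mask=missing, analyte_class=classes,
                         units=pd.Series("ug/L", index=cols))


def test_read_panel_round_trip(tmp_path):
    exp = tmp_path / "exp.csv"
    lod = tmp_path / "lod.csv"
    exp.write_text("participant_id,pb,cd\nA,1.5,0.4\nB,2.0,0.6\nC,0.1,0.9\n")
    lod.write_text("analyte,lod,units,class\npb,0.2,ug/L,metal\ncd,0.1,ug/L,metal\n")
    pan = read_panel(exp, lod)
    assert pan.shape == (3, 2)
    assert list(pan.analytes) == ["pb", "cd"]
    # 0.1 < LOD 0.2 → censored sentinel
    assert not pan.detect_flag.loc["C", "pb"]
    assert np.isnan(pan.values.loc["C", "pb"])


def test_read_panel_errors(tmp_path):
    lod = tmp_path / "lod.csv"
    lod.write_text("analyte,lod,units,class\npb,0.2,ug/L,metal\n")
    missing_lod = tmp_path / "m.csv"
    missing_lod.write_text("participant_id,pb,cd\nA,1.5,0.4\n")
    with pytest.raises(PanelError, match="cd"):
        read_panel(missing_lod, lod)
    bad_cell = tmp_path / "b.csv"
    bad_cell.write_text("participant_id,pb\nA,oops\n")
    with pytest.raises(PanelError, match="non-numeric"):
        read_panel(bad_cell, lod)
    negative = tmp_path / "n.csv"
    negative.write_text("participant_id,pb\nA,-3.0\n")
    with pytest.raises(PanelError, match="negative"):
        read_panel(negative, lod)


@pytest.mark.parametrize("lod_value, expected", [(2.0, 2.0 / math.sqrt(2)),
                                                 (1.0, 1.0 / math.sqrt(2))])
def test_substitute_lod_fills_censored_cells(lod_value, expected):
    detect = [[True, True], [False, True]]
    pan = _make_panel([[1.0, 2.0], [np.nan, 3.0]], [lod_value, 0.5], detect=detect)
    out = substitute_lod(pan)
    assert out.values.iloc[1, 0] == pytest.approx(expected, abs=1e-12)
    # detected cells untouched
    assert out.values.iloc[0, 0] == 1.0 and out.values.iloc[1, 1] == 3.0


def test_substitute_lod_identity_when_all_detected():
    pan = _make_panel([[1.0, 2.0], [3.0, 4.0]], [0.1, 0.1])
    out = substitute_lod(pan)
    pd.testing.assert_frame_equal(out.values, pan.values)


def test_detection_frequency_and_inclusive_boundary():
    detect = np.ones((100, 2), dtype=bool)
    detect[:51, 0] = False   # 49 detects of 100
    detect[:50, 1] = False   # 50 detects of 100
    vals = np.abs(np.random.default_rng(0).normal(size=(100, 2))) + 1
    vals[~detect] = np.nan
    pan = _make_panel(vals, [0.5, 0.5], detect=detect)
    summaries = {s.analyte: s for s in detection_frequency(pan, threshold=0.5)}
    assert summaries["a0"].frequency == pytest.approx(0.49)
    assert not summaries["a0"].retained
    assert summaries["a1"].frequency == pytest.approx(0.50)
    assert summaries["a1"].retained  # >= is inclusive


def test_detection_frequency_simple_counts():
    detect = [[True], [True], [True], [False]]
    missing = [[False], [False], [False], [False]]
    pan = _make_panel([[1.0], [2.0], [3.0], [np.nan]], [0.5],
                      detect=detect, missing=missing)
    (s,) = detection_frequency(pan)
    assert s.frequency == pytest.approx(0.75)
    assert s.n_measured == 4


def test_filter_by_detection_drops_low_detect_analyte():
    from expomix import MixtureSimConfig, generate_exposure_matrix
    cfg = MixtureSimConfig(n_participants=300, n_analytes=6, true_rank=2,
                           lod_quantiles=[0.0, 0.0, 0.7, 0.0, 0.0, 0.0], seed=1)
    st = generate_exposure_matrix(cfg)
    filtered = filter_by_detection(st.panel, threshold=0.5)
    assert st.panel.analytes[2] not in filtered.analytes
    assert filtered.shape[1] == 5
    # idempotence
    again = filter_by_detection(filtered, threshold=0.5)
    assert again.analytes == filtered.analytes


def test_filter_threshold_zero_is_identity():
    pan = _make_panel([[1.0, 2.0], [3.0, 4.0]], [0.1, 0.1])
    assert filter_by_detection(pan, threshold=0.0).analytes == pan.analytes


def test_filter_all_excluded_is_error():
    detect = [[False, False], [False, False]]
    pan = _make_panel([[np.nan, np.nan], [np.nan, np.nan]], [1.0, 1.0], detect=detect)
    with pytest.raises(PanelError):
        filter_by_detection(pan, threshold=0.5)


def test_scale_columns_unit_sd_and_round_trip():
    rng = np.random.default_rng(4)
    vals = np.abs(rng.normal(size=(50, 3))) * np.array([2.0, 5.0, 0.5])
    pan = _make_panel(vals, [0.1, 0.1, 0.1])
    scaled, factors, lod_scaled = scale_columns(pan)
    np.testing.assert_allclose(scaled.std(ddof=1), 1.0, atol=1e-12)
    np.testing.assert_allclose((scaled * factors).values, vals, atol=1e-10)
    np.testing.assert_allclose(lod_scaled.values, 0.1 / factors.values)


def test_scale_columns_lod_factor_example():
    vals = np.array([[0.0, 1.0], [4.0, 2.0], [8.0, 3.0]], dtype=float)
    pan = _make_panel(vals, [2.0, 0.5])
    _, factors, lod_scaled = scale_columns(pan)
    assert factors.iloc[0] == pytest.approx(4.0)
    assert lod_scaled.iloc[0] == pytest.approx(0.5)


def test_scale_columns_zero_variance_error():
    pan = _make_panel([[1.0, 2.0], [1.0, 3.0]], [0.1, 0.1])
    with pytest.raises(PanelError, match="a0"):
        scale_columns(pan)


def test_detection_frequency_invariant_under_scaling():
    from expomix import MixtureSimConfig, generate_exposure_matrix
    cfg = MixtureSimConfig(n_participants=200, n_analytes=8, true_rank=2,
                           lod_quantiles=0.25, seed=6)
    st = generate_exposure_matrix(cfg)
    before = [s.frequency for s in detection_frequency(st.panel)]
    sub = substitute_lod(st.panel)
    scaled, factors, lod_scaled = scale_columns(sub)
    rescaled_panel = sub.copy()
    rescaled_panel.values = scaled
    rescaled_panel.lod = lod_scaled
    after = [s.frequency for s in detection_frequency(rescaled_panel)]
    assert before == after


def test_descriptive_table_uses_lod_sqrt2_substitution():
    detect = [[True], [False], [True], [False]]
    pan = _make_panel([[3.0], [np.nan], [5.0], [np.nan]], [2.0], detect=detect)
    table = descriptive_table(pan)
    sub = 2.0 / math.sqrt(2)
    expected_mean = (3.0 + 5.0 + 2 * sub) / 4
    assert table.loc["a0", "mean"] == pytest.approx(expected_mean)
    assert table.loc["a0", "n"] == 4


def test_duplicate_participant_id_rejected():
    values = pd.DataFrame({"a0": [1.0, 2.0]},
                          index=pd.Index(["P1", "P1"], name="participant_id"))
    with pytest.raises(PanelError, match="duplicate"):
        ExposurePanel(values=values,
                      lod=pd.Series([0.1], index=["a0"]),
                      detect_flag=pd.DataFrame(True, index=values.index, columns=["a0"]),
                      missing_mask=pd.DataFrame(False, index=values.index, columns=["a0"]),
                      analyte_class=pd.Series(["metal"], index=["a0"]),
                      units=pd.Series(["ug/L"], index=["a0"]))
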