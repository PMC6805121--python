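"""Temporal windows, fixation-rank FPSA, searchlight maps, ROI contrasts."""

import numpy as np
import pytest

from fpsa.config import PipelineConfig
from fpsa.density import build_fdm, select_events
from fpsa.models import build_predictors, fit_subject
from fpsa.similarity import dissimilarity_matrix, vectorize_lower_triangle
from fpsa.density import remove_common_mean
from fpsa.spatiotemporal import (
    _windows,
    density_mask,
    roi_anisotropy_contrast,
    searchlight_fpsa,
    temporal_fpsa,
)


def test_window_count_and_layout(small_config):
    windows = _windows(small_config)
    assert len(windows) == 21  # (1500 - 500) / 50 + 1
    assert windows[0] == (0.0, 500.0)
    assert windows[-1] == (1000.0, 1500.0)
    for a, b in windows:
        assert 0.0 <= a and b <= small_config.stim_duration_ms


def test_density_mask_smallest_region():
    rng = np.random.default_rng(0)
    d = rng.random((30, 30))
    d /= d.sum()
    mask = density_mask(d, 0.90)
    assert d[mask].sum() >= 0.90
    # smallest such region: dropping the dimmest masked pixel goes below
    dimmest = np.min(d[mask])
    assert d[mask].sum() - dimmest < 0.90


def _cond_maps_and_angles(cohort, config, phases=("baseline", "generalization")):
    cond_maps, angles = {}, {}
    for m in cohort.models_base:
        angles[m.subject_id] = m.cs_plus_angle
        for phase in phases:
            ev = select_events(cohort.events, subject_id=m.subject_id, phase=phase)
            cond_maps[(m.subject_id, phase)] = [
                build_fdm(ev, config, condition=f"face_{a}")
                for a in range(0, 360, 45)
            ]
    return cond_maps, angles


def test_searchlight_full_window_equals_global_fit(small_cohort, small_config):
    """A searchlight spanning the whole grid reproduces the global
    adversity-model fit."""
    cfg = PipelineConfig(
        crop_size=100, px_per_deg=6.0, screen_size=(320, 240),
        searchlight_px=100, searchlight_stride_px=1,
        density_mask_quantile=0.999999,
    )
    model = small_cohort.models_base[0]
    sid = model.subject_id
    ev = select_events(small_cohort.events, subject_id=sid, phase="baseline")
    maps = [build_fdm(ev, cfg, condition=f"face_{a}") for a in range(0, 360, 45)]
    sl = searchlight_fpsa(
        {(sid, "baseline"): maps}, {sid: model.cs_plus_angle}, cfg
    )
    center = sl["baseline"].w_specific
    vals = center[np.isfinite(center)]
    assert vals.size == 1  # single admissible center
    corrected = remove_common_mean(maps)
    dm = dissimilarity_matrix(corrected, model.cs_plus_angle)
    fit = fit_subject(
        vectorize_lower_triangle(dm.values), "adversity", build_predictors()
    )
    assert vals[0] == pytest.approx(fit.weights["specific"], abs=1e-10)
    wu = sl["baseline"].w_unspecific
    assert wu[np.isfinite(wu)][0] == pytest.approx(
        fit.weights["unspecific"], abs=1e-10
    )


def test_searchlight_localizes_eye_effect(small_cohort, small_config):
    """The injected effect lives on an eye-region dipole, so the
    anisotropy phase contrast peaks inside the eyes ROI."""
    cond_maps, angles = _cond_maps_and_angles(small_cohort, small_config)
    sl = searchlight_fpsa(cond_maps, angles, small_config)
    contrast = sl["contrast"]["delta_anisotropy"]
    r, c = np.unravel_index(np.nanargmax(contrast), contrast.shape)
    eyes = small_config.roi_map["eyes"]
    assert eyes.y0 <= r < eyes.y1 and eyes.x0 <= c < eyes.x1


def test_roi_contrast_table(small_cohort, small_config):
    cond_maps, angles = _cond_maps_and_angles(small_cohort, small_config)
    sl = searchlight_fpsa(cond_maps, angles, small_config)
    table = roi_anisotropy_contrast(sl, small_config.roi_map, small_config)
    assert set(table["roi"]) == {"eyes", "nose", "mouth"}
    eyes = table[table["roi"] == "eyes"].iloc[0]
    assert eyes["delta_anisotropy"] > 0
    # identical phases give a null contrast
    sl_same = {
        "baseline": sl["baseline"], "generalization": sl["baseline"],
    }
    t0 = roi_anisotropy_contrast(sl_same, small_config.roi_map, small_config)
    assert np.allclose(t0["delta_anisotropy"], 0.0)
    assert np.allclose(t0["p_uncorrected"], 1.0)


def test_roi_contrast_rejects_missing_phase(small_cohort, small_config):
    with pytest.raises(ValueError, match="generalization"):
        roi_anisotropy_contrast({"baseline": None}, small_config.roi_map)


def test_temporal_fpsa_runs_and_contrasts(small_cohort, small_config):
    angles = {m.subject_id: m.cs_plus_angle for m in small_cohort.models_base}
    tc = temporal_fpsa(small_cohort.events, angles, small_config)
    assert len(tc.centers) == 21
    assert {"baseline", "generalization"} == set(tc.table["phase"])
    # injected anisotropy present throughout the trial: the mean contrast
    # across windows is positive
    assert tc.contrast["delta_anisotropy"].mean() > 0


def test_rank_fpsa(small_cohort, small_config):
    angles = {m.subject_id: m.cs_plus_angle for m in small_cohort.models_base}
    tc = temporal_fpsa(
        small_cohort.events, angles, small_config, mode="rank", max_rank=3
    )
    assert list(tc.centers) == [1.0, 2.0, 3.0]
    assert tc.per_subject["valid"].all()
    with pytest.raises(ValueError, match="mode"):
        temporal_fpsa(small_cohort.events, angles, small_config, mode="bogus")


def test_full_trial_window_matches_global_fit(small_cohort):
    """Widening the window to the whole trial reproduces the standard
    whole-trial FPSA weights."""
    cfg = PipelineConfig(
        crop_size=100, px_per_deg=6.0, screen_size=(320, 240),
        temporal_window_ms=(1500.0, 1500.0),
    )
    model = small_cohort.models_base[0]
    sid = model.subject_id
    angles = {sid: model.cs_plus_angle}
    events = select_events(small_cohort.events, subject_id=sid)
    tc = temporal_fpsa(events, angles, cfg, phases=("baseline",))
    assert len(tc.centers) == 1
    ev = select_events(events, phase="baseline")
    maps = [build_fdm(ev, cfg, condition=f"face_{a}") for a in range(0, 360, 45)]
    dm = dissimilarity_matrix(remove_common_mean(maps), model.cs_plus_angle)
    fit = fit_subject(
        vectorize_lower_triangle(dm.values), "adversity", build_predictors()
    )
    row = tc.per_subject.iloc[0]
    assert row["w_specific"] == pytest.approx(fit.weights["specific"], abs=1e-10)
    assert row["w_unspecific"] == pytest.approx(fit.weights["unspecific"], abs=1e-10)
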