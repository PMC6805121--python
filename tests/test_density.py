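"""FDM construction, mean correction, ROI shares, classical features."""

import numpy as np
import pytest

from fpsa.config import PipelineConfig, fwhm_to_sigma
from fpsa.density import (
    EmptyMapError,
    FixationDensityMap,
    build_fdm,
    classical_features,
    fdm_entropy,
    remove_common_mean,
    roi_share,
)
from fpsa.io import FixationEvent

CFG = PipelineConfig()  # full-size window for geometry checks


def _ev(x, y, trial=0, rank=1, cond="face_0", phase="baseline", sid="S1",
        start=None, stop=None):
    start = 50.0 * rank if start is None else start
    stop = start + 40.0 if stop is None else stop
    return FixationEvent(
        subject_id=sid, phase=phase, run=1, trial=trial, condition=cond,
        x=float(x), y=float(y), start=start, stop=stop, rank=rank,
        in_crop=CFG.in_crop(x, y),
    )


def test_single_fixation_map_peaks_there():
    x0, y0 = CFG.crop_origin
    fdm = build_fdm([_ev(x0 + 250.5, y0 + 250.5)], CFG)
    assert fdm.grid.sum() == pytest.approx(1.0, abs=1e-9)
    assert np.unravel_index(fdm.grid.argmax(), fdm.grid.shape) == (250, 250)
    assert np.all(fdm.grid >= 0)


def test_two_far_fixations_split_mass_equally():
    x0, y0 = CFG.crop_origin
    fdm = build_fdm(
        [_ev(x0 + 100.5, y0 + 100.5), _ev(x0 + 400.5, y0 + 400.5, rank=2)],
        CFG,
    )
    half = fdm.grid[:250, :250].sum()
    assert half == pytest.approx(0.5, abs=1e-6)


def test_smoothing_sigma_from_fwhm():
    # 1 deg FWHM at 30 px/deg -> sigma = 30 / 2.3548 = 12.7398 px
    assert CFG.fdm_sigma_px == pytest.approx(30.0 / 2.3548, abs=1e-3)
    assert fwhm_to_sigma(65.0) == pytest.approx(27.60, abs=0.01)


def test_fdm_invariances():
    x0, y0 = CFG.crop_origin
    events = [
        _ev(x0 + 100, y0 + 120), _ev(x0 + 300, y0 + 310, rank=2),
        _ev(x0 + 210, y0 + 260, rank=3),
    ]
    a = build_fdm(events, CFG)
    b = build_fdm(events[::-1], CFG)                    # order permuted
    c = build_fdm(events + events, CFG)                 # every fixation doubled
    assert np.allclose(a.grid, b.grid)
    assert np.allclose(a.grid, c.grid, atol=1e-12)


def test_empty_selection_raises():
    with pytest.raises(EmptyMapError):
        build_fdm([_ev(-5.0, -5.0)], CFG)  # out of crop only


def test_mean_correction_zero_mean():
    rng = np.random.default_rng(0)
    maps = [
        FixationDensityMap(grid=rng.random((40, 40)), phase="baseline")
        for _ in range(8)
    ]
    for m in maps:
        m.grid /= m.grid.sum()
    corrected = remove_common_mean(maps)
    mean = np.mean([m.grid for m in corrected], axis=0)
    assert np.max(np.abs(mean)) < 1e-12
    assert all(m.corrected for m in corrected)
    assert all(abs(m.grid.sum()) < 1e-9 for m in corrected)


def test_mean_correction_identical_maps_degenerate():
    g = np.full((20, 20), 1.0 / 400)
    maps = [FixationDensityMap(grid=g.copy(), phase="baseline") for _ in range(8)]
    corrected = remove_common_mean(maps)
    assert all(np.allclose(m.grid, 0) for m in corrected)


def test_mean_correction_rejects_mixed_phases():
    a = FixationDensityMap(grid=np.ones((5, 5)) / 25, phase="baseline")
    b = FixationDensityMap(grid=np.ones((5, 5)) / 25, phase="generalization")
    with pytest.raises(ValueError, match="phases"):
        remove_common_mean([a, b])


def test_corrected_random_maps_correlation_near_minus_one_seventh():
    """Exchangeability: for n i.i.d. maps the mean pairwise correlation
    of mean-corrected maps is -1/(n-1)."""
    rng = np.random.default_rng(1)
    vals = []
    for _ in range(300):
        maps = [
            FixationDensityMap(grid=rng.standard_normal((12, 12)),
                               phase="baseline")
            for _ in range(8)
        ]
        x = np.array([m.grid.ravel() for m in remove_common_mean(maps)])
        r = np.corrcoef(x)
        vals.append(r[np.triu_indices(8, k=1)].mean())
    assert np.mean(vals) == pytest.approx(-1.0 / 7.0, abs=0.01)


def test_roi_share_all_inside_one_roi():
    x0, y0 = CFG.crop_origin
    eyes = CFG.roi_map["eyes"]
    cx, cy = (eyes.x0 + eyes.x1) / 2, (eyes.y0 + eyes.y1) / 2
    events = [_ev(x0 + cx, y0 + cy, rank=r) for r in (1, 2, 3)]
    shares = roi_share(events, CFG.roi_map, CFG)
    assert shares["eyes"] == 1.0
    assert shares["elsewhere"] == pytest.approx(0.0, abs=1e-12)


def test_roi_share_uniform_density_proportional_to_area():
    n = CFG.crop_size
    uniform = FixationDensityMap(grid=np.full((n, n), 1.0 / n**2))
    shares = roi_share(uniform, CFG.roi_map, CFG)
    for name, roi in CFG.roi_map.items():
        assert shares[name] == pytest.approx(roi.area / n**2, rel=1e-9)


def test_roi_overlap_rejected():
    with pytest.raises(ValueError, match="overlap"):
        roi_share(
            FixationDensityMap(grid=np.ones((100, 100))),
            {"a": (0, 0, 50, 50), "b": (40, 40, 30, 30)},
        )


def test_entropy_of_uniform_map():
    n = 50
    uniform = FixationDensityMap(grid=np.full((n, n), 1.0 / n**2))
    assert fdm_entropy(uniform) == pytest.approx(np.log(n**2), rel=1e-12)


def test_classical_features_saccade_and_zscore():
    x0, y0 = CFG.crop_origin
    events = []
    # two conditions so z-scoring is defined; condition A has the 3-4-5
    # saccade, condition B a 6-8-10 saccade
    for cond, scale in (("face_0", 1.0), ("face_90", 2.0)):
        events += [
            _ev(x0 + 100, y0 + 100, cond=cond, rank=1),
            _ev(x0 + 100 + 3 * scale, y0 + 100 + 4 * scale, cond=cond, rank=2),
        ]
    events.append(_ev(x0 + 150, y0 + 150, cond="face_90", rank=3))
    df = classical_features(events, config=CFG)
    a = df[df["condition"] == "face_0"].iloc[0]
    assert a["mean_saccade_length"] == pytest.approx(5.0)
    for col in ["n_fixations_z", "mean_saccade_length_z"]:
        grp = df.groupby(["subject_id", "phase"])[col]
        assert np.allclose(grp.mean(), 0.0, atol=1e-12)
        assert np.allclose(grp.std(ddof=1).dropna(), 1.0, atol=1e-12)


def test_classical_features_single_condition_zscore_error():
    x0, y0 = CFG.crop_origin
    events = [_ev(x0 + 100, y0 + 100), _ev(x0 + 150, y0 + 150, rank=2)]
    with pytest.raises(ValueError, match="z-score"):
        classical_features(events, config=CFG)
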