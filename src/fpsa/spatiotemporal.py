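"""Spatiotemporal FPSA: moving-window, fixation-rank and searchlight.

The temporal variant rebuilds condition FDMs from the fixations whose
start time falls inside a 500-ms window stepped by 50 ms (21 windows on
a 1.5-s trial), refits the adversity model per subject and window, and
contrasts anisotropy between phases per window.  The rank variant does
the same per fixation rank (1st, 2nd, ... fixation).

The searchlight variant slides a 30-px square window over the FDM grid
(inside a mask covering the top 90% of group fixation density), locally
re-applies mean-pattern correction, computes the 8x8 pattern
dissimilarities of the window contents and assigns the fitted specific/
unspecific weights to the window center.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig, Rect
from .density import EmptyMapError, build_fdm, remove_common_mean, select_events
from .models import build_predictors, fit_subject
from .similarity import dissimilarity_matrix, vectorize_lower_triangle


@dataclass
class AnisotropyTimecourse:
    """Per-window adversity-model weights and phase contrasts."""

    mode: str                      # "time" or "rank"
    centers: np.ndarray            # window centers (ms) or ranks
    table: pd.DataFrame            # per (window, phase) group weights
    contrast: pd.DataFrame         # per window: paired t/p on anisotropy
    per_subject: pd.DataFrame      # per (window, phase, subject) weights


@dataclass
class AnisotropyMap:
    """Searchlight weight maps for one phase (subject stack + group mean)."""

    phase: str
    w_specific: np.ndarray         # group mean, NaN outside mask
    w_unspecific: np.ndarray
    anisotropy: np.ndarray
    mask: np.ndarray
    subject_specific: np.ndarray = field(default=None)    # (n_sub, H, W)
    subject_unspecific: np.ndarray = field(default=None)


def _windows(config: PipelineConfig):
    length, step = config.temporal_window_ms
    starts = np.arange(0.0, config.stim_duration_ms - length + step / 2, step)
    return [(s, s + length) for s in starts]


def _adversity_fit_from_maps(maps, cs_angle, predictors):
    corrected = remove_common_mean(maps)
    dm = dissimilarity_matrix(corrected, cs_angle)
    vec = vectorize_lower_triangle(dm.values)
    return fit_subject(vec, "adversity", predictors)


def temporal_fpsa(
    events,
    cs_plus_angles: dict,
    config: PipelineConfig | None = None,
    mode: str = "time",
    max_rank: int = 4,
    phases: tuple = ("baseline", "generalization"),
) -> AnisotropyTimecourse:
    """Moving-window (or fixation-rank) adversity-model timecourse.

    A fixation belongs to a time window iff its start time falls inside
    it.  Windows in which any condition has no fixations for a subject
    are flagged missing for that subject, never fabricated.  The phase
    contrast per window is a paired t-test on anisotropy across the
    subjects with valid fits in both phases.
    """
    if config is None:
        config = PipelineConfig()
    if mode not in ("time", "rank"):
        raise ValueError(f"unknown mode {mode!r}")
    predictors = build_predictors(config.cs_gauss_fwhm_deg)
    if mode == "time":
        slices = _windows(config)
        centers = np.array([(a + b) / 2.0 for a, b in slices])
    else:
        slices = list(range(1, max_rank + 1))
        centers = np.array(slices, dtype=float)

    subjects = sorted(cs_plus_angles)
    rows = []
    for wi, sl in enumerate(slices):
        for phase in phases:
            for sid in subjects:
                sel = select_events(events, subject_id=sid, phase=phase)
                if mode == "time":
                    a, b = sl
                    sel = [e for e in sel if a <= e.start < b]
                else:
                    sel = [e for e in sel if e.rank == sl]
                try:
                    maps = [
                        build_fdm(sel, config, condition=f"face_{ang}")
                        for ang in range(0, 360, 45)
                    ]
                    fit = _adversity_fit_from_maps(
                        maps, cs_plus_angles[sid], predictors
                    )
                    rows.append(
                        {
                            "window": wi, "center": centers[wi],
                            "phase": phase, "subject_id": sid,
                            "w_specific": fit.weights["specific"],
                            "w_unspecific": fit.weights["unspecific"],
                            "anisotropy": fit.anisotropy,
                            "valid": True,
                        }
                    )
                except (EmptyMapError, ValueError):
                    rows.append(
                        {
                            "window": wi, "center": centers[wi],
                            "phase": phase, "subject_id": sid,
                            "w_specific": np.nan, "w_unspecific": np.nan,
                            "anisotropy": np.nan, "valid": False,
                        }
                    )
    per_subject = pd.DataFrame(rows)

    group = (
        per_subject[per_subject["valid"]]
        .groupby(["window", "center", "phase"], as_index=False)
        .agg(
            w_specific=("w_specific", "mean"),
            w_unspecific=("w_unspecific", "mean"),
            anisotropy=("anisotropy", "mean"),
            sem_specific=("w_specific", "sem"),
            sem_unspecific=("w_unspecific", "sem"),
            n=("subject_id", "count"),
        )
    )

    contrast_rows = []
    if len(phases) == 2:
        p0, p1 = phases
        for wi in range(len(slices)):
            sub = per_subject[per_subject["window"] == wi]
            a = sub[sub["phase"] == p0].set_index("subject_id")["anisotropy"]
            b = sub[sub["phase"] == p1].set_index("subject_id")["anisotropy"]
            common = a.index.intersection(b.index)
            av = a.loc[common].to_numpy()
            bv = b.loc[common].to_numpy()
            ok = np.isfinite(av) & np.isfinite(bv)
            if ok.sum() >= 3 and not np.allclose(bv[ok] - av[ok], 0):
                t, p = stats.ttest_rel(bv[ok], av[ok])
            elif ok.sum() >= 3:
                t, p = 0.0, 1.0
            else:
                t, p = np.nan, np.nan
            contrast_rows.append(
                {
                    "window": wi, "center": centers[wi],
                    "n": int(ok.sum()),
                    "delta_anisotropy": float(np.mean(bv[ok] - av[ok]))
                    if ok.any() else np.nan,
                    "t": float(t) if np.isfinite(t) else np.nan,
                    "p": float(p) if np.isfinite(p) else np.nan,
                }
            )
    contrast = pd.DataFrame(contrast_rows)
    return AnisotropyTimecourse(
        mode=mode, centers=centers, table=group,
        contrast=contrast, per_subject=per_subject,
    )


def density_mask(mean_density: np.ndarray, quantile: float = 0.90) -> np.ndarray:
    """Smallest pixel set holding ``quantile`` of the total density."""
    flat = mean_density.ravel()
    order = np.argsort(flat)[::-1]
    cum = np.cumsum(flat[order]) / flat.sum()
    k = int(np.searchsorted(cum, quantile) + 1)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:k]] = True
    return mask.reshape(mean_density.shape)


def _searchlight_centers(mask: np.ndarray, window: int, stride: int):
    """Mask pixels on the stride grid whose window fits inside the grid."""
    h, w = mask.shape
    half = window // 2
    rows = np.arange(half, h - window + half + 1, stride)
    cols = np.arange(half, w - window + half + 1, stride)
    rr, cc = np.meshgrid(rows, cols, indexing="ij")
    keep = mask[rr, cc]
    return rr[keep], cc[keep]


def _searchlight_weights(stack: np.ndarray, rows, cols, window: int,
                         pinv: np.ndarray, chunk: int = 512):
    """Adversity weights at each center for one (8, H, W) aligned stack.

    Local mean-pattern correction is re-applied inside every window.
    Returns (n_centers, 2) columns (w_specific, w_unspecific); NaN where
    a window is degenerate (a condition pattern with zero variance).
    """
    half = window // 2
    view = np.lib.stride_tricks.sliding_window_view(
        stack, (window, window), axis=(1, 2)
    )  # (8, H-w+1, W-w+1, w, w)
    out = np.full((rows.size, 2), np.nan)
    tri = np.tril_indices(8, k=-1)
    for s in range(0, rows.size, chunk):
        r = rows[s:s + chunk] - half
        c = cols[s:s + chunk] - half
        patches = view[:, r, c].reshape(8, r.size, window * window)
        patches = np.ascontiguousarray(patches.transpose(1, 0, 2))  # (C,8,w2)
        patches = patches - patches.mean(axis=1, keepdims=True)  # local correction
        patches = patches - patches.mean(axis=2, keepdims=True)  # center rows
        norms = np.linalg.norm(patches, axis=2)
        good = np.all(norms > 1e-14, axis=1)
        rmat = np.einsum("cik,cjk->cij", patches, patches)
        denom = norms[:, :, None] * norms[:, None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - rmat / denom
        vecs = d[:, tri[0], tri[1]]                  # (C, 28)
        w = vecs @ pinv.T                            # (C, n_params)
        out[s:s + chunk][good] = w[good][:, 1:3]     # specific, unspecific
    return out


def searchlight_fpsa(
    cond_maps: dict,
    cs_plus_angles: dict,
    config: PipelineConfig | None = None,
) -> dict:
    """Searchlight adversity-model maps per phase plus the group contrast.

    ``cond_maps`` maps ``(subject_id, phase)`` to the subject's 8
    *uncorrected* condition FDMs (any order; matched by condition
    label).  Returns ``{"baseline": AnisotropyMap, "generalization":
    AnisotropyMap, "contrast": DataFrame-free dict}`` where the contrast
    holds the per-pixel paired t/p maps of the anisotropy difference.
    """
    if config is None:
        config = PipelineConfig()
    window = config.searchlight_px
    stride = config.searchlight_stride_px
    predictors = build_predictors(config.cs_gauss_fwhm_deg)
    X = predictors.design("adversity")
    pinv = np.linalg.pinv(X)

    subjects = sorted({k[0] for k in cond_maps})
    phases = sorted({k[1] for k in cond_maps})
    # group mask from the mean uncorrected density over everything
    all_grids = [f.grid for maps in cond_maps.values() for f in maps]
    mean_density = np.mean(all_grids, axis=0)
    mask = density_mask(mean_density, config.density_mask_quantile)
    rows, cols = _searchlight_centers(mask, window, stride)
    shape = mean_density.shape

    def aligned_stack(maps, cs_angle):
        by_cond = {f.condition: f.grid for f in maps}
        from .similarity import _aligned_order
        from .config import FACE_ANGLES
        grids = [by_cond[f"face_{a}"] for a in FACE_ANGLES]
        order = _aligned_order(cs_angle)
        return np.stack([grids[i] for i in order])

    results = {}
    per_phase_subject = {}
    for phase in phases:
        ws_maps, wu_maps = [], []
        for sid in subjects:
            stack = aligned_stack(cond_maps[(sid, phase)], cs_plus_angles[sid])
            w = _searchlight_weights(stack, rows, cols, window, pinv)
            ws = np.full(shape, np.nan)
            wu = np.full(shape, np.nan)
            ws[rows, cols] = w[:, 0]
            wu[rows, cols] = w[:, 1]
            if stride > 1:
                ws = _upsample_nearest(ws, rows, cols, mask)
                wu = _upsample_nearest(wu, rows, cols, mask)
            ws_maps.append(ws)
            wu_maps.append(wu)
        ws_stack = np.stack(ws_maps)
        wu_stack = np.stack(wu_maps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN off-mask
            results[phase] = AnisotropyMap(
                phase=phase,
                w_specific=np.nanmean(ws_stack, axis=0),
                w_unspecific=np.nanmean(wu_stack, axis=0),
                anisotropy=np.nanmean(ws_stack - wu_stack, axis=0),
                mask=mask,
                subject_specific=ws_stack,
                subject_unspecific=wu_stack,
            )
        per_phase_subject[phase] = ws_stack - wu_stack

    out = {p: results[p] for p in phases}
    if "baseline" in results and "generalization" in results:
        diff = (
            per_phase_subject["generalization"] - per_phase_subject["baseline"]
        )
        with warnings.catch_warnings(), np.errstate(invalid="ignore", divide="ignore"):
            warnings.simplefilter("ignore")
            t, p = stats.ttest_1samp(diff, 0.0, axis=0, nan_policy="omit")
            out["contrast"] = {
                "delta_anisotropy": np.nanmean(diff, axis=0),
                "t": np.asarray(t, dtype=float),
                "p": np.asarray(p, dtype=float),
            }
    return out


def _upsample_nearest(sparse_map, rows, cols, mask):
    """Fill masked pixels with the value of their nearest stride center."""
    from scipy.interpolate import NearestNDInterpolator

    vals = sparse_map[rows, cols]
    ok = np.isfinite(vals)
    if not ok.any():
        return sparse_map
    interp = NearestNDInterpolator(
        np.column_stack([rows[ok], cols[ok]]), vals[ok]
    )
    out = np.full_like(sparse_map, np.nan)
    rr, cc = np.nonzero(mask)
    out[rr, cc] = interp(np.column_stack([rr, cc]))
    return out


def roi_anisotropy_contrast(
    searchlight: dict,
    roi_map: dict,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-ROI anisotropy difference (generalization - baseline).

    Averages each subject's searchlight anisotropy inside every ROI and
    runs a paired t-test across subjects per ROI.  P-values are reported
    uncorrected (flagged as such) with a Bonferroni column as the
    optional correction.
    """
    if config is None:
        config = PipelineConfig()
    for req in ("baseline", "generalization"):
        if req not in searchlight:
            raise ValueError(f"missing {req!r} searchlight maps")
    base = searchlight["baseline"]
    gen = searchlight["generalization"]
    rows = []
    n_roi = len(roi_map)
    for name, roi in roi_map.items():
        r = Rect(*roi) if not isinstance(roi, Rect) else roi
        if r.area == 0:
            raise ValueError(f"ROI {name!r} is empty")
        sl = (slice(r.y0, r.y1), slice(r.x0, r.x1))
        a_b = np.nanmean(
            (base.subject_specific - base.subject_unspecific)[:, sl[0], sl[1]],
            axis=(1, 2),
        )
        a_g = np.nanmean(
            (gen.subject_specific - gen.subject_unspecific)[:, sl[0], sl[1]],
            axis=(1, 2),
        )
        ok = np.isfinite(a_b) & np.isfinite(a_g)
        if ok.sum() >= 3 and not np.allclose(a_g[ok] - a_b[ok], 0):
            t, p = stats.ttest_rel(a_g[ok], a_b[ok])
        elif ok.sum() >= 3:
            t, p = 0.0, 1.0
        else:
            t, p = np.nan, np.nan
        rows.append(
            {
                "roi": name, "n": int(ok.sum()),
                "delta_anisotropy": float(np.mean(a_g[ok] - a_b[ok]))
                if ok.any() else np.nan,
                "t": float(t), "p_uncorrected": float(p),
                "p_bonferroni": float(min(p * n_roi, 1.0))
                if np.isfinite(p) else np.nan,
            }
        )
    return pd.DataFrame(rows)
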