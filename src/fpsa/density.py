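"""Fixation density maps and classical gaze features.

An FDM is a 2D histogram of fixation locations over the centered face
window, smoothed with a Gaussian kernel of 1 degree FWHM and normalized
to unit sum (a probability density over pixels).  FPSA operates on
*mean-corrected* FDMs: the across-condition mean pattern is removed
separately per phase, leaving zero-sum contrast maps.

Classical features (fixation count, duration, saccade length, FDM
entropy) are computed per (subject, phase, condition) and z-scored
within (subject, phase).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .config import PipelineConfig, Rect


class EmptyMapError(ValueError):
    """No in-crop fixations remained after filtering."""


class DegenerateMapError(ValueError):
    """A map is constant; downstream correlations are undefined."""


@dataclass
class FixationDensityMap:
    """A smoothed fixation density over the face window.

    Uncorrected maps are nonnegative with unit sum; mean-corrected maps
    sum to zero (``corrected`` flag).
    """

    grid: np.ndarray
    subject_id: str = ""
    phase: str = ""
    condition: str = ""
    run: object = None            # int, tuple of ints, or None (pooled)
    px_per_deg: float = 30.0
    fwhm_deg: float = 1.0
    corrected: bool = False
    n_fixations: int = 0

    def copy_with(self, **kw) -> "FixationDensityMap":
        d = dict(
            grid=self.grid, subject_id=self.subject_id, phase=self.phase,
            condition=self.condition, run=self.run,
            px_per_deg=self.px_per_deg, fwhm_deg=self.fwhm_deg,
            corrected=self.corrected, n_fixations=self.n_fixations,
        )
        d.update(kw)
        return FixationDensityMap(**d)


def _match(value, selector):
    if selector is None:
        return True
    if isinstance(selector, (list, tuple, set, frozenset)):
        return value in selector
    return value == selector


def select_events(
    events,
    subject_id=None,
    phase=None,
    run=None,
    condition=None,
    in_crop_only: bool = False,
) -> list:
    """Filter an event collection by labels."""
    return [
        e
        for e in events
        if _match(e.subject_id, subject_id)
        and _match(e.phase, phase)
        and _match(e.run, run)
        and _match(e.condition, condition)
        and (e.in_crop or not in_crop_only)
    ]


def build_fdm(
    events,
    config: PipelineConfig | None = None,
    smooth: bool = True,
    **selector,
) -> FixationDensityMap:
    """Build one FDM from (a selection of) fixation events.

    The 2D count histogram over the crop window is convolved with a
    Gaussian of FWHM ``config.fdm_fwhm_deg`` (truncated at the window
    boundary) and renormalized to unit sum.  Out-of-crop fixations are
    excluded here; zero usable fixations raise :class:`EmptyMapError`.
    """
    if config is None:
        config = PipelineConfig()
    sel = select_events(events, **selector) if selector else list(events)
    sel = [e for e in sel if e.in_crop]
    if not sel:
        raise EmptyMapError("no in-crop fixations for the requested selection")
    n = config.crop_size
    xs = np.array([e.x for e in sel])
    ys = np.array([e.y for e in sel])
    lx, ly = config.to_local(xs, ys)
    grid, _, _ = np.histogram2d(
        ly, lx, bins=n, range=[[0, n], [0, n]]
    )  # rows = y, cols = x
    if smooth:
        grid = gaussian_filter(grid, sigma=config.fdm_sigma_px, mode="constant")
    grid /= grid.sum()
    first = sel[0]
    same = lambda attr: (
        getattr(first, attr)
        if len({getattr(e, attr) for e in sel}) == 1
        else ""
    )
    runs = sorted({e.run for e in sel})
    return FixationDensityMap(
        grid=grid,
        subject_id=same("subject_id"),
        phase=same("phase"),
        condition=same("condition"),
        run=runs[0] if len(runs) == 1 else tuple(runs),
        px_per_deg=config.px_per_deg,
        fwhm_deg=config.fdm_fwhm_deg,
        corrected=False,
        n_fixations=len(sel),
    )


def remove_common_mean(fdms: list) -> list:
    """Remove the across-condition mean pattern from a set of FDMs.

    Must be applied separately per phase (and subject); mixing phases
    raises.  The returned maps carry the ``corrected`` flag and their
    across-map mean is the zero map.
    """
    if len(fdms) < 2:
        raise ValueError("need at least 2 maps to remove a common mean")
    phases = {f.phase for f in fdms}
    if len(phases) > 1:
        raise ValueError(f"maps from mixed phases: {sorted(phases)}")
    shapes = {f.grid.shape for f in fdms}
    if len(shapes) > 1:
        raise ValueError("maps have mismatched shapes")
    mean = np.mean([f.grid for f in fdms], axis=0)
    return [f.copy_with(grid=f.grid - mean, corrected=True) for f in fdms]


def roi_share(fdm_or_events, roi_map: dict, config: PipelineConfig | None = None) -> dict:
    """Fraction of density (FDM input) or of fixations (event input) per ROI.

    ROIs must be disjoint and inside the crop; the residual share is
    returned under ``"elsewhere"`` so the values sum to 1.
    """
    if config is None:
        config = PipelineConfig()
    rois = {k: (Rect(*v) if not isinstance(v, Rect) else v) for k, v in roi_map.items()}
    names = list(rois)
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            if rois[a].overlaps(rois[b]):
                raise ValueError(f"ROIs {a!r} and {b!r} overlap")
    shares = {}
    if isinstance(fdm_or_events, FixationDensityMap):
        g = fdm_or_events.grid
        total = g.sum()
        for k, r in rois.items():
            shares[k] = float(g[r.y0:r.y1, r.x0:r.x1].sum() / total)
    else:
        sel = [e for e in fdm_or_events if e.in_crop]
        if not sel:
            raise EmptyMapError("no in-crop fixations")
        lx, ly = zip(*(config.to_local(e.x, e.y) for e in sel))
        lx, ly = np.array(lx), np.array(ly)
        for k, r in rois.items():
            inside = (lx >= r.x0) & (lx < r.x1) & (ly >= r.y0) & (ly < r.y1)
            shares[k] = float(inside.mean())
    shares["elsewhere"] = float(1.0 - sum(shares.values()))
    return shares


def fdm_entropy(fdm: FixationDensityMap) -> float:
    """Shannon entropy of the density over pixels, in nats."""
    p = fdm.grid[fdm.grid > 0]
    return float(-(p * np.log(p)).sum())


def _saccade_lengths(trial_events) -> list:
    """Euclidean distances between consecutive-rank fixations of one trial."""
    se = sorted(trial_events, key=lambda e: e.rank)
    return [
        float(np.hypot(b.x - a.x, b.y - a.y))
        for a, b in zip(se, se[1:])
    ]


def classical_features(
    events,
    fdms: dict | None = None,
    config: PipelineConfig | None = None,
) -> pd.DataFrame:
    """Per-(subject, phase, condition) classical gaze features.

    Returns a table with raw features (``n_fixations``, ``mean_duration``
    in ms, ``mean_saccade_length`` in px, ``fdm_entropy`` in nats) and
    their within-(subject, phase) z-scored variants (``*_z``).  Saccade
    lengths use the full fixation stream (including out-of-crop events);
    entropy needs per-condition FDMs, passed as a dict keyed by
    (subject_id, phase, condition) or built on the fly.
    """
    if config is None:
        config = PipelineConfig()
    rows = []
    keys = sorted({(e.subject_id, e.phase, e.condition) for e in events})
    for sid, phase, cond in keys:
        sel = select_events(events, subject_id=sid, phase=phase, condition=cond)
        by_trial: dict = {}
        for e in sel:
            by_trial.setdefault((e.run, e.trial), []).append(e)
        sacc = [l for tr in by_trial.values() for l in _saccade_lengths(tr)]
        if fdms is not None and (sid, phase, cond) in fdms:
            ent = fdm_entropy(fdms[(sid, phase, cond)])
        else:
            try:
                ent = fdm_entropy(build_fdm(sel, config))
            except EmptyMapError:
                ent = np.nan
        rows.append(
            {
                "subject_id": sid, "phase": phase, "condition": cond,
                "n_fixations": len(sel),
                "mean_duration": float(np.mean([e.stop - e.start for e in sel])),
                "mean_saccade_length": float(np.mean(sacc)) if sacc else np.nan,
                "fdm_entropy": ent,
            }
        )
    df = pd.DataFrame(rows)
    feats = ["n_fixations", "mean_duration", "mean_saccade_length", "fdm_entropy"]
    for f in feats:
        def _z(s):
            if len(s) < 2:
                raise ValueError(
                    f"cannot z-score {f!r}: a single condition leaves the "
                    "within-(subject, phase) sd undefined"
                )
            sd = s.std(ddof=1)
            if not np.isfinite(sd) or sd == 0:
                return s * 0.0  # constant feature: centered, no spread
            return (s - s.mean()) / sd
        df[f + "_z"] = df.groupby(["subject_id", "phase"])[f].transform(_z)
    return df
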