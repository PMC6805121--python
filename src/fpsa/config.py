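"""Shared pipeline configuration.

All geometric and statistical choices that more than one stage depends on
live here: screen/crop geometry, FDM smoothing, the condition circle, ROI
rectangles, temporal-window and searchlight parameters, and the seed.

Conventions
-----------
Coordinates are 0-based pixel indices with the origin at the top-left of
the full screen; ``crop`` converts screen coordinates to FDM-local ones.
Angles on the stimulus continuum are degrees in {0, 45, ..., 315}.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import yaml

# FWHM = 2 sqrt(2 ln 2) sigma for a Gaussian
FWHM_FACTOR = 2.0 * math.sqrt(2.0 * math.log(2.0))

#: The eight face angles of the stimulus circle, degrees.
FACE_ANGLES = tuple(range(0, 360, 45))

#: Non-face condition labels.
SPECIAL_CONDITIONS = ("ucs", "oddball", "null")


def fwhm_to_sigma(fwhm: float) -> float:
    """Convert a full width at half maximum to the Gaussian sigma."""
    return fwhm / FWHM_FACTOR


@dataclass(frozen=True)
class Rect:
    """Axis-aligned rectangle ``(x0, y0, width, height)`` in pixel units."""

    x0: int
    y0: int
    width: int
    height: int

    @property
    def x1(self) -> int:
        return self.x0 + self.width

    @property
    def y1(self) -> int:
        return self.y0 + self.height

    def contains(self, x, y) -> bool:
        return (self.x0 <= x < self.x1) and (self.y0 <= y < self.y1)

    def overlaps(self, other: "Rect") -> bool:
        return not (
            self.x1 <= other.x0
            or other.x1 <= self.x0
            or self.y1 <= other.y0
            or other.y1 <= self.y0
        )

    @property
    def area(self) -> int:
        return self.width * self.height


def _default_rois(size: int) -> dict:
    """Default eyes/nose/mouth rectangles, scaled to the crop size.

    The outlines are a declared choice: an upper band spanning both eyes,
    a central nose band and a lower mouth band, mutually disjoint.
    """
    r = lambda a, b, c, d: Rect(
        int(a * size), int(b * size), int(c * size), int(d * size)
    )
    return {
        "eyes": r(0.10, 0.20, 0.80, 0.24),
        "nose": r(0.30, 0.46, 0.40, 0.20),
        "mouth": r(0.26, 0.68, 0.48, 0.18),
    }


@dataclass
class PipelineConfig:
    """Run configuration shared by every pipeline stage.

    Parameters
    ----------
    px_per_deg
        Pixels per degree of visual angle (viewing geometry).
    screen_size
        Full screen (width, height) in pixels.
    crop_size
        Side length of the square analysis window centered on the face.
        FDMs are computed on this window only.
    fdm_fwhm_deg
        FWHM of the Gaussian used to smooth fixation histograms, degrees.
    cs_gauss_fwhm_deg
        FWHM of the CS+-centered Gaussian similarity component, degrees
        on the condition circle.
    stim_duration_ms, soa_s, soa_null_s
        Trial timing: stimulus duration and stimulus onset asynchrony
        (null trials extend the effective SOA to ~12 s).
    temporal_window_ms
        (length, step) of the moving window for temporal FPSA.
    searchlight_px
        Side of the square searchlight window.
    searchlight_stride_px
        Stride between searchlight centers (1 = dense).
    density_mask_quantile
        Searchlight mask covers this fraction of total fixation density.
    decoder_downscale
        Block-averaging factor applied to FDMs before decoding.
    decoder_pixel_filter
        Keep pixels with mean/std above this threshold.
    decoder_pca_variance
        Retain the smallest number of PCs reaching this variance fraction.
    """

    px_per_deg: float = 30.0
    screen_size: tuple = (1600, 1200)
    crop_size: int = 500
    fdm_fwhm_deg: float = 1.0
    cs_gauss_fwhm_deg: float = 65.0
    stim_duration_ms: float = 1500.0
    soa_s: float = 6.0
    soa_null_s: float = 12.0
    temporal_window_ms: tuple = (500.0, 50.0)
    searchlight_px: int = 30
    searchlight_stride_px: int = 1
    density_mask_quantile: float = 0.90
    decoder_downscale: int = 10
    decoder_pixel_filter: float = 0.075
    decoder_pca_variance: float = 0.50
    svm_C: float = 1.0
    seed: int = 0
    roi_map: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.px_per_deg <= 0 or self.crop_size <= 0 or self.fdm_fwhm_deg <= 0:
            raise ValueError("lengths and smoothing widths must be positive")
        if not self.roi_map:
            self.roi_map = _default_rois(self.crop_size)
        for name, roi in self.roi_map.items():
            if isinstance(roi, (tuple, list)):
                self.roi_map[name] = roi = Rect(*roi)
            if roi.x0 < 0 or roi.y0 < 0 or roi.x1 > self.crop_size or roi.y1 > self.crop_size:
                raise ValueError(f"ROI {name!r} lies outside the crop window")

    # -- geometry -------------------------------------------------------
    @property
    def crop_origin(self) -> tuple:
        """Top-left screen coordinate of the centered crop window."""
        w, h = self.screen_size
        return ((w - self.crop_size) // 2, (h - self.crop_size) // 2)

    @property
    def fdm_sigma_px(self) -> float:
        """Smoothing sigma of the FDM kernel in pixels."""
        return fwhm_to_sigma(self.fdm_fwhm_deg * self.px_per_deg)

    def in_crop(self, x, y) -> bool:
        x0, y0 = self.crop_origin
        n = self.crop_size
        return (x0 <= x < x0 + n) and (y0 <= y < y0 + n)

    def to_local(self, x, y):
        """Screen coordinates -> FDM-local coordinates."""
        x0, y0 = self.crop_origin
        return x - x0, y - y0

    # -- (de)serialization ----------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["roi_map"] = {
            k: [v.x0, v.y0, v.width, v.height] for k, v in self.roi_map.items()
        }
        d["screen_size"] = list(self.screen_size)
        d["temporal_window_ms"] = list(self.temporal_window_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "screen_size" in d:
            d["screen_size"] = tuple(d["screen_size"])
        if "temporal_window_ms" in d:
            d["temporal_window_ms"] = tuple(d["temporal_window_ms"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        """Stable hash of the configuration, for provenance stamping."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
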