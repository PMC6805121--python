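"""Single-trial FDM decoding with linear SVMs.

Two binary decoders per subject and phase: CS+ vs CS- (the *specific*
axis) and +90 vs -90 degrees (the *unspecific* axis).  Single-trial
FDMs are block-averaged 10x (500x500 -> 50x50 -> 2500 pixels), pixels
with low mean-to-variability ratio are discarded (keep mean/std >
0.075), and the surviving pixels are projected onto the smallest number
of principal components reaching 50% of the training variance.  All
preprocessing statistics (pixel filter, PCA, scaling) are estimated on
the training folds only; accuracies come from stratified 3-fold
cross-validation.

For interpretation, linear decoder weights are converted to activation
patterns A = Cov(X) w (the encoding pattern that drives the decoder),
mapped back to the downscaled pixel grid and z-scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import block_reduce
from sklearn.decomposition import PCA
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import LinearSVC

from .config import PipelineConfig


class PreprocessingError(ValueError):
    """Feature preprocessing removed every pixel."""


@dataclass
class FeatureTransform:
    """Fitted preprocessing: pixel filter mask + PCA projection."""

    mask: np.ndarray          # boolean over the downscaled grid
    pca: PCA
    n_components: int
    grid_shape: tuple

    def apply(self, trials: np.ndarray) -> np.ndarray:
        return self.pca.transform(trials[:, self.mask.ravel()])[
            :, : self.n_components
        ]

    def weights_to_grid(self, w_pixels: np.ndarray) -> np.ndarray:
        out = np.full(self.mask.size, np.nan)
        out[self.mask.ravel()] = w_pixels
        return out.reshape(self.grid_shape)


@dataclass
class DecoderResult:
    """Cross-validated decoding outcome for one subject/phase/axis."""

    subject_id: str
    phase: str
    axis: str                     # "specific" or "unspecific"
    fold_accuracies: np.ndarray
    n_components: list
    activation_map: np.ndarray | None = None

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.fold_accuracies))


def downscale_trials(trial_maps: np.ndarray, factor: int = 10) -> np.ndarray:
    """Block-mean downscale a (trials, H, W) stack; returns (trials, h*w)."""
    t = np.asarray(trial_maps, dtype=float)
    if t.ndim != 3:
        raise ValueError("expected a (trials, H, W) stack")
    small = block_reduce(t, block_size=(1, factor, factor), func=np.mean)
    return small.reshape(small.shape[0], -1), small.shape[1:]


def pixel_filter_mask(trials_2500: np.ndarray, threshold: float = 0.075) -> np.ndarray:
    """Keep pixels whose mean/std exceeds the threshold.

    Pixels with zero variability everywhere (std 0) or zero mean are
    excluded: a constant-zero pixel carries no signal, and the ratio is
    undefined.
    """
    mean = trials_2500.mean(axis=0)
    std = trials_2500.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(std > 0, mean / std, 0.0)
    return ratio > threshold


def fit_transform(
    train: np.ndarray,
    grid_shape: tuple,
    config: PipelineConfig | None = None,
) -> FeatureTransform:
    """Fit the pixel filter and PCA on training trials only."""
    if config is None:
        config = PipelineConfig()
    mask_flat = pixel_filter_mask(train, config.decoder_pixel_filter)
    if not mask_flat.any():
        raise PreprocessingError("pixel filter removed every pixel")
    pca = PCA(svd_solver="full")
    pca.fit(train[:, mask_flat])
    cum = np.cumsum(pca.explained_variance_ratio_)
    n_comp = int(np.searchsorted(cum, config.decoder_pca_variance) + 1)
    n_comp = min(n_comp, cum.size)
    return FeatureTransform(
        mask=mask_flat.reshape(grid_shape),
        pca=pca,
        n_components=n_comp,
        grid_shape=grid_shape,
    )


def preprocess_features(
    trial_maps: np.ndarray,
    config: PipelineConfig | None = None,
):
    """Downscale + filter + PCA-project a full trial stack (no CV).

    Convenience path for visualization-style fits on 100% of trials;
    cross-validated decoding uses per-fold transforms internally.
    Returns ``(features, transform)``.
    """
    if config is None:
        config = PipelineConfig()
    flat, grid_shape = downscale_trials(trial_maps, config.decoder_downscale)
    tr = fit_transform(flat, grid_shape, config)
    return tr.apply(flat), tr


def train_decode_cv(
    trial_maps: np.ndarray,
    labels: np.ndarray,
    seed: int,
    folds: int = 3,
    config: PipelineConfig | None = None,
    subject_id: str = "",
    phase: str = "",
    axis: str = "",
    with_activation: bool = True,
) -> DecoderResult:
    """Stratified k-fold linear-SVM decoding of single-trial FDMs.

    Every preprocessing statistic is re-estimated inside each training
    fold; the test fold only passes through the fitted transforms.
    The activation map is computed from a final fit on all trials
    (visualization only, never used for accuracy).
    """
    if config is None:
        config = PipelineConfig()
    y = np.asarray(labels)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"need exactly 2 classes, got {classes.size}")
    counts = [int((y == c).sum()) for c in classes]
    if min(counts) < folds:
        raise ValueError("need at least `folds` trials per class")
    flat, grid_shape = downscale_trials(trial_maps, config.decoder_downscale)
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    accs, n_comps = [], []
    for train_idx, test_idx in skf.split(flat, y):
        tr = fit_transform(flat[train_idx], grid_shape, config)
        Xtr = tr.apply(flat[train_idx])
        Xte = tr.apply(flat[test_idx])
        clf = LinearSVC(C=config.svm_C, random_state=seed)
        clf.fit(Xtr, y[train_idx])
        accs.append(float(clf.score(Xte, y[test_idx])))
        n_comps.append(tr.n_components)
    activation = None
    if with_activation:
        tr = fit_transform(flat, grid_shape, config)
        X = tr.apply(flat)
        clf = LinearSVC(C=config.svm_C, random_state=seed)
        clf.fit(X, y)
        activation = activation_pattern(clf, X, tr)
    return DecoderResult(
        subject_id=subject_id, phase=phase, axis=axis,
        fold_accuracies=np.array(accs), n_components=n_comps,
        activation_map=activation,
    )


def activation_pattern(
    clf,
    train_features: np.ndarray,
    transform: FeatureTransform | None = None,
    z_score: bool = True,
) -> np.ndarray:
    """Covariance-projected decoder weights (encoding pattern).

    ``A = Cov(X) w`` in the decoder's feature space.  With a fitted
    :class:`FeatureTransform` the pattern is mapped back through the PCA
    and pixel filter onto the downscaled grid (NaN outside the mask) and
    z-scored over retained pixels.
    """
    if not hasattr(clf, "coef_"):
        raise ValueError("decoder is not fitted")
    w = np.asarray(clf.coef_).ravel()
    X = np.asarray(train_features, dtype=float)
    Xc = X - X.mean(axis=0)
    cov = (Xc.T @ Xc) / max(X.shape[0] - 1, 1)
    a = cov @ w
    if transform is None:
        return a
    # back through PCA: pattern in pixel space over retained pixels
    comps = transform.pca.components_[: transform.n_components]
    a_px = comps.T @ a
    if z_score:
        sd = a_px.std()
        if sd > 0:
            a_px = (a_px - a_px.mean()) / sd
    return transform.weights_to_grid(a_px)


def average_activation_maps(results: list, cs_plus_angles: list) -> dict:
    """Group activation maps, averaged over subjects sharing a CS+ face."""
    groups: dict = {}
    for res, ang in zip(results, cs_plus_angles):
        if res.activation_map is None:
            continue
        groups.setdefault(float(ang), []).append(res.activation_map)
    return {
        ang: np.nanmean(np.stack(maps), axis=0) for ang, maps in groups.items()
    }
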