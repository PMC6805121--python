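"""Dissimilarity geometry of fixation patterns.

Pattern distance is 1 - Pearson correlation between vectorized,
mean-corrected FDMs.  Matrices are aligned to each subject's CS+: after
re-indexing, row/column 4 (1-based) is the CS+ and row/column 8 the CS-,
so condition k sits at signed angular distance 45 * (k - 4) degrees from
the CS+.  The generalization phase is computed per run and averaged on
the raw 1 - r scale; Fisher z (atanh of the implied correlation) is
applied only for inferential statistics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.manifold import MDS

from .config import FACE_ANGLES
from .density import DegenerateMapError

#: signed angular distances (deg) from the CS+ at aligned positions 1..8
ALIGNED_ANGLES = np.array([-135.0, -90.0, -45.0, 0.0, 45.0, 90.0, 135.0, 180.0])

CS_PLUS_POS = 3   # 0-based index of the CS+ after alignment (position 4)
CS_MINUS_POS = 7  # 0-based index of the CS- (position 8)


@dataclass
class DissimilarityMatrix:
    """Symmetric condition-by-condition 1 - Pearson distance matrix."""

    values: np.ndarray
    subject_id: str = ""
    phase: str = ""
    cs_plus_angle: float = 0.0
    runs: tuple = field(default_factory=tuple)

    @property
    def n(self) -> int:
        return self.values.shape[0]


def _aligned_order(cs_plus_angle: float) -> np.ndarray:
    """Raw condition indices (by FACE_ANGLES order) in aligned order."""
    cs_idx = list(FACE_ANGLES).index(int(cs_plus_angle) % 360)
    # aligned position p (0-based) holds the face at cs + 45*(p - 3)
    return np.array([(cs_idx + (p - CS_PLUS_POS)) % 8 for p in range(8)])


def dissimilarity_matrix(
    fdms: list,
    cs_plus_angle: float,
) -> DissimilarityMatrix:
    """1 - Pearson distance matrix of 8 corrected FDMs, CS+-aligned.

    ``fdms`` must hold one mean-corrected map per face condition
    (``face_0`` ... ``face_315``).  A constant map has no defined
    correlation and raises :class:`DegenerateMapError` naming it.
    """
    if len(fdms) != 8:
        raise ValueError(f"need 8 condition maps, got {len(fdms)}")
    by_cond = {f.condition: f for f in fdms}
    mats = []
    for a in FACE_ANGLES:
        key = f"face_{a}"
        if key not in by_cond:
            raise ValueError(f"missing condition map {key!r}")
        v = by_cond[key].grid.ravel()
        if np.ptp(v) == 0:
            raise DegenerateMapError(
                f"map {key!r} is constant; correlation undefined"
            )
        mats.append(v)
    x = np.array(mats)
    order = _aligned_order(cs_plus_angle)
    x = x[order]
    r = np.corrcoef(x)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = (d + d.T) / 2.0
    runs = sorted({f.run for f in fdms if f.run is not None})
    return DissimilarityMatrix(
        values=d,
        subject_id=fdms[0].subject_id,
        phase=fdms[0].phase,
        cs_plus_angle=float(cs_plus_angle),
        runs=tuple(runs),
    )


def average_runs(matrices: list) -> DissimilarityMatrix:
    """Element-wise mean of per-run matrices (raw 1 - r scale)."""
    if not matrices:
        raise ValueError("no matrices to average")
    first = matrices[0]
    for m in matrices[1:]:
        if m.n != first.n or m.cs_plus_angle != first.cs_plus_angle:
            raise ValueError("matrices have mismatched size or alignment")
    runs = tuple(r for m in matrices for r in m.runs)
    return DissimilarityMatrix(
        values=np.mean([m.values for m in matrices], axis=0),
        subject_id=first.subject_id,
        phase=first.phase,
        cs_plus_angle=first.cs_plus_angle,
        runs=runs,
    )


def combine_phases(base: DissimilarityMatrix, gen: DissimilarityMatrix,
                   cross: np.ndarray | None = None) -> DissimilarityMatrix:
    """Stack two aligned 8x8 phase blocks into the joint 16x16 matrix.

    The off-diagonal block holds cross-phase distances when provided,
    otherwise the average of the two within-phase blocks as a neutral
    placeholder for embedding.
    """
    if base.n != 8 or gen.n != 8:
        raise ValueError("phase blocks must be 8x8")
    if cross is None:
        cross = (base.values + gen.values) / 2.0
    top = np.hstack([base.values, cross])
    bot = np.hstack([cross.T, gen.values])
    return DissimilarityMatrix(
        values=np.vstack([top, bot]),
        subject_id=base.subject_id,
        phase="joint",
        cs_plus_angle=base.cs_plus_angle,
        runs=base.runs + gen.runs,
    )


def cross_phase_block(fdms_base: list, fdms_gen: list) -> np.ndarray:
    """8x8 cross-phase 1 - Pearson distances (rows baseline, cols gen.)."""
    xb = np.array([f.grid.ravel() for f in fdms_base])
    xg = np.array([f.grid.ravel() for f in fdms_gen])
    xb = xb - xb.mean(axis=1, keepdims=True)
    xg = xg - xg.mean(axis=1, keepdims=True)
    nb = np.linalg.norm(xb, axis=1)
    ng = np.linalg.norm(xg, axis=1)
    if np.any(nb == 0) or np.any(ng == 0):
        raise DegenerateMapError("constant map in cross-phase block")
    return 1.0 - (xb @ xg.T) / np.outer(nb, ng)


def vectorize_lower_triangle(matrix: np.ndarray) -> np.ndarray:
    """Row-major lower triangle (diagonal excluded) of a symmetric matrix."""
    m = np.asarray(matrix)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    i, j = np.tril_indices(m.shape[0], k=-1)
    return m[i, j]


def devectorize_lower_triangle(vec: np.ndarray, n: int) -> np.ndarray:
    """Inverse of :func:`vectorize_lower_triangle` (zero diagonal)."""
    vec = np.asarray(vec)
    if vec.size != n * (n - 1) // 2:
        raise ValueError("vector length does not match matrix size")
    out = np.zeros((n, n))
    i, j = np.tril_indices(n, k=-1)
    out[i, j] = vec
    return out + out.T


def fisher_z(dissimilarities, clamp: float = 1.0 - 1e-12) -> np.ndarray:
    """Fisher transform of the correlations implied by 1 - r distances.

    ``z = atanh(1 - d)``; implied correlations at the open-interval ends
    (d in {0, 2}) are clamped with a warning to keep z finite.
    """
    d = np.asarray(dissimilarities, dtype=float)
    r = 1.0 - d
    if np.any(np.abs(r) >= 1.0):
        warnings.warn(
            "dissimilarities at the boundary of (0, 2); clamping before atanh",
            RuntimeWarning, stacklevel=2,
        )
        r = np.clip(r, -clamp, clamp)
    return np.arctanh(r)


def _classical_mds(d: np.ndarray, dims: int) -> np.ndarray:
    """Torgerson double-centering solution, used as a SMACOF warm start."""
    n = d.shape[0]
    j = np.eye(n) - 1.0 / n
    b = -0.5 * j @ (d**2) @ j
    w, v = np.linalg.eigh(b)
    idx = np.argsort(w)[::-1][:dims]
    return v[:, idx] * np.sqrt(np.clip(w[idx], 0.0, None))


def mds_embed(matrix: np.ndarray, dims: int = 2, seed: int = 0,
              n_init: int = 8):
    """Metric MDS embedding of a dissimilarity matrix.

    Runs SMACOF from a classical-MDS warm start plus ``n_init`` random
    seeded restarts and keeps the lowest-stress solution.  Returns
    ``(coords, stress1)`` with Kruskal's normalized stress-1.
    """
    from sklearn.manifold import smacof

    m = np.asarray(matrix, dtype=float)
    if not np.all(np.isfinite(m)):
        raise ValueError("dissimilarity matrix contains non-finite entries")
    if not np.allclose(m, m.T):
        raise ValueError("dissimilarity matrix must be symmetric")
    common = dict(
        metric=True, n_components=dims, eps=1e-12, max_iter=2000,
        normalized_stress=False,
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        coords, stress = smacof(
            m, init=_classical_mds(m, dims), n_init=1, random_state=seed,
            **common,
        )
        if n_init > 0:
            c2, s2 = smacof(m, n_init=n_init, random_state=seed, **common)
            if s2 < stress:
                coords, stress = c2, s2
    denom = (m**2).sum() / 2.0
    stress1 = float(np.sqrt(stress / denom)) if denom > 0 else 0.0
    return coords, stress1


def elementwise_phase_test(
    baseline: list,
    generalization: list,
    alpha: float = 0.05,
):
    """Paired t-test per off-diagonal element across subjects.

    Both lists hold one aligned matrix per subject, in the same subject
    order.  Tests run on Fisher-z transformed values.  Returns a dict
    with ``t``, ``p`` (n x n, NaN diagonal) and the boolean ``flagged``
    matrix at the (uncorrected) ``alpha`` level.
    """
    if len(baseline) != len(generalization):
        raise ValueError("phases have different subject counts")
    n_sub = len(baseline)
    if n_sub < 3:
        raise ValueError("need at least 3 subjects for a paired test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # zero diagonal clamps
        zb = np.array([fisher_z(m.values) for m in baseline])
        zg = np.array([fisher_z(m.values) for m in generalization])
    diff = zg - zb
    with np.errstate(invalid="ignore", divide="ignore"):
        t, p = stats.ttest_rel(zg, zb, axis=0)
    # exact zero differences across every subject: no effect, not NaN
    all_zero = np.all(diff == 0, axis=0)
    t = np.where(all_zero, 0.0, t)
    p = np.where(all_zero, 1.0, p)
    n = baseline[0].n
    eye = np.eye(n, dtype=bool)
    t = np.where(eye, np.nan, t)
    p = np.where(eye, np.nan, p)
    flagged = (p < alpha) & ~eye
    return {"t": t, "p": p, "flagged": flagged, "alpha": alpha, "corrected": False}
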