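"""Synthetic cohorts with controllable similarity geometry.

The generator emulates the study design at desk scale: 74 subjects, a
circular continuum of 8 faces, one 120-trial baseline run, a conditioning
run, three 120-trial generalization runs, 3-6 fixations per 1.5-s trial
on a centered face window.

Gaze is modeled per subject as a base fixation density (a mixture of 2D
Gaussians over eyes/nose/mouth with idiosyncratic weights and jitter)
plus two orthogonal zero-integral modulation maps that carry the
*specific* (CS+/CS-) and *unspecific* (+/-90 deg) axes of the condition
circle:

    p_theta  ∝  max(0, base + g_s cos(theta) M_s + g_u sin(theta) M_u)

where ``theta`` is the angular distance from the subject's CS+.  With
equal gains the implied condition geometry is circular; a larger specific
gain separates the CS+/CS- pair more than the orthogonal pair, which is
the ground-truth anisotropy the analysis stages must recover.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import FACE_ANGLES, PipelineConfig, fwhm_to_sigma
from .design import TrialSequence, face_condition, generate_trial_sequence
from .io import FixationEvent

__all__ = [
    "SubjectGazeModel", "make_subject_model", "sample_fixations",
    "simulate_subject_events", "simulate_cohort", "generate_ratings_scr",
    "gaussian_tuning", "simulate_dissimilarity_cohort",
]


def gaussian_tuning(x_deg, alpha, sigma_deg):
    """Gaussian generalization profile G(x) = alpha exp(-(x/sigma)^2 / 2)."""
    x = np.asarray(x_deg, dtype=float)
    return alpha * np.exp(-((x / sigma_deg) ** 2) / 2.0)


def _gauss2d(size, cx, cy, sigma):
    """Unnormalized isotropic Gaussian bump on a size x size grid."""
    yy, xx = np.mgrid[0:size, 0:size]
    return np.exp(-(((xx - cx) ** 2 + (yy - cy) ** 2) / (2.0 * sigma**2)))


def signed_angle(angle_deg, reference_deg):
    """Signed angular distance in (-180, 180] from reference to angle."""
    d = (float(angle_deg) - float(reference_deg)) % 360.0
    return d - 360.0 if d > 180.0 else d


@dataclass
class SubjectGazeModel:
    """Generative gaze model of one subject.

    ``base_density`` is a valid probability density over the face window;
    the modulation maps integrate to zero.  ``condition_density`` yields
    the (clipped, renormalized) density for a face at a given angle.
    """

    subject_id: str
    cs_plus_angle: float
    base_density: np.ndarray
    mod_specific: np.ndarray
    mod_unspecific: np.ndarray
    specific_gain: float = 0.0
    unspecific_gain: float = 0.0
    fixations_per_trial: tuple = (3, 6)
    post_learning: bool = False
    #: fixations starting before this latency (ms) are drawn from the
    #: unmodulated base density; None applies the modulation throughout
    effect_onset_ms: float | None = None

    def __post_init__(self):
        if self.specific_gain < 0 or self.unspecific_gain < 0:
            raise ValueError("modulation gains must be >= 0")
        if np.any(self.base_density < 0):
            raise ValueError("base density must be nonnegative")
        s = self.base_density.sum()
        if not np.isclose(s, 1.0):
            raise ValueError("base density must integrate to 1")

    @property
    def cs_minus_angle(self) -> float:
        return (self.cs_plus_angle + 180.0) % 360.0

    def condition_density(self, face_angle: float) -> np.ndarray:
        """Fixation density for the face at ``face_angle`` degrees."""
        x = np.deg2rad(signed_angle(face_angle, self.cs_plus_angle))
        d = (
            self.base_density
            + self.specific_gain * np.cos(x) * self.mod_specific
            + self.unspecific_gain * np.sin(x) * self.mod_unspecific
        )
        d = np.clip(d, 0.0, None)
        total = d.sum()
        if total <= 0:
            raise ValueError("degenerate condition density (all zero)")
        return d / total


# default component loci in crop-relative units (x, y, sigma, weight)
_BASE_COMPONENTS = {
    "left_eye": (0.33, 0.36, 0.075, 0.32),
    "right_eye": (0.67, 0.36, 0.075, 0.32),
    "nose": (0.50, 0.57, 0.085, 0.24),
    "mouth": (0.50, 0.78, 0.080, 0.12),
}

# default modulation dipoles, placed on well-supported base regions so
# the modulated densities stay nonnegative at realistic gains: the
# specific axis contrasts the two eyes, the unspecific axis contrasts
# the eye region with the nose
_MOD_LOCI = {
    "specific": ((0.33, 0.36), (0.67, 0.36)),
    "unspecific": ((0.50, 0.36), (0.50, 0.57)),
}

#: fraction of base density spread uniformly over the window (stray
#: fixations); keeps modulated densities bounded away from zero
_UNIFORM_FLOOR = 0.10


def _dipole(size, pos_xy, neg_xy, sigma_px):
    """Smooth +1/-1 contrast pattern between two loci (peak height 1)."""
    return _gauss2d(size, pos_xy[0] * size, pos_xy[1] * size, sigma_px) - _gauss2d(
        size, neg_xy[0] * size, neg_xy[1] * size, sigma_px
    )


def _orthonormal_modulations(pat_s, pat_u, base):
    """Build orthogonal, base-supported modulation carriers.

    The raw carriers are base-weighted contrast patterns (pointwise
    bounded by the base density, so modulated densities stay
    nonnegative).  Equal-gain circular geometry additionally requires
    the two carriers to form an orthogonal pair of equal L2 norm,
    orthogonal also to the centered base density — otherwise the
    correlation distance between two conditions would depend on their
    axis, not only on their angular separation.  Both maps are
    zero-integral; the common scale is set so that a gain of 1 is the
    nonnegativity limit (the strongest pointwise modulation equals the
    base density there).
    """
    bc = base - base.mean()
    bn2 = float(bc.ravel() @ bc.ravel())

    def _prepare(pat):
        m = base * pat
        m = m - m.mean()
        if bn2 > 0:
            m = m - (m.ravel() @ bc.ravel()) / bn2 * bc
        return m

    ms = _prepare(pat_s)
    ms = ms / np.linalg.norm(ms)
    mu = _prepare(pat_u)
    mu = mu - (mu.ravel() @ ms.ravel()) * ms
    mu = mu / np.linalg.norm(mu)
    # joint scale: gain 1 puts the most-modulated pixel exactly at zero
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.maximum(np.abs(ms), np.abs(mu)) / base
    scale = 1.0 / np.nanmax(ratio)
    return ms * scale, mu * scale


def make_subject_model(
    subject_id: str,
    seed: int,
    config: PipelineConfig | None = None,
    cs_plus_angle: float | None = None,
    specific_gain: float = 0.0,
    unspecific_gain: float = 0.0,
    fixations_per_trial: tuple = (3, 6),
    modulation_loci: dict | None = None,
    idiosyncrasy: float = 1.0,
    post_learning: bool = False,
    effect_onset_ms: float | None = None,
) -> SubjectGazeModel:
    """Build a subject's gaze model with idiosyncratic base density.

    ``idiosyncrasy`` scales the subject-specific jitter of component
    positions and weights (0 disables it).  ``modulation_loci`` overrides
    the dipole positions of the specific/unspecific modulation maps
    (crop-relative (x, y) pairs), e.g. to confine or move the injected
    effect for localization tests.
    """
    if config is None:
        config = PipelineConfig()
    if specific_gain < 0 or unspecific_gain < 0:
        raise ValueError("modulation gains must be >= 0")
    rng = np.random.default_rng(seed)
    n = config.crop_size

    base = np.zeros((n, n))
    names = list(_BASE_COMPONENTS)
    raw_w = np.array([_BASE_COMPONENTS[k][3] for k in names])
    # Dirichlet jitter around the canonical weights
    w = rng.dirichlet(raw_w * (60.0 / max(idiosyncrasy, 1e-9))) if idiosyncrasy else raw_w
    for k, wk in zip(names, w / w.sum()):
        cx, cy, sig, _ = _BASE_COMPONENTS[k]
        jx, jy = rng.normal(0.0, 0.02 * idiosyncrasy, size=2)
        base += wk * _gauss2d(n, (cx + jx) * n, (cy + jy) * n, sig * n)
    base /= base.sum()
    base = (1.0 - _UNIFORM_FLOOR) * base + _UNIFORM_FLOOR / base.size

    loci = dict(_MOD_LOCI)
    if modulation_loci:
        loci.update(modulation_loci)
    sigma_mod = 0.06 * n
    mod_s, mod_u = _orthonormal_modulations(
        _dipole(n, *loci["specific"], sigma_mod),
        _dipole(n, *loci["unspecific"], sigma_mod),
        base,
    )

    if cs_plus_angle is None:
        cs_plus_angle = float(rng.choice(FACE_ANGLES))

    return SubjectGazeModel(
        subject_id=subject_id,
        cs_plus_angle=float(cs_plus_angle),
        base_density=base,
        mod_specific=mod_s,
        mod_unspecific=mod_u,
        specific_gain=float(specific_gain),
        unspecific_gain=float(unspecific_gain),
        fixations_per_trial=tuple(fixations_per_trial),
        post_learning=post_learning,
        effect_onset_ms=effect_onset_ms,
    )


def _sample_positions(density, n, rng, config):
    """Draw n fixation positions (screen coords) from a density grid."""
    flat = density.ravel()
    cdf = np.cumsum(flat)
    cdf /= cdf[-1]
    idx = np.searchsorted(cdf, rng.random(n))
    rows, cols = np.unravel_index(idx, density.shape)
    x0, y0 = config.crop_origin
    x = x0 + cols + rng.random(n)
    y = y0 + rows + rng.random(n)
    return x, y


def _sample_timings(n, rng, stim_ms, median_ms=250.0, gap_ms=30.0):
    """Log-normal fixation durations packed into the stimulus window."""
    dur = rng.lognormal(mean=np.log(median_ms), sigma=0.35, size=n)
    budget = stim_ms - n * gap_ms
    if dur.sum() > budget:
        dur *= budget / dur.sum()
    starts = np.concatenate([[gap_ms], gap_ms + dur[:-1]]).cumsum()
    stops = np.minimum(starts + dur, stim_ms)  # guard float rounding
    return starts, stops


def sample_fixations(
    model: SubjectGazeModel,
    sequence: TrialSequence,
    seed: int,
    config: PipelineConfig | None = None,
) -> list:
    """Sample fixation events for every face trial of one run.

    Null, oddball and reinforced (UCS) trials yield no face fixations.
    Conditioning-run labels ``cs_plus``/``cs_minus`` are resolved to the
    subject's own faces.  Positions are i.i.d. draws from the condition
    density; durations are log-normal (median 250 ms), packed to fit the
    stimulus duration, with ranks 1..n per trial.
    """
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(seed)
    stim_ms = config.stim_duration_ms
    nmin, nmax = model.fixations_per_trial

    # resolve and cache condition densities once per distinct face
    cache: dict = {}

    def density_for(cond: str):
        if cond not in cache:
            if cond == "cs_plus":
                angle = model.cs_plus_angle
            elif cond == "cs_minus":
                angle = model.cs_minus_angle
            else:
                angle = float(cond.split("_", 1)[1])
            cache[cond] = model.condition_density(angle)
        return cache[cond]

    events = []
    for trial in sequence.trials:
        cond = trial.condition
        if trial.reinforced or cond in ("null", "oddball", "ucs"):
            continue
        if not (cond.startswith("face_") or cond in ("cs_plus", "cs_minus")):
            continue
        n = int(rng.integers(nmin, nmax + 1)) if nmax > nmin else int(nmin)
        start, stop = _sample_timings(n, rng, stim_ms)
        if model.effect_onset_ms is None:
            x, y = _sample_positions(density_for(cond), n, rng, config)
        else:
            # early fixations come from the unmodulated base density
            late = start >= model.effect_onset_ms
            x = np.empty(n)
            y = np.empty(n)
            if (~late).any():
                xb, yb = _sample_positions(
                    model.base_density, int((~late).sum()), rng, config
                )
                x[~late], y[~late] = xb, yb
            if late.any():
                xl, yl = _sample_positions(
                    density_for(cond), int(late.sum()), rng, config
                )
                x[late], y[late] = xl, yl
        if cond == "cs_plus":
            label = face_condition(model.cs_plus_angle)
        elif cond == "cs_minus":
            label = face_condition(model.cs_minus_angle)
        else:
            label = cond
        for k in range(n):
            events.append(
                FixationEvent(
                    subject_id=model.subject_id, phase=sequence.phase,
                    run=sequence.run, trial=trial.index, condition=label,
                    x=float(x[k]), y=float(y[k]),
                    start=float(start[k]), stop=float(stop[k]), rank=k + 1,
                    in_crop=config.in_crop(float(x[k]), float(y[k])),
                )
            )
    return events


def simulate_subject_events(
    model_base: SubjectGazeModel,
    model_gen: SubjectGazeModel,
    seed: int,
    config: PipelineConfig | None = None,
    n_generalization_runs: int = 3,
    include_conditioning: bool = False,
) -> list:
    """Full event stream of one subject: baseline run + generalization runs."""
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(seed)
    events = []
    seq = generate_trial_sequence("baseline", 1, int(rng.integers(2**31)), config)
    events += sample_fixations(model_base, seq, int(rng.integers(2**31)), config)
    if include_conditioning:
        seq = generate_trial_sequence("conditioning", 1, int(rng.integers(2**31)), config)
        events += sample_fixations(model_gen, seq, int(rng.integers(2**31)), config)
    for run in range(1, n_generalization_runs + 1):
        seq = generate_trial_sequence("generalization", run, int(rng.integers(2**31)), config)
        events += sample_fixations(model_gen, seq, int(rng.integers(2**31)), config)
    return events


def generate_ratings_scr(
    alpha: float,
    sigma_deg: float,
    offset: float,
    noise_sd: float,
    n_subjects: int,
    seed: int,
    phase: str = "generalization",
    cs_plus_angles=None,
    scr_null_level: float = 0.1,
) -> tuple:
    """Gaussian-tuned shock-expectancy ratings and SCR condition tables.

    Per subject, responses at signed angular distances x in {0, +/-45,
    +/-90, +/-135, 180} follow D(x) = offset + G(x | alpha, sigma) +
    N(0, noise_sd).  The SCR table additionally carries a null-condition
    baseline level.  Returns ``(ratings, scr, truth)`` where the tables
    use raw face-condition labels resolved per subject's CS+.
    """
    if sigma_deg <= 0:
        raise ValueError("sigma_deg must be > 0")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    if cs_plus_angles is None:
        cs_plus_angles = [FACE_ANGLES[i % 8] for i in range(n_subjects)]
    ratings, scr = [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        cs = float(cs_plus_angles[i])
        for angle in FACE_ANGLES:
            x = signed_angle(angle, cs)
            mu = offset + gaussian_tuning(x, alpha, sigma_deg)
            ratings.append(
                {"subject_id": sid, "phase": phase,
                 "condition": face_condition(angle),
                 "rating": mu + rng.normal(0.0, noise_sd)}
            )
            scr.append(
                {"subject_id": sid, "phase": phase, "run": 1, "trial": -1,
                 "condition": face_condition(angle),
                 "phasic_amp": max(0.0, mu + rng.normal(0.0, noise_sd))}
            )
        scr.append(
            {"subject_id": sid, "phase": phase, "run": 1, "trial": -1,
             "condition": "null",
             "phasic_amp": max(0.0, scr_null_level + rng.normal(0.0, noise_sd))}
        )
    truth = {
        "alpha": alpha, "sigma_deg": sigma_deg, "offset": offset,
        "noise_sd": noise_sd, "n_subjects": n_subjects,
        "cs_plus_angles": [float(a) for a in cs_plus_angles],
    }
    return pd.DataFrame(ratings), pd.DataFrame(scr), truth


@dataclass
class Cohort:
    """A fully simulated study with its ground truth."""

    events: list
    ratings: pd.DataFrame
    scr: pd.DataFrame
    models_base: list = field(default_factory=list)
    models_gen: list = field(default_factory=list)
    truth: dict = field(default_factory=dict)

    @property
    def subjects(self):
        return [m.subject_id for m in self.models_base]


def simulate_cohort(
    n_subjects: int,
    seed: int,
    config: PipelineConfig | None = None,
    base_gain: float = 0.5,
    anisotropy: float = 0.35,
    rating_alpha: float = 4.0,
    rating_sigma_deg: float = 45.0,
    rating_offset: float = 2.0,
    rating_noise_sd: float = 1.0,
    n_generalization_runs: int = 3,
    fixations_per_trial: tuple = (3, 6),
    modulation_loci: dict | None = None,
) -> Cohort:
    """Simulate a full cohort with known anisotropy ground truth.

    Baseline gaze geometry is circular (equal gains ``base_gain``); after
    learning the specific gain rises by ``anisotropy`` while the
    unspecific gain stays put.  CS+ faces are counterbalanced across
    subjects.  Ratings/SCR follow a Gaussian tuning with amplitude
    ``rating_alpha`` in the generalization phase and a flat profile at
    baseline.
    """
    if config is None:
        config = PipelineConfig()
    rng = np.random.default_rng(seed)
    cs_angles = [FACE_ANGLES[i % 8] for i in range(n_subjects)]
    models_base, models_gen, events = [], [], []
    for i in range(n_subjects):
        sid = f"S{i + 1:03d}"
        mseed = int(rng.integers(2**31))
        kwargs = dict(
            config=config, cs_plus_angle=cs_angles[i],
            fixations_per_trial=fixations_per_trial,
            modulation_loci=modulation_loci,
        )
        mb = make_subject_model(
            sid, mseed, specific_gain=base_gain, unspecific_gain=base_gain,
            **kwargs,
        )
        mg = make_subject_model(
            sid, mseed, specific_gain=base_gain + anisotropy,
            unspecific_gain=base_gain, post_learning=True, **kwargs,
        )
        models_base.append(mb)
        models_gen.append(mg)
        events += simulate_subject_events(
            mb, mg, int(rng.integers(2**31)), config,
            n_generalization_runs=n_generalization_runs,
        )
    rat_g, scr_g, _ = generate_ratings_scr(
        rating_alpha, rating_sigma_deg, rating_offset, rating_noise_sd,
        n_subjects, int(rng.integers(2**31)), phase="generalization",
        cs_plus_angles=cs_angles,
    )
    rat_b, scr_b, _ = generate_ratings_scr(
        0.0, rating_sigma_deg, rating_offset, rating_noise_sd,
        n_subjects, int(rng.integers(2**31)), phase="baseline",
        cs_plus_angles=cs_angles,
    )
    truth = {
        "n_subjects": n_subjects, "seed": seed, "base_gain": base_gain,
        "anisotropy_gain": anisotropy, "rating_alpha": rating_alpha,
        "rating_sigma_deg": rating_sigma_deg,
        "cs_plus_angles": [float(a) for a in cs_angles],
    }
    return Cohort(
        events=events,
        ratings=pd.concat([rat_b, rat_g], ignore_index=True),
        scr=pd.concat([scr_b, scr_g], ignore_index=True),
        models_base=models_base,
        models_gen=models_gen,
        truth=truth,
    )


def simulate_dissimilarity_cohort(
    n_subjects: int,
    intercept: float,
    w_specific: float,
    w_unspecific: float,
    noise_sd: float,
    seed: int,
    cs_gauss_fwhm_deg: float = 65.0,
    w_gauss: float = 0.0,
    between_sd: float = 0.0,
) -> np.ndarray:
    """Generate per-subject 28-entry dissimilarity vectors directly.

    Bypasses fixation sampling: each subject's vector is built from the
    quadrature predictors with the given weights (optionally jittered
    across subjects with sd ``between_sd``) plus i.i.d. Gaussian noise.
    Returns an (n_subjects, 28) array.  Useful for exact-recovery and
    model-recovery tests where the dissimilarity scale is the target.
    """
    from .models import build_predictors

    pred = build_predictors(cs_gauss_fwhm_deg)
    rng = np.random.default_rng(seed)
    out = np.empty((n_subjects, pred.specific.size))
    for i in range(n_subjects):
        ws = w_specific + (rng.normal(0, between_sd) if between_sd else 0.0)
        wu = w_unspecific + (rng.normal(0, between_sd) if between_sd else 0.0)
        mu = intercept + ws * pred.specific + wu * pred.unspecific
        if w_gauss:
            mu = mu + w_gauss * pred.cs_gauss
        out[i] = mu + rng.normal(0.0, noise_sd, size=mu.size)
    return out
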