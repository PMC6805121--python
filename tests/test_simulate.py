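"""Synthetic gaze generator: density geometry, sampling, tuning tables."""

import numpy as np
import pytest

from fpsa.config import PipelineConfig
from fpsa.design import generate_trial_sequence
from fpsa.simulate import (
    generate_ratings_scr,
    gaussian_tuning,
    make_subject_model,
    sample_fixations,
    signed_angle,
)


def _dissim(a, b):
    return 1.0 - np.corrcoef(a.ravel(), b.ravel())[0, 1]


def test_zero_gains_give_identical_densities(flat_model, angles):
    for a in angles:
        assert np.allclose(
            flat_model.condition_density(a), flat_model.base_density
        )


def test_equal_gains_make_circular_geometry(small_config, angles):
    """With equal gains, density dissimilarity depends only on the
    absolute angular separation of the two conditions."""
    m = make_subject_model(
        "S1", seed=2, config=small_config,
        specific_gain=0.2, unspecific_gain=0.2, cs_plus_angle=0.0,
    )
    dens = {a: m.condition_density(a) for a in angles}
    by_sep = {}
    for i, ai in enumerate(angles):
        for aj in angles[:i]:
            sep = abs(signed_angle(ai, aj))
            by_sep.setdefault(sep, []).append(_dissim(dens[ai], dens[aj]))
    seps = sorted(by_sep)
    means = [np.mean(by_sep[s]) for s in seps]
    # within-separation spread is tiny compared to between-separation
    for s in seps:
        assert np.ptp(by_sep[s]) < 0.02 * means[-1] + 1e-12
    # and dissimilarity grows with separation up to 180 degrees
    assert np.all(np.diff(means) > 0)


def test_anisotropic_gains_separate_cs_axis_more(small_config):
    m = make_subject_model(
        "S1", seed=2, config=small_config,
        specific_gain=0.4, unspecific_gain=0.2, cs_plus_angle=0.0,
    )
    d_cs = _dissim(m.condition_density(0.0), m.condition_density(180.0))
    d_orth = _dissim(m.condition_density(90.0), m.condition_density(270.0))
    assert d_cs > d_orth


def test_densities_valid_for_admissible_gains(small_config):
    for gains in [(0.0, 0.0), (0.3, 0.1), (1.5, 1.5)]:
        m = make_subject_model(
            "S1", seed=9, config=small_config,
            specific_gain=gains[0], unspecific_gain=gains[1],
        )
        for a in range(0, 360, 45):
            d = m.condition_density(a)
            assert np.all(d >= 0)
            assert d.sum() == pytest.approx(1.0, abs=1e-9)


def test_negative_gain_rejected(small_config):
    with pytest.raises(ValueError, match="gain"):
        make_subject_model("S1", 1, small_config, specific_gain=-0.1)


def test_sampling_converges_to_target_density(small_config):
    """Empirical histogram of 1e6 draws matches the target density to
    L1 distance 0.02 after aggregating to 20x20 blocks."""
    m = make_subject_model(
        "S1", seed=4, config=small_config,
        specific_gain=0.3, unspecific_gain=0.15, cs_plus_angle=45.0,
    )
    target = m.condition_density(45.0)
    rng = np.random.default_rng(0)
    n = 1_000_000
    flat = target.ravel()
    cdf = np.cumsum(flat)
    idx = np.searchsorted(cdf / cdf[-1], rng.random(n))
    hist = np.bincount(idx, minlength=flat.size).astype(float) / n
    k = small_config.crop_size // 20
    emp = hist.reshape(100, 100).reshape(20, k, 20, k).sum(axis=(1, 3))
    tgt = target.reshape(20, k, 20, k).sum(axis=(1, 3))
    assert np.abs(emp - tgt).sum() < 0.02


def test_fixation_events_structure(small_config):
    m = make_subject_model(
        "S1", seed=6, config=small_config,
        specific_gain=0.2, unspecific_gain=0.2,
        fixations_per_trial=(4, 4),
    )
    seq = generate_trial_sequence("baseline", 1, seed=0, config=small_config)
    events = sample_fixations(m, seq, seed=1, config=small_config)
    by_trial = {}
    for e in events:
        by_trial.setdefault(e.trial, []).append(e)
    face_trials = [t for t in seq.trials if t.condition.startswith("face_")]
    assert len(by_trial) == len(face_trials)
    for trial_events in by_trial.values():
        assert sorted(e.rank for e in trial_events) == [1, 2, 3, 4]
        for e in trial_events:
            assert 0 <= e.start < e.stop <= small_config.stim_duration_ms
    # null/oddball/ucs trials yield nothing
    non_face = {t.index for t in seq.trials if not t.condition.startswith("face_")}
    assert not non_face & set(by_trial)


def test_sampling_reproducible(small_config, flat_model):
    seq = generate_trial_sequence("baseline", 1, seed=0, config=small_config)
    a = sample_fixations(flat_model, seq, seed=3, config=small_config)
    b = sample_fixations(flat_model, seq, seed=3, config=small_config)
    assert [(e.x, e.y, e.start) for e in a] == [(e.x, e.y, e.start) for e in b]


def test_effect_onset_gates_modulation(small_config):
    """With an effect onset, early fixations follow the base density and
    late fixations the modulated condition density."""
    m = make_subject_model(
        "S1", seed=6, config=small_config, cs_plus_angle=0.0,
        specific_gain=1.0, unspecific_gain=0.0,
        fixations_per_trial=(5, 5), effect_onset_ms=750.0,
        idiosyncrasy=0.0,
    )
    early_pts, late_pts = [], []
    for run in range(12):
        seq = generate_trial_sequence("baseline", 1, seed=run, config=small_config)
        for e in sample_fixations(m, seq, seed=100 + run, config=small_config):
            if e.condition != "face_0":
                continue
            lx, ly = small_config.to_local(e.x, e.y)
            (early_pts if e.start < 750.0 else late_pts).append(
                (int(ly), int(lx))
            )

    # per-fixation log density ratio (condition vs base): positive in
    # expectation for draws from the condition density, negative for
    # draws from the base density
    cond = m.condition_density(0.0)
    base = m.base_density
    def mean_llr(pts):
        idx = np.array(pts)
        return float(
            np.mean(np.log(cond[idx[:, 0], idx[:, 1]])
                    - np.log(base[idx[:, 0], idx[:, 1]]))
        )
    assert mean_llr(late_pts) > 0.0
    assert mean_llr(early_pts) < mean_llr(late_pts)
    assert mean_llr(early_pts) <= 0.005  # base draws: E[llr] = -KL < 0


def test_ratings_noiseless_exact():
    ratings, scr, truth = generate_ratings_scr(
        alpha=1.0, sigma_deg=45.0, offset=0.5, noise_sd=0.0,
        n_subjects=3, seed=0,
    )
    for sid, cs in zip(ratings["subject_id"].unique(), truth["cs_plus_angles"]):
        sub = ratings[ratings["subject_id"] == sid]
        for _, row in sub.iterrows():
            ang = float(row["condition"].split("_")[1])
            x = signed_angle(ang, cs)
            assert row["rating"] == pytest.approx(
                0.5 + gaussian_tuning(x, 1.0, 45.0), abs=1e-12
            )
    assert (scr[scr["condition"] == "null"]["phasic_amp"] > 0).all()


def test_flat_ratings_when_alpha_zero():
    ratings, _, _ = generate_ratings_scr(0.0, 45.0, 2.0, 0.0, 2, seed=1)
    assert ratings["rating"].nunique() == 1


def test_invalid_tuning_parameters_rejected():
    with pytest.raises(ValueError, match="sigma"):
        generate_ratings_scr(1.0, 0.0, 0.0, 0.1, 2, seed=0)
    with pytest.raises(ValueError, match="noise"):
        generate_ratings_scr(1.0, 45.0, 0.0, -0.1, 2, seed=0)
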