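"""Quadrature predictors, subject/group fits, anisotropy statistics."""

import warnings

import numpy as np
import pytest

from fpsa.config import fwhm_to_sigma
from fpsa.models import (
    anisotropy_tuning_correlation,
    build_predictors,
    compare_models,
    exposure_control,
    fit_group_mixed,
    fit_subject,
    gmm_anisotropy,
    lr_test,
    phase_anisotropy_stats,
)
from fpsa.simulate import simulate_dissimilarity_cohort
from fpsa.similarity import ALIGNED_ANGLES, devectorize_lower_triangle

PRED = build_predictors()


def test_quadrature_identity_exact():
    """C = S + U to machine precision (cosine angle-difference formula)."""
    assert np.max(np.abs(PRED.circle - (PRED.specific + PRED.unspecific))) < 1e-12


def test_circle_predictor_values():
    full = devectorize_lower_triangle(PRED.circle, 8)
    x = ALIGNED_ANGLES
    # delta = 0 -> -1 (diagonal is excluded from the vector; check via
    # the formula at identical angles using the matrix completion)
    i0 = 3          # CS+ (0 deg)
    i90 = 5         # +90 deg
    i180 = 7        # 180 deg
    assert full[i0, i90] == pytest.approx(0.0, abs=1e-12)
    assert full[i0, i180] == pytest.approx(1.0, abs=1e-12)
    assert -np.cos(np.deg2rad(x[i0] - x[i0])) == pytest.approx(-1.0)


def test_cs_gauss_sigma_and_shape():
    assert fwhm_to_sigma(PRED.cs_gauss_fwhm_deg) == pytest.approx(27.60, abs=0.01)
    full = devectorize_lower_triangle(PRED.cs_gauss, 8)
    # the CS+-adjacent entry is the most negative (greatest similarity pull)
    i_cs, i_n = 3, 4        # CS+ and its 45-deg neighbor
    off = ~np.eye(8, dtype=bool)
    assert full[i_cs, i_n] == pytest.approx(full[off].min())


def test_exact_linear_recovery_perceptual():
    y = 1.13 + 0.09 * PRED.circle
    fit = fit_subject(y, "perceptual", PRED)
    assert fit.weights["intercept"] == pytest.approx(1.13, abs=1e-10)
    assert fit.weights["circle"] == pytest.approx(0.09, abs=1e-10)
    assert fit.adj_r2 == pytest.approx(1.0, abs=1e-10)


def test_circular_data_gives_zero_anisotropy():
    y = 1.13 + 0.09 * PRED.circle
    fit = fit_subject(y, "adversity", PRED)
    assert fit.weights["specific"] == pytest.approx(0.09, abs=1e-10)
    assert fit.weights["unspecific"] == pytest.approx(0.09, abs=1e-10)
    assert fit.anisotropy == pytest.approx(0.0, abs=1e-10)


def test_exact_linear_recovery_adversity():
    y = 1.2 + 0.13 * PRED.specific + 0.05 * PRED.unspecific
    fit = fit_subject(y, "adversity", PRED)
    assert fit.anisotropy == pytest.approx(0.08, abs=1e-10)


def test_constrained_adversity_equals_perceptual():
    """Fitting specific = unspecific reproduces the perceptual fit."""
    rng = np.random.default_rng(0)
    y = 1.1 + 0.1 * PRED.circle + rng.normal(0, 0.05, PRED.circle.size)
    fp = fit_subject(y, "perceptual", PRED)
    # perceptual weight applied to both quadrature terms reconstructs
    # the same predictions, so the log-likelihoods agree
    pred_p = fp.weights["intercept"] + fp.weights["circle"] * PRED.circle
    pred_c = (
        fp.weights["intercept"]
        + fp.weights["circle"] * PRED.specific
        + fp.weights["circle"] * PRED.unspecific
    )
    assert np.max(np.abs(pred_p - pred_c)) < 1e-10


def test_anisotropy_undefined_for_perceptual():
    fit = fit_subject(1.1 + 0.1 * PRED.circle, "perceptual", PRED)
    with pytest.raises(ValueError, match="anisotropy"):
        fit.anisotropy


def test_mixed_fixed_effects_match_pooled_ols_without_heterogeneity():
    """With zero between-subject variance, ML fixed effects converge to
    the pooled OLS solution."""
    V = simulate_dissimilarity_cohort(
        20, 1.14, 0.13, 0.05, noise_sd=0.05, seed=0, between_sd=0.0
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        mixed = fit_group_mixed(V, "adversity")
    X = PRED.design("adversity")
    beta, _, _, _ = np.linalg.lstsq(np.tile(X, (20, 1)), V.ravel(), rcond=None)
    for i, name in enumerate(("intercept", "specific", "unspecific")):
        assert mixed.weights[name] == pytest.approx(beta[i], abs=1e-6)


def test_model_comparison_table():
    V = simulate_dissimilarity_cohort(
        24, 1.14, 0.13, 0.05, noise_sd=0.05, seed=1, between_sd=0.02
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fits = [fit_group_mixed(V, m) for m in ("null", "perceptual", "adversity")]
    table = compare_models(fits)
    assert list(table["model"])[0] == "adversity"
    assert table["delta_bic"].iloc[0] == 0.0
    dup = compare_models([fits[2], fits[2]])
    assert dup["delta_bic"].iloc[1] == pytest.approx(0.0)
    # LR of adversity vs perceptual is significant under true anisotropy
    assert lr_test(fits[2], fits[1])["p"] < 1e-6
    with pytest.raises(ValueError, match="nested"):
        lr_test(fits[1], fits[2])


def test_adversity_adds_nothing_on_noiseless_circular_data():
    """On perceptual-generated noiseless data the extra quadrature
    freedom explains no additional variance."""
    y = 1.1 + 0.1 * PRED.circle
    p = fit_subject(y, "perceptual", PRED)
    a = fit_subject(y, "adversity", PRED)
    X_p = PRED.design("perceptual")
    X_a = PRED.design("adversity")
    rss_p = np.sum((y - X_p @ [p.weights["intercept"], p.weights["circle"]]) ** 2)
    rss_a = np.sum(
        (y - X_a @ [a.weights["intercept"], a.weights["specific"],
                    a.weights["unspecific"]]) ** 2
    )
    assert rss_p < 1e-20 and rss_a < 1e-20
    assert a.weights["specific"] == pytest.approx(a.weights["unspecific"], abs=1e-9)


def test_phase_anisotropy_identical_phases():
    y = [1.1 + 0.1 * PRED.circle + 0.02 * PRED.specific for _ in range(6)]
    fits = [fit_subject(v, "adversity", PRED) for v in y]
    stats_ = phase_anisotropy_stats(fits, fits)
    assert stats_["anova"]["interaction"]["F"] == pytest.approx(0.0, abs=1e-12)
    assert stats_["prevalence"] == 0  # strict increase required


def test_phase_anisotropy_specific_only_effect():
    rng = np.random.default_rng(2)
    n = 24
    base, gen = [], []
    for _ in range(n):
        noise = lambda: rng.normal(0, 0.03, 28)
        base.append(fit_subject(
            1.1 + 0.09 * PRED.specific + 0.09 * PRED.unspecific + noise(),
            "adversity", PRED))
        gen.append(fit_subject(
            1.1 + 0.17 * PRED.specific + 0.09 * PRED.unspecific + noise(),
            "adversity", PRED))
    res = phase_anisotropy_stats(base, gen)
    assert res["anova"]["interaction"]["p"] < 0.01
    assert res["specific"]["p"] < 0.01
    assert res["unspecific"]["p"] > 0.05
    assert res["prevalence"] > n / 2


def test_exposure_control_trends():
    rng = np.random.default_rng(3)
    n = 12

    def run_fits(wu):
        return [
            fit_subject(
                1.1 + 0.1 * PRED.specific + wu * PRED.unspecific
                + rng.normal(0, 0.02, 28),
                "adversity", PRED,
            )
            for _ in range(n)
        ]

    same = {1: run_fits(0.08), 2: run_fits(0.08), 3: run_fits(0.08)}
    res = exposure_control(same)
    assert abs(res["mean_slope"]) < 0.02
    assert res["ci95"][0] < 0 < res["ci95"][1]

    rising = {r: run_fits(0.05 + 0.04 * r) for r in (1, 2, 3)}
    res2 = exposure_control(rising)
    assert res2["mean_slope"] == pytest.approx(0.04, abs=0.01)
    assert res2["p"] < 0.01

    with pytest.raises(ValueError, match="2 runs"):
        exposure_control({1: same[1]})


def test_gmm_component_selection():
    rng = np.random.default_rng(4)
    single = rng.normal(0.05, 0.1, 200)
    res = gmm_anisotropy(single, k_max=3, seed=0)
    assert res["best_k"] == 1
    assert res["mixing_proportions"].sum() == pytest.approx(1.0, abs=1e-9)
    two = np.concatenate([rng.normal(-1.5, 0.3, 120), rng.normal(1.5, 0.3, 120)])
    res2 = gmm_anisotropy(two, k_max=3, seed=0)
    assert res2["best_k"] == 2


def test_anisotropy_tuning_correlation_bounds():
    x = np.linspace(0, 1, 20)
    assert anisotropy_tuning_correlation(x, x)["r"] == pytest.approx(1.0)
    assert anisotropy_tuning_correlation(x, -x)["r"] == pytest.approx(-1.0)
    with pytest.raises(ValueError, match="variance"):
        anisotropy_tuning_correlation(np.ones(10), x[:10])
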