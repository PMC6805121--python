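"""Quadrature similarity models and their fits.

A circular similarity geometry over 8 equally spaced conditions can be
written as the outer product M (x) M with M = [cos x, sin x], where x is
the angular distance from the CS+.  Splitting the two quadrature terms
gives independent *specific* (cos x_i cos x_j, the CS+/CS- axis) and
*unspecific* (sin x_i sin x_j, the orthogonal axis) components.  Because
the data are dissimilarities, predictors are sign-flipped (-cos form) so
that positive weights mean greater pattern separation along that axis;
the intercept absorbs the constant.  The CS+ attraction component is a
2D Gaussian on angular distances centered on the CS+, sign-flipped so a
positive weight means increased CS+-local similarity.

Models (nested chain):

- ``null``          intercept only
- ``perceptual``    intercept + circular (specific + unspecific, equal)
- ``adversity``     intercept + specific + unspecific
- ``cs_attraction`` adversity + CS+ Gaussian (FWHM 65 deg default)

``anisotropy = w_specific - w_unspecific`` quantifies selective
separation along the adversity axis.  Subject-level fits are OLS on the
28-entry vectorized dissimilarities; group-level fits are linear mixed
models with per-subject random intercept and slopes, estimated by
maximum likelihood so BIC/likelihood ratios are comparable across
fixed-effect structures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.mixture import GaussianMixture

from .config import fwhm_to_sigma
from .similarity import ALIGNED_ANGLES, vectorize_lower_triangle

MODEL_NAMES = ("null", "perceptual", "adversity", "cs_attraction")

#: predictors used by each model, in design-matrix order
MODEL_TERMS = {
    "null": (),
    "perceptual": ("circle",),
    "adversity": ("specific", "unspecific"),
    "cs_attraction": ("specific", "unspecific", "cs_gauss"),
}


class FitError(RuntimeError):
    """A model fit failed to converge or is numerically unusable."""


@dataclass(frozen=True)
class SimilarityPredictors:
    """Vectorized (28-entry) model predictors on the aligned circle."""

    circle: np.ndarray
    specific: np.ndarray
    unspecific: np.ndarray
    cs_gauss: np.ndarray
    cs_gauss_fwhm_deg: float

    def term(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def design(self, model: str) -> np.ndarray:
        """Design matrix (intercept first) for a named model."""
        if model not in MODEL_TERMS:
            raise ValueError(f"unknown model {model!r}")
        cols = [np.ones_like(self.circle)]
        cols += [self.term(t) for t in MODEL_TERMS[model]]
        return np.column_stack(cols)


def build_predictors(cs_gauss_fwhm_deg: float = 65.0) -> SimilarityPredictors:
    """Build the quadrature similarity predictors.

    With x_i the signed angular distance of condition i from the CS+:

    - circle:     C_ij = -cos(x_i - x_j)
    - specific:   S_ij = -cos(x_i) cos(x_j)
    - unspecific: U_ij = -sin(x_i) sin(x_j)
    - cs_gauss:   G_ij = -exp(-(x_i^2 + x_j^2) / (2 sigma^2)),
      sigma = FWHM / (2 sqrt(2 ln 2))

    The identity C = S + U holds exactly (cosine angle-difference
    formula), which makes the perceptual model the equal-weights
    constraint of the adversity model.
    """
    if cs_gauss_fwhm_deg <= 0:
        raise ValueError("FWHM must be > 0")
    x = np.deg2rad(ALIGNED_ANGLES)
    ci, cj = np.meshgrid(np.cos(x), np.cos(x), indexing="ij")
    si, sj = np.meshgrid(np.sin(x), np.sin(x), indexing="ij")
    specific = -(ci * cj)
    unspecific = -(si * sj)
    circle = -np.cos(x[:, None] - x[None, :])
    sigma = fwhm_to_sigma(cs_gauss_fwhm_deg)
    xi, xj = np.meshgrid(ALIGNED_ANGLES, ALIGNED_ANGLES, indexing="ij")
    cs_gauss = -np.exp(-(xi**2 + xj**2) / (2.0 * sigma**2))
    return SimilarityPredictors(
        circle=vectorize_lower_triangle(circle),
        specific=vectorize_lower_triangle(specific),
        unspecific=vectorize_lower_triangle(unspecific),
        cs_gauss=vectorize_lower_triangle(cs_gauss),
        cs_gauss_fwhm_deg=float(cs_gauss_fwhm_deg),
    )


@dataclass
class SimilarityModelFit:
    """Result of one similarity-model fit (subject OLS or group mixed)."""

    model: str
    scope: str                      # "subject" or "group-mixed"
    weights: dict                   # intercept + per-term weights
    log_likelihood: float
    bic: float
    adj_r2: float = np.nan
    n_obs: int = 0
    n_params: int = 0
    subject_id: str = ""
    phase: str = ""
    random_effect_var: dict = field(default_factory=dict)
    converged: bool = True

    @property
    def anisotropy(self) -> float:
        """w_specific - w_unspecific; defined for adversity-family fits."""
        if "specific" not in self.weights:
            raise ValueError(
                f"anisotropy undefined for the {self.model!r} model"
            )
        return self.weights["specific"] - self.weights["unspecific"]


def _gaussian_loglik(resid: np.ndarray) -> float:
    """Maximized Gaussian log-likelihood given OLS residuals."""
    n = resid.size
    s2 = float(resid @ resid) / n
    return -0.5 * n * (np.log(2.0 * np.pi * s2) + 1.0)


def fit_subject(
    vector: np.ndarray,
    model: str,
    predictors: SimilarityPredictors | None = None,
    subject_id: str = "",
    phase: str = "",
    max_condition_number: float = 1e8,
) -> SimilarityModelFit:
    """Ordinary least squares fit of one subject's dissimilarity vector.

    Reports ML log-likelihood, BIC (parameter count = regression
    coefficients + residual variance) and adjusted R^2.
    """
    if predictors is None:
        predictors = build_predictors()
    y = np.asarray(vector, dtype=float)
    if not np.all(np.isfinite(y)):
        raise ValueError("dissimilarity vector contains non-finite values")
    X = predictors.design(model)
    if y.size != X.shape[0]:
        raise ValueError(f"expected a vector of length {X.shape[0]}")
    if np.linalg.cond(X) > max_condition_number:
        raise FitError(f"predictor matrix for {model!r} is ill-conditioned")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    n, k = X.shape
    llf = _gaussian_loglik(resid)
    bic = (k + 1) * np.log(n) - 2.0 * llf
    tss = float(((y - y.mean()) ** 2).sum())
    rss = float(resid @ resid)
    adj_r2 = (
        1.0 - (rss / max(n - k, 1)) / (tss / (n - 1)) if tss > 0 else np.nan
    )
    names = ("intercept",) + MODEL_TERMS[model]
    return SimilarityModelFit(
        model=model, scope="subject",
        weights=dict(zip(names, beta.tolist())),
        log_likelihood=llf, bic=bic, adj_r2=adj_r2,
        n_obs=n, n_params=k + 1,
        subject_id=subject_id, phase=phase,
    )


def fit_group_mixed(
    vectors: np.ndarray,
    model: str,
    predictors: SimilarityPredictors | None = None,
    phase: str = "",
) -> SimilarityModelFit:
    """Linear mixed-effects fit across subjects.

    Every predictor (and the intercept) enters as fixed effect and as
    per-subject random effect; estimation is maximum likelihood.  On a
    singular random-effects covariance the structure is reduced to a
    random intercept with a warning.
    """
    import statsmodels.api as sm

    if predictors is None:
        predictors = build_predictors()
    V = np.asarray(vectors, dtype=float)
    if V.ndim != 2:
        raise ValueError("vectors must be a (subjects, entries) array")
    n_sub, n_entry = V.shape
    if n_sub < 5:
        raise ValueError("need at least 5 subjects for a mixed fit")
    Xs = predictors.design(model)
    X = np.tile(Xs, (n_sub, 1))
    y = V.ravel()
    groups = np.repeat(np.arange(n_sub), n_entry)
    names = ("intercept",) + MODEL_TERMS[model]

    def _run(exog_re):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            m = sm.regression.mixed_linear_model.MixedLM(
                y, X, groups=groups, exog_re=exog_re
            )
            return m.fit(reml=False, method=["lbfgs", "powell"], maxiter=500)

    reduced = False
    res = _run(X)
    cov = np.atleast_2d(res.cov_re)
    if (not res.converged) or np.linalg.matrix_rank(cov) < cov.shape[0]:
        warnings.warn(
            "singular or non-converged random-effects covariance; "
            "falling back to a random-intercept structure",
            RuntimeWarning, stacklevel=2,
        )
        reduced = True
        res = _run(X[:, :1])
        if not res.converged:
            raise FitError(f"mixed model {model!r} did not converge")

    k_fixed = X.shape[1]
    n_re = 1 if reduced else k_fixed
    k_total = k_fixed + n_re * (n_re + 1) // 2 + 1  # + residual variance
    llf = float(res.llf)
    weights = np.asarray(res.fe_params)
    re_cov = np.atleast_2d(res.cov_re)
    if not np.isfinite(llf):
        # random-effect variance at the zero boundary: the mixed model
        # degenerates to pooled OLS, whose likelihood is the correct limit
        beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
        llf = _gaussian_loglik(y - X @ beta)
        weights = beta
        re_cov = np.zeros_like(re_cov)
    bic = k_total * np.log(y.size) - 2.0 * llf
    re_names = names[: re_cov.shape[0]]
    return SimilarityModelFit(
        model=model, scope="group-mixed",
        weights=dict(zip(names, weights.tolist())),
        log_likelihood=llf, bic=bic,
        n_obs=y.size, n_params=k_total, phase=phase,
        random_effect_var={
            nm: float(re_cov[i, i]) for i, nm in enumerate(re_names)
        },
        converged=bool(res.converged),
    )


def compare_models(fits: list) -> pd.DataFrame:
    """Rank fits by BIC and run LR tests between nested neighbors.

    All fits must be on identical data (same scope and observation
    count).  Returns a table sorted by BIC with ``delta_bic`` relative to
    the best model and, for each fit, the likelihood-ratio test against
    the largest nested sub-model present.
    """
    if not fits:
        raise ValueError("no fits to compare")
    scopes = {f.scope for f in fits}
    nobs = {f.n_obs for f in fits}
    if len(scopes) > 1 or len(nobs) > 1:
        raise ValueError("fits are not on identical data")
    order = {m: i for i, m in enumerate(MODEL_NAMES)}
    by_model = {f.model: f for f in fits}
    rows = []
    for f in fits:
        nested = [
            by_model[m] for m in MODEL_NAMES
            if m in by_model and order[m] < order[f.model]
        ]
        lr_chi2 = lr_df = lr_p = np.nan
        against = ""
        if nested:
            sub = nested[-1]
            lr_chi2 = 2.0 * (f.log_likelihood - sub.log_likelihood)
            lr_df = f.n_params - sub.n_params
            lr_p = float(stats.chi2.sf(max(lr_chi2, 0.0), lr_df))
            against = sub.model
        rows.append(
            {
                "model": f.model, "bic": f.bic,
                "log_likelihood": f.log_likelihood, "n_params": f.n_params,
                "lr_vs": against, "lr_chi2": lr_chi2, "lr_df": lr_df,
                "lr_p": lr_p,
            }
        )
    df = pd.DataFrame(rows).sort_values("bic").reset_index(drop=True)
    df["delta_bic"] = df["bic"] - df["bic"].iloc[0]
    return df


def lr_test(full: SimilarityModelFit, nested: SimilarityModelFit) -> dict:
    """Likelihood-ratio test of a nested model pair."""
    order = {m: i for i, m in enumerate(MODEL_NAMES)}
    if order[nested.model] >= order[full.model]:
        raise ValueError(
            f"{nested.model!r} is not nested within {full.model!r}"
        )
    chi2 = 2.0 * (full.log_likelihood - nested.log_likelihood)
    df = full.n_params - nested.n_params
    return {
        "chi2": chi2, "df": df,
        "p": float(stats.chi2.sf(max(chi2, 0.0), df)),
    }


def _paired_f(a: np.ndarray, b: np.ndarray):
    """Paired contrast as F(1, n-1) = t^2, with its p-value."""
    d = a - b
    n = d.size
    if np.allclose(d, 0):
        return 0.0, 1.0
    t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
    f = t**2
    return float(f), float(stats.f.sf(f, 1, n - 1))


def phase_anisotropy_stats(
    fits_base: list,
    fits_gen: list,
    learner_mask=None,
) -> dict:
    """Phase x predictor repeated-measures statistics on adversity fits.

    Implements the 2x2 within-subject ANOVA as orthogonal paired
    contrasts (each F(1, n-1) equals the squared paired t of the
    corresponding contrast), plus per-component paired t-tests and the
    prevalence of subjects whose anisotropy increased after learning.
    ``learner_mask`` restricts the prevalence count to a subject subset.
    """
    if len(fits_base) != len(fits_gen) or not fits_base:
        raise ValueError("need matched per-subject fits for both phases")
    ws_b = np.array([f.weights["specific"] for f in fits_base])
    wu_b = np.array([f.weights["unspecific"] for f in fits_base])
    ws_g = np.array([f.weights["specific"] for f in fits_gen])
    wu_g = np.array([f.weights["unspecific"] for f in fits_gen])
    n = ws_b.size

    f_phase, p_phase = _paired_f((ws_g + wu_g) / 2, (ws_b + wu_b) / 2)
    f_pred, p_pred = _paired_f((ws_b + ws_g) / 2, (wu_b + wu_g) / 2)
    f_int, p_int = _paired_f(ws_g - wu_g, ws_b - wu_b)

    def _paired_t(a, b):
        if np.allclose(a, b):
            return 0.0, 1.0
        t, p = stats.ttest_rel(a, b)
        return float(t), float(p)

    t_spec, p_spec = _paired_t(ws_g, ws_b)
    t_unspec, p_unspec = _paired_t(wu_g, wu_b)

    aniso_b = ws_b - wu_b
    aniso_g = ws_g - wu_g
    increased = aniso_g > aniso_b
    mask = np.ones(n, dtype=bool) if learner_mask is None else np.asarray(learner_mask)
    return {
        "n_subjects": n,
        "anova": {
            "phase": {"F": f_phase, "df": (1, n - 1), "p": p_phase},
            "predictor": {"F": f_pred, "df": (1, n - 1), "p": p_pred},
            "interaction": {"F": f_int, "df": (1, n - 1), "p": p_int},
        },
        "specific": {"t": t_spec, "p": p_spec,
                     "mean_base": float(ws_b.mean()), "mean_gen": float(ws_g.mean())},
        "unspecific": {"t": t_unspec, "p": p_unspec,
                       "mean_base": float(wu_b.mean()), "mean_gen": float(wu_g.mean())},
        "anisotropy_base": aniso_b,
        "anisotropy_gen": aniso_g,
        "prevalence": int(increased.sum()),
        "prevalence_fraction": float(increased.mean()),
        "prevalence_learners": int(increased[mask].sum()),
        "n_learners": int(mask.sum()),
    }


def exposure_control(per_run_fits: dict) -> dict:
    """Trend of the unspecific weight across generalization runs.

    ``per_run_fits`` maps run number -> list of per-subject adversity
    fits (same subject order across runs).  Fits a per-subject linear
    slope of w_unspecific on run index and tests the group mean slope
    against zero (one-sample t), with a 95% CI.
    """
    runs = sorted(per_run_fits)
    if len(runs) < 2:
        raise ValueError("need at least 2 runs for a trend test")
    W = np.array(
        [[f.weights["unspecific"] for f in per_run_fits[r]] for r in runs]
    )  # (runs, subjects)
    x = np.array(runs, dtype=float)
    xc = x - x.mean()
    slopes = (xc @ W) / (xc @ xc)
    n = slopes.size
    mean = float(slopes.mean())
    if np.allclose(slopes, slopes.mean()) and np.allclose(W.std(axis=0), 0):
        t, p = (0.0, 1.0) if np.isclose(mean, 0) else (np.inf, 0.0)
    else:
        t, p = stats.ttest_1samp(slopes, 0.0)
    se = slopes.std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
    half = stats.t.ppf(0.975, n - 1) * se if n > 1 else np.nan
    return {
        "runs": runs,
        "mean_weights": W.mean(axis=1),
        "slopes": slopes,
        "mean_slope": mean,
        "t": float(t), "p": float(p),
        "ci95": (mean - half, mean + half),
    }


def gmm_anisotropy(values, k_max: int = 3, seed: int = 0, n_init: int = 5) -> dict:
    """Gaussian-mixture fits of the anisotropy distribution.

    Fits 1..k_max component mixtures with seeded restarts and returns the
    per-k BIC table, the BIC-best k and the best model's mixing
    proportions.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    x = np.asarray(values, dtype=float).reshape(-1, 1)
    if x.size < 10:
        raise ValueError("need at least 10 values for a mixture fit")
    rows, models = [], {}
    for k in range(1, k_max + 1):
        gm = GaussianMixture(
            n_components=k, n_init=n_init, random_state=seed,
            covariance_type="full",
        ).fit(x)
        rows.append({"k": k, "bic": float(gm.bic(x)),
                     "log_likelihood": float(gm.score(x) * x.size)})
        models[k] = gm
    table = pd.DataFrame(rows)
    best_k = int(table.loc[table["bic"].idxmin(), "k"])
    best = models[best_k]
    return {
        "bic_table": table,
        "best_k": best_k,
        "mixing_proportions": best.weights_.copy(),
        "means": best.means_.ravel().copy(),
    }


def anisotropy_tuning_correlation(anisotropy, tuning_amplitude) -> dict:
    """Pearson correlation between FPSA anisotropy and tuning depth."""
    a = np.asarray(anisotropy, dtype=float)
    b = np.asarray(tuning_amplitude, dtype=float)
    if a.size != b.size or a.size < 4:
        raise ValueError("need paired samples with n >= 4")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("non-finite values in correlation input")
    if a.std() == 0 or b.std() == 0:
        raise ValueError("zero variance; correlation undefined")
    r, p = stats.pearsonr(a, b)
    return {"r": float(r), "p": float(p), "n": int(a.size)}
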