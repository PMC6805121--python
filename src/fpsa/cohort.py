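"""Cohort-level summaries and the end-to-end report.

Learner classification (CS+ rating strictly above CS-), prevalence
summaries, the regression of FPSA anisotropy on classical-feature
anisotropies, and a plain-text/markdown report that assembles whatever
stage outputs are present.
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .design import face_condition


def classify_learners(ratings: pd.DataFrame, cs_plus_angles: dict,
                      phase: str = "generalization") -> pd.DataFrame:
    """Flag subjects whose shock-expectancy ratings show learning.

    A subject is a learner iff their mean CS+ rating strictly exceeds
    their mean CS- rating in the given phase (ties are non-learners).
    """
    out = []
    sub = ratings[ratings["phase"] == phase]
    for sid, cs in sorted(cs_plus_angles.items()):
        mine = sub[sub["subject_id"] == sid]
        cs_cond = face_condition(cs)
        csm_cond = face_condition((cs + 180.0) % 360.0)
        plus = mine[mine["condition"] == cs_cond]["rating"]
        minus = mine[mine["condition"] == csm_cond]["rating"]
        if plus.empty or minus.empty:
            raise ValueError(f"subject {sid}: missing CS+ or CS- ratings")
        out.append(
            {
                "subject_id": sid,
                "cs_plus_rating": float(plus.mean()),
                "cs_minus_rating": float(minus.mean()),
                "learner": bool(plus.mean() > minus.mean()),
            }
        )
    return pd.DataFrame(out)


def feature_anisotropy_regression(
    feature_anisotropies: pd.DataFrame,
    fpsa_anisotropy: np.ndarray,
) -> dict:
    """Regress FPSA anisotropy on classical-feature anisotropies.

    ``feature_anisotropies`` holds one row per subject with one column
    per feature (each the specific-minus-unspecific contrast of that
    feature).  Constant columns are dropped with a warning.  Returns the
    overall F test, adjusted R^2 and the per-feature coefficient table.
    """
    import statsmodels.api as sm

    y = np.asarray(fpsa_anisotropy, dtype=float)
    X = feature_anisotropies.copy()
    if len(X) != y.size:
        raise ValueError("feature table and anisotropy vector disagree in n")
    dropped = [
        c for c in X.columns
        if X[c].std(ddof=0) <= 1e-12 * max(1.0, abs(float(X[c].mean())))
    ]
    if dropped:
        warnings.warn(
            f"dropping constant feature column(s): {', '.join(dropped)}",
            RuntimeWarning, stacklevel=2,
        )
        X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise ValueError("no non-constant features remain")
    design = sm.add_constant(X.to_numpy())
    res = sm.OLS(y, design).fit()
    coefs = pd.DataFrame(
        {
            "feature": ["intercept"] + list(X.columns),
            "coef": res.params,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    return {
        "F": float(res.fvalue),
        "df": (int(res.df_model), int(res.df_resid)),
        "p": float(res.f_pvalue),
        "adj_r2": float(res.rsquared_adj),
        "coefficients": coefs,
        "dropped": dropped,
    }


def prevalence_summary(anisotropy_base, anisotropy_gen,
                       learner_mask=None) -> dict:
    """Counts of subjects whose anisotropy increased after learning."""
    a = np.asarray(anisotropy_base, dtype=float)
    g = np.asarray(anisotropy_gen, dtype=float)
    inc = g > a
    mask = np.ones(a.size, dtype=bool) if learner_mask is None else np.asarray(learner_mask)
    t, p = (0.0, 1.0) if np.allclose(g, a) else stats.ttest_rel(g, a)
    return {
        "n_subjects": int(a.size),
        "n_increased": int(inc.sum()),
        "fraction_increased": float(inc.mean()),
        "n_learners": int(mask.sum()),
        "n_increased_learners": int(inc[mask].sum()),
        "mean_delta": float((g - a).mean()),
        "t": float(t), "p": float(p),
    }


def build_report(stage_outputs: dict, out_dir,
                 config: PipelineConfig | None = None) -> Path:
    """Assemble a markdown report from whatever stage outputs exist.

    ``stage_outputs`` may hold any of: ``dissimilarity`` (table),
    ``mds`` (table), ``model_comparison`` (table), ``anisotropy``
    (dict), ``tuning`` (table), ``decoding`` (table), ``timecourse``
    (table), ``searchlight_roi`` (table), ``classical`` (table).
    Missing stages are listed as absent; the report always builds.
    Tables are written alongside the report; the config hash is
    embedded for provenance.
    """
    if config is None:
        config = PipelineConfig()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sections = [
        ("dissimilarity", "Dissimilarity matrices"),
        ("mds", "MDS embedding"),
        ("model_comparison", "Similarity-model comparison"),
        ("anisotropy", "Anisotropy statistics"),
        ("tuning", "Tuning fits"),
        ("decoding", "Decoder accuracies"),
        ("timecourse", "Temporal FPSA"),
        ("searchlight_roi", "Searchlight ROI contrasts"),
        ("classical", "Classical gaze features"),
    ]
    lines = [
        "# Fixation-pattern similarity analysis report",
        "",
        f"config hash: `{config.content_hash()}`",
        "",
    ]
    for key, title in sections:
        lines.append(f"## {title}")
        lines.append("")
        if key not in stage_outputs or stage_outputs[key] is None:
            lines.append("_absent_")
            lines.append("")
            continue
        value = stage_outputs[key]
        if isinstance(value, pd.DataFrame):
            path = out_dir / f"{key}.tsv"
            value.to_csv(path, sep="\t", index=False)
            lines.append(f"table: `{path.name}` ({len(value)} rows)")
            lines.append("")
            lines.append(value.head(12).to_markdown(index=False))
        elif isinstance(value, dict):
            for k, v in value.items():
                if isinstance(v, (int, float, str, bool)):
                    lines.append(f"- {k}: {v}")
                elif isinstance(v, np.ndarray) and v.size <= 16:
                    lines.append(f"- {k}: {np.array2string(v, precision=4)}")
        else:
            lines.append(str(value))
        lines.append("")
    report = out_dir / "report.md"
    report.write_text("\n".join(lines))
    return report
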