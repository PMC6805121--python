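"""Cohort-level summary: learners, prevalence, correlations, report.

Classifies learners from ratings, summarizes anisotropy prevalence,
correlates FPSA anisotropy with tuning depth, regresses anisotropy on
classical-feature contrasts, and assembles the markdown report from all
stage outputs present in results/.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from fpsa.config import PipelineConfig
from fpsa.cohort import (
    build_report,
    classify_learners,
    feature_anisotropy_regression,
    prevalence_summary,
)
from fpsa.io import read_table
from fpsa.models import anisotropy_tuning_correlation
from fpsa.simulate import signed_angle


def feature_contrasts(features, cs_angles):
    """Specific-minus-unspecific contrast per classical feature."""
    rows = []
    for sid, cs in sorted(cs_angles.items()):
        sub = features[(features["subject_id"] == sid)
                       & (features["phase"] == "generalization")]
        by_cond = sub.set_index("condition")
        def pair_mean(a1, a2, col):
            return (by_cond.loc[f"face_{int(a1) % 360}", col]
                    + by_cond.loc[f"face_{int(a2) % 360}", col]) / 2.0
        row = {"subject_id": sid}
        for col in ("n_fixations_z", "mean_duration_z",
                    "mean_saccade_length_z", "fdm_entropy_z"):
            row[col.replace("_z", "_aniso")] = (
                pair_mean(cs, cs + 180, col)
                - pair_mean(cs + 90, cs + 270, col)
            )
        rows.append(row)
    return pd.DataFrame(rows).set_index("subject_id")


def main() -> None:
    config = PipelineConfig.from_yaml(RESULTS / "config.yaml")
    truth = json.loads((RESULTS / "truth.json").read_text())
    cs_angles = {
        f"S{i + 1:03d}": a for i, a in enumerate(truth["cs_plus_angles"])
    }
    ratings = read_table(RESULTS / "ratings.tsv")
    aniso = read_table(RESULTS / "anisotropy.tsv").set_index("subject_id")
    tuning = read_table(RESULTS / "tuning_fits.tsv")
    features = read_table(RESULTS / "classical_features.tsv")

    learners = classify_learners(ratings, cs_angles)
    prev = prevalence_summary(
        aniso["anisotropy_baseline"].to_numpy(),
        aniso["anisotropy_generalization"].to_numpy(),
        learner_mask=learners.set_index("subject_id").loc[
            aniso.index, "learner"].to_numpy(),
    )
    print(f"learners: {learners['learner'].sum()}/{len(learners)}; "
          f"prevalence {prev['n_increased']}/{prev['n_subjects']} "
          f"({prev['n_increased_learners']}/{prev['n_learners']} in learners)")

    gen_tuning = tuning[(tuning["phase"] == "generalization")
                        & (tuning["modality"] == "ratings")]
    amp = gen_tuning.set_index("subject_id").loc[aniso.index, "alpha"]
    corr = anisotropy_tuning_correlation(
        aniso["anisotropy_generalization"].to_numpy(), amp.to_numpy()
    )
    print(f"anisotropy x tuning-depth correlation: r = {corr['r']:.2f}, "
          f"p = {corr['p']:.3f} (n = {corr['n']})")

    contrasts = feature_contrasts(features, cs_angles).loc[aniso.index]
    reg = feature_anisotropy_regression(
        contrasts, aniso["anisotropy_generalization"].to_numpy()
    )
    print(f"classical-feature regression: F({reg['df'][0]}, {reg['df'][1]}) "
          f"= {reg['F']:.2f}, p = {reg['p']:.2f}, "
          f"adj R^2 = {reg['adj_r2']:.2f}")

    stage_outputs = {
        "model_comparison": read_table(RESULTS / "model_comparison.tsv"),
        "anisotropy": {
            "prevalence": prev["n_increased"],
            "n_subjects": prev["n_subjects"],
            "mean_delta": prev["mean_delta"],
            "tuning_correlation_r": corr["r"],
            "tuning_correlation_p": corr["p"],
        },
        "tuning": tuning,
        "decoding": read_table(RESULTS / "decoding.tsv"),
        "timecourse": read_table(RESULTS / "timecourse_contrast.tsv"),
        "searchlight_roi": read_table(RESULTS / "roi_contrast.tsv"),
        "classical": features,
        "mds": read_table(RESULTS / "mds_coordinates.tsv"),
        "dissimilarity": read_table(RESULTS / "dissimilarity_baseline.tsv"),
    }
    path = build_report(stage_outputs, RESULTS / "report", config)
    print(f"report -> {path}")


if __name__ == "__main__":
    sys.exit(main())
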