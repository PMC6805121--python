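"""Decode CS+/CS- and +/-90-degree trials from single-trial FDMs.

Per subject, phase and axis: a PCA-reduced linear SVM with stratified
3-fold cross-validation, plus the covariance-projected activation
pattern of a final all-trials fit.  Writes the accuracy table.
"""

import json
import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from fpsa.config import PipelineConfig
from fpsa.decoding import train_decode_cv
from fpsa.density import build_fdm, select_events
from fpsa.io import read_fixation_table, write_results


def trial_maps(events, config, sid, phase, condition):
    """Single-trial FDMs (stacked) for one condition."""
    sel = select_events(events, subject_id=sid, phase=phase,
                        condition=condition)
    keys = sorted({(e.run, e.trial) for e in sel})
    maps = []
    for run, trial in keys:
        trial_events = [e for e in sel if e.run == run and e.trial == trial]
        try:
            maps.append(build_fdm(trial_events, config).grid)
        except ValueError:
            continue
    return maps


def main() -> None:
    config = PipelineConfig.from_yaml(RESULTS / "config.yaml")
    # the small desk-scale window downscales 5x rather than 10x
    config.decoder_downscale = max(config.crop_size // 50, 1)
    events = read_fixation_table(RESULTS / "fixations.tsv", config)
    truth = json.loads((RESULTS / "truth.json").read_text())
    cs_angles = {
        f"S{i + 1:03d}": a for i, a in enumerate(truth["cs_plus_angles"])
    }

    rows = []
    for sid, cs in sorted(cs_angles.items()):
        axes = {
            "specific": (cs, (cs + 180) % 360),
            "unspecific": ((cs + 90) % 360, (cs + 270) % 360),
        }
        for phase in ("baseline", "generalization"):
            for axis, (a1, a2) in axes.items():
                m1 = trial_maps(events, config, sid, phase, f"face_{int(a1)}")
                m2 = trial_maps(events, config, sid, phase, f"face_{int(a2)}")
                if min(len(m1), len(m2)) < 3:
                    continue
                res = train_decode_cv(
                    np.array(m1 + m2),
                    np.array([0] * len(m1) + [1] * len(m2)),
                    seed=config.seed, config=config,
                    subject_id=sid, phase=phase, axis=axis,
                    with_activation=False,
                )
                rows.append({
                    "subject_id": sid, "phase": phase, "axis": axis,
                    "accuracy": res.accuracy,
                    "n_trials": len(m1) + len(m2),
                    "n_components": int(np.mean(res.n_components)),
                })
    table = pd.DataFrame(rows)
    summary = table.groupby(["phase", "axis"])["accuracy"].mean().unstack()
    print("mean decoding accuracy:")
    print(summary.round(3).to_string())
    write_results({"decoding": table}, RESULTS)


if __name__ == "__main__":
    sys.exit(main())
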