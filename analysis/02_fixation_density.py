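"""Build condition FDMs and classical gaze features for the cohort.

Reads the simulated fixation table, builds per-(subject, phase,
condition) fixation density maps, and writes ROI density shares plus
the z-scored classical features (fixation count, duration, saccade
length, FDM entropy).
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

ROOT = Path(__file__).resolve().parents[1]
RESULTS = ROOT / "results"

from fpsa.config import PipelineConfig
from fpsa.density import build_fdm, classical_features, roi_share, select_events
from fpsa.io import read_fixation_table, write_results


def main() -> None:
    config = PipelineConfig.from_yaml(RESULTS / "config.yaml")
    events = read_fixation_table(RESULTS / "fixations.tsv", config)
    subjects = sorted({e.subject_id for e in events})

    roi_rows, fdm_store = [], {}
    for sid in subjects:
        for phase in ("baseline", "generalization"):
            for angle in range(0, 360, 45):
                cond = f"face_{angle}"
                sel = select_events(events, subject_id=sid, phase=phase,
                                    condition=cond)
                fdm = build_fdm(sel, config)
                fdm_store[(sid, phase, cond)] = fdm
                shares = roi_share(fdm, config.roi_map, config)
                roi_rows.append(
                    {"subject_id": sid, "phase": phase, "condition": cond,
                     **{f"share_{k}": v for k, v in shares.items()}}
                )
    roi_table = pd.DataFrame(roi_rows)
    features = classical_features(events, fdm_store, config)
    write_results({"roi_shares": roi_table, "classical_features": features},
                  RESULTS)

    eyes = roi_table.filter(like="share_").mean()
    print("mean density share per ROI:")
    print(eyes.round(3).to_string())
    print(f"features table: {len(features)} rows -> classical_features.tsv")


if __name__ == "__main__":
    sys.exit(main())
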