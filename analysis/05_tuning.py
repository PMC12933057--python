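"""Tuning metrics per unit: responsiveness, DSI/OSI, recovery vs truth.

Builds each unit's direction-tuning curve at its best spatial frequency,
tests visual responsiveness (paired rank test + 1 Hz evoked floor), computes
the contrast-form direction and orientation indices, and scores them
against the generator's targets.
"""

import argparse
from pathlib import Path

import pandas as pd

from wavepipe import io as wio
from wavepipe import tuning as tun

TRIAL_S, BASELINE_S = 1.0, 0.5


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    bundle = wio.read_sorted_session(args.results / "session")
    trials = bundle.trials
    rows = []
    for uid, sub in trials.groupby("unit_id"):
        curve = tun.compute_tuning_curve(sub, TRIAL_S, BASELINE_S)
        best_sf = sub.groupby("spatial_frequency")["stimulus_count"].mean().idxmax()
        at_best = sub[sub.spatial_frequency == best_sf]
        responsive, p = tun.responsiveness(
            at_best.stimulus_count, at_best.baseline_count, TRIAL_S, BASELINE_S
        )
        rows.append((uid, curve.preferred_direction_deg, curve.dsi, curve.osi,
                     responsive, p))
    df = pd.DataFrame(rows, columns=["unit_id", "preferred_direction_deg",
                                     "dsi", "osi", "visually_responsive", "p"])
    df.to_csv(args.results / "tuning.tsv", sep="\t", index=False)
    print(f"{df.visually_responsive.mean():.0%} of units visually responsive")

    truth = bundle.ground_truth
    merged = df.merge(truth, on="unit_id")
    for col, target in (("dsi", "dsi_target"), ("osi", "osi_target")):
        err = (merged[col] - merged[target]).abs().median()
        print(f"median |{col} - target| = {err:.3f}")


if __name__ == "__main__":
    main()
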