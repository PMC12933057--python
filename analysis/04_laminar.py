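"""Assign units to layers and test laminar enrichment of each cluster.

Scales depths onto the average layer boundaries, assigns layers, and runs
the 1,000-shuffle enrichment test of each cluster's layer-4 fraction
(L4a/4b + L4c), flagging clusters outside the 1st/99th percentiles of the
shuffled distribution.  Also reports the mean distance of narrow-spiking
units from layer 4 with its 95% CI.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from wavepipe import laminar as lam


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--results", type=Path, default=Path("results"))
    args = ap.parse_args()

    curated = pd.read_csv(args.results / "curated_units.tsv", sep="\t")
    clusters = pd.read_csv(args.results / "clusters.tsv", sep="\t")
    boundaries = pd.read_csv(args.results / "session" / "layer_boundaries.tsv", sep="\t")
    edges = boundaries["top_um"].to_numpy(dtype=float)
    model = lam.LayerModel.from_sessions(
        {"s0": edges}, layer_names=tuple(boundaries["layer"])
    )
    df = clusters.merge(curated, on="unit_id")
    df["scaled_depth_um"] = [
        lam.scale_depth(d, edges, model.average_edges) for d in df.depth_um
    ]
    df["layer"] = [lam.assign_layer(d, model) for d in df.scaled_depth_um]

    rng = np.random.default_rng(args.seed)
    rows = []
    for cname in sorted(df.cluster_name.unique()):
        res = lam.enrichment_shuffle_test(
            df.cluster_name, df.layer, cname, ["L4a/4b", "L4c"],
            n_shuffles=1000, seed=rng,
        )
        rows.append((cname, res.observed, res.flag, res.p_value))
        print(f"{cname}: {res.observed:.0%} in L4 ({res.flag}, P={res.p_value:.3f})")
    pd.DataFrame(rows, columns=["cluster", "frac_in_L4", "flag", "p"]).to_csv(
        args.results / "layer_enrichment.tsv", sep="\t", index=False
    )

    narrow = df[df.cluster_name.str.startswith("NS")]
    if len(narrow):
        mean, ci = lam.distance_from_layer(narrow.scaled_depth_um, model, "L4c")
        print(f"narrow-spiking mean distance from L4c: {mean:.0f} um "
              f"(95% CI {ci[0]:.0f}, {ci[1]:.0f})")
    df.to_csv(args.results / "laminar_units.tsv", sep="\t", index=False)


if __name__ == "__main__":
    main()
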