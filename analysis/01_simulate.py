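"""Build the default six-class synthetic session and write it to disk.

Creates the study population (150 units across cortical layers, 240 s of
spontaneous activity per unit, drifting-grating trials, three planted
coupling edges) in a phy-style directory under results/session/, plus the
ground-truth table the later stages score themselves against.
"""

import argparse
from pathlib import Path

from wavepipe import io as wio
from wavepipe import synthetic as syn


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--seed", type=int, default=0)
    ap.add_argument("--out", type=Path, default=Path("results"))
    args = ap.parse_args()

    session = syn.build_population(syn.default_config(), seed=args.seed)
    out = wio.write_session(session, args.out / "session")
    truth = session.ground_truth
    print(f"wrote session to {out}")
    print(f"{len(session.units)} units, digest {session.digest()[:12]}")
    print(truth.groupby(["class_name", "layer"]).size().unstack(fill_value=0))


if __name__ == "__main__":
    main()
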