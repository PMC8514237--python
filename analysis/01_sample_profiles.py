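#!/usr/bin/env python
"""Draw the study's random composition effect profiles and summarise them.

Each profile (x0, x1, b, alpha) is one hypothetical way soma-role cells
could shorten the cell-doubling time: x0 = soma fraction below which they
are useless, x1 = fraction beyond which the benefit saturates, b = maximal
reduction of the doubling time, alpha = synergy shape between thresholds.

Writes the sampled profiles to results/profiles.csv.
"""

import argparse
from pathlib import Path

from germsoma.experiments import study_profiles
from germsoma.profiles import profiles_to_frame

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--count", type=int, default=300)
    args = ap.parse_args()

    frame = profiles_to_frame(study_profiles(args.seed, args.count))
    RESULTS.mkdir(exist_ok=True)
    out = RESULTS / "profiles.csv"
    frame.to_csv(out, index=False)

    print(f"sampled {len(frame)} composition effect profiles (seed {args.seed})")
    print(frame.describe().loc[["mean", "50%", "min", "max"]].round(3).to_string())
    print(f"-> {out}")


if __name__ == "__main__":
    main()
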