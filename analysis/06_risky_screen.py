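#!/usr/bin/env python
"""The risky-differentiation variant of the cost-plane screen.

Instead of delaying division, each differentiation event here carries a
probability of killing the whole organism (a cancer-like side effect).
The class layout across the (delta_sg, delta_gs) risk plane mirrors the
delay model: the precise cost mechanism matters little for when
irreversible differentiation evolves.

Writes per-profile records and per-cell class fractions under results/.
"""

import argparse
import json
import time
from pathlib import Path

from germsoma.experiments import risk_cost_plane

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--profiles", type=int, default=50)
    ap.add_argument("--n", type=int, default=6)
    args = ap.parse_args()

    t0 = time.time()
    res = risk_cost_plane(args.seed, n=args.n, n_profiles=args.profiles, progress=True)
    RESULTS.mkdir(exist_ok=True)
    res.records.to_csv(RESULTS / "risk_plane_records.csv", index=False)
    res.cells.to_csv(RESULTS / "risk_plane_cells.csv", index=False)
    (RESULTS / "risk_plane_config.json").write_text(json.dumps(res.config, indent=2))

    cols = ["cost_sg", "cost_gs", "frac_irreversible", "frac_reversible",
            "frac_no_differentiation"]
    print(res.cells[cols].rename(
        columns={"cost_sg": "delta_sg", "cost_gs": "delta_gs"}
    ).to_string(index=False))
    print(f"elapsed {time.time() - t0:.0f}s; tables under {RESULTS}/")


if __name__ == "__main__":
    main()
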