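#!/usr/bin/env python
"""Round trip: synthetic peaks -> identification -> normalized fingerprints.

Simulates an apple-pectin digest, synthesizes an LC-MS-like peak table with
9% CV measurement noise, identifies peaks at 0.5 Da tolerance against the
enumerated candidate library, and reports the normalized product profile and
its DP aggregation.  Writes results/roundtrip_profile.csv and
results/roundtrip_dp_aggregation.csv.
"""

from pathlib import Path

import pandas as pd

from pectolyze.profiling import NormalizedProfile, aggregate_by_dp
from pectolyze.workflows import roundtrip_experiment

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rt = roundtrip_experiment(seed=SEED)
    pd.DataFrame(
        [{"compound": k, "normalized_intensity": v} for k, v in sorted(rt.profile.items())]
    ).to_csv(OUT / "roundtrip_profile.csv", index=False)
    normed = NormalizedProfile("sim-enzyme", "apple", 1440.0, rt.profile)
    agg = aggregate_by_dp(normed, split_acetyl=True)
    pd.DataFrame(
        [{"dp": dp, "acetylated": ace, "summed_intensity": v}
         for (dp, ace), v in sorted(agg.items())]
    ).to_csv(OUT / "roundtrip_dp_aggregation.csv", index=False)

    print(f"synthesized {rt.n_synthesized} library-compound peaks; "
          f"recovered {rt.recovery_pct:.1f}% at 0.5 Da")
    print(f"normalized profile max: {rt.normalized_max}")
    print("dominant products (normalized):")
    for name, value in rt.dominant:
        print(f"  {name:18s} {value:6.3f}")


if __name__ == "__main__":
    main()
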