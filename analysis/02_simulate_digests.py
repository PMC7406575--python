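#!/usr/bin/env python
"""Simulate pectin-lyase digests of the four substrate presets.

For apple, citrus, sugar beet and polygalacturonic acid substrates, runs a
seeded subsite-rule digestion (10^4 residues each), tracks product
composition counts over time and the A235 progress curve, and reports the
relative initial rates — the mechanistic analog of the apple > citrus >
sugar beet > PGA activity ranking.  Writes results/digest_products.csv and
results/absorbance_traces.csv.
"""

from pathlib import Path

import pandas as pd

from pectolyze.simulate import (
    CleavageRule,
    absorbance_trace,
    generate_chains,
    initial_total_rate,
    preset_spec,
    simulate_digest,
)

OUT = Path(__file__).resolve().parents[1] / "results"
SEED = 1
TIMES = (0.0, 5.0, 20.0, 120.0, 1440.0)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    rule = CleavageRule()  # rho 0.25, acetyl penalty 0.5
    product_rows, trace_frames, rates = [], [], {}
    for preset in ("apple", "citrus", "sugarbeet", "pga"):
        chains = generate_chains(preset_spec(preset, 100, 100), SEED)
        rates[preset] = initial_total_rate(chains, rule)
        states = simulate_digest(chains, rule, time_points=TIMES, seed=SEED + 1)
        for state in states:
            for comp, count in sorted(state.composition_counts().items()):
                product_rows.append(
                    {"substrate": preset, "time_min": state.time_min, "dp": comp.dp,
                     "n_methyl": comp.n_methyl, "n_acetyl": comp.n_acetyl,
                     "unsaturated": comp.unsaturated, "count": count}
                )
        trace = absorbance_trace(states)
        trace.insert(0, "substrate", preset)
        trace_frames.append(trace)
    pd.DataFrame(product_rows).to_csv(OUT / "digest_products.csv", index=False)
    pd.concat(trace_frames, ignore_index=True).to_csv(OUT / "absorbance_traces.csv", index=False)

    print("initial total cleavable-bond rate by substrate (relative units):")
    for preset, rate in sorted(rates.items(), key=lambda kv: -kv[1]):
        print(f"  {preset:10s} {rate:10.1f}")
    ranked = sorted(rates, key=rates.get, reverse=True)
    print(f"ranking: {' > '.join(ranked)}")


if __name__ == "__main__":
    main()
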