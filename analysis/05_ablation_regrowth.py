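#!/usr/bin/env python
"""Ablation-regrowth kinetics: binned curves, growth rates, recovery.

Simulates ensembles of ablated fibers (8 per condition, cut at t = 0)
with their unablated neighbours, bins lengths by minute, regresses the
first five minutes for the initial growth rate, and normalizes recovery
against the unablated reference.
"""

from pathlib import Path

from kfiber.ablation import (
    RegrowthDataset,
    fraction_recovered,
    group_bin_average,
    initial_growth_rate,
)
from kfiber.synthgen import simulate_ablation_series

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

for label, rate, seed in [("control", 0.85, 20), ("unfocused", 0.38, 21)]:
    ds = RegrowthDataset(
        [simulate_ablation_series(8, 3, rate, 0, 14, 0.5, 0.2, seed * 100 + i,
                                  fiber_id=f"abl{i}") for i in range(8)],
        [simulate_ablation_series(8.0, 7.99, 0.0, 0, 14, 0.5, 0.2, seed * 100 + 50 + i,
                                  fiber_id=f"ctl{i}") for i in range(8)],
        condition=label,
    )
    binned = group_bin_average(ds)
    binned.to_csv(OUT / f"regrowth_binned_{label}.csv")
    rates = initial_growth_rate(ds)
    frac = fraction_recovered(ds)
    frac.to_csv(OUT / f"fraction_recovered_{label}.csv", index=False)
    recovered = frac.loc[frac.p >= 0.05, "minute"]
    first_ns = int(recovered.iloc[0]) if len(recovered) else None
    print(f"{label}: planted rate {rate} µm/min, estimated "
          f"{rates['mean']:.3f} ± {rates['sd']:.3f} (n = {rates['n']}); "
          f"first minute indistinguishable from unablated: {first_ns}")
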