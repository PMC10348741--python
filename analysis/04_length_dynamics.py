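#!/usr/bin/env python
"""Length dynamics: temporal CVs, sister-sum conservation, autocorrelation.

Simulates sister-pair length series for both conditions, computes per-
fiber time-averaged lengths and CVs, sister-sum CVs, the per-fiber
length autocorrelation, and the per-lag Welch comparison between
conditions.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from kfiber.dynamics import (
    autocorr_group_test,
    autocorrelation,
    bin_by_minute,
    series_stats,
    sister_sum_stats,
)
from kfiber.synthgen import simulate_length_series

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

MAX_LAG = 8
acfs, stats_rows = {}, []
for label, cond, n_pairs, seed in [("control", "focused", 26, 10),
                                   ("unfocused", "unfocused", 23, 11)]:
    pairs, _ = simulate_length_series(cond, n_pairs, 15, 0.5, seed)
    fibers = [p.a for p in pairs] + [p.b for p in pairs]
    # raw series are regenerable from the seed; persist the derived tables
    cond_acf = []
    for f in fibers:
        st = series_stats(f)
        stats_rows.append({"condition": label, "fiber_id": f.fiber_id, **st})
        b = bin_by_minute(f)
        cond_acf.append(autocorrelation(b, min(MAX_LAG, len(b.lengths) - 2)))
    acfs[label] = np.array([np.pad(r, (0, MAX_LAG + 1 - len(r)), constant_values=np.nan)
                            for r in cond_acf])
    sum_cvs = [sister_sum_stats(p)["sum_cv"] for p in pairs]
    cvs = [series_stats(f)["cv"] for f in fibers]
    print(f"{label}: time-averaged length "
          f"{np.mean([series_stats(f)['time_mean'] for f in fibers]):.2f} µm; "
          f"CV {np.mean(cvs):.1f}; sister-sum CV {np.mean(sum_cvs):.1f}")

pd.DataFrame(stats_rows).to_csv(OUT / "series_stats.csv", index=False)
res = autocorr_group_test(acfs)
res.to_csv(OUT / "acf_group_test.csv", index=False)
sig = res.loc[(res.lag > 0) & (res.p < 0.05), "lag"].tolist()
print(f"ACF group test: unfocused autocorrelation higher; "
      f"lags significant at p < 0.05: {sig}")
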