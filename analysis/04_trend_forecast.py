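#!/usr/bin/env python
"""Fit and plot the monthly trend with its 2:1 train/test evaluation.

Reads results/monthly_counts.csv (written by 02_run_pipeline.py), fits the
OLS trend on the 24-month training prefix, scores it out of sample on the
12-month suffix alongside the seasonal-naive baseline, writes
results/trend_metrics.csv and a figure under scratch/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

from lyrictrace.forecasting import (evaluate, fit_ols, forecast_adapter,
                                    predict, split_series)

REPO = Path(__file__).resolve().parent.parent
RESULTS = REPO / "results"


def main() -> int:
    path = RESULTS / "monthly_counts.csv"
    if not path.exists():
        print("monthly series missing; run analysis/02_run_pipeline.py first",
              file=sys.stderr)
        return 1
    series = pd.read_csv(path)
    series["t"] = np.arange(len(series))
    split = split_series(series)
    fit = fit_ols(split.train)
    metrics = evaluate(fit, split.test)

    rows = [{"model": "ols", "ratio": "2:1",
             "rmse": round(metrics.rmse, 2), "r2": round(metrics.r2, 5),
             "slope": round(fit.m, 4), "intercept": round(fit.b, 4)}]
    naive = forecast_adapter("seasonal_naive", split.train, len(split.test))
    y = split.test["count"].to_numpy(dtype=float)
    rmse = float(np.sqrt(np.mean((y - naive) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum((y - naive) ** 2)) / ss_tot if ss_tot else None
    rows.append({"model": "seasonal_naive", "ratio": "2:1",
                 "rmse": round(rmse, 2),
                 "r2": round(r2, 5) if r2 is not None else "",
                 "slope": "", "intercept": ""})
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "trend_metrics.csv", index=False)

    print(f"monthly lyric-match series: {len(series)} months, "
          f"{int(series['count'].sum())} matches")
    print(f"fitted trend: count = {fit.m:.4f} * t + {fit.b:.4f} "
          f"({'declining' if fit.m < 0 else 'rising'})")
    print(table.to_string(index=False))

    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.plot(split.train["t"], split.train["count"], "o-", label="train")
    ax.plot(split.test["t"], split.test["count"], "o-", label="test")
    ax.plot(series["t"], predict(fit, series["t"].to_numpy()), "--",
            label=f"OLS fit (m={fit.m:.2f})")
    ax.set_xlabel("month index")
    ax.set_ylabel("lyric matches / month")
    ax.legend()
    fig.tight_layout()
    fig_path = REPO / "scratch" / "trend_fit.png"
    fig_path.parent.mkdir(exist_ok=True)
    fig.savefig(fig_path, dpi=120)
    print(f"figure written to {fig_path}")
    return 0


if __name__ == "__main__":
    sys.exit(main())
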