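#!/usr/bin/env python
"""Validate the MVAR/GPDC estimation chain against analytic ground truth.

Uses synthetic VAR processes where the true GPDC is known in closed form:
(a) estimation error at T = 30,000 over seeds, (b) spurious-edge levels on
independent white noise, (c) AIC order recovery for a VAR(3), and (d) the
mediated-chain effect (bivariate estimates inflate absent direct edges).
"""

import pathlib

import numpy as np
import pandas as pd

from corticonn.mvar import conditioned_gpdc, edge_summary, gpdc, select_order
from corticonn.synthetic import generate_var_truth, sample_var

OUT = pathlib.Path(__file__).resolve().parent.parent / "results" / "estimator"


def estimation_error():
    truth = generate_var_truth(
        [(0, 1, 0.5), (1, 2, 0.4), (2, 0, 0.3)], 3, self_coupling=0.3
    )
    errs = []
    for seed in range(10):
        x = sample_var(truth, 30_000, seed=seed)
        _, model = select_order(x, p_max=10)
        errs.append(np.abs(gpdc(model).values - truth.analytic_gpdc.values).max())
    return pd.DataFrame({"seed": range(10), "max_abs_error": errs})


def null_specificity():
    peaks = []
    off = ~np.eye(10, dtype=bool)
    for seed in range(3):
        x = np.random.default_rng(seed).standard_normal((10, 30_000))
        _, model = select_order(x, p_max=20)
        peaks.append(edge_summary(gpdc(model), "peak")[off])
    return np.percentile(np.concatenate(peaks), 95)


def order_recovery(n_rep=50):
    a = np.zeros((3, 3, 3))
    a[0] = 0.3 * np.eye(3)
    a[0, 1, 0] = 0.4
    a[2] = np.diag([0.25, -0.25, 0.25])
    a[2, 2, 1] = 0.3
    truth = generate_var_truth([], 3, p=3)
    truth = type(truth)(a, np.eye(3), truth.analytic_gpdc, True)
    orders = []
    for seed in range(n_rep):
        x = sample_var(truth, 30_000, seed=100 + seed)
        orders.append(select_order(x, p_max=50)[0])
    return pd.Series(orders)


def mediated_chain(n_rep=100):
    truth = generate_var_truth([(0, 1, 0.6), (1, 2, 0.6)], 3, self_coupling=0.3)
    wins = 0
    for seed in range(n_rep):
        x = sample_var(truth, 5000, seed=200 + seed)
        tri = conditioned_gpdc(x, [0, 1, 2], mode="subset", p_max=5)
        pair = conditioned_gpdc(x, [0, 2], mode="subset", p_max=5)
        wins += pair[1, 0] > tri[2, 0]
    return wins / n_rep


def main():
    OUT.mkdir(parents=True, exist_ok=True)
    err = estimation_error()
    err.to_csv(OUT / "estimation_error.csv", index=False)
    print(f"max |GPDC_est - GPDC_true| over 10 seeds: "
          f"{err['max_abs_error'].max():.4f} (each < 0.05 expected)")

    p95 = null_specificity()
    print(f"white-noise null: 95th pct of off-diagonal peaks = {p95:.4f}")

    orders = order_recovery()
    frac = (orders.sub(3).abs() <= 1).mean()
    orders.value_counts().sort_index().to_csv(OUT / "order_recovery.csv",
                                              header=["count"])
    print(f"VAR(3) order recovery within +-1: {100 * frac:.0f}% of 50 replicates")

    win = mediated_chain()
    print(f"chain x->y->z: bivariate x->z exceeds conditioned x->z in "
          f"{100 * win:.0f}% of 100 seeds")
    pd.DataFrame(
        {"check": ["null_p95", "order_recovery_frac", "chain_inflation_frac"],
         "value": [p95, frac, win]}
    ).to_csv(OUT / "summary.csv", index=False)
    print(f"wrote {OUT}/")


if __name__ == "__main__":
    main()
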