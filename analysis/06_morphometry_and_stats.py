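#!/usr/bin/env python
"""Neurite morphometry recovery, ΔΔCT, and group statistics.

Measures the analytic neurite field (straight, diagonal and Y-tree
neurites), computes relative expression for a synthetic two-group CT
table with a known 4-fold knockdown, and compares three synthetic
conditions by one-way ANOVA with Tukey post-hoc pairs. Finding: chain-
code lengths land within 0.5% of the analytic values, the ΔΔCT control
group sits at relative expression 1 with the treated group at ~0.25, and
the ANOVA separates shifted conditions.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd

from synspread import (
    LabelMap,
    delta_delta_ct,
    generate_neurite_field,
    group_compare,
    measure_neurites,
)

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    results = ROOT / "results"
    results.mkdir(exist_ok=True)

    image, truth = generate_neurite_field()
    lab = np.zeros(image.shape, np.int32)
    rr, cc = np.mgrid[0: image.shape[0], 0: image.shape[1]]
    for _, n in truth.iterrows():
        lab[(rr - n.row) ** 2 + (cc - n.col) ** 2 <= 64.0] = int(n.neuron_id)
    table = measure_neurites(image, "NFH", LabelMap(labels=lab))
    merged = table.merge(truth, on="neuron_id")
    merged.to_csv(results / "morphometry_recovery.csv", index=False)
    err = 100 * np.abs(
        merged["total_tree_length"] - merged["expected_total_um"]
    ) / merged["expected_total_um"]
    print(f"Neurite tree length errors (%): {err.round(3).tolist()}")

    rng = np.random.default_rng(SEED)
    ct = pd.DataFrame({
        "ct_target": np.r_[rng.normal(20.0, 0.1, 3), rng.normal(22.0, 0.1, 3)],
        "ct_reference": rng.normal(17.0, 0.1, 6),
        "group": ["CONTROL"] * 3 + ["TREATED"] * 3,
    })
    expression = delta_delta_ct(ct)
    expression.to_csv(results / "ddct_expression.csv", index=False)
    treated = expression.loc[expression["group"] == "TREATED", "relative_expression"]
    print(f"Treated relative expression: {treated.mean():.3f} (generative 0.25)")

    groups = {
        "control": rng.normal(1.0, 0.1, 6),
        "kd1": rng.normal(0.6, 0.1, 6),
        "kd2": rng.normal(0.4, 0.1, 6),
    }
    comparison = group_compare(groups, design="MULTI_GROUP")
    report = {
        "test": comparison.test,
        "F": comparison.statistic,
        "p_value": comparison.p_value,
        "df": list(comparison.df),
        "posthoc": comparison.posthoc.to_dict(orient="records"),
    }
    (results / "group_comparison.json").write_text(
        json.dumps(report, indent=1, sort_keys=True) + "\n"
    )
    print(f"One-way ANOVA: F = {comparison.statistic:.2f}, "
          f"p = {comparison.p_value:.2e}")


if __name__ == "__main__":
    main()
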