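#!/usr/bin/env python
"""Synthetic scramblase-knockdown analogue: control vs depleted spread.

Control fields are generated at p_spread = 0.2 and depleted fields at
p_spread = 0.05 (5 replicate ~200-cell fields per condition). Each of
100 repetitions normalises spread to the control mean and applies the
package's own two-tailed t-test. Finding: the depleted condition shows
~4-fold lower normalised spread and the difference reaches p < 0.05 in
at least 95 of 100 repetitions.
"""

from pathlib import Path

from synspread.experiments import knockdown_analogue

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    table = knockdown_analogue(seed=SEED, n_repetitions=100)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    table.to_csv(results / "knockdown_comparison.csv", index=False)
    rate = table["detected"].mean()
    print(f"Detection rate (p < 0.05, depleted < control): {100 * rate:.0f}%")
    print(f"Mean normalised spread, control:  "
          f"{table['mean_norm_spread_control'].mean():.3f}")
    print(f"Mean normalised spread, depleted: "
          f"{table['mean_norm_spread_depleted'].mean():.3f}")


if __name__ == "__main__":
    main()
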