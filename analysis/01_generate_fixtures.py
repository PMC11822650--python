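#!/usr/bin/env python
"""Generate the synthetic fixture suite with ground truth.

Writes multi-channel TIFF fields (noiseless and noisy cultures, a brain
section with region mask, puncta and neurite fields, control
preparations, a flow event table) plus per-fixture ground-truth CSVs and
a manifest under scratch/fixtures/, and copies the manifest to results/
for reference. Every downstream script can regenerate identical inputs
from the same seed.
"""

import json
from pathlib import Path

from synspread import generate_fixture_suite

SEED = 1
ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    out = ROOT / "scratch" / "fixtures"
    manifest = generate_fixture_suite(out, seed=SEED)
    results = ROOT / "results"
    results.mkdir(exist_ok=True)
    (results / "fixture_manifest.json").write_text(
        json.dumps(manifest, indent=1) + "\n"
    )
    print(f"Wrote {len(manifest['fixtures'])} fixtures to {out} (seed {SEED}).")
    for name, entry in manifest["fixtures"].items():
        print(f"  {name}: image={entry.get('image')} truth={entry.get('ground_truth')}")


if __name__ == "__main__":
    main()
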