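#!/usr/bin/env python
"""Simulate one life table under the emulated rearing design.

Draws the default 2-species x 2-sex x 5-temperature experiment (50
individuals per cell, lognormal development-time noise sigma = 0.05,
temperature-dependent survival) and writes it in the life-table CSV format
consumed by the fit pipeline.
"""

import sys
from collections import Counter
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

from thermaldev import write_lifetable
from thermaldev.synthetic_data import default_config, simulate_lifetable

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    cfg = default_config(seed=1)
    records = simulate_lifetable(cfg)
    out = OUT / "synthetic_lifetable.csv"
    write_lifetable(records, out, header_comment=f"synthetic life table, seed={cfg.seed}")

    emerged = Counter()
    total = Counter()
    for rec in records:
        key = (rec.species, rec.temperature)
        total[key] += 1
        emerged[key] += rec.emerged
    print(f"wrote {len(records)} records -> {out}")
    print("emergence by species and temperature:")
    for key in sorted(total):
        print(f"  {key[0]:>12s} @ {key[1]:>4.0f} °C: {emerged[key]:>3d}/{total[key]}")
    print("note: no emergence outside each group's thermal window; the cooler-")
    print("rising survival of the second species leaves 10-15 °C cells empty.")


if __name__ == "__main__":
    main()
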