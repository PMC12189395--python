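#!/usr/bin/env python
"""Generate the study run and summarise what was planted.

Writes the paired FASTQ and truth table under scratch/run/ and a realized
planted-rate table to results/01_simulation_summary.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from dnbaudit import truth_rates  # noqa: E402


def main() -> None:
    p1, p2, truth = common.write_run_to_scratch()
    rates = truth_rates(truth)
    summary = pd.DataFrame(
        [{"planted_class": k, "fraction": v, "count": round(v * len(truth))}
         for k, v in rates.items()]
    )
    out = common.results_dir() / "01_simulation_summary.tsv"
    summary.to_csv(out, sep="\t", index=False)
    print(f"run written: {p1}, {p2} ({len(truth)} pairs)")
    print(summary.to_string(index=False))
    print(f"\nsummary -> {out}")


if __name__ == "__main__":
    main()
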