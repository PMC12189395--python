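#!/usr/bin/env python
"""Find optical duplicates and their ID-offset structure.

Runs the exhaustive within-frame scan and the offset-restricted fast scan
per FOV over the forward reads, compares both rates with the planted
truth, and writes the ID-difference histogram (the five neighbourhood
modes: 1, 63, 85, 195, 217).

Writes results/03_duplicate_rates.tsv and 03_id_difference_histogram.tsv.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
import common  # noqa: E402

from dnbaudit import scan_run  # noqa: E402


def main() -> None:
    _config, pairs, truth, _panel, _refs = common.load_run()
    forward = [p.forward for p in pairs]

    rep_all, _ = scan_run(forward, method="all")
    rep_fast, _ = scan_run(forward, method="fast")

    dup = truth[truth.planted_class.str.startswith("duplicate_of:")]
    src = dup.planted_class.str.extract(r":(\d+)$")[0].astype(int)
    involved = set(zip(dup.lane, dup.fov_col, dup.fov_row, dup.ordinal))
    involved |= set(zip(dup.lane, dup.fov_col, dup.fov_row, src))
    truth_rate = 100.0 * len(involved) / len(truth)

    rates = pd.DataFrame([
        {"method": "all_to_all", "reads_with_duplicate": rep_all.n_reads_with_duplicate,
         "rate_pct": round(100 * rep_all.rate, 3)},
        {"method": "fast", "reads_with_duplicate": rep_fast.n_reads_with_duplicate,
         "rate_pct": round(100 * rep_fast.rate, 3)},
        {"method": "planted_truth", "reads_with_duplicate": len(involved),
         "rate_pct": round(truth_rate, 3)},
    ])
    hist = pd.DataFrame(
        sorted(rep_all.histogram.items()), columns=["id_difference", "hit_count"]
    )
    out_dir = common.results_dir()
    rates.to_csv(out_dir / "03_duplicate_rates.tsv", sep="\t", index=False)
    hist.to_csv(out_dir / "03_id_difference_histogram.tsv", sep="\t", index=False)
    print(rates.to_string(index=False))
    print("\nhistogram modes:", ", ".join(map(str, hist.id_difference.tolist())))
    print(f"tables -> {out_dir}/03_*.tsv")


if __name__ == "__main__":
    main()
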