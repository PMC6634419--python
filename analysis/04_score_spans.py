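#!/usr/bin/env python
"""Score the simulated cohort: spans, the 2 x 2 cell table, equation accuracy.

Reads results/trial_logs.csv (simulating it first if absent), applies the
quarter-point span rule per block, and writes the cell table and the
concurrent-task accuracy summary.
"""

import argparse
import json
import subprocess
import sys
from pathlib import Path

from chunkspan.io import read_trial_log
from chunkspan.scoring import (
    cell_table,
    concurrent_accuracy,
    format_cell_table,
    score_sessions,
)

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()
    OUT.mkdir(exist_ok=True)
    logs_path = OUT / "trial_logs.csv"
    if not logs_path.exists():
        subprocess.run([sys.executable, str(Path(__file__).parent / "03_simulate_cohort.py"),
                        "--seed", str(args.seed)], check=True)

    logs = read_trial_log(logs_path)
    scores = score_sessions(logs)
    table = cell_table(scores)
    acc = concurrent_accuracy(logs)

    print(format_cell_table(table))
    print("\nconcurrent-task accuracy (complex span):")
    for cond, stats in sorted(acc["by_condition"].items()):
        print(f"  {cond:<13} {100 * stats['mean']:.0f}% (sd = {stats['sd']:.2f})")

    payload = {
        "cell_table": {f"{t}/{c}": s for (t, c), s in table.stats.items()},
        "concurrent_accuracy": {c: s for c, s in acc["by_condition"].items()},
        "per_length_accuracy": acc["per_length"],
    }
    (OUT / "cell_table.json").write_text(json.dumps(payload, indent=1, sort_keys=True))
    (OUT / "cell_table.txt").write_text(format_cell_table(table) + "\n")
    print(f"\nwrote {OUT / 'cell_table.json'}")


if __name__ == "__main__":
    main()
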