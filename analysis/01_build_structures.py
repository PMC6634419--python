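#!/usr/bin/env python
"""Build the chunkable / non-chunkable structure libraries.

Enumerates, for every list length 1..8, the minimum-complexity category
structures (chunkable condition, hierarchically ordered) and the
maximum-complexity structures that admit a consecutive-distance >= 2
ordering (non-chunkable condition, tagged most/less incompressible), and
writes the full library to results/structure_library.json.

Finding: complexity separates the conditions strictly at lengths 2-6
(e.g. 1 vs 10 literals at length 4); at lengths 7-8 every subset's
complexity is forced by parity, so only serial order differs.
"""

import json
from pathlib import Path

from chunkspan.stimuli import build_structure_library, library_json

OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    (OUT / "structure_library.json").write_text(library_json())
    print(f"{'len':>3} {'chunkable':>12} {'nc most':>10} {'nc less':>10}")
    for length in range(1, 9):
        ch = {t.nominal_complexity for t in build_structure_library(length, "chunkable")}
        nc = build_structure_library(length, "nonchunkable")
        most = {t.nominal_complexity for t in nc if t.incompressibility_rank == "most"}
        less = {t.nominal_complexity for t in nc if t.incompressibility_rank == "less"}
        print(f"{length:>3} {str(sorted(ch)):>12} {str(sorted(most)):>10} {str(sorted(less)):>10}")
    print(f"\nwrote {OUT / 'structure_library.json'}")


if __name__ == "__main__":
    main()
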