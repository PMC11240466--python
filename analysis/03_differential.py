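#!/usr/bin/env python
"""Differential screen over the normalized marker table.

Applies the 50% fold-change screen and per-marker Student's t-tests, bands
the results at p < 0.05 (significant) and 0.05 <= p < 0.10 (near), and
compares recovered directions against the planted ground truth.
"""

import importlib
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
sim = importlib.import_module("01_simulate")

from peptistage import MarkerTable, filter_significant, generate_cohort, screen_candidates, test_markers
from peptistage.differential import candidates_frame


def main() -> None:
    table = MarkerTable.from_csv(sim.RESULTS / "marker_table.csv")
    _, _, truth = generate_cohort(sim.STUDY_CONFIG)

    kept = screen_candidates(table, min_fold=1.5)
    candidates = test_markers(table, kept, renumber=False)
    significant, near = filter_significant(candidates)
    print(f"screen retained {len(kept)}/{table.n_markers} markers")
    print(f"{len(significant)} significant (p < 0.05), {len(near)} near (0.05 <= p < 0.10)")

    truth_dir = truth.marker_coords.set_index("serial")["direction"]
    agree = sum(c.status == truth_dir.get(c.serial) for c in significant)
    n_up = sum(c.status == "U" for c in significant)
    print(f"direction: {len(significant) - n_up} D / {n_up} U; "
          f"{agree}/{len(significant)} agree with planted truth")

    report = candidates_frame(test_markers(table, kept))  # serials by ascending m/z
    report = report[report["p_value"] < 0.05]
    report.to_csv(sim.RESULTS / "discovery_candidates.csv", index=False)
    print(f"wrote {len(report)} rows to results/discovery_candidates.csv")


if __name__ == "__main__":
    main()
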