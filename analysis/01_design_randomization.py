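#!/usr/bin/env python
"""Stage 1 - intervention design: enumerate the randomization space and
assign a simulated cohort to it.

Enumerates all 3x3 Latin squares (the menu-plan-order randomization space),
draws the study-2 cohort at its recruited marginals, assigns each participant
a square and an independent "Pre"-day dinner order, and scores the planned
over-enrolment.  Outputs go to results/design/.
"""

import sys
from pathlib import Path

import pandas as pd

from bfikit import design, simulate
from bfikit.pipeline import _write_assignments

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
OUT = Path("results/design")
OUT.mkdir(parents=True, exist_ok=True)

squares = design.enumerate_latin_squares(3)
print(f"order-3 Latin squares enumerated: {len(squares)}")
pd.DataFrame(
    [{"square_index": i, "grid": ";".join("".join(map(str, r)) for r in s.grid)}
     for i, s in enumerate(squares)]
).to_csv(OUT / "latin_squares.tsv", sep="\t", index=False)

base = simulate.STUDY_PROFILES["study2"]
cohort = simulate.generate_cohort(base, seed=SEED)
cohort.to_frame().to_csv(OUT / "cohort.tsv", sep="\t", index=False,
                         float_format="%.10g")
pct_female = 100 * cohort.female_count / len(cohort)
print(f"study-2 cohort: n={len(cohort)}, {pct_female:.0f}% female, "
      f"mean age {cohort.to_frame()['age'].mean():.1f} y")
print(f"planned target 30, enrolled {len(cohort)}: "
      f"+{design.over_enrolment_percent(2):.0f}% over-enrolment")

assignments = design.randomize_study2(cohort.ids, seed=SEED)
_write_assignments(assignments, OUT / "assignments.tsv")
used = len({a.square_index for a in assignments})
print(f"assignments written: {len(assignments)} participants over "
      f"{used} distinct squares -> {OUT}")
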