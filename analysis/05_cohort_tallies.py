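#!/usr/bin/env python
"""Deterministic cohort tallies from the packaged study tables.

Counts patients per lesion type in the diabetes group and study eyes
per group and per retinopathy grade.
"""

import json
from pathlib import Path

from aoangio import load_cohort, tally_eyes, tally_lesions

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    table = load_cohort()
    eyes = tally_eyes(table)
    out = {"patients_with_lesion": tally_lesions(table).patients_with_lesion,
           "eyes_by_group": eyes.eyes_by_group,
           "eyes_by_grade": eyes.eyes_by_grade}
    with open(OUT / "cohort_tallies.json", "w") as fh:
        json.dump(out, fh, indent=2)
    print(json.dumps(out, indent=2))


if __name__ == "__main__":
    main()
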