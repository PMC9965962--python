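#!/usr/bin/env python
"""Simulate the enrolled cohort: 96 children, 10-day DLW + accelerometry.

Writes the cohort table, the isotope records and the ground-truth
manifest under results/replication; a few example epoch files (one per
condition) go to scratch/ because a full 10-day 15-s stream is ~20 MB
of text per child.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))
from common import CONFIG, RESULTS, SCRATCH

from paee.data_io import write_cohort, write_epoch_stream, write_isotope_records
from paee.synthetic import generate_participants, iter_epoch_streams, iter_isotope_records


def main() -> None:
    RESULTS.mkdir(parents=True, exist_ok=True)
    SCRATCH.mkdir(parents=True, exist_ok=True)

    cohort, truth = generate_participants(CONFIG)
    write_cohort(cohort, RESULTS / "cohort.csv")
    truth.to_csv(RESULTS / "truth.csv", index=False, float_format="%.10g")
    write_isotope_records(
        iter_isotope_records(CONFIG, truth), RESULTS / "isotopes.csv"
    )

    examples = {"", "weartime_fail"}
    written = []
    for pid, stream, _ in iter_epoch_streams(CONFIG, truth):
        plant = truth.loc[truth.participant_id == pid, "plant"].iloc[0]
        if plant in examples:
            examples.discard(plant)
            path = SCRATCH / f"epochs_{pid}.csv"
            write_epoch_stream(stream, path, participant_id=pid)
            written.append(path.name)
        if not examples:
            break

    n_boys = int((cohort.sex_code == 1).sum())
    print(f"enrolled {len(cohort)} participants ({n_boys} boys)")
    print(f"planted conditions: {truth['plant'].value_counts().to_dict()}")
    print(f"tables under {RESULTS}; example epoch files: {written}")


if __name__ == "__main__":
    main()
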