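"""Step 5: biomarker-cognition association models (Tables 2-4 analog).

Reads results/prepared.csv and writes:
  results/table2.csv  - adjusted standardized estimates, composites x biomarkers
  results/table3.csv  - adjusted standardized estimates, subtests x biomarkers
  results/table4.csv  - Spearman rho by diagnostic group

Each model regresses the CU-z-scored outcome on the CU-z-scored biomarker
plus age, sex and education.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from mtdrive.pipeline import (
    BIOMARKER_PREDICTORS,
    COMPOSITE_OUTCOMES,
    SUBTEST_OUTCOMES,
    association_table,
    spearman_table,
)

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="input", type=Path, default=RESULTS / "prepared.csv")
    args = parser.parse_args()

    frame = pd.read_csv(args.input)
    cu = (frame["diagnosis"] == "CU").to_numpy()
    group = pd.Series(np.where(cu, "CU", "MCI/DEM"), index=frame.index)

    t2 = association_table(frame, COMPOSITE_OUTCOMES, BIOMARKER_PREDICTORS, cu)
    t3 = association_table(frame, SUBTEST_OUTCOMES, BIOMARKER_PREDICTORS, cu)
    t4 = spearman_table(frame, list(COMPOSITE_OUTCOMES) + list(SUBTEST_OUTCOMES), BIOMARKER_PREDICTORS, group)
    t2.to_csv(RESULTS / "table2.csv", index=False)
    t3.to_csv(RESULTS / "table3.csv", index=False)
    t4.to_csv(RESULTS / "table4.csv", index=False)

    print("composite x biomarker adjusted estimates:")
    print(t2.round(3).to_string(index=False))


if __name__ == "__main__":
    main()
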