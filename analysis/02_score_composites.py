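"""Step 2: (re)score the cohort and attach all cognitive composites.

Reads results/cohort.csv, recomputes SYMaw / MTD-SBCr / MTD-SBCz from the
session summaries with CU-referenced z-scoring, attaches the in-person
z-composites (Mayo-PACC, global cognition z) and writes results/scored.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mtdrive.pipeline import attach_composites
from mtdrive.scoring import score_cohort

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="input", type=Path, default=RESULTS / "cohort.csv")
    parser.add_argument("--out", type=Path, default=RESULTS / "scored.csv")
    args = parser.parse_args()

    frame = pd.read_csv(args.input)
    cu = (frame["diagnosis"] == "CU").to_numpy()
    scored = score_cohort(frame, reference_mask=cu)
    scored = attach_composites(scored, cu)
    scored.to_csv(args.out, index=False)

    cu_z = scored.loc[cu, "mtd_sbcz"]
    print(f"wrote {args.out}")
    print(f"CU MTD-SBCz mean {cu_z.mean():+.2e}, SD {cu_z.std(ddof=1):.6f}")
    print(f"CU MTD-SBCr mean {scored.loc[cu, 'mtd_sbcr'].mean():.3f}")


if __name__ == "__main__":
    main()
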