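"""Step 3: derive the analysis-ready imaging variables.

Reads results/scored.csv and attaches ln/z-transformed PET SUVRs, the
sex-specific ICV-residualized hippocampal volume z-score, and the
ln(percent-of-ICV) WMH variable; writes results/prepared.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from mtdrive.biomarkers import PREPARED_COLUMNS, prepare_biomarkers

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--in", dest="input", type=Path, default=RESULTS / "scored.csv")
    parser.add_argument("--out", type=Path, default=RESULTS / "prepared.csv")
    args = parser.parse_args()

    frame = pd.read_csv(args.input)
    cu = (frame["diagnosis"] == "CU").to_numpy()
    prepared = prepare_biomarkers(frame, cu)
    prepared.to_csv(args.out, index=False)

    cols = [c for c in PREPARED_COLUMNS if c in prepared.columns]
    print(f"wrote {args.out}")
    print(prepared.loc[cu, cols].agg(["mean", "std"]).round(6).to_string())


if __name__ == "__main__":
    main()
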