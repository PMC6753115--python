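"""Post-run statistics: gradient table, SCD-vs-CH scan, symptom interactions.

Reads the artifacts of 03_run_pipeline.py and summarizes what the study
design asks of them: which groups separate from healthy controls on each
measure, whether any region distinguishes SCD from CH after FDR
correction, and whether anxiety/depression scores moderate the
complaint-biomarker association.
"""

from __future__ import annotations

import argparse
from pathlib import Path

import pandas as pd

from snipegrade.pipeline import render_report


def main() -> None:
    ap = argparse.ArgumentParser()
    ap.add_argument("--run", type=Path, default=Path("results/run"))
    args = ap.parse_args()

    print(render_report(args.run))

    scan = pd.read_csv(args.run / "fdr_scan.csv")
    n_raw = int(scan["significant_raw"].sum())
    n_fdr = int(scan["significant_fdr"].sum())
    print(
        f"SCD vs CH region scan: {n_raw} raw-significant of {len(scan)} "
        f"measures; {n_fdr} survive FDR correction"
    )

    inter = pd.read_csv(args.run / "interactions.csv")
    if "p" in inter:
        sig = inter[inter["p"] < 0.05]
        print(
            f"symptom x complaint interactions: {len(sig)} of {len(inter)} "
            f"at p < 0.05"
        )
        print(inter.round(4).to_string(index=False))


if __name__ == "__main__":
    main()
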