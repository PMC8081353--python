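#!/usr/bin/env python
"""Summarize protocol similarity from the experiment tables.

Reads the outputs of 02_run_pipeline.py and reports the trends the
study design is about: how connectome similarity to the reference
(120 directions, full resolution) decays with angular downsampling,
and which nodes stay robust under spatial downsampling.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent.parent / "src"))

OUT = Path(__file__).resolve().parent.parent / "results" / "experiment"


def main() -> None:
    sp = pd.read_csv(OUT / "spearman.csv")
    ref = sp[(sp.angles_a == 120) & (sp.factor_a == 1) | (sp.angles_b == 120) & (sp.factor_b == 1)]
    ref = ref.assign(
        other=[
            f"A{r.angles_b}_S{r.factor_b}" if (r.angles_a, r.factor_a) == (120, 1)
            else f"A{r.angles_a}_S{r.factor_a}"
            for r in ref.itertuples()
        ]
    ).sort_values("rho", ascending=False)
    print("Similarity to the reference protocol (A120, full resolution):")
    print(ref[["other", "rho", "p"]].to_string(index=False))

    disp = pd.read_csv(OUT / "dispersion.csv")
    d1 = disp[disp.dyad == 1].groupby(["factor", "angles"]).median_dispersion.median()
    print("\nMedian dyad-1 dispersion (over regions):")
    print(d1.to_string())

    bl = pd.read_csv(OUT / "blondel_nodes.csv")
    spa = bl[(bl.comparison == "spatial") & (bl.angles == 120)]
    for f in sorted(spa.factor.unique()):
        sub = spa[spa.factor == f].sort_values("score", ascending=False)
        print(f"\nBlondel node scores, A120 full resolution vs factor {f}:")
        print(sub[["region", "score"]].to_string(index=False))


if __name__ == "__main__":
    main()
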