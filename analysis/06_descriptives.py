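#!/usr/bin/env python
"""Average-based group differences (the static counterpart of 05).

Collapses each subject to their person mean per variable on the raw
observed scales and compares the groups with Welch's unequal-variance
t-test.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import emanet as en  # noqa: E402
from emanet import io  # noqa: E402

SCRATCH = ROOT / "scratch" / "data"
RESULTS = ROOT / "results" / "analysis"


def main():
    # person means belong on the raw scales: rebuild the untransformed table
    ds = io.read_ema_csv(SCRATCH / "ema_data.csv")
    table = en.assemble_analysis_table(ds)
    rep = en.group_comparison_table(table)
    rep.to_csv(RESULTS / "person_mean_comparison.csv", index=False)
    g1, g2 = table.groups
    print(f"person-mean comparison ({g1} vs {g2}, Welch t):")
    for _, r in rep.iterrows():
        star = "*" if r.p < 0.05 else " "
        print(
            f"  {r.variable:18s} {r[f'mean_{g1}']:7.2f} ({r[f'sd_{g1}']:.2f})  vs "
            f"{r[f'mean_{g2}']:7.2f} ({r[f'sd_{g2}']:.2f})   p={r.p:.3f}{star}"
        )
    print(f"wrote {RESULTS / 'person_mean_comparison.csv'}")


if __name__ == "__main__":
    main()
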