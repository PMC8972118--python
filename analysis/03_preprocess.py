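#!/usr/bin/env python
"""Assemble the analysis table and check stationarity.

Reads the simulated cohort (01), joins the seven variables, applies the
per-group nonparanormal transformation, and runs both stationarity
screens: moment-to-moment inertia (two-level AR(1) per variable and
group) and the per-(subject, variable) KPSS battery.
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
    ds = io.read_ema_csv(SCRATCH / "ema_data.csv")
    table = en.assemble_analysis_table(ds)
    if table.excluded_subjects:
        print(f"excluded subjects: {table.excluded_subjects}")
    table = en.nonparanormal_transform(table)
    io.write_analysis_csv(table, SCRATCH / "analysis_table.csv")

    inertia = en.inertia_diagnostic(table)
    inertia.inertia.to_csv(RESULTS / "inertia.csv", index=False)
    lo, hi = inertia.inertia["inertia"].min(), inertia.inertia["inertia"].max()
    print(f"moment-to-moment inertia range across variables/groups: {lo:.3f} .. {hi:.3f}")
    flags = inertia.inertia["flag"].value_counts().to_dict()
    print(f"inertia flags: {flags}")

    kpss = en.kpss_stationarity(table)
    kpss.kpss.to_csv(RESULTS / "kpss.csv", index=False)
    print(
        f"KPSS: {100 * kpss.proportion_stationary:.1f}% of "
        f"{len(kpss.kpss)} series stationary ({kpss.n_skipped} skipped)"
    )
    print(f"wrote {SCRATCH / 'analysis_table.csv'}")


if __name__ == "__main__":
    main()
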