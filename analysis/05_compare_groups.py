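#!/usr/bin/env python
"""Permutation comparison of the two stages' networks.

Whole subjects are reassigned between the groups (2,000 permutations,
scaled down from a full-scale 100,000), both networks are refit per
permutation, and every edge difference, in-/out-strength difference and
the overall-connectivity difference gets a two-sided p-value. Differences
are reported as no_lockdown minus lockdown.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import emanet as en  # noqa: E402
from emanet import io  # noqa: E402

SCRATCH = ROOT / "scratch" / "data"
RESULTS = ROOT / "results" / "analysis"
SEED = 2022
N_PERM = 2000


def main():
    table = io.read_analysis_csv(SCRATCH / "analysis_table.csv")
    g1, g2 = table.groups
    res = en.permutation_compare(
        table.for_group(g1),
        table.for_group(g2),
        n_permutations=N_PERM,
        seed=SEED,
        keep_distributions=False,
    )
    res.to_json(RESULTS / "permutation.json")
    io.write_permutation_csv(res, RESULTS / "permutation.csv")

    sig = res.table[res.table["p"] < 0.05].sort_values("p")
    print(f"{N_PERM} permutations of {g1} vs {g2}; "
          f"{len(sig)}/{len(res.table)} statistics differ at uncorrected p < .05")
    for _, r in sig.iterrows():
        print(f"    {r.statistic}: diff={r.observed:+.4f}, p={r.p:.4f}")
    print(f"connectivity difference: {res.observed('connectivity'):+.4f} "
          f"(p={res.pvalue('connectivity'):.3f})")


if __name__ == "__main__":
    main()
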