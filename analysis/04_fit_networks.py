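#!/usr/bin/env python
"""Fit each group's temporal network and its centrality profile.

Per group: z-standardize the transformed variables, build within-day lag-1
pairs with within-person-centered predictors, and fit the nodewise
multilevel model. Exports full networks (JSON), significant-edge lists,
centrality tables and minimal network drawings.
"""

import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

import emanet as en  # noqa: E402
from emanet import io, viz  # noqa: E402

SCRATCH = ROOT / "scratch" / "data"
RESULTS = ROOT / "results" / "analysis"
ALPHA = 0.05


def main():
    table = io.read_analysis_csv(SCRATCH / "analysis_table.csv")
    cents = {}
    for g in table.groups:
        st = en.standardize_table(table.for_group(g))
        design = en.build_lagged_design(st)
        net = en.fit_temporal_network(design)
        net.to_json(RESULTS / f"network_{g}.json")
        edges = en.significant_edges(net, ALPHA)
        edges.to_csv(RESULTS / f"edges_{g}.csv", index=False)
        cents[g] = en.strength_centrality(net)
        cents[g].table.to_csv(RESULTS / f"centrality_{g}.csv", index=False)
        viz.plot_network(net, ROOT / "scratch" / f"network_{g}.png", ALPHA, title=g)

        print(f"[{g}] {net.n_subjects} subjects, {net.n_pairs} lag-1 pairs, "
              f"{len(edges)} significant edges at alpha={ALPHA}")
        top = edges.head(3)
        for _, r in top.iterrows():
            print(f"    {r.predictor} -> {r.outcome}: {r.weight:+.3f} (p={r.p:.1e})")
        strongest = cents[g].table.sort_values("out_strength", ascending=False).iloc[0]
        print(f"    highest out-strength: {strongest.node} ({strongest.out_strength:.3f})")
    viz.plot_centrality(cents, ROOT / "scratch" / "centrality.png")


if __name__ == "__main__":
    main()
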