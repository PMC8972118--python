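"""End-to-end pipeline: simulate/ingest -> preprocess -> fit -> compare.

``run_pipeline`` executes the whole analysis for a configuration and
writes every artifact (networks, edge lists, centrality, permutation
results, stationarity reports, descriptives, run manifest) under the
configured output directory. Reruns with the same configuration and seed
are bit-identical for every deterministic stage.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np

from . import descriptives, io, metrics, mlvar, permutation, preprocess, synthetic
from .config import PipelineConfig

__all__ = ["run_pipeline"]

log = logging.getLogger(__name__)


def _stage(name):
    """Decorator-free stage wrapper: re-raise with the failing stage named."""

    class _Ctx:
        def __enter__(self):
            log.info("stage: %s", name)
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            return False

    return _Ctx()


def simulate_dataset(config: PipelineConfig) -> synthetic.EmaDataset:
    sim = config.simulate
    delta = None
    if sim.group_delta:
        delta = synthetic.GroupDelta(**sim.group_delta)
    spec = synthetic.generate_true_network(
        n_groups=2,
        sparsity=sim.sparsity,
        group_delta=delta,
        seed=config.seed,
        random_effect_sd=sim.random_effect_sd,
        innovation_sd=sim.innovation_sd,
        spectral_cap=sim.spectral_cap,
    )
    sim_cfg = synthetic.SimulationConfig(
        n_subjects_per_group=sim.n_subjects_per_group,
        n_days=sim.n_days,
        beeps_per_day=sim.beeps_per_day,
        missing_rate=sim.missing_rate,
        subject_mean_sd=sim.subject_mean_sd,
        seed=config.seed + 1,
    )
    return synthetic.generate_dataset(spec, sim_cfg)


def run_pipeline(config: PipelineConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    fh = logging.FileHandler(outdir / "run.log")
    fh.setLevel(logging.INFO)
    logging.getLogger("emanet").addHandler(fh)
    artifacts: dict = {"outdir": outdir}
    try:
        with _stage("simulate/ingest"):
            if config.ema_csv is not None:
                if not Path(config.ema_csv).exists():
                    raise FileNotFoundError(f"EMA file not found: {config.ema_csv}")
                dataset = io.read_ema_csv(config.ema_csv)
            else:
                dataset = simulate_dataset(config)
                io.write_ema_csv(dataset, outdir / "ema_data.csv")
            artifacts["dataset"] = dataset

        with _stage("preprocess"):
            table = preprocess.assemble_analysis_table(dataset)
            table = preprocess.nonparanormal_transform(table, per=config.transform_per)
            inertia = preprocess.inertia_diagnostic(table)
            kpss = preprocess.kpss_stationarity(table)
            with open(outdir / "stationarity.json", "w") as f:
                json.dump(
                    {**inertia.to_dict(), **kpss.to_dict()}, f, indent=2, sort_keys=True
                )
                f.write("\n")
            inertia.inertia.to_csv(outdir / "inertia.csv", index=False)
            artifacts["table"] = table
            artifacts["inertia"] = inertia
            artifacts["kpss"] = kpss

        with _stage("fit"):
            groups = list(table.groups)
            networks = {}
            options = mlvar.EstimationOptions(
                backend=config.estimator.backend,
                random_slopes=config.estimator.random_slopes,
            )
            for g in groups:
                gt = preprocess.standardize_table(table.for_group(g))
                design = mlvar.build_lagged_design(gt)
                net = mlvar.fit_temporal_network(design, options)
                networks[g] = net
                net.to_json(outdir / f"network_{g}.json")
                mlvar.significant_edges(net, config.alpha).to_csv(
                    outdir / f"edges_{g}.csv", index=False
                )
            artifacts["networks"] = networks

        with _stage("metrics"):
            cents = {g: metrics.strength_centrality(net) for g, net in networks.items()}
            for g, cent in cents.items():
                cent.table.to_csv(outdir / f"centrality_{g}.csv", index=False)
            artifacts["centrality"] = cents
            if config.plots:
                from . import viz

                viz.plot_centrality(cents, outdir / "centrality.png")
                for g, net in networks.items():
                    viz.plot_network(net, outdir / f"network_{g}.png", config.alpha, title=g)

        if len(groups) == 2:
            with _stage("permutation"):
                result = permutation.permutation_compare(
                    table.for_group(groups[0]),
                    table.for_group(groups[1]),
                    n_permutations=config.n_permutations,
                    seed=config.seed + 2,
                    statistics=config.statistics,
                )
                result.to_json(outdir / "permutation.json")
                io.write_permutation_csv(result, outdir / "permutation.csv")
                artifacts["permutation"] = result

        with _stage("descriptives"):
            desc = descriptives.group_comparison_table(table)
            desc.to_csv(outdir / "person_mean_comparison.csv", index=False)
            artifacts["descriptives"] = desc

        with _stage("manifest"):
            config.write_resolved(outdir)
            with open(outdir / "manifest.json", "w") as f:
                json.dump(
                    {"seed": config.seed, "config_hash": config.hash()},
                    f,
                    indent=2,
                    sort_keys=True,
                )
                f.write("\n")
    finally:
        logging.getLogger("emanet").removeHandler(fh)
        fh.close()
    return artifacts
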