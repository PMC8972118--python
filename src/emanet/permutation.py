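"""Permutation comparison of two groups' temporal networks.

The two stages being compared were measured in independent samples, so the
exchangeable unit under the null hypothesis of "no group difference" is
the *subject*: a permutation reassigns whole subjects to groups (group
sizes preserved, time series kept intact), refits both networks with the
same estimator settings as the observed fit, and records the difference of
every selected statistic — each of the k^2 directed edges, the 2k strength
centralities, and overall connectivity. Two-sided p-values use the add-one
rule

    p = (1 + #{ |d_perm| >= |d_obs| }) / (1 + n_permutations),

which keeps p positive and the test valid at any finite permutation count.
For tiny groups the full set of label reassignments can be enumerated
(``exhaustive=True``), in which case p is the exact proportion over all
splits.

The nodewise refits use the closed-form random-intercept identity (see
``emanet.mlvar``): per-subject cross-products are computed once, so each
permutation only re-aggregates them, re-standardizes per permuted group
and solves one small linear system per outcome.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import metrics
from .mlvar import build_lagged_design

__all__ = ["PermutationResult", "permutation_compare", "pvalue_two_sided"]


def pvalue_two_sided(observed: float, permuted) -> float:
    """Add-one two-sided permutation p-value of an observed difference."""
    permuted = np.asarray(permuted, dtype=float)
    if permuted.size == 0:
        raise ValueError("permuted list is empty")
    if not np.isfinite(observed) or not np.all(np.isfinite(permuted)):
        raise ValueError("non-finite inputs")
    n = permuted.size
    return float((1 + np.sum(np.abs(permuted) >= abs(observed))) / (1 + n))


# ---------------------------------------------------------------------------
# per-subject sufficient statistics
# ---------------------------------------------------------------------------


@dataclass
class _SubjectBlocks:
    """Per-subject cross-products sufficient for any relabelled group fit."""

    node_labels: tuple
    subject_keys: list
    G: np.ndarray  # (S, k, k)  Xc' Xc over the subject's lag pairs
    H: np.ndarray  # (S, k, k)  Xc' Y
    n_pairs: np.ndarray  # (S,)
    obs_n: np.ndarray  # (S, k)   non-missing observation counts
    obs_sum: np.ndarray  # (S, k)
    obs_sumsq: np.ndarray  # (S, k)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_keys)


def _blocks_from_table(table, tag: str) -> _SubjectBlocks:
    labels = tuple(table.node_labels)
    k = len(labels)
    design = build_lagged_design(table)
    keys, G, H, npairs = [], [], [], []
    obs_n, obs_sum, obs_sumsq = [], [], []
    vals = table.data[list(labels)].to_numpy(dtype=float)
    subj_col = table.data["subject_id"].to_numpy()
    for sid in pd.unique(design.subject_ids):
        m = design.subject_ids == sid
        xc = design.x_centered[m]
        y = design.y[m]
        keys.append(f"{tag}:{sid}")
        G.append(xc.T @ xc)
        H.append(xc.T @ y)
        npairs.append(int(m.sum()))
        v = vals[subj_col == sid]
        fin = np.isfinite(v)
        obs_n.append(fin.sum(axis=0))
        obs_sum.append(np.where(fin, v, 0.0).sum(axis=0))
        obs_sumsq.append(np.where(fin, v**2, 0.0).sum(axis=0))
    return _SubjectBlocks(
        node_labels=labels,
        subject_keys=keys,
        G=np.array(G),
        H=np.array(H),
        n_pairs=np.array(npairs),
        obs_n=np.array(obs_n, dtype=float),
        obs_sum=np.array(obs_sum),
        obs_sumsq=np.array(obs_sumsq),
    )


def _merge_blocks(a: _SubjectBlocks, b: _SubjectBlocks) -> _SubjectBlocks:
    if a.node_labels != b.node_labels:
        raise ValueError("tables do not share a node set")
    return _SubjectBlocks(
        node_labels=a.node_labels,
        subject_keys=a.subject_keys + b.subject_keys,
        G=np.concatenate([a.G, b.G]),
        H=np.concatenate([a.H, b.H]),
        n_pairs=np.concatenate([a.n_pairs, b.n_pairs]),
        obs_n=np.concatenate([a.obs_n, b.obs_n]),
        obs_sum=np.concatenate([a.obs_sum, b.obs_sum]),
        obs_sumsq=np.concatenate([a.obs_sumsq, b.obs_sumsq]),
    )


def _group_coefficients(blocks: _SubjectBlocks, idx: np.ndarray) -> np.ndarray:
    """Standardized lag-1 coefficient matrix for the subjects in ``idx``.

    Slopes come from the pooled centered cross-products (the closed-form
    random-intercept fixed effects); standardization rescales edge (k -> j)
    by sd_k / sd_j with the SDs taken over the permuted group's
    observations, which reproduces fitting on z-scored data.
    """
    G = blocks.G[idx].sum(axis=0)
    H = blocks.H[idx].sum(axis=0)
    if np.linalg.cond(G) > 1e10:
        raise np.linalg.LinAlgError("ill-conditioned pooled design")
    B_raw = np.linalg.solve(G, H).T  # rows = outcome
    n = blocks.obs_n[idx].sum(axis=0)
    s1 = blocks.obs_sum[idx].sum(axis=0)
    s2 = blocks.obs_sumsq[idx].sum(axis=0)
    var = (s2 - s1**2 / n) / (n - 1.0)
    if np.any(~np.isfinite(var)) or np.any(var <= 0):
        raise np.linalg.LinAlgError("degenerate variable variance in group")
    s = np.sqrt(var)
    return B_raw * s[None, :] / s[:, None]


def _statistic_vector(B: np.ndarray, labels: tuple, statistics: tuple) -> tuple[np.ndarray, list, list]:
    vals, names, kinds = [], [], []
    k = len(labels)
    if "edges" in statistics:
        for j in range(k):
            for i in range(k):
                vals.append(B[j, i])
                names.append(f"edge:{labels[i]}->{labels[j]}")
                kinds.append("edge")
    if "strength" in statistics:
        cent = metrics.strength_centrality(B)
        for j in range(k):
            vals.append(cent.table["in_strength"].iloc[j])
            names.append(f"in_strength:{labels[j]}")
            kinds.append("in_strength")
        for j in range(k):
            vals.append(cent.table["out_strength"].iloc[j])
            names.append(f"out_strength:{labels[j]}")
            kinds.append("out_strength")
    if "connectivity" in statistics:
        vals.append(metrics.global_connectivity(B))
        names.append("connectivity")
        kinds.append("connectivity")
    return np.array(vals), names, kinds


@dataclass
class PermutationResult:
    """Observed group differences with their permutation p-values.

    ``table`` columns: statistic, kind, observed (group1 - group2), p,
    perm_mean, perm_sd. ``distributions`` maps statistic name to its
    permutation distribution (kept for diagnostics and tests).
    """

    table: pd.DataFrame
    n_permutations: int
    seed: int | None
    node_labels: tuple
    exhaustive: bool = False
    n_redrawn: int = 0
    distributions: dict | None = None
    B_group1: np.ndarray | None = None
    B_group2: np.ndarray | None = None

    def pvalue(self, name: str) -> float:
        return float(self.table.set_index("statistic").loc[name, "p"])

    def observed(self, name: str) -> float:
        return float(self.table.set_index("statistic").loc[name, "observed"])

    def to_dict(self) -> dict:
        return {
            "node_labels": list(self.node_labels),
            "n_permutations": int(self.n_permutations),
            "seed": self.seed,
            "exhaustive": bool(self.exhaustive),
            "n_redrawn": int(self.n_redrawn),
            "statistics": self.table.to_dict(orient="records"),
        }

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s


def permutation_compare(
    tableA,
    tableB,
    n_permutations: int = 2000,
    seed: int = 0,
    statistics: tuple = ("edges", "strength", "connectivity"),
    exhaustive: bool = False,
    max_failure_rate: float = 0.05,
    keep_distributions: bool = True,
) -> PermutationResult:
    """Compare the temporal networks of two groups by subject permutation.

    ``tableA``/``tableB`` are the two groups' (transformed) analysis
    tables. Differences are reported as group1 - group2. A permutation
    whose refit fails (singular pooled design) is redrawn and counted; the
    test errors out if more than ``max_failure_rate`` of draws fail.
    """
    statistics = tuple(statistics)
    unknown = set(statistics) - {"edges", "strength", "connectivity"}
    if unknown:
        raise ValueError(f"unknown statistics: {sorted(unknown)}")
    bA = _blocks_from_table(tableA, "g1")
    bB = _blocks_from_table(tableB, "g2")
    if bA.n_subjects < 2 or bB.n_subjects < 2:
        raise ValueError("each group needs at least 2 subjects")
    blocks = _merge_blocks(bA, bB)
    nA, S = bA.n_subjects, blocks.n_subjects
    labels = blocks.node_labels

    idx_all = np.arange(S)
    B1 = _group_coefficients(blocks, idx_all[:nA])
    B2 = _group_coefficients(blocks, idx_all[nA:])
    v1, names, kinds = _statistic_vector(B1, labels, statistics)
    v2, _, _ = _statistic_vector(B2, labels, statistics)
    obs = v1 - v2

    def split_diff(idxA: np.ndarray, idxB: np.ndarray) -> np.ndarray:
        Ba = _group_coefficients(blocks, idxA)
        Bb = _group_coefficients(blocks, idxB)
        wa, _, _ = _statistic_vector(Ba, labels, statistics)
        wb, _, _ = _statistic_vector(Bb, labels, statistics)
        return wa - wb

    redrawn = 0
    if exhaustive:
        perms = []
        for comb in itertools.combinations(range(S), nA):
            ia = np.array(comb)
            ib = np.setdiff1d(idx_all, ia, assume_unique=True)
            perms.append(split_diff(ia, ib))
        perms = np.array(perms)
        n_done = perms.shape[0]
        # exact test: proportion over all splits (the observed one included)
        p = (np.abs(perms) >= np.abs(obs)[None, :]).mean(axis=0)
    else:
        rng = np.random.default_rng(seed)
        perms = np.empty((n_permutations, obs.size))
        done = 0
        max_fail = max(1, int(np.ceil(max_failure_rate * n_permutations)))
        while done < n_permutations:
            order = rng.permutation(S)
            try:
                perms[done] = split_diff(order[:nA], order[nA:])
            except np.linalg.LinAlgError:
                redrawn += 1
                if redrawn > max_fail:
                    raise RuntimeError(
                        f"permutation refit failure rate exceeded "
                        f"{max_failure_rate:.0%} ({redrawn} failures)"
                    )
                continue
            done += 1
        n_done = n_permutations
        p = np.array([pvalue_two_sided(obs[i], perms[:, i]) for i in range(obs.size)])

    table = pd.DataFrame(
        {
            "statistic": names,
            "kind": kinds,
            "observed": obs,
            "p": p,
            "perm_mean": perms.mean(axis=0),
            "perm_sd": perms.std(axis=0, ddof=1),
        }
    )
    return PermutationResult(
        table=table,
        n_permutations=n_done,
        seed=None if exhaustive else seed,
        node_labels=labels,
        exhaustive=exhaustive,
        n_redrawn=redrawn,
        distributions=(
            {names[i]: perms[:, i].copy() for i in range(len(names))}
            if keep_distributions
            else None
        ),
        B_group1=B1,
        B_group2=B2,
    )
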