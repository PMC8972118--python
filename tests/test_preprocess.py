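"""Analysis-table assembly, nonparanormal transform, stationarity checks."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

import emanet as en
from emanet.actigraphy import BeepActivity
from emanet.preprocess import AnalysisTable, npn_column

from conftest import make_dataset


def npn_oracle(values):
    """Independent brute-force nonparanormal oracle.

    Counts below/equal per value (no rankdata), truncates the ECDF at
    delta = 1/(4 n^(1/4) sqrt(pi log n)) and applies the normal quantile.
    """
    values = list(values)
    n = len(values)
    delta = 1.0 / (4.0 * n**0.25 * math.sqrt(math.pi * math.log(n)))
    out = []
    for v in values:
        below = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        rank = below + (equal + 1) / 2.0  # average rank
        u = min(max(rank / n, delta), 1.0 - delta)
        out.append(stats.norm.ppf(u))
    return np.array(out)


class TestAssemble:
    def test_row_without_activity_kept_missing(self, small_dataset):
        acts = [
            BeepActivity(r.subject_id, r.timestamp, 42.0)
            for r in small_dataset.data.iloc[:1].itertuples()
        ]
        table = en.assemble_analysis_table(small_dataset, activity=acts)
        pa = table.data["physical_activity"]
        assert pa.notna().sum() == 1
        assert len(table.data) == len(small_dataset.data)

    def test_subject_over_half_missing_excluded(self, small_spec):
        cfg = en.SimulationConfig(n_subjects_per_group=5, missing_rate=0.0, seed=2)
        ds = en.generate_dataset(small_spec, cfg)
        items = [v for v in ds.node_labels if v != "physical_activity"]
        sid = ds.data["subject_id"].iloc[0]
        rows = ds.data["subject_id"] == sid
        idx = ds.data.index[rows][:34]  # 34/56 = 60.7% of prompts
        ds.data.loc[idx, items] = np.nan
        table = en.assemble_analysis_table(ds)
        assert sid in table.excluded_subjects
        assert sid not in set(table.data["subject_id"])

    def test_disjoint_subject_sets_error(self, small_dataset):
        acts = [BeepActivity("nobody", pd.Timestamp("2020-08-08 09:00"), 1.0)]
        with pytest.raises(ValueError, match="disjoint"):
            en.assemble_analysis_table(small_dataset, activity=acts)


class TestNonparanormal:
    def test_matches_independent_oracle_exactly(self):
        rng = np.random.default_rng(7)
        for n in (5, 10, 23, 50):
            x = np.round(rng.uniform(0, 100, n), 1)  # some ties after rounding
            assert np.array_equal(npn_column(x), npn_oracle(x))

    def test_five_distinct_values(self):
        x = np.array([3.0, 1.0, 4.0, 1.5, 9.0])
        assert np.allclose(npn_column(x), npn_oracle(x), atol=0, rtol=0)

    @given(
        st.lists(st.integers(-10**6, 10**6), min_size=3, max_size=200, unique=True)
    )
    def test_rank_preservation(self, vals):
        # order is preserved everywhere; strictly so away from the
        # Winsorized tails (clipping ties the extreme order statistics)
        x = np.array(vals, dtype=float)
        y = npn_column(x)
        order = np.argsort(x)
        assert np.all(np.diff(y[order]) >= 0)
        n = len(x)
        delta = 1.0 / (4.0 * n**0.25 * math.sqrt(math.pi * math.log(n)))
        u = (np.arange(n) + 1) / n
        interior = (u[:-1] > delta) & (u[1:] < 1 - delta)
        assert np.all(np.diff(y[order])[interior] > 0)

    @given(
        st.lists(st.integers(-5000, 5000), min_size=4, max_size=100, unique=True),
        st.sampled_from(["tanh", "affine"]),
    )
    def test_monotone_distortion_invariance(self, vals, kind):
        x = np.array(vals, dtype=float) / 100.0
        f = {"tanh": lambda v: v + np.tanh(v), "affine": lambda v: 3 * v - 7}[kind]
        assert np.allclose(npn_column(x), npn_column(f(x)), atol=1e-12)

    def test_idempotent_up_to_ties(self):
        x = np.random.default_rng(0).normal(size=40)
        once = npn_column(x)
        assert np.allclose(npn_column(once), once, atol=1e-12)

    def test_transformed_marginal_close_to_normal(self):
        x = np.random.default_rng(1).exponential(size=1000)
        y = npn_column(x)
        ks = stats.kstest(y, "norm").statistic
        assert ks < 0.02

    def test_constant_column_error_names_variable(self, small_table):
        df = small_table.data.copy()
        df["stress"] = 1.0
        bad = AnalysisTable(data=df, node_labels=small_table.node_labels)
        with pytest.raises(ValueError, match="stress"):
            en.nonparanormal_transform(bad)

    def test_missing_values_pass_through(self, small_table):
        assert small_table.data[list(small_table.node_labels)].isna().sum().sum() > 0
        # missingness pattern identical to the raw table
        for v in small_table.node_labels:
            assert (
                small_table.data[v].isna() == small_table.raw[v].isna()
            ).all()


def ar_table(rho, n_subjects=50, seed=0, mean_sd=0.0, random_walk=False):
    """Single-variable battery on the 7x8 schedule for stationarity checks."""
    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        mu = rng.normal(0, mean_sd)
        walk = np.cumsum(rng.normal(size=56)).reshape(7, 8) if random_walk else None
        for d in range(1, 8):
            if random_walk:
                x = walk[d - 1]  # one continuous walk across the whole week
            else:
                x = np.empty(8)
                x[0] = rng.normal(0, 1 / np.sqrt(1 - rho**2)) if abs(rho) < 1 else rng.normal()
                for t in range(1, 8):
                    x[t] = rho * x[t - 1] + rng.normal()
            for b in range(1, 9):
                rows.append(
                    {
                        "subject_id": f"s{s:03d}",
                        "group": "g1",
                        "day": d,
                        "beep": b,
                        "timestamp": pd.Timestamp("2020-08-08") + pd.Timedelta(days=d, hours=8 + b),
                        "y": mu + x[b - 1],
                    }
                )
    return AnalysisTable(data=pd.DataFrame(rows), node_labels=("y",))


class TestInertia:
    def test_recovers_moderate_autoregression(self):
        # mean estimate over replicates stays inside the single-fit 95% band
        ests, ses = [], []
        for seed in range(10):
            rep = en.inertia_diagnostic(ar_table(0.3, seed=seed, mean_sd=1.0))
            ests.append(rep.inertia["inertia"].iloc[0])
            ses.append(rep.inertia["se"].iloc[0])
        assert abs(np.mean(ests) - 0.3) < 1.96 * np.mean(ses)
        assert (rep.inertia["flag"] == "stationary").all()

    def test_white_noise_inertia_near_zero(self):
        rep = en.inertia_diagnostic(ar_table(0.0, seed=1))
        assert abs(rep.inertia["inertia"].iloc[0]) < 1.96 * rep.inertia["se"].iloc[0] + 0.03

    def test_random_walk_flagged(self):
        rep = en.inertia_diagnostic(ar_table(1.0, seed=2, random_walk=True))
        coef = rep.inertia["inertia"].iloc[0]
        assert coef > 0.8
        assert rep.inertia["flag"].iloc[0] in ("borderline", "nonstationary")

    def test_single_subject_rejected(self):
        with pytest.raises(ValueError):
            en.inertia_diagnostic(ar_table(0.3, n_subjects=1))


class TestKpss:
    def test_stationary_battery_mostly_stationary(self):
        rep = en.kpss_stationarity(ar_table(0.3, n_subjects=150, seed=3))
        assert rep.proportion_stationary >= 0.9

    def test_random_walks_often_rejected(self):
        rep = en.kpss_stationarity(ar_table(0.0, n_subjects=150, seed=4, random_walk=True))
        assert rep.proportion_stationary <= 0.5

    def test_constant_series_skipped(self):
        t = ar_table(0.3, n_subjects=3, seed=5)
        t.data.loc[t.data["subject_id"] == "s000", "y"] = 7.0
        rep = en.kpss_stationarity(t)
        assert rep.n_skipped == 1
        assert len(rep.kpss) == 2


class TestStandardize:
    def test_zero_mean_unit_sd_per_group(self, small_table):
        st_ = en.standardize_table(small_table)
        for g in st_.groups:
            sub = st_.data[st_.data["group"] == g]
            for v in st_.node_labels:
                assert abs(sub[v].mean()) < 1e-12
                assert sub[v].std(ddof=1) == pytest.approx(1.0)
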