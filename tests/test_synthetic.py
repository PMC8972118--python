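"""Generator: network draws, dataset structure, schedules, accelerometry."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import emanet as en
from emanet.synthetic import (
    ExpMap,
    LogisticMap,
    QuantileLikertMap,
    spectral_radius,
)


class TestGenerateTrueNetwork:
    def test_zero_sparsity_gives_diagonal_matrices(self):
        spec = en.generate_true_network(n_groups=2, sparsity=0.0, seed=1)
        for B in spec.B_group:
            off = B[~np.eye(7, dtype=bool)]
            assert np.all(off == 0.0)

    def test_group_delta_is_exact_single_edge(self):
        spec = en.generate_true_network(
            n_groups=2, sparsity=0.3, group_delta=("loneliness", "restriction", 0.12), seed=2
        )
        D = spec.B_group[1] - spec.B_group[0]
        j = spec.index("restriction")
        i = spec.index("loneliness")
        assert D[j, i] == pytest.approx(0.12, abs=1e-15)
        D[j, i] = 0.0
        assert np.all(D == 0.0)

    def test_mean_offdiagonal_nonzero_fraction_tracks_sparsity(self):
        # Monte-Carlo over seeds: each off-diagonal entry is Bernoulli(0.3)
        fracs = []
        off = ~np.eye(7, dtype=bool)
        for seed in range(1000):
            spec = en.generate_true_network(n_groups=1, sparsity=0.3, seed=seed)
            fracs.append((spec.B_group[0][off] != 0).mean())
        assert abs(np.mean(fracs) - 0.3) < 0.02

    def test_spectral_radius_capped(self):
        for seed in range(20):
            spec = en.generate_true_network(
                n_groups=2, sparsity=0.8, offdiag_range=(0.2, 0.4), seed=seed
            )
            for B in spec.B_group:
                assert spectral_radius(B) < spec.spectral_cap

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            en.generate_true_network(sparsity=1.5)
        with pytest.raises(ValueError):
            en.generate_true_network(n_groups=3)
        with pytest.raises(ValueError):
            en.generate_true_network(n_groups=1, group_delta=("loneliness", "worry", 0.1))


class TestGenerateDataset:
    def test_same_seed_bit_identical(self, small_spec):
        cfg = en.SimulationConfig(n_subjects_per_group=5, seed=9)
        a = en.generate_dataset(small_spec, cfg)
        b = en.generate_dataset(small_spec, cfg)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_realized_missingness_near_nominal(self, small_spec):
        cfg = en.SimulationConfig(n_subjects_per_group=50, missing_rate=0.175, seed=3)
        ds = en.generate_dataset(small_spec, cfg)
        m = ds.realized_missingness()
        assert abs(m.mean() - 0.175) < 0.02
        assert m.max() <= 0.5

    def test_beep_schedule_inside_blocks(self, small_dataset):
        df = small_dataset.data
        tod = df["timestamp"].dt.hour * 3600 + df["timestamp"].dt.minute * 60 + df["timestamp"].dt.second
        start = 8 * 3600 + (df["beep"] - 1) * 105 * 60
        assert ((tod >= start) & (tod < start + 105 * 60)).all()
        assert (df["timestamp"].dt.hour >= 8).all()
        assert (df["timestamp"].dt.hour < 22).all()

    def test_observed_values_in_declared_ranges(self, small_dataset):
        df = small_dataset.data
        for var in ("loneliness", "worry", "restriction", "info_seeking", "stress"):
            v = df[var].dropna()
            assert v.between(0, 100).all()
        sc = df["social_contact"].dropna()
        assert sc.isin(range(1, 8)).all()
        assert (df["physical_activity"].dropna() > 0).all()

    def test_latent_variance_matches_stationary_solution(self):
        # long series, no subject heterogeneity: sample variance of the
        # latent VAR should match the discrete-Lyapunov solution
        from scipy.linalg import solve_discrete_lyapunov

        from emanet.synthetic import _simulate_subject_latent

        spec = en.generate_true_network(
            n_groups=1, sparsity=0.3, node_labels=en.VARIABLES[:3], seed=4
        )
        B = spec.B_group[0]
        cfg = en.SimulationConfig(n_subjects_per_group=1, n_days=2000, seed=0)
        rng = np.random.default_rng(12)
        lat = _simulate_subject_latent(
            B, np.linalg.cholesky(spec.innovation_cov), spec.innovation_cov, cfg, rng
        )
        target = np.diag(solve_discrete_lyapunov(B, spec.innovation_cov))
        assert np.all(np.isfinite(lat))
        assert np.allclose(lat.var(axis=0), target, rtol=0.1)

    def test_missing_rate_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            en.SimulationConfig(missing_rate=0.6)
        with pytest.raises(ValueError):
            en.SimulationConfig(beeps_per_day=9)  # 9 x 105 min > 14 h window


class TestMarginalMaps:
    @given(st.lists(st.integers(-5000, 5000), min_size=8, max_size=60, unique=True))
    def test_maps_preserve_order(self, vals):
        z = np.array(vals, dtype=float) / 1000.0
        order = np.argsort(z)
        for m in (LogisticMap(), ExpMap()):
            obs = m(z)
            assert np.all(np.diff(obs[order]) > 0)  # strictly monotone
        lik = QuantileLikertMap()(z)
        assert np.all(np.diff(lik[order]) >= 0)  # monotone with ties

    def test_likert_levels_cover_range(self):
        z = np.random.default_rng(0).normal(size=2000)
        lik = QuantileLikertMap()(z)
        assert set(np.unique(lik)) == set(range(1, 8))


class TestGenerateRawAccel:
    def test_sample_count_exact(self):
        prof = en.AccelProfile(duration=3600.0, rest_segments=[(0, 3600.0)])
        sig = en.generate_raw_accel(prof, seed=0)
        assert sig.n_samples == 36000

    def test_rest_vector_magnitude_near_one_g(self):
        prof = en.AccelProfile(duration=3600.0, rest_segments=[(0, 3600.0)], noise_sd=5.0)
        sig = en.generate_raw_accel(prof, seed=1)
        norm = np.linalg.norm(sig.axes(), axis=1)
        assert abs(norm.mean() - 1000.0) < 2.0

    def test_nonwear_below_thresholds_by_construction(self):
        prof = en.AccelProfile(
            duration=7200.0,
            rest_segments=[(0, 3600.0)],
            nonwear_segments=[(3600.0, 7200.0)],
        )
        sig = en.generate_raw_accel(prof, seed=2)
        nw = sig.axes()[36000:]
        assert np.all(nw.std(axis=0, ddof=1) < 13.0)
        assert np.all(nw.max(axis=0) - nw.min(axis=0) < 50.0)

    def test_overlapping_or_gappy_segments_rejected(self):
        with pytest.raises(ValueError):
            en.AccelProfile(duration=100.0, rest_segments=[(0, 60.0), (50.0, 100.0)])
        with pytest.raises(ValueError):
            en.AccelProfile(duration=100.0, rest_segments=[(0, 40.0), (60.0, 100.0)])
        with pytest.raises(ValueError):
            en.AccelProfile(duration=100.0, rest_segments=[(0, 100.0)], sampling_rate=5.0)
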