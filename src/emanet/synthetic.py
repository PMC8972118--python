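"""Synthetic two-group EMA + actigraphy data with known generating structure.

The study design emulated here: two independent groups of subjects, each
prompted 8 times a day for 7 consecutive days, prompts randomized within
105-minute blocks between 08:00 and 22:00. Seven variables are observed per
prompt — five visual-analog items (0-100), one 7-point Likert item (duration
of social contact) and a nonnegative physical-activity value — all driven by
a latent subject-level VAR(1) process so that every downstream estimator has
a known truth to recover. Roughly 17.5% of prompts are missed completely at
random, and no subject misses more than half.

Raw accelerometry is generated separately (``generate_raw_accel``): wear
segments carry gravity plus orientation changes and optional movement
bursts; nonwear segments are still by construction, below the nonwear
detector's thresholds.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.linalg import solve_discrete_lyapunov

from .actigraphy import RawAccelSignal

__all__ = [
    "VARIABLES",
    "EMA_ITEMS",
    "GroupDelta",
    "TrueNetworkSpec",
    "SimulationConfig",
    "EmaDataset",
    "AccelProfile",
    "generate_true_network",
    "generate_dataset",
    "generate_raw_accel",
]

#: Analysis variables in canonical order. The first five are visual-analog
#: items (0-100), social_contact is a 7-point Likert item, physical_activity
#: is the actigraphy-derived ENMO summary (mg).
VARIABLES = (
    "loneliness",
    "worry",
    "restriction",
    "info_seeking",
    "stress",
    "social_contact",
    "physical_activity",
)

#: The six self-report items (everything except physical activity).
EMA_ITEMS = VARIABLES[:5] + ("social_contact",)

GROUP_LABELS = ("no_lockdown", "lockdown")


@dataclass(frozen=True)
class GroupDelta:
    """A single-edge group difference: group 2's lag-1 coefficient from
    ``source`` (predictor at t-1) to ``target`` (outcome at t) differs from
    group 1's by exactly ``amount``."""

    source: str
    target: str
    amount: float


# ---------------------------------------------------------------------------
# marginal maps: strictly monotone latent -> observed transforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LogisticMap:
    """Bounded visual-analog scale: obs = lo + (hi-lo) * logistic(z/scale)."""

    lo: float = 0.0
    hi: float = 100.0
    scale: float = 1.0

    def __call__(self, z: np.ndarray, rng=None) -> np.ndarray:
        return self.lo + (self.hi - self.lo) / (1.0 + np.exp(-z / self.scale))


@dataclass(frozen=True)
class QuantileLikertMap:
    """Ordinal item: empirical-quantile discretization into ``levels`` bins.

    Bins adapt to the pooled latent distribution, so the map is monotone
    (weakly — ties within a bin) at any latent scale.
    """

    levels: int = 7

    def __call__(self, z: np.ndarray, rng=None) -> np.ndarray:
        qs = np.quantile(z[np.isfinite(z)], np.linspace(0, 1, self.levels + 1)[1:-1])
        return (np.searchsorted(qs, z, side="right") + 1).astype(float)


@dataclass(frozen=True)
class ExpMap:
    """Nonnegative continuous scale: obs = exp(a + b z) (lognormal marginal)."""

    a: float = 3.5
    b: float = 0.35

    def __call__(self, z: np.ndarray, rng=None) -> np.ndarray:
        return np.exp(self.a + self.b * z)


def default_marginal_maps(node_labels=VARIABLES) -> dict:
    maps = {}
    for name in node_labels:
        if name == "social_contact":
            maps[name] = QuantileLikertMap()
        elif name == "physical_activity":
            maps[name] = ExpMap()
        else:
            maps[name] = LogisticMap()
    return maps


# ---------------------------------------------------------------------------
# generating network
# ---------------------------------------------------------------------------


@dataclass
class TrueNetworkSpec:
    """Generating analogue of the estimated lag-1 network.

    ``B_group[g][j, k]`` is the coefficient of predictor ``k`` at t-1 on
    outcome ``j`` at t (rows = outcome), on the latent scale.
    """

    node_labels: tuple
    B_group: list
    random_effect_sd: np.ndarray
    innovation_cov: np.ndarray
    spectral_cap: float = 0.9

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        k = len(self.node_labels)
        if len(set(self.node_labels)) != k:
            raise ValueError("node_labels has duplicates")
        self.B_group = [np.asarray(B, dtype=float) for B in self.B_group]
        self.random_effect_sd = np.asarray(self.random_effect_sd, dtype=float)
        self.innovation_cov = np.asarray(self.innovation_cov, dtype=float)
        for B in self.B_group:
            if B.shape != (k, k):
                raise ValueError("B_group matrices must conform to node_labels")
            if spectral_radius(B) > self.spectral_cap + 1e-12:
                raise ValueError("spectral radius exceeds spectral_cap")
        if self.random_effect_sd.shape != (k, k):
            raise ValueError("random_effect_sd must be k x k")
        if np.any(self.random_effect_sd < 0):
            raise ValueError("random_effect_sd must be nonnegative")
        if self.innovation_cov.shape != (k, k):
            raise ValueError("innovation_cov must be k x k")
        if not np.allclose(self.innovation_cov, self.innovation_cov.T):
            raise ValueError("innovation_cov must be symmetric")
        if np.linalg.eigvalsh(self.innovation_cov).min() <= 0:
            raise ValueError("innovation_cov must be positive definite")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    @property
    def n_groups(self) -> int:
        return len(self.B_group)

    def index(self, label: str) -> int:
        return self.node_labels.index(label)


def spectral_radius(B: np.ndarray) -> float:
    return float(np.abs(np.linalg.eigvals(B)).max())


def generate_true_network(
    n_groups: int = 2,
    sparsity: float = 0.3,
    group_delta: GroupDelta | tuple | None = None,
    seed: int = 0,
    node_labels=VARIABLES,
    diag_range: tuple = (0.13, 0.37),
    offdiag_range: tuple = (0.05, 0.15),
    random_effect_sd: float = 0.05,
    innovation_sd: float = 1.0,
    spectral_cap: float = 0.9,
    max_tries: int = 100,
) -> TrueNetworkSpec:
    """Draw a random generating network.

    Diagonal (autoregressive) coefficients are uniform on ``diag_range``,
    the moment-to-moment inertia range typical of EMA items. Each
    off-diagonal entry is nonzero with probability ``sparsity``, with random
    sign and magnitude uniform on ``offdiag_range``. If the spectral radius
    exceeds ``spectral_cap`` the matrix is rescaled below the cap. With a
    ``group_delta``, group 2's matrix differs from group 1's by exactly that
    amount on that single edge; draws for which the perturbed matrix
    violates the cap are rejected and redrawn (bounded retries).
    """
    if not 0.0 <= sparsity <= 1.0:
        raise ValueError("sparsity must lie in [0, 1]")
    if n_groups not in (1, 2):
        raise ValueError("n_groups must be 1 or 2")
    node_labels = tuple(node_labels)
    k = len(node_labels)
    if group_delta is not None and not isinstance(group_delta, GroupDelta):
        group_delta = GroupDelta(*group_delta)
    if group_delta is not None and n_groups != 2:
        raise ValueError("group_delta requires n_groups=2")

    rng = np.random.default_rng(seed)
    for _ in range(max_tries):
        B = np.zeros((k, k))
        np.fill_diagonal(B, rng.uniform(*diag_range, size=k))
        off = ~np.eye(k, dtype=bool)
        nz = rng.random((k, k)) < sparsity
        mag = rng.uniform(*offdiag_range, size=(k, k))
        sign = rng.choice([-1.0, 1.0], size=(k, k))
        B[off & nz] = (sign * mag)[off & nz]
        rho = spectral_radius(B)
        if rho >= spectral_cap:
            B *= 0.95 * spectral_cap / rho
        groups = [B]
        if n_groups == 2:
            B2 = B.copy()
            if group_delta is not None:
                j = node_labels.index(group_delta.target)
                i = node_labels.index(group_delta.source)
                B2[j, i] += group_delta.amount
                if spectral_radius(B2) >= spectral_cap:
                    continue  # redraw: rescaling would break the exact delta
            groups.append(B2)
        return TrueNetworkSpec(
            node_labels=node_labels,
            B_group=groups,
            random_effect_sd=np.full((k, k), float(random_effect_sd)),
            innovation_cov=np.eye(k) * innovation_sd**2,
            spectral_cap=spectral_cap,
        )
    raise RuntimeError(
        f"could not satisfy spectral_cap={spectral_cap} after {max_tries} draws"
    )


# ---------------------------------------------------------------------------
# EMA dataset
# ---------------------------------------------------------------------------


@dataclass
class SimulationConfig:
    """Study-design parameters for the EMA simulation.

    Defaults reproduce the emulated design: ~130 subjects per group, 7 days
    of 8 prompts randomized within 105-minute blocks between 08:00 and
    22:00, and 17.5% of prompts missed completely at random.
    """

    n_subjects_per_group: int = 130
    n_days: int = 7
    beeps_per_day: int = 8
    block_minutes: float = 105.0
    day_window: tuple = ("08:00", "22:00")
    missing_rate: float = 0.175
    pa_missing_rate: float = 0.008  # nonwear-like dropout of the activity value
    subject_mean_sd: float = 1.0  # between-subject SD of latent trait means
    marginal_maps: dict | None = None
    start_date: str = "2020-08-08"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_rate <= 0.5:
            raise ValueError("missing_rate must lie in [0, 0.5]")
        if self.n_subjects_per_group < 1 or self.n_days < 1 or self.beeps_per_day < 1:
            raise ValueError("counts must be positive")
        lo, hi = (pd.Timedelta(f"{t}:00") for t in self.day_window)
        window_min = (hi - lo).total_seconds() / 60.0
        if self.beeps_per_day * self.block_minutes > window_min + 1e-9:
            raise ValueError("beep blocks do not fit inside day_window")

    @property
    def beeps_per_subject(self) -> int:
        return self.n_days * self.beeps_per_day


@dataclass
class EmaDataset:
    """Long-format multi-subject beep-level observations.

    ``data`` columns: subject_id, group, day (1-based), beep (1-based within
    day), timestamp, then one column per variable (NaN = missing).
    """

    data: pd.DataFrame
    node_labels: tuple
    provenance: str = "synthetic"
    true_spec: TrueNetworkSpec | None = None

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        key = ["subject_id", "day", "beep"]
        if self.data.duplicated(key).any():
            raise ValueError("duplicate (subject_id, day, beep) rows")
        ts = self.data.sort_values(key).groupby("subject_id")["timestamp"]
        if not ts.apply(lambda s: s.is_monotonic_increasing and s.is_unique).all():
            raise ValueError("timestamps must be strictly increasing within subject")

    @property
    def groups(self) -> tuple:
        return tuple(pd.unique(self.data["group"]))

    def realized_missingness(self) -> pd.Series:
        """Per-subject fraction of prompts with all EMA items missing."""
        items = [v for v in self.node_labels if v != "physical_activity"]
        miss = self.data[items].isna().all(axis=1)
        return miss.groupby(self.data["subject_id"]).mean()


def _beep_schedule(config: SimulationConfig, rng: np.random.Generator) -> pd.Series:
    """Timestamps of one subject's prompts: uniform within successive blocks."""
    day0 = pd.Timestamp(config.start_date)
    window_start = pd.Timedelta(f"{config.day_window[0]}:00")
    block = pd.Timedelta(minutes=config.block_minutes)
    times = []
    for d in range(config.n_days):
        base = day0 + pd.Timedelta(days=d) + window_start
        # whole-second resolution, matching what a prompt app would log
        offsets = rng.integers(0, int(config.block_minutes * 60), size=config.beeps_per_day)
        for b in range(config.beeps_per_day):
            times.append(base + b * block + pd.Timedelta(seconds=int(offsets[b])))
    return pd.Series(times)


def _draw_subject_matrix(
    B: np.ndarray, sd: np.ndarray, rng: np.random.Generator, max_tries: int = 100
) -> np.ndarray:
    """Subject coefficient matrix: B + entrywise normal noise, resampled
    until stationary (spectral radius < 1)."""
    if not np.any(sd > 0):
        return B.copy()
    for _ in range(max_tries):
        Bi = B + rng.normal(0.0, 1.0, B.shape) * sd
        if spectral_radius(Bi) < 1.0:
            return Bi
    raise RuntimeError("could not draw a stationary subject matrix")


def _simulate_subject_latent(
    Bi: np.ndarray, innov_chol: np.ndarray, innovation_cov: np.ndarray,
    config: SimulationConfig, rng: np.random.Generator,
) -> np.ndarray:
    """Latent VAR(1) series for one subject; each day restarts from the
    stationary distribution (overnight gaps break the lag-1 chain)."""
    k = Bi.shape[0]
    cov0 = solve_discrete_lyapunov(Bi, innovation_cov)
    # enforce symmetry before Cholesky (numerical asymmetry from the solver)
    L0 = np.linalg.cholesky((cov0 + cov0.T) / 2.0 + 1e-12 * np.eye(k))
    out = np.empty((config.beeps_per_subject, k))
    row = 0
    for _d in range(config.n_days):
        x = L0 @ rng.normal(size=k)
        out[row] = x
        row += 1
        for _b in range(config.beeps_per_day - 1):
            x = Bi @ x + innov_chol @ rng.normal(size=k)
            out[row] = x
            row += 1
    return out


def _missing_mask(
    n_beeps: int, rate: float, rng: np.random.Generator, max_tries: int = 1000
) -> np.ndarray:
    """MCAR prompt mask, redrawn until realized missingness <= 0.5."""
    if rate == 0.0:
        return np.zeros(n_beeps, dtype=bool)
    for _ in range(max_tries):
        m = rng.random(n_beeps) < rate
        if m.mean() <= 0.5:
            return m
    raise RuntimeError("could not draw a mask with missingness <= 0.5")


def generate_dataset(spec: TrueNetworkSpec, config: SimulationConfig) -> EmaDataset:
    """Simulate a multilevel VAR(1) EMA dataset for every group in ``spec``.

    Per subject: a coefficient matrix ``B_i = B_group + noise`` (resampled
    until stationary) and a latent trait mean ``mu_i`` drive a latent VAR(1);
    latent values are pushed through strictly monotone marginal maps (fitted
    on the group's pooled latents where the map is quantile-based); prompts
    are deleted completely at random at ``missing_rate``. Identical
    (spec, config) including the seed reproduces the dataset bit-for-bit.
    """
    k = spec.n_nodes
    maps = config.marginal_maps or default_marginal_maps(spec.node_labels)
    if set(maps) != set(spec.node_labels):
        raise ValueError("marginal_maps keys must match spec.node_labels")
    innov_chol = np.linalg.cholesky(spec.innovation_cov)

    rng = np.random.default_rng(config.seed)
    frames = []
    for g, B in enumerate(spec.B_group):
        glabel = GROUP_LABELS[g] if len(spec.B_group) <= len(GROUP_LABELS) else f"group{g+1}"
        latents = []
        meta = []
        for s in range(config.n_subjects_per_group):
            sid = f"{glabel}_{s+1:03d}"
            Bi = _draw_subject_matrix(B, spec.random_effect_sd, rng)
            mu = rng.normal(0.0, config.subject_mean_sd, size=k)
            lat = _simulate_subject_latent(Bi, innov_chol, spec.innovation_cov, config, rng) + mu
            latents.append(lat)
            ts = _beep_schedule(config, rng)
            meta.append(
                pd.DataFrame(
                    {
                        "subject_id": sid,
                        "group": glabel,
                        "day": np.repeat(np.arange(1, config.n_days + 1), config.beeps_per_day),
                        "beep": np.tile(np.arange(1, config.beeps_per_day + 1), config.n_days),
                        "timestamp": ts,
                    }
                )
            )
        lat_all = np.vstack(latents)  # pooled within group for quantile maps
        obs = np.column_stack(
            [maps[name](lat_all[:, j]) for j, name in enumerate(spec.node_labels)]
        )
        gframe = pd.concat(meta, ignore_index=True)
        for j, name in enumerate(spec.node_labels):
            gframe[name] = obs[:, j]
        # MCAR deletion: whole prompts for the EMA items, separate thin
        # dropout for the activity column (emulating nonwear exclusion).
        items = [v for v in spec.node_labels if v != "physical_activity"]
        n_b = config.beeps_per_subject
        for s in range(config.n_subjects_per_group):
            rows = slice(s * n_b, (s + 1) * n_b)
            mask = _missing_mask(n_b, config.missing_rate, rng)
            gframe.loc[gframe.index[rows][mask], items] = np.nan
            if "physical_activity" in spec.node_labels and config.pa_missing_rate > 0:
                pa_mask = rng.random(n_b) < config.pa_missing_rate
                gframe.loc[gframe.index[rows][pa_mask], "physical_activity"] = np.nan
        frames.append(gframe)

    data = pd.concat(frames, ignore_index=True)
    return EmaDataset(data=data, node_labels=spec.node_labels, provenance="synthetic", true_spec=spec)


# ---------------------------------------------------------------------------
# raw accelerometry
# ---------------------------------------------------------------------------


@dataclass
class AccelProfile:
    """Segment layout of one synthetic recording.

    ``rest_segments``, ``activity_segments`` and ``nonwear_segments`` are
    half-open ``(start, end)`` intervals in seconds that must be disjoint
    and jointly cover ``[0, duration)``.
    """

    duration: float
    sampling_rate: float = 10.0
    rest_segments: list = field(default_factory=list)
    activity_segments: list = field(default_factory=list)
    nonwear_segments: list = field(default_factory=list)
    noise_sd: float = 5.0  # mg, wear-segment sensor noise
    nonwear_noise_sd: float = 2.0  # mg, still-device noise (clipped)
    orientation_change_s: float = 120.0  # wrist re-orientation cadence at rest
    activity_amp_range: tuple = (50.0, 300.0)  # mg burst amplitude
    activity_freq_range: tuple = (0.5, 3.0)  # Hz, arm-swing band

    def __post_init__(self) -> None:
        if not 10.0 <= self.sampling_rate <= 100.0:
            raise ValueError("sampling_rate must lie in the device range 10-100 Hz")
        segs = self.all_segments()
        if not segs:
            raise ValueError("profile has no segments")
        pos = 0.0
        for s, e, _kind in sorted(segs, key=lambda t: t[0]):
            if s < pos - 1e-9:
                raise ValueError("segments overlap")
            if s > pos + 1e-9:
                raise ValueError("segments do not cover the duration (gap)")
            if e <= s:
                raise ValueError("empty segment")
            pos = e
        if abs(pos - self.duration) > 1e-9:
            raise ValueError("segments do not cover the duration")

    def all_segments(self) -> list:
        return (
            [(s, e, "rest") for s, e in self.rest_segments]
            + [(s, e, "activity") for s, e in self.activity_segments]
            + [(s, e, "nonwear") for s, e in self.nonwear_segments]
        )


def _random_orientation(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_raw_accel(profile: AccelProfile, seed: int = 0) -> RawAccelSignal:
    """Synthesize a triaxial recording in milligravity.

    Rest: gravity along a piecewise-constant random orientation (re-drawn
    every ``orientation_change_s``) plus white noise, so the vector norm
    stays near 1000 mg while per-axis ranges over long windows stay large
    enough not to mimic nonwear. Activity: rest plus band-limited sinusoidal
    bursts. Nonwear: one fixed orientation plus tiny clipped noise, keeping
    per-axis std and range below the default nonwear thresholds by
    construction.
    """
    rng = np.random.default_rng(seed)
    rate = profile.sampling_rate
    n = int(round(profile.duration * rate))
    t = np.arange(n) / rate
    a = np.empty((n, 3))

    for s, e, kind in sorted(profile.all_segments(), key=lambda x: x[0]):
        idx = (t >= s) & (t < e)
        m = int(idx.sum())
        if m == 0:
            continue
        if kind == "nonwear":
            g = _random_orientation(rng) * 1000.0
            noise = rng.normal(0.0, profile.nonwear_noise_sd, size=(m, 3))
            clip = 4.0 * profile.nonwear_noise_sd
            a[idx] = g + np.clip(noise, -clip, clip)
            continue
        # wear: piecewise-constant orientation
        tt = t[idx]
        chunk = np.floor((tt - s) / profile.orientation_change_s).astype(int)
        seg = np.empty((m, 3))
        for c in np.unique(chunk):
            g = _random_orientation(rng) * 1000.0
            seg[chunk == c] = g
        seg += rng.normal(0.0, profile.noise_sd, size=(m, 3))
        if kind == "activity":
            for ax in range(3):
                f = rng.uniform(*profile.activity_freq_range)
                amp = rng.uniform(*profile.activity_amp_range)
                phase = rng.uniform(0, 2 * np.pi)
                seg[:, ax] += amp * np.sin(2 * np.pi * f * tt + phase)
        a[idx] = seg

    return RawAccelSignal(t, a[:, 0], a[:, 1], a[:, 2], rate)
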