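"""Analysis-table assembly, nonparanormal transformation, stationarity checks.

The analysis table joins the six self-report items with the actigraphy
summary into one long-format table of (subject, day, beep) rows over the
seven analysis variables. Because the observed marginals are bounded and
markedly nonnormal (visual-analog scales pile up at the ends, the Likert
item is ordinal, activity is right-skewed), every variable is passed
through the nonparanormal transformation — the rank-based gaussianization
of the Gaussian-copula model — before the VAR is fit: values are mapped
through the truncated empirical CDF to standard-normal quantiles, with the
Winsorization level

    delta_n = 1 / (4 n^{1/4} sqrt(pi log n))

controlling the tail behaviour of the estimate.

Two stationarity diagnostics mirror the usual screening of intensive
longitudinal data: the per-variable "moment-to-moment inertia" (the
fixed-effect coefficient of a two-level AR(1), a value above 1 indicating a
nonstationary process) and a per-(subject, variable) KPSS battery.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .mlvar import random_intercept_fit
from .synthetic import EmaDataset

__all__ = [
    "AnalysisTable",
    "StationarityReport",
    "assemble_analysis_table",
    "nonparanormal_transform",
    "npn_column",
    "standardize_table",
    "inertia_diagnostic",
    "kpss_stationarity",
]

log = logging.getLogger(__name__)

#: inertia above this is flagged outright nonstationary; above the lower
#: bound of the band it is flagged borderline (a warning, not an exclusion).
INERTIA_NONSTATIONARY = 1.0
INERTIA_WARN = 0.9


@dataclass
class AnalysisTable:
    """Long-format analysis data plus the untransformed originals.

    ``data`` holds the current analysis values (raw, transformed or
    standardized depending on the processing stage); ``raw`` always keeps
    the original observed scales for descriptive statistics.
    """

    data: pd.DataFrame
    node_labels: tuple
    raw: pd.DataFrame | None = None
    transform: str | None = None
    excluded_subjects: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        if self.raw is None:
            self.raw = self.data.copy()

    @property
    def groups(self) -> tuple:
        return tuple(pd.unique(self.data["group"]))

    @property
    def subjects(self) -> np.ndarray:
        return pd.unique(self.data["subject_id"])

    def for_group(self, group: str) -> "AnalysisTable":
        m = self.data["group"] == group
        return AnalysisTable(
            data=self.data[m].reset_index(drop=True),
            node_labels=self.node_labels,
            raw=self.raw[m.to_numpy()].reset_index(drop=True),
            transform=self.transform,
        )


@dataclass
class StationarityReport:
    """Output of either stationarity diagnostic (fields filled as
    applicable)."""

    inertia: pd.DataFrame | None = None  # group, variable, coef, se, flag
    kpss: pd.DataFrame | None = None  # subject, variable, statistic, p, stationary
    proportion_stationary: float | None = None
    n_skipped: int = 0

    def to_dict(self) -> dict:
        d: dict = {"n_skipped": int(self.n_skipped)}
        if self.proportion_stationary is not None:
            d["proportion_stationary"] = float(self.proportion_stationary)
        if self.inertia is not None:
            d["inertia"] = self.inertia.to_dict(orient="records")
        if self.kpss is not None:
            d["kpss"] = self.kpss.to_dict(orient="records")
        return d


def assemble_analysis_table(
    ema: EmaDataset,
    activity=None,
    max_missing: float = 0.5,
) -> AnalysisTable:
    """Join the EMA items with per-beep activity summaries.

    ``activity`` is a list of BeepActivity whose timestamps match the EMA
    beep timestamps exactly; rows without an activity value are kept with a
    missing flag. When ``activity`` is None the dataset's own
    physical_activity column (synthetic provenance) is used. Subjects who
    missed more than ``max_missing`` of their prompts are excluded, with
    the reason logged.
    """
    df = ema.data.copy()
    key = ["subject_id", "day", "beep"]
    if df.duplicated(key).any():
        raise ValueError("duplicate beep keys in EMA data")

    if activity is not None:
        act = pd.DataFrame(
            {
                "subject_id": [a.subject_id for a in activity],
                "timestamp": [a.timestamp for a in activity],
                "physical_activity": [a.mean_enmo for a in activity],
            }
        )
        if not set(act["subject_id"]) & set(df["subject_id"]):
            raise ValueError("EMA and actigraphy subject sets are disjoint")
        df = df.drop(columns=["physical_activity"], errors="ignore").merge(
            act, on=["subject_id", "timestamp"], how="left"
        )
    elif "physical_activity" not in df.columns and "physical_activity" in ema.node_labels:
        raise ValueError("no activity summaries and no physical_activity column")

    labels = tuple(ema.node_labels)
    items = [v for v in labels if v != "physical_activity"]
    prompt_missing = df[items].isna().all(axis=1)
    frac = prompt_missing.groupby(df["subject_id"]).mean()
    dropped = frac[frac > max_missing]
    excluded = {
        sid: f"missed {100 * f:.1f}% of prompts (> {100 * max_missing:.0f}%)"
        for sid, f in dropped.items()
    }
    for sid, reason in excluded.items():
        log.info("excluding subject %s: %s", sid, reason)
    df = df[~df["subject_id"].isin(dropped.index)].reset_index(drop=True)
    return AnalysisTable(data=df, node_labels=labels, excluded_subjects=excluded)


# ---------------------------------------------------------------------------
# nonparanormal transformation
# ---------------------------------------------------------------------------


def npn_column(x: np.ndarray) -> np.ndarray:
    """Nonparanormal transform of one column (NaNs pass through).

    Ranks (ties averaged) over the non-missing values are scaled to the
    empirical CDF, Winsorized at ``delta_n = 1/(4 n^{1/4} sqrt(pi log n))``
    and mapped to standard-normal quantiles.
    """
    x = np.asarray(x, dtype=float)
    out = np.full_like(x, np.nan)
    obs = np.isfinite(x)
    v = x[obs]
    n = len(v)
    if n < 2 or np.unique(v).size < 2:
        raise ValueError("nonparanormal transform needs >= 2 distinct values")
    u = stats.rankdata(v, method="average") / n
    delta = 1.0 / (4.0 * n**0.25 * math.sqrt(math.pi * math.log(n)))
    u = np.clip(u, delta, 1.0 - delta)
    out[obs] = stats.norm.ppf(u)
    return out


def nonparanormal_transform(table: AnalysisTable, per: str = "group") -> AnalysisTable:
    """Gaussianize every analysis variable.

    ``per`` selects the pooling level the empirical CDF is fitted on:
    ``"group"`` (default — one CDF per variable per group), ``"subject"``
    or ``"pooled"``. Missing values stay missing; a constant column raises
    with the variable named.
    """
    if per not in ("group", "subject", "pooled"):
        raise ValueError("per must be 'group', 'subject' or 'pooled'")
    df = table.data.copy()
    by = {"group": "group", "subject": "subject_id"}.get(per)
    for var in table.node_labels:
        try:
            if by is None:
                df[var] = npn_column(df[var].to_numpy())
            else:
                df[var] = (
                    df.groupby(by, group_keys=False)[var]
                    .apply(lambda s: pd.Series(npn_column(s.to_numpy()), index=s.index))
                )
        except ValueError as err:
            raise ValueError(f"variable {var!r}: {err}") from err
    return AnalysisTable(
        data=df,
        node_labels=table.node_labels,
        raw=table.raw,
        transform=f"nonparanormal/{per}",
        excluded_subjects=table.excluded_subjects,
    )


def standardize_table(table: AnalysisTable, per: str = "group") -> AnalysisTable:
    """z-score each variable (within group by default) so edge weights are
    comparable across the network."""
    df = table.data.copy()
    by = "group" if per == "group" else None
    for var in table.node_labels:
        if by is None:
            df[var] = (df[var] - df[var].mean()) / df[var].std(ddof=1)
        else:
            g = df.groupby(by)[var]
            df[var] = (df[var] - g.transform("mean")) / g.transform("std")
    return AnalysisTable(
        data=df,
        node_labels=table.node_labels,
        raw=table.raw,
        transform=(table.transform or "") + "+zscore",
        excluded_subjects=table.excluded_subjects,
    )


# ---------------------------------------------------------------------------
# stationarity diagnostics
# ---------------------------------------------------------------------------


def _inertia_flag(coef: float) -> str:
    if coef > INERTIA_NONSTATIONARY:
        return "nonstationary"
    if coef > INERTIA_WARN:
        return "borderline"
    return "stationary"


def inertia_diagnostic(table: AnalysisTable) -> StationarityReport:
    """Moment-to-moment inertia per variable and group.

    For each variable, the score is regressed on the immediately preceding
    score of that variable (lag-1 within subject-day) in a two-level model
    with a random intercept per subject; the fixed-effect autoregressive
    coefficient is the inertia. Values above 1 are flagged nonstationary,
    values above 0.9 borderline.
    """
    rows = []
    for group in table.groups:
        sub = table.data[table.data["group"] == group]
        sub = sub.sort_values(["subject_id", "day", "beep"])
        sid = sub["subject_id"].to_numpy()
        day = sub["day"].to_numpy()
        beep = sub["beep"].to_numpy()
        consec = np.zeros(len(sub), dtype=bool)
        if len(sub) > 1:
            consec[1:] = (
                (sid[1:] == sid[:-1]) & (day[1:] == day[:-1]) & (beep[1:] == beep[:-1] + 1)
            )
        if pd.unique(sid).size < 2:
            raise ValueError("inertia diagnostic needs >= 2 subjects per group")
        for var in table.node_labels:
            v = sub[var].to_numpy(dtype=float)
            ok = consec.copy()
            ok &= np.isfinite(v)
            ok[1:] &= np.isfinite(v[:-1])
            if ok.sum() < 3:
                raise ValueError(f"not enough lag pairs for {var!r} in group {group!r}")
            y = v[ok]
            x = v[np.flatnonzero(ok) - 1]
            subjects = sid[ok]
            xc = x.copy()
            for s in np.unique(subjects):
                m = subjects == s
                xc[m] -= x[m].mean()
            fit = random_intercept_fit(y, xc[:, None], subjects)
            coef = float(fit["beta"][0])
            rows.append(
                {
                    "group": group,
                    "variable": var,
                    "inertia": coef,
                    "se": float(fit["se"][0]),
                    "flag": _inertia_flag(coef),
                }
            )
    return StationarityReport(inertia=pd.DataFrame(rows))


def kpss_stationarity(table: AnalysisTable, alpha: float = 0.05, min_length: int = 10) -> StationarityReport:
    """Level-stationarity KPSS test per (subject, variable).

    The KPSS null is stationarity, so a series is counted stationary when
    the test fails to reject at ``alpha``. Series shorter than
    ``min_length`` non-missing points, or constant, are skipped and
    counted.
    """
    import warnings

    from statsmodels.tsa.stattools import kpss

    rows = []
    skipped = 0
    for (sid, _group), sub in table.data.groupby(["subject_id", "group"], sort=True):
        sub = sub.sort_values(["day", "beep"])
        for var in table.node_labels:
            v = sub[var].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if len(v) < min_length or np.ptp(v) == 0:
                skipped += 1
                continue
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                stat, p, *_ = kpss(v, regression="c", nlags="auto")
            rows.append(
                {
                    "subject_id": sid,
                    "variable": var,
                    "statistic": float(stat),
                    "p": float(p),
                    "stationary": bool(p > alpha),
                }
            )
    if skipped:
        log.info("kpss: skipped %d series (too short or constant)", skipped)
    kdf = pd.DataFrame(rows)
    prop = float(kdf["stationary"].mean()) if len(kdf) else float("nan")
    return StationarityReport(kpss=kdf, proportion_stationary=prop, n_skipped=skipped)
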