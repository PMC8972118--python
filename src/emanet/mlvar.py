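"""Multilevel lag-1 vector autoregression estimated nodewise.

The temporal network is a directed graph over the analysis variables whose
edge (k -> j) is the fixed-effect coefficient of predictor k at occasion
t-1 on outcome j at occasion t, estimated across subjects with a
per-subject random intercept. Following the usual mlVAR recipe, each
outcome is fit in its own mixed-effects regression on all seven
within-person-centered lagged predictors; lag-1 pairs are formed only
between consecutive prompts within the same day (overnight intervals break
the equal-spacing premise).

Estimation detail that the speed of the permutation machinery rests on:
when every predictor column sums to zero within each subject, the GLS
fixed-effect slopes of the random-intercept model do not depend on the
variance ratio and reduce to pooled least squares on the centered
predictors, with slope covariance ``sigma_e^2 (Xc' Xc)^{-1}``. The default
backend exploits this closed form; ``backend="mixedlm"`` fits the same
model (optionally with uncorrelated random slopes) through statsmodels and
is used in the test suite as an independent cross-check.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "LaggedDesign",
    "TemporalNetwork",
    "EstimationOptions",
    "build_lagged_design",
    "fit_temporal_network",
    "significant_edges",
]


@dataclass
class LaggedDesign:
    """Stacked outcome/centered-predictor pairs for the nodewise fits.

    ``y[i]`` holds the k outcomes at occasion t of pair i; ``x_centered[i]``
    the k predictors at t-1, centered on the subject's own mean over the
    included pairs. No pair spans a day boundary or a missing endpoint.
    """

    y: np.ndarray  # (n, k)
    x_centered: np.ndarray  # (n, k)
    subject_ids: np.ndarray  # (n,)
    node_labels: tuple
    n_dropped_missing: int = 0
    n_dropped_boundary: int = 0

    @property
    def n_pairs(self) -> int:
        return self.y.shape[0]

    @property
    def n_subjects(self) -> int:
        return len(np.unique(self.subject_ids))


@dataclass
class EstimationOptions:
    backend: str = "closed_form"  # or "mixedlm"
    random_slopes: bool = False  # uncorrelated slopes, mixedlm backend only
    reml: bool = True

    def __post_init__(self) -> None:
        if self.backend not in ("closed_form", "mixedlm"):
            raise ValueError(f"unknown backend {self.backend!r}")
        if self.random_slopes and self.backend != "mixedlm":
            raise ValueError("random slopes require backend='mixedlm'")


@dataclass
class TemporalNetwork:
    """Directed lag-1 network: ``B[j, k]`` predicts outcome j from lagged
    predictor k (diagonal = autoregressive effects)."""

    node_labels: tuple
    B: np.ndarray
    SE: np.ndarray
    p: np.ndarray
    n_subjects: int
    n_pairs: int
    intercepts: np.ndarray | None = None
    resid_sd: np.ndarray | None = None
    random_intercept_sd: np.ndarray | None = None
    df: float | None = None

    def __post_init__(self) -> None:
        self.node_labels = tuple(self.node_labels)
        k = len(self.node_labels)
        for name in ("B", "SE", "p"):
            m = np.asarray(getattr(self, name), dtype=float)
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k} x {k}")
            setattr(self, name, m)
        if np.nanmin(self.p) < 0 or np.nanmax(self.p) > 1:
            raise ValueError("p-values must lie in [0, 1]")

    @property
    def n_nodes(self) -> int:
        return len(self.node_labels)

    def edge_list(self) -> pd.DataFrame:
        rows = []
        for j, out in enumerate(self.node_labels):
            for k_, pred in enumerate(self.node_labels):
                rows.append(
                    {
                        "predictor": pred,
                        "outcome": out,
                        "weight": self.B[j, k_],
                        "se": self.SE[j, k_],
                        "p": self.p[j, k_],
                    }
                )
        return pd.DataFrame(rows)

    def to_dict(self) -> dict:
        d = {
            "node_labels": list(self.node_labels),
            "B": self.B.tolist(),
            "SE": self.SE.tolist(),
            "p": self.p.tolist(),
            "n_subjects": int(self.n_subjects),
            "n_pairs": int(self.n_pairs),
        }
        if self.df is not None:
            d["df"] = float(self.df)
        return d

    def to_json(self, path=None) -> str:
        s = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(s + "\n")
        return s

    @classmethod
    def from_dict(cls, d: dict) -> "TemporalNetwork":
        return cls(
            node_labels=tuple(d["node_labels"]),
            B=np.array(d["B"]),
            SE=np.array(d["SE"]),
            p=np.array(d["p"]),
            n_subjects=d["n_subjects"],
            n_pairs=d["n_pairs"],
            df=d.get("df"),
        )


def build_lagged_design(table, group: str | None = None) -> LaggedDesign:
    """Pair each prompt with the immediately preceding prompt of the same
    subject-day.

    ``table`` is an AnalysisTable (or anything with ``.data`` and
    ``.node_labels``). Pairs with any missing endpoint are dropped
    (listwise over the variables); predictors are then centered on the
    subject's mean over the retained pairs.
    """
    df = table.data
    labels = tuple(table.node_labels)
    if group is not None:
        df = df[df["group"] == group]
    cols = list(labels)
    df = df.sort_values(["subject_id", "day", "beep"])

    vals = df[cols].to_numpy(dtype=float)
    complete = np.isfinite(vals).all(axis=1)
    sub = df["subject_id"].to_numpy()
    day = df["day"].to_numpy()
    beep = df["beep"].to_numpy()

    prev_ok = np.zeros(len(df), dtype=bool)
    if len(df) > 1:
        prev_ok[1:] = (sub[1:] == sub[:-1]) & (day[1:] == day[:-1]) & (beep[1:] == beep[:-1] + 1)
    pair = prev_ok & complete
    pair[1:] &= complete[:-1]

    n_boundary = int((~prev_ok[1:]).sum())
    n_missing = int((prev_ok & ~pair).sum())
    if not pair.any():
        raise ValueError("no valid lag-1 pairs")

    y = vals[pair]
    x = vals[np.flatnonzero(pair) - 1]
    subjects = sub[pair]

    xc = x.copy()
    for s in np.unique(subjects):
        m = subjects == s
        xc[m] -= x[m].mean(axis=0)
    return LaggedDesign(
        y=y,
        x_centered=xc,
        subject_ids=subjects,
        node_labels=labels,
        n_dropped_missing=n_missing,
        n_dropped_boundary=n_boundary,
    )


# ---------------------------------------------------------------------------
# closed-form random-intercept engine
# ---------------------------------------------------------------------------


def random_intercept_fit(
    y: np.ndarray, xc: np.ndarray, subjects: np.ndarray
) -> dict:
    """Random-intercept regression of ``y`` on within-person-centered ``xc``.

    Returns slopes, their SEs, t-based p-values, the residual and
    random-intercept SDs and the residual degrees of freedom. Slopes are
    exact GLS (independent of the variance ratio because the predictors are
    centered within subject); the within residual variance is a
    method-of-moments estimate.
    """
    from scipy import stats

    y = np.asarray(y, dtype=float)
    xc = np.atleast_2d(np.asarray(xc, dtype=float))
    if xc.shape[0] != len(y):
        xc = xc.T
    n, p = xc.shape

    G = xc.T @ xc
    try:
        Ginv = np.linalg.inv(G)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError("singular design (collinear predictors)") from err
    beta = Ginv @ (xc.T @ y)

    # subject-wise residual decomposition
    codes, _ = pd.factorize(subjects)
    S = codes.max() + 1
    resid = y - xc @ beta
    n_s = np.bincount(codes, minlength=S).astype(float)
    mean_s = np.bincount(codes, weights=resid, minlength=S) / n_s
    within = resid - mean_s[codes]
    df = n - S - p
    if df <= 0:
        raise ValueError("not enough within-subject pairs for the fit")
    s2e = float(within @ within) / df
    grand = resid.mean()
    ssb = float(np.sum(n_s * (mean_s - grand) ** 2))
    nbar = n_s.mean()
    s2b = max(0.0, (ssb / max(S - 1, 1) - s2e) / nbar)

    se = np.sqrt(s2e * np.diag(Ginv))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, 0.0)
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    return {
        "beta": beta,
        "se": se,
        "p": pvals,
        "intercept": float(grand),
        "resid_sd": float(np.sqrt(s2e)),
        "random_intercept_sd": float(np.sqrt(s2b)),
        "df": float(df),
    }


def _fit_closed_form(design: LaggedDesign) -> TemporalNetwork:
    k = len(design.node_labels)
    B = np.empty((k, k))
    SE = np.empty((k, k))
    P = np.empty((k, k))
    intercepts = np.empty(k)
    rsd = np.empty(k)
    risd = np.empty(k)
    df = None
    for j in range(k):
        fit = random_intercept_fit(design.y[:, j], design.x_centered, design.subject_ids)
        B[j] = fit["beta"]
        SE[j] = fit["se"]
        P[j] = fit["p"]
        intercepts[j] = fit["intercept"]
        rsd[j] = fit["resid_sd"]
        risd[j] = fit["random_intercept_sd"]
        df = fit["df"]
    return TemporalNetwork(
        node_labels=design.node_labels,
        B=B,
        SE=SE,
        p=P,
        n_subjects=design.n_subjects,
        n_pairs=design.n_pairs,
        intercepts=intercepts,
        resid_sd=rsd,
        random_intercept_sd=risd,
        df=df,
    )


def _fit_mixedlm(design: LaggedDesign, options: EstimationOptions) -> TemporalNetwork:
    import statsmodels.api as sm
    from statsmodels.regression.mixed_linear_model import MixedLM, MixedLMParams

    k = len(design.node_labels)
    X = sm.add_constant(design.x_centered)
    B = np.empty((k, k))
    SE = np.empty((k, k))
    P = np.empty((k, k))
    for j in range(k):
        yj = design.y[:, j]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if options.random_slopes:
                exog_re = X  # intercept + slopes
                model = MixedLM(yj, X, groups=design.subject_ids, exog_re=exog_re)
                free = MixedLMParams.from_components(
                    fe_params=np.ones(k + 1), cov_re=np.eye(k + 1)
                )
                try:
                    res = model.fit(reml=options.reml, free=free, method="lbfgs")
                except (np.linalg.LinAlgError, ValueError):
                    warnings.warn(
                        f"random-slope fit failed for outcome "
                        f"{design.node_labels[j]!r}; refitting intercept-only"
                    )
                    res = MixedLM(yj, X, groups=design.subject_ids).fit(reml=options.reml)
            else:
                res = MixedLM(yj, X, groups=design.subject_ids).fit(reml=options.reml)
        B[j] = res.fe_params[1:]
        SE[j] = res.bse_fe[1:]
        P[j] = res.pvalues[1 : k + 1]
    return TemporalNetwork(
        node_labels=design.node_labels,
        B=B,
        SE=SE,
        p=P,
        n_subjects=design.n_subjects,
        n_pairs=design.n_pairs,
    )


def fit_temporal_network(
    design: LaggedDesign, options: EstimationOptions | None = None
) -> TemporalNetwork:
    """Estimate the group-level temporal network from a lagged design."""
    options = options or EstimationOptions()
    if design.n_subjects < 2:
        raise ValueError("multilevel estimation needs at least 2 subjects")
    if design.n_pairs / design.n_subjects < 2:
        raise ValueError("too few lag-1 pairs per subject")
    if options.backend == "closed_form":
        return _fit_closed_form(design)
    return _fit_mixedlm(design, options)


def significant_edges(network: TemporalNetwork, alpha: float = 0.05) -> pd.DataFrame:
    """Directed edges with p < alpha (self-loops included), ordered by
    |weight| descending with label ties broken alphabetically."""
    if not 0.0 < alpha <= 1.0:
        raise ValueError("alpha must lie in (0, 1]")
    edges = network.edge_list()
    sig = edges[edges["p"] < alpha].copy()
    sig["abs_w"] = sig["weight"].abs()
    sig = sig.sort_values(
        ["abs_w", "predictor", "outcome"], ascending=[False, True, True]
    ).drop(columns="abs_w")
    return sig.reset_index(drop=True)
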