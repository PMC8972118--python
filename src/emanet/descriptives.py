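"""Person-mean group comparisons (the averaged, non-dynamic view).

Each subject is reduced to their mean on every variable (on the raw
observed scales), and the two groups are compared variable-by-variable
with Welch's unequal-variance t-test using the Welch-Satterthwaite
approximation to the degrees of freedom.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["person_means", "welch_t", "group_comparison_table"]

log = logging.getLogger(__name__)


def person_means(table) -> pd.DataFrame:
    """Per-subject mean of each variable over all non-missing beeps.

    Means are taken on the untransformed scales (``table.raw``). A subject
    with no data at all for a variable gets a missing mean, logged.
    """
    raw = table.raw
    cols = list(table.node_labels)
    out = raw.groupby(["subject_id", "group"], sort=True)[cols].mean().reset_index()
    n_missing = int(out[cols].isna().sum().sum())
    if n_missing:
        log.info("person_means: %d subject-variable means are missing", n_missing)
    return out


def welch_t(means_a, means_b) -> tuple[float, float, float]:
    """Welch two-sample t-test: returns (t, df, two-sided p).

    ``t`` is positive when group A's mean exceeds group B's.
    """
    a = np.asarray(means_a, dtype=float)
    b = np.asarray(means_b, dtype=float)
    a = a[np.isfinite(a)]
    b = b[np.isfinite(b)]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 finite values")
    res = stats.ttest_ind(a, b, equal_var=False)
    return float(res.statistic), float(res.df), float(res.pvalue)


def group_comparison_table(table, group1: str | None = None, group2: str | None = None) -> pd.DataFrame:
    """Per-variable mean (SD) of person means per group, with Welch p.

    Groups default to the table's two groups in order of appearance.
    """
    pm = person_means(table)
    groups = list(pd.unique(pm["group"]))
    if group1 is None or group2 is None:
        if len(groups) != 2:
            raise ValueError("table must contain exactly 2 groups (or name them)")
        group1, group2 = groups
    rows = []
    for var in table.node_labels:
        a = pm.loc[pm["group"] == group1, var]
        b = pm.loc[pm["group"] == group2, var]
        t, df, p = welch_t(a, b)
        rows.append(
            {
                "variable": var,
                f"mean_{group1}": a.mean(),
                f"sd_{group1}": a.std(ddof=1),
                f"mean_{group2}": b.mean(),
                f"sd_{group2}": b.std(ddof=1),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)
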