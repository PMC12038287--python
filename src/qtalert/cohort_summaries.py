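"""Descriptive cohort outputs: cluster comparison cells, alert-response
cross-tabulations, and pre/post-CDS era counts.

Standardized measures follow the study convention: for a continuous
variable, the standardized mean difference of a cluster against the whole
population ((cluster mean - population mean) / population SD); for a binary
variable, the ratio of the cluster's odds to the population's odds, with
odds computed on the percent scale as pct / (100 - pct).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .comorbidity_clusters import bin_age

__all__ = [
    "smd",
    "cluster_or",
    "pct",
    "response_table",
    "era_table",
    "compare_groups",
]


def smd(cluster_mean: float, pop_mean: float, pop_sd: float) -> float:
    """Standardized mean difference: (cluster_mean - pop_mean) / pop_sd."""
    if pop_sd <= 0:
        raise ValueError("population SD must be positive")
    return (cluster_mean - pop_mean) / pop_sd


def cluster_or(cluster_pct: float, pop_pct: float) -> float:
    """Population-standardized odds ratio from two percentages in (0, 100)."""
    for p in (cluster_pct, pop_pct):
        if not 0 < p < 100:
            raise ValueError("percentages must lie strictly between 0 and 100")
    return (cluster_pct / (100.0 - cluster_pct)) / (pop_pct / (100.0 - pop_pct))


def pct(numerator: float, denominator: float, ndigits: int | None = None) -> float:
    """Percentage numerator/denominator * 100, optionally rounded."""
    if denominator == 0:
        return np.nan
    value = 100.0 * numerator / denominator
    return round(value, ndigits) if ndigits is not None else value


def _strata(events: pd.DataFrame):
    yield "age", events["age_years"].map(bin_age)
    yield "sex", events["sex"]
    yield "race", events["race"]
    yield "ethnicity", events["ethnicity"]
    for loc in ("icu", "telemetry", "stepdown", "obgyn"):
        yield "location", pd.Series(np.where(events[loc].astype(bool), loc, None),
                                    index=events.index)
    yield "medication", events["medication"]
    if "cluster" in events.columns:
        yield "cluster", events["cluster"].astype(str)


def response_table(events: pd.DataFrame) -> pd.DataFrame:
    """Alert firing and compliance rates per stratum.

    Per stratum: event count, alerts fired (and % of events), in-alert
    action compliance (% of fired alerts with a non-missing response), and
    order/administration compliance (% of fired alerts outside the
    respective recode classes).  Ends with a Total row.
    """
    rows = []

    def summarize(group_kind, label, sub):
        n = len(sub)
        fired = sub[sub["alert_fired"].astype(bool)]
        nf = len(fired)
        resp = fired[fired["action_group"].notna()]
        comply = int((resp["action_group"] == "comply").sum())
        oc = fired["order_complied"].dropna()
        ac = fired["admin_complied"].dropna()
        rows.append({
            "group": group_kind,
            "stratum": label,
            "n": n,
            "fired_n": nf,
            "fired_pct": pct(nf, n) if n else np.nan,
            "action_comply_n": comply,
            "action_comply_pct": pct(comply, len(resp)) if len(resp) else np.nan,
            "order_comply_n": int(oc.sum()),
            "order_comply_pct": pct(oc.sum(), len(oc)) if len(oc) else np.nan,
            "admin_comply_n": int(ac.sum()),
            "admin_comply_pct": pct(ac.sum(), len(ac)) if len(ac) else np.nan,
        })

    for kind, labels in _strata(events):
        for label in sorted({x for x in labels.dropna().unique()}):
            summarize(kind, label, events[labels == label])
    summarize("total", "total", events)
    return pd.DataFrame(rows)


def era_table(events: pd.DataFrame) -> pd.DataFrame:
    """Per-medication pre/post-CDS counts with row percentages and a total row."""
    rows = []
    meds = sorted(events["medication"].unique())
    for med in meds + ["total"]:
        sub = events if med == "total" else events[events["medication"] == med]
        n = len(sub)
        pre = int((sub["cds_era"] == "pre").sum())
        rows.append({
            "medication": med,
            "pre_n": pre,
            "pre_pct": pct(pre, n) if n else np.nan,
            "post_n": n - pre,
            "post_pct": pct(n - pre, n) if n else np.nan,
        })
    return pd.DataFrame(rows)


def compare_groups(values, groups, kind: str = "auto"):
    """Compare a variable across groups.

    Categorical (``kind="categorical"``): Pearson chi-square without
    continuity correction on the groups-by-levels contingency table.
    Continuous (``kind="continuous"``): one-way ANOVA F test.  ``"auto"``
    treats numeric float input as continuous.

    Returns ``(statistic, p_value, warning)`` where ``warning`` is True for
    a chi-square table with any expected cell below 1.
    """
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    if groups.nunique() < 2:
        raise ValueError("need at least two groups")
    if kind == "auto":
        kind = "continuous" if pd.api.types.is_float_dtype(values) else "categorical"
    if kind == "continuous":
        samples = [values[groups == g].dropna().to_numpy() for g in groups.unique()]
        stat, p = stats.f_oneway(*samples)
        return float(stat), float(p), False
    table = pd.crosstab(groups, values)
    stat, p, _, expected = stats.chi2_contingency(table.to_numpy(), correction=False)
    return float(stat), float(p), bool((expected < 1).any())
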