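"""CDS alert rule, provider-response classification, and index-event assembly.

The analysis unit is the *index event*: one (encounter, culprit medication)
pair anchored at the first order of that medication in the encounter.  This
module applies the interruptive-alert firing rule (any prior Bazett QTc
>= 500 ms), dichotomizes the in-alert provider action, classifies downstream
order/administration compliance with its four missingness-recode rules, and
attaches covariates and outcomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ecg_qtc import add_qtc_columns

__all__ = [
    "CULPRIT_MEDICATIONS",
    "DEPLOYMENT_MONTH",
    "PROVIDER_ACTIONS",
    "COMPLY_ACTION",
    "RECODE_REASONS",
    "fire_alert_rule",
    "classify_action",
    "classify_compliance",
    "classify_cds_era",
    "add_months",
    "collapse_race",
    "collapse_ethnicity",
    "build_index_events",
    "BuildAudit",
]

#: The ten culprit medications covered by the alert system.
CULPRIT_MEDICATIONS = (
    "azithromycin",
    "citalopram",
    "droperidol",
    "escitalopram",
    "haloperidol",
    "hydroxychloroquine",
    "levofloxacin",
    "methadone",
    "ondansetron",
    "sotalol",
)

#: Medication-specific deployment month of the alert (year, month); the
#: boundary is the first calendar day of the month, inclusive on the post side.
DEPLOYMENT_MONTH = {
    "haloperidol": (2011, 11),
    "sotalol": (2015, 6),
    "methadone": (2016, 7),
    "citalopram": (2016, 7),
    "droperidol": (2016, 7),
    "ondansetron": (2016, 7),
    "azithromycin": (2016, 7),
    "escitalopram": (2016, 7),
    "levofloxacin": (2016, 9),
    "hydroxychloroquine": (2020, 3),
}

#: The four in-alert provider actions.  Only the removal of the triggering
#: order counts as compliance; the other three are grouped as "ignore".
PROVIDER_ACTIONS = (
    "Remove single order",
    "Acknowledge or Override warning",
    "Accept BPA",
    "Cancel BPA",
)
COMPLY_ACTION = "Remove single order"

RECODE_REASONS = ("order_gt_48h", "admin_gt_72h", "order_no_admin", "admin_no_order", "none")

ORDER_WINDOW_H = 48.0
ADMIN_WINDOW_H = 72.0


def fire_alert_rule(prior_ecgs: pd.DataFrame, order_ts) -> bool:
    """True iff any ECG before ``order_ts`` has a Bazett QTc >= 500 ms.

    ``prior_ecgs`` may contain ECGs at or after the order; they are ignored.
    Monotone in the ECG list: adding records can only turn False into True.
    """
    if len(prior_ecgs) == 0:
        return False
    if "qtc_bazett_ms" not in prior_ecgs.columns:
        prior_ecgs = add_qtc_columns(prior_ecgs)
    ts = pd.to_datetime(prior_ecgs["ts"])
    mask = (ts < pd.Timestamp(order_ts)).to_numpy()
    return bool((prior_ecgs["qtc_bazett_ms"].to_numpy(dtype=float)[mask] >= 500.0).any())


def classify_action(provider_action) -> str | None:
    """Dichotomize the in-alert provider action into comply/ignore.

    "Remove single order" -> "comply"; the other three actions -> "ignore";
    a missing action returns None (excluded from action analyses).
    """
    if provider_action is None or (isinstance(provider_action, float) and np.isnan(provider_action)):
        return None
    if provider_action == COMPLY_ACTION:
        return "comply"
    if provider_action in PROVIDER_ACTIONS:
        return "ignore"
    raise ValueError(f"unknown provider action: {provider_action!r}")


def classify_compliance(alert_ts, order_signed_ts=None, admin_ts=None):
    """Classify order/administration compliance after a fired alert.

    Compliance means *absence* of a signed culprit order within 48 h
    (``order_complied``) and of an administration within 72 h
    (``admin_complied``) of the alert.  Four discrepancy classes are recoded
    to missing, in this precedence: (a) order signed more than 48 h after
    the alert, (b) administration more than 72 h after the alert, (c) order
    signed with no administration record, (d) administration without a
    signed order.  Recoded events get null compliance flags.

    Returns ``(order_complied, admin_complied, recode_missing_reason)``.
    """
    alert_ts = pd.Timestamp(alert_ts)
    has_order = order_signed_ts is not None and not pd.isna(order_signed_ts)
    has_admin = admin_ts is not None and not pd.isna(admin_ts)
    order_lag_h = (pd.Timestamp(order_signed_ts) - alert_ts) / pd.Timedelta(hours=1) if has_order else np.nan
    admin_lag_h = (pd.Timestamp(admin_ts) - alert_ts) / pd.Timedelta(hours=1) if has_admin else np.nan

    if has_order and order_lag_h > ORDER_WINDOW_H:
        return None, None, "order_gt_48h"
    if has_admin and admin_lag_h > ADMIN_WINDOW_H:
        return None, None, "admin_gt_72h"
    if has_order and not has_admin:
        return None, None, "order_no_admin"
    if has_admin and not has_order:
        return None, None, "admin_no_order"
    if not has_order and not has_admin:
        return True, True, "none"
    return False, False, "none"


def classify_cds_era(medication: str, order_ts) -> str:
    """"post" iff the order falls on/after the first day of the medication's
    deployment month, else "pre"."""
    if medication not in DEPLOYMENT_MONTH:
        raise ValueError(f"unknown culprit medication: {medication!r}")
    year, month = DEPLOYMENT_MONTH[medication]
    return "post" if pd.Timestamp(order_ts) >= pd.Timestamp(year=year, month=month, day=1) else "pre"


def add_months(ts, months: int):
    """Calendar-month offset with end-of-month clamping (Jan 31 + 1m -> Feb 28)."""
    return pd.Timestamp(ts) + pd.DateOffset(months=months)


def collapse_race(race: pd.Series) -> pd.Series:
    """Collapse recorded race into {Caucasian, Black, Other}."""
    out = pd.Series("Other", index=race.index, dtype=object)
    out[race.isin(["White", "Caucasian"])] = "Caucasian"
    out[race == "Black"] = "Black"
    return out


def collapse_ethnicity(eth: pd.Series) -> pd.Series:
    """Collapse recorded ethnicity into {Hispanic, Non-Hispanic}."""
    return pd.Series(np.where(eth == "Hispanic", "Hispanic", "Non-Hispanic"), index=eth.index)


@dataclass
class BuildAudit:
    """Accounting emitted by :func:`build_index_events`."""

    n_events: int = 0
    n_excluded_age: int = 0
    n_encounters_without_order: int = 0
    recode_counts: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [("n_events", self.n_events), ("n_excluded_age", self.n_excluded_age),
                ("n_encounters_without_order", self.n_encounters_without_order)]
        rows += [(f"recode_{k}", v) for k, v in self.recode_counts.items()]
        return pd.DataFrame(rows, columns=["item", "count"])


LAB_ANALYTES = ("potassium", "magnesium", "creatinine")
LAB_WINDOW_H = 24.0


def _first_ts_after(df: pd.DataFrame, ts_col: str, events: pd.DataFrame) -> pd.Series:
    """First df timestamp at/after the event's alert, per (encounter, medication)."""
    merged = events[["event_id", "encounter_id", "medication", "alert_ts"]].merge(
        df, on=["encounter_id", "medication"], how="inner"
    )
    merged = merged[merged[ts_col] >= merged["alert_ts"]]
    merged = merged.sort_values(ts_col).drop_duplicates("event_id")
    return merged.set_index("event_id")[ts_col]


def build_index_events(
    bundle,
    post_window_h: float = 1.0,
    pre_scope: str = "history",
) -> tuple[pd.DataFrame, BuildAudit]:
    """Assemble one index event per (encounter, culprit medication).

    Each event is anchored at the first order of its medication within the
    encounter.  Pre-exposure QTc aggregates cover all of the patient's ECGs
    strictly before the order (``pre_scope="history"``, the default) or only
    the encounter's own ECGs (``pre_scope="encounter"``); the post window is
    the half-open hour (configurable) after the later of order and alert.
    Events for patients outside 18-90 years at the anchor are excluded and
    counted in the audit.

    Returns the event table and a :class:`BuildAudit`.
    """
    if pre_scope not in ("history", "encounter"):
        raise ValueError("pre_scope must be 'history' or 'encounter'")

    orders = bundle.orders.copy()
    orders["order_ts"] = pd.to_datetime(orders["order_ts"])
    encounters = bundle.encounters.copy()
    for c in ("admit_ts", "discharge_ts", "death_date"):
        encounters[c] = pd.to_datetime(encounters[c])

    audit = BuildAudit()
    audit.n_encounters_without_order = int(
        (~encounters["encounter_id"].isin(orders["encounter_id"])).sum()
    )

    events = (
        orders.sort_values(["order_ts", "order_id"])
        .drop_duplicates(["encounter_id", "medication"])
        .loc[:, ["encounter_id", "medication", "order_ts"]]
        .reset_index(drop=True)
    )
    events = events.merge(
        encounters[["encounter_id", "patient_id", "admit_ts", "discharge_ts",
                    "icu", "telemetry", "stepdown", "obgyn",
                    "inpatient_death", "death_date"]],
        on="encounter_id", how="left",
    )
    events = events.merge(bundle.patients, on="patient_id", how="left")

    # alerts: first per (encounter, medication)
    alerts = bundle.alerts.copy()
    if len(alerts):
        alerts["alert_ts"] = pd.to_datetime(alerts["alert_ts"])
        first_alert = alerts.sort_values("alert_ts").drop_duplicates(["encounter_id", "medication"])
        events = events.merge(
            first_alert[["encounter_id", "medication", "alert_ts", "provider_action"]],
            on=["encounter_id", "medication"], how="left",
        )
    else:
        events["alert_ts"] = pd.NaT
        events["provider_action"] = np.nan
    events["alert_fired"] = events["alert_ts"].notna()

    # anchors: post-window anchor is the later of order and alert; the
    # covariate anchor is the earlier of the two
    events["anchor_ts"] = events[["order_ts", "alert_ts"]].max(axis=1)
    events["cov_anchor_ts"] = events[["order_ts", "alert_ts"]].min(axis=1)

    # age filter (18-90 at the covariate anchor)
    birth_mid = pd.to_datetime(dict(year=events["birth_year"], month=7, day=1))
    events["age_years"] = (events["cov_anchor_ts"] - birth_mid).dt.days / 365.25
    in_range = (events["age_years"] >= 18) & (events["age_years"] <= 90)
    audit.n_excluded_age = int((~in_range).sum())
    events = events[in_range].reset_index(drop=True)
    events["event_id"] = np.arange(len(events))

    # ---- QTc aggregates ------------------------------------------------
    ecgs = add_qtc_columns(bundle.ecgs)
    ecgs["ts"] = pd.to_datetime(ecgs["ts"])
    if pre_scope == "history":
        key = "patient_id"
    else:
        key = "encounter_id"
    ev_keys = events[["event_id", key, "order_ts", "anchor_ts"]]
    merged = ev_keys.merge(
        ecgs[[key, "ts", "qtc_adjfrid_ms", "qtc_bazett_ms"]], on=key, how="inner"
    )

    pre = merged[merged["ts"] < merged["order_ts"]]
    pre_agg = pre.groupby("event_id")["qtc_adjfrid_ms"].agg(["max", "mean", "count"])
    pre_agg.columns = ["max_pre_qt", "mean_pre_qt", "n_pre"]
    pre_bazett = pre.groupby("event_id")["qtc_bazett_ms"].max().rename("max_pre_bazett")

    hi = merged["anchor_ts"] + pd.to_timedelta(post_window_h, unit="h")
    post = merged[(merged["ts"] > merged["anchor_ts"]) & (merged["ts"] <= hi)]
    post_agg = post.groupby("event_id")["qtc_adjfrid_ms"].agg(["max", "mean", "count"])
    post_agg.columns = ["max_post_qt", "mean_post_qt", "n_post"]

    events = events.set_index("event_id")
    events = events.join(pre_agg).join(pre_bazett).join(post_agg)
    events[["n_pre", "n_post"]] = events[["n_pre", "n_post"]].fillna(0).astype(int)

    # rule-based eligibility (diagnostic; should equal alert_fired when the
    # alert was live for the medication at order time)
    events["rule_eligible"] = events["max_pre_bazett"].fillna(0) >= 500.0

    # diLQTS adjudication: missing when no post-window ECG
    has_post = events["n_post"] > 0
    delta_hit = (events["n_pre"] > 0) & (events["max_post_qt"] - events["max_pre_qt"] > 60.0)
    dilqts = np.where(has_post, ((events["max_post_qt"] >= 500.0) | delta_hit).astype(float), np.nan)
    events["dilqts"] = dilqts

    # ---- compliance ----------------------------------------------------
    ev = events.reset_index()
    signed = orders[orders["signed"].astype(int) == 1]
    signed_ts = _first_ts_after(signed.rename(columns={"order_ts": "signed_ts"}), "signed_ts", ev)
    admins = bundle.administrations.copy()
    if len(admins):
        admins["admin_ts"] = pd.to_datetime(admins["admin_ts"])
        admin_ts = _first_ts_after(admins, "admin_ts", ev)
    else:
        admin_ts = pd.Series(dtype="datetime64[ns]")
    events["signed_order_ts"] = signed_ts.reindex(events.index)
    events["admin_ts"] = admin_ts.reindex(events.index)

    fired = events["alert_fired"].to_numpy()
    order_lag = (events["signed_order_ts"] - events["alert_ts"]) / pd.Timedelta(hours=1)
    admin_lag = (events["admin_ts"] - events["alert_ts"]) / pd.Timedelta(hours=1)
    has_order = events["signed_order_ts"].notna().to_numpy() & fired
    has_admin = events["admin_ts"].notna().to_numpy() & fired

    reason = np.full(len(events), "none", dtype=object)
    a = has_order & (order_lag > ORDER_WINDOW_H).to_numpy()
    b = ~a & has_admin & (admin_lag > ADMIN_WINDOW_H).to_numpy()
    c = ~a & ~b & has_order & ~has_admin
    d = ~a & ~b & ~c & has_admin & ~has_order
    reason[a] = "order_gt_48h"
    reason[b] = "admin_gt_72h"
    reason[c] = "order_no_admin"
    reason[d] = "admin_no_order"
    reason[~fired] = "none"
    recoded = a | b | c | d

    order_complied = np.where(fired & ~recoded, ~has_order, np.nan)
    admin_complied = np.where(fired & ~recoded, ~has_admin, np.nan)
    events["order_complied"] = order_complied
    events["admin_complied"] = admin_complied
    events["recode_missing_reason"] = reason
    audit.recode_counts = {
        r: int((reason[fired] == r).sum()) for r in RECODE_REASONS if r != "none"
    }

    events["action_group"] = [
        classify_action(x) if f else None
        for x, f in zip(events["provider_action"], fired)
    ]

    # ---- covariates ----------------------------------------------------
    events["race"] = collapse_race(events["race"])
    events["ethnicity"] = collapse_ethnicity(events["ethnicity"])

    labs = bundle.labs.copy()
    ev = events.reset_index()
    if len(labs):
        labs["ts"] = pd.to_datetime(labs["ts"])
        lm = ev[["event_id", "encounter_id", "cov_anchor_ts"]].merge(
            labs, on="encounter_id", how="inner"
        )
        lm["offset_h"] = (lm["ts"] - lm["cov_anchor_ts"]) / pd.Timedelta(hours=1)
        lm = lm[lm["offset_h"].abs() <= LAB_WINDOW_H]
        lm = lm.sort_values("offset_h", key=lambda s: s.abs()).drop_duplicates(
            ["event_id", "analyte"]
        )
        for analyte in LAB_ANALYTES:
            sub = lm[lm["analyte"] == analyte].set_index("event_id")
            events[analyte] = sub["value"].reindex(events.index)
            events[f"{analyte}_offset_h"] = sub["offset_h"].reindex(events.index)
    else:
        for analyte in LAB_ANALYTES:
            events[analyte] = np.nan
            events[f"{analyte}_offset_h"] = np.nan

    # ---- outcomes ------------------------------------------------------
    events["los_days"] = (events["discharge_ts"] - events["admit_ts"]) / pd.Timedelta(days=1)
    events["inpatient_death"] = events["inpatient_death"].astype(bool)
    for label, months in (("death_3m", 3), ("death_6m", 6), ("death_12m", 12)):
        limit = events["admit_ts"] + pd.DateOffset(months=months)
        events[label] = events["death_date"].notna() & (events["death_date"] <= limit)

    # ---- CDS era -------------------------------------------------------
    deploy = events["medication"].map(
        {m: pd.Timestamp(y, mo, 1) for m, (y, mo) in DEPLOYMENT_MONTH.items()}
    )
    events["cds_era"] = np.where(events["order_ts"] >= deploy, "post", "pre")

    keep = [
        "encounter_id", "patient_id", "medication", "order_ts", "alert_ts",
        "anchor_ts", "cov_anchor_ts", "alert_fired", "provider_action",
        "action_group", "order_complied", "admin_complied",
        "recode_missing_reason", "signed_order_ts", "admin_ts",
        "max_pre_qt", "mean_pre_qt", "n_pre", "max_post_qt", "mean_post_qt",
        "n_post", "rule_eligible", "dilqts",
        "age_years", "sex", "race", "ethnicity",
        "icu", "telemetry", "stepdown", "obgyn",
        "potassium", "potassium_offset_h", "magnesium", "magnesium_offset_h",
        "creatinine", "creatinine_offset_h",
        "los_days", "inpatient_death", "death_3m", "death_6m", "death_12m",
        "cds_era",
    ]
    events = events.reset_index()[["event_id"] + keep]
    audit.n_events = len(events)
    return events, audit
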