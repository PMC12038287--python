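"""Synthetic EHR cohort generator with a ground-truth registry.

Produces a schema-complete bundle of flat tables (patients, encounters,
ECGs, orders, administrations, alerts, labs, diagnoses, medication lists)
whose statistical structure mirrors the study population: within-patient
repeated encounters, a 10-drug culprit-medication mix, baseline QTc around
422 (SD 58) ms, ~8% alert prevalence and ~8% outcome prevalence, nested
location flags (ICU implies telemetry; ICU and stepdown exclusive), and
drug-conditional provider-action multinomials.  Effect sizes (the
conditional alert->outcome log-odds, the multiplicative alert->length-of-stay
effect) are configurable and echoed in a :class:`GroundTruth` registry so
that downstream estimators can be tested for parameter recovery.

Every draw flows from a single :class:`numpy.random.Generator` seeded from
the config, so identical configs yield byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .alert_cohort import (
    COMPLY_ACTION,
    CULPRIT_MEDICATIONS,
    DEPLOYMENT_MONTH,
    PROVIDER_ACTIONS,
)
from .ecg_qtc import qtc_adjusted_fridericia

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "DatasetBundle",
    "ConfigError",
    "generate",
    "sample_action",
    "write_bundle",
    "read_bundle",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# population moments used when the config does not override them
AGE_MEAN, AGE_SD, AGE_LO, AGE_HI = 59.19, 17.94, 19.0, 88.0
FEMALE_PROB = 0.526
RACE_PROBS = {"White": 0.744, "Black": 0.097, "Asian": 0.080, "Other": 0.079}
HISPANIC_PROB = 0.150

#: per-medication share of index orders (order-slot multinomial)
DEFAULT_MED_PREVALENCE = {
    "ondansetron": 0.6021,
    "haloperidol": 0.1507,
    "azithromycin": 0.0866,
    "levofloxacin": 0.0538,
    "droperidol": 0.0368,
    "escitalopram": 0.0278,
    "citalopram": 0.0206,
    "methadone": 0.0089,
    "hydroxychloroquine": 0.0073,
    "sotalol": 0.0054,
}

#: in-alert compliance ("Remove single order") rate per medication; the
#: residual mass is split over the three ignore actions 60/25/15.
_COMPLY_RATE = {
    "azithromycin": 0.698,
    "citalopram": 0.163,
    "droperidol": 0.592,
    "escitalopram": 0.137,
    "haloperidol": 0.615,
    "hydroxychloroquine": 0.181,
    "levofloxacin": 0.606,
    "methadone": 0.260,
    "ondansetron": 0.694,
    "sotalol": 0.106,
}


def _default_action_policy() -> dict:
    policy = {}
    for med, r in _COMPLY_RATE.items():
        rest = 1.0 - r
        policy[med] = {
            COMPLY_ACTION: r,
            "Acknowledge or Override warning": rest * 0.60,
            "Accept BPA": rest * 0.25,
            "Cancel BPA": rest * 0.15,
        }
    return policy


def _default_mortality_logodds() -> dict:
    return {
        "inpatient": float(logit(0.0323)),
        "3m": float(logit(0.0688)),
        "6m": float(logit(0.0839)),
        "12m": float(logit(0.1031)),
    }


def _default_discrepancy_rates() -> dict:
    return {"order_gt_48h": 0.0, "admin_gt_72h": 0.0, "order_no_admin": 0.0, "admin_no_order": 0.0}


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``encounters_per_patient_dist`` is a ``(name, params)`` pair; supported
    laws are ``("shifted_geometric", {"p": p})`` on {1, 2, ...},
    ``("poisson_plus_one", {"lam": lam})`` and ``("fixed", {"n": n})``.
    ``alert_effect_logodds`` is the conditional (given covariates and the
    patient random effect) log-odds increment of the diLQTS outcome for
    alert-eligible patients; ``alert_los_log_irr`` the log multiplicative
    effect of eligibility on expected length of stay.
    """

    n_patients: int = 1000
    encounters_per_patient_dist: tuple = ("shifted_geometric", {"p": 0.588})
    med_prevalence: dict = field(default_factory=lambda: dict(DEFAULT_MED_PREVALENCE))
    baseline_qtc_mean: float = 422.0
    baseline_qtc_sd: float = 58.0
    high_qtc_prob: float = 0.084
    dilqts_base_prevalence: float = 0.0825
    alert_effect_logodds: float = math.log(2.28)
    per_medication_dilqts_logodds: dict = field(
        default_factory=lambda: {m: 0.0 for m in CULPRIT_MEDICATIONS} | {"sotalol": 0.8, "haloperidol": 0.1}
    )
    action_policy: dict = field(default_factory=_default_action_policy)
    missing_action_prob: float = 0.0014
    order_noncompliance_prob: float = 0.3219
    los_rate_days: float = 5.5
    alert_los_log_irr: float = math.log(1.08)
    mortality_logodds: dict = field(default_factory=_default_mortality_logodds)
    patient_random_effect_sd: float = 0.3
    second_med_prob: float = 0.0
    discrepancy_rates: dict = field(default_factory=_default_discrepancy_rates)
    lab_missing_prob: float = 0.10
    period_start: str = "2016-10-01"
    period_end: str = "2024-02-01"
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        name, params = self.encounters_per_patient_dist
        if name == "shifted_geometric":
            if not 0 < params.get("p", 0) <= 1:
                raise ConfigError("shifted_geometric needs 0 < p <= 1")
        elif name == "poisson_plus_one":
            if not 0 <= params.get("lam", -1) < math.inf:
                raise ConfigError("poisson_plus_one needs finite lam >= 0")
        elif name == "fixed":
            if params.get("n", 0) < 1:
                raise ConfigError("fixed law needs n >= 1")
        else:
            raise ConfigError(f"unknown encounter distribution {name!r}")
        for p in [self.high_qtc_prob, self.dilqts_base_prevalence, self.missing_action_prob,
                  self.order_noncompliance_prob, self.lab_missing_prob, self.second_med_prob]:
            if not 0 <= p <= 1:
                raise ConfigError("probabilities must lie in [0, 1]")
        prev = self.med_prevalence
        if any(p < 0 for p in prev.values()) or sum(prev.values()) > 1 + 1e-9:
            raise ConfigError("med_prevalence values must be non-negative and sum to <= 1")
        if set(prev) - set(CULPRIT_MEDICATIONS):
            raise ConfigError("med_prevalence contains unknown medications")
        for med, pol in self.action_policy.items():
            if med not in CULPRIT_MEDICATIONS:
                raise ConfigError(f"action policy for unknown medication {med!r}")
            if abs(sum(pol.values()) - 1.0) > 1e-6 or any(v < 0 for v in pol.values()):
                raise ConfigError(f"action policy for {med} is not a distribution")
            if set(pol) - set(PROVIDER_ACTIONS):
                raise ConfigError(f"action policy for {med} has unknown actions")
        if self.patient_random_effect_sd < 0:
            raise ConfigError("patient_random_effect_sd must be >= 0")
        if self.los_rate_days <= 0:
            raise ConfigError("los_rate_days must be positive")
        if any(r < 0 for r in self.discrepancy_rates.values()) or sum(self.discrepancy_rates.values()) > 1:
            raise ConfigError("discrepancy rates must be non-negative and sum to <= 1")
        lo = self.mortality_logodds
        if not (lo["3m"] <= lo["6m"] <= lo["12m"]):
            raise ConfigError("mortality log-odds must be monotone over 3m <= 6m <= 12m")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["encounters_per_patient_dist"] = list(d["encounters_per_patient_dist"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        dist = d.get("encounters_per_patient_dist")
        if dist is not None:
            d["encounters_per_patient_dist"] = (dist[0], dict(dist[1]))
        return cls(**d)


@dataclass
class GroundTruth:
    """Registry of the true parameters behind a generated bundle."""

    config_echo: dict
    true_marginal_or_alert_dilqts: float
    true_irr_alert_los: float
    per_medication_dilqts_logodds: dict
    dilqts_intercept: float
    injected_discrepancies: dict
    n_encounters: int
    n_index_events: int

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class DatasetBundle:
    """The flat tables of one synthetic cohort."""

    patients: pd.DataFrame
    encounters: pd.DataFrame
    ecgs: pd.DataFrame
    orders: pd.DataFrame
    administrations: pd.DataFrame
    alerts: pd.DataFrame
    labs: pd.DataFrame
    diagnoses: pd.DataFrame
    medications_list: pd.DataFrame

    TABLES = ("patients", "encounters", "ecgs", "orders", "administrations",
              "alerts", "labs", "diagnoses", "medications_list")


def sample_action(medication: str, rng: np.random.Generator, policy: dict | None = None) -> str:
    """Draw one provider action for a fired alert on ``medication``."""
    if medication not in CULPRIT_MEDICATIONS:
        raise ValueError(f"unknown culprit medication: {medication!r}")
    policy = policy if policy is not None else _default_action_policy()
    pol = policy[medication]
    actions = list(pol)
    return str(actions[rng.choice(len(actions), p=np.asarray(list(pol.values())))])


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated normal via inverse-CDF (deterministic under rng)."""
    from scipy.stats import norm
    a, b = norm.cdf(lo, mean, sd), norm.cdf(hi, mean, sd)
    u = rng.uniform(a, b, size)
    return norm.ppf(u, mean, sd)


def _minute(ts: pd.Series | pd.DatetimeIndex) -> pd.Series:
    return pd.Series(ts).dt.floor("min")


def _n_encounters(rng, cfg: GeneratorConfig) -> np.ndarray:
    name, params = cfg.encounters_per_patient_dist
    if name == "shifted_geometric":
        return rng.geometric(params["p"], cfg.n_patients)
    if name == "poisson_plus_one":
        return 1 + rng.poisson(params["lam"], cfg.n_patients)
    return np.full(cfg.n_patients, int(params["n"]))


def generate(config: GeneratorConfig) -> tuple[DatasetBundle, GroundTruth]:
    """Generate a synthetic cohort and its ground-truth registry.

    Deterministic given ``config`` (including its seed).  Raises
    :class:`ConfigError` for invalid configs and for ``n_patients == 0``.
    """
    config.validate()
    if config.n_patients == 0:
        raise ConfigError("n_patients=0 would produce an empty bundle")
    rng = np.random.default_rng(config.seed)

    # ---------------- patients -----------------------------------------
    npat = config.n_patients
    patient_id = np.array([f"P{i:07d}" for i in range(npat)])
    age0 = _truncnorm(rng, AGE_MEAN, AGE_SD, AGE_LO, AGE_HI, npat)
    sex = np.where(rng.uniform(size=npat) < FEMALE_PROB, "F", "M")
    race = rng.choice(list(RACE_PROBS), p=list(RACE_PROBS.values()), size=npat)
    ethnicity = np.where(rng.uniform(size=npat) < HISPANIC_PROB, "Hispanic", "Non-Hispanic")
    severity = rng.normal(0.0, 1.0, npat)
    rand_eff = rng.normal(0.0, config.patient_random_effect_sd, npat)
    eligible = rng.uniform(size=npat) < config.high_qtc_prob

    start = pd.Timestamp(config.period_start)
    end = pd.Timestamp(config.period_end)
    span_days = (end - start).days
    ref_day = rng.uniform(0, span_days, npat)

    # ---------------- encounters ---------------------------------------
    n_enc = _n_encounters(rng, config)
    nenc = int(n_enc.sum())
    pat_ix = np.repeat(np.arange(npat), n_enc)
    encounter_id = np.array([f"E{i:07d}" for i in range(nenc)])

    admit_day = np.clip(ref_day[pat_ix] + rng.uniform(-300, 300, nenc), 0, span_days - 1)
    admit = _minute(start + pd.to_timedelta(admit_day * 24 * 60, unit="m"))

    sev_e = severity[pat_ix]
    b_e = rand_eff[pat_ix]
    elig_e = eligible[pat_ix]

    los_mu = config.los_rate_days * np.exp(
        0.25 * sev_e + config.alert_los_log_irr * elig_e + 0.15 * b_e
    )
    los_days = np.maximum(0.25, rng.gamma(2.0, los_mu / 2.0, nenc))
    discharge = _minute(admit + pd.to_timedelta(los_days * 24 * 60, unit="m"))

    icu = rng.uniform(size=nenc) < expit(-1.8 + 1.2 * sev_e)
    stepdown = (~icu) & (rng.uniform(size=nenc) < expit(-2.0 + 0.8 * sev_e))
    telemetry = icu | (rng.uniform(size=nenc) < expit(-0.8 + 0.6 * sev_e))
    obgyn = rng.uniform(size=nenc) < 0.006

    # ---------------- index medications / orders -----------------------
    meds = np.array(list(config.med_prevalence))
    med_p = np.array(list(config.med_prevalence.values()), dtype=float)
    med_p = med_p / med_p.sum()
    med1 = meds[rng.choice(len(meds), p=med_p, size=nenc)]

    los_min = los_days * 24 * 60
    off_hi = np.minimum(1440.0, los_min - 120.0)
    order_off1 = 30.0 + rng.uniform(size=nenc) * np.maximum(1.0, off_hi - 30.0)
    order_ts1 = _minute(admit + pd.to_timedelta(order_off1, unit="m"))

    # optional second culprit medication, ordered >= 2 h after the first
    want2 = (rng.uniform(size=nenc) < config.second_med_prob) & (los_min - order_off1 > 360)
    med2 = meds[rng.choice(len(meds), p=med_p, size=nenc)]
    want2 &= med2 != med1
    order_off2 = order_off1 + 120.0 + rng.uniform(size=nenc) * np.maximum(
        1.0, (los_min - 90.0) - (order_off1 + 120.0)
    )
    order_ts2 = _minute(admit + pd.to_timedelta(order_off2, unit="m"))

    # index events: one row per (encounter, culprit medication)
    ix2 = np.flatnonzero(want2)
    ev_enc = np.concatenate([np.arange(nenc), ix2])
    ev_med = np.concatenate([med1, med2[ix2]])
    ev_order_ts = pd.concat([order_ts1, order_ts2.iloc[ix2]], ignore_index=True)
    nev = len(ev_enc)

    # alert fires for eligible patients once the medication's CDS is live
    deploy = pd.Series({m: pd.Timestamp(y, mo, 1) for m, (y, mo) in DEPLOYMENT_MONTH.items()})
    live = ev_order_ts.to_numpy() >= deploy.reindex(ev_med).to_numpy()
    ev_elig = elig_e[ev_enc]
    fired = ev_elig & live

    # ---------------- ECGs ----------------------------------------------
    qlo, qhi = max(300.0, config.baseline_qtc_mean - 4 * config.baseline_qtc_sd), 497.0

    # pre-admission high-QTc ECG for eligible patients (before first admit)
    first_admit = pd.Series(admit.to_numpy()).groupby(pat_ix).min()
    elig_pat = np.flatnonzero(eligible)
    hist_qtc = 500.0 + rng.exponential(15.0, elig_pat.size)
    hist = pd.DataFrame({
        "patient_ix": elig_pat,
        "encounter_ix": -1,
        "ts": first_admit.reindex(elig_pat).to_numpy() - pd.Timedelta(days=30),
        "qt_ms": hist_qtc,  # rr = 1.0, qrs = 90 -> both corrections equal qt
        "qrs_ms": 90.0,
        "rr_s": 1.0,
    })

    # in-encounter pre-exposure ECGs, strictly before the first order
    n_pre = 1 + rng.poisson(0.8, nenc)
    pre_enc = np.repeat(np.arange(nenc), n_pre)
    npre = pre_enc.size
    pre_frac = rng.uniform(0.02, 0.95, npre)
    pre_ts = _minute(
        admit.iloc[pre_enc].reset_index(drop=True)
        + pd.to_timedelta(pre_frac * np.maximum(5.0, order_off1[pre_enc] - 5.0), unit="m")
    )
    pre_bazett = _truncnorm(rng, config.baseline_qtc_mean, config.baseline_qtc_sd, qlo, qhi, npre)
    pre_rr = rng.uniform(0.75, 1.05, npre)
    pre_qrs = np.clip(rng.normal(92.0, 12.0, npre), 60.0, 140.0)
    pre_qt = pre_bazett * np.sqrt(pre_rr)
    pre = pd.DataFrame({
        "patient_ix": pat_ix[pre_enc],
        "encounter_ix": pre_enc,
        "ts": pre_ts,
        "qt_ms": pre_qt,
        "qrs_ms": pre_qrs,
        "rr_s": pre_rr,
    })

    # ---------------- diLQTS outcome ------------------------------------
    med_lo_map = {m: 0.0 for m in CULPRIT_MEDICATIONS} | dict(config.per_medication_dilqts_logodds)
    med_lo = np.array([med_lo_map[m] for m in ev_med])
    lp_core = med_lo + 0.2 * sev_e[ev_enc] + b_e[ev_enc]
    a = config.alert_effect_logodds

    def _prev(c):
        return float(np.mean(expit(c + lp_core + a * ev_elig))) - config.dilqts_base_prevalence

    intercept = brentq(_prev, -15.0, 10.0, xtol=1e-10)
    p_dilqts = expit(intercept + lp_core + a * ev_elig)
    dilqts = rng.uniform(size=nev) < p_dilqts

    p1 = float(np.mean(expit(intercept + lp_core + a)))
    p0 = float(np.mean(expit(intercept + lp_core)))
    true_marginal_or = (p1 / (1 - p1)) / (p0 / (1 - p0))

    # assumed pre-exposure maximum (adjusted Fridericia) per event; a lower
    # bound on the true history-wide maximum, which is all the post-ECG
    # realization needs
    pre_adjfrid = qtc_adjusted_fridericia(pre_qt, pre_qrs, pre_rr)
    enc_pre_max = (
        pd.Series(pre_adjfrid).groupby(pre_enc).max().reindex(np.arange(nenc)).to_numpy()
    )
    hist_max = np.full(npat, -np.inf)
    hist_max[elig_pat] = hist_qtc
    assumed_pre = np.maximum(enc_pre_max[ev_enc], hist_max[pat_ix[ev_enc]])

    # one post-exposure ECG 30 min after the order; cases realize the
    # >=500 ms clause under the adjusted-Fridericia correction while keeping
    # Bazett below 500 so they never retrigger the alert rule downstream
    post_target = np.where(
        dilqts,
        500.0 + np.minimum(rng.exponential(12.0, nev), 55.0),
        np.maximum(330.0, np.minimum(499.0, assumed_pre + 59.0) - rng.exponential(15.0, nev)),
    )
    post_rr = np.where(dilqts, 1.1 * (post_target / 500.0) ** 6, 1.0)
    post_qrs = np.where(dilqts, 100.0, 90.0)
    post_qt = post_target * post_rr ** (1.0 / 3.0)
    post_ts = _minute(ev_order_ts + pd.Timedelta(minutes=30))
    post = pd.DataFrame({
        "patient_ix": pat_ix[ev_enc],
        "encounter_ix": ev_enc,
        "ts": post_ts,
        "qt_ms": post_qt,
        "qrs_ms": post_qrs,
        "rr_s": post_rr,
    })

    ecgs = pd.concat([hist, pre, post], ignore_index=True)
    ecgs = ecgs.sort_values(["patient_ix", "ts"], kind="stable").reset_index(drop=True)
    ecgs.insert(0, "ecg_id", [f"G{i:08d}" for i in range(len(ecgs))])

    # ---------------- alerts, provider actions --------------------------
    fired_ix = np.flatnonzero(fired)
    nal = fired_ix.size
    action_idx = np.full(nal, -1)
    act_names = list(PROVIDER_ACTIONS)
    for med in np.unique(ev_med[fired_ix]):
        pol = config.action_policy.get(med, _default_action_policy()[med])
        probs = np.array([pol.get(act, 0.0) for act in act_names])
        sel = np.flatnonzero(ev_med[fired_ix] == med)
        action_idx[sel] = rng.choice(len(act_names), p=probs / probs.sum(), size=sel.size)
    actions = np.array(act_names, dtype=object)[action_idx]
    actions[rng.uniform(size=nal) < config.missing_action_prob] = None

    alerts = pd.DataFrame({
        "alert_id": [f"A{i:07d}" for i in range(nal)],
        "encounter_id": encounter_id[ev_enc[fired_ix]],
        "medication": ev_med[fired_ix],
        "alert_ts": ev_order_ts.iloc[fired_ix].to_numpy(),
        "provider_action": actions,
    })

    # ---------------- compliance & discrepancy injection ----------------
    # per fired alert: an unsigned triggering order always exists; a signed
    # re-order and/or administration follow per the compliance law or per an
    # injected discrepancy class
    alert_ts = ev_order_ts.iloc[fired_ix].reset_index(drop=True)
    avail_h = (
        discharge.iloc[ev_enc[fired_ix]].reset_index(drop=True) - alert_ts
    ) / pd.Timedelta(hours=1)
    avail_h = avail_h.to_numpy()

    classes = ["none"] + list(_default_discrepancy_rates())
    rates = np.array([1.0 - sum(config.discrepancy_rates.values())]
                     + [config.discrepancy_rates.get(c, 0.0) for c in classes[1:]])
    cls = np.array(classes, dtype=object)[rng.choice(len(classes), p=rates, size=nal)]
    cls[(cls == "order_gt_48h") & (avail_h < 60)] = "none"
    cls[(cls == "admin_gt_72h") & (avail_h < 85)] = "none"
    injected = {c: int((cls == c).sum()) for c in classes[1:]}

    noncomp = rng.uniform(size=nal) < config.order_noncompliance_prob
    order_lag = np.clip(rng.exponential(3.6, nal), 0.2, np.minimum(47.0, 0.90 * avail_h))
    admin_lag = np.clip(order_lag + rng.exponential(5.0, nal), 0.3,
                        np.minimum(71.0, 0.95 * avail_h))

    has_signed = np.where(cls == "none", noncomp, np.isin(cls, ["order_gt_48h", "admin_gt_72h", "order_no_admin"]))
    has_admin = np.where(cls == "none", noncomp, np.isin(cls, ["admin_gt_72h", "admin_no_order"]))
    late_order = np.clip(rng.uniform(49.0, 110.0, nal), None, 0.95 * np.maximum(avail_h, 52.0))
    late_admin = np.clip(rng.uniform(73.0, 120.0, nal), None, 0.95 * np.maximum(avail_h, 78.0))
    order_lag = np.where(cls == "order_gt_48h", late_order, order_lag)
    admin_lag = np.where(cls == "admin_gt_72h", late_admin, admin_lag)
    admin_lag = np.where(cls == "admin_no_order", np.clip(rng.exponential(8.6, nal) + 0.5, 0.5, np.minimum(71.0, 0.9 * avail_h)), admin_lag)

    # ---------------- orders & administrations tables --------------------
    # the triggering order for every index event (unsigned when the alert
    # fired: the order is held pending the provider's response)
    base_orders = pd.DataFrame({
        "encounter_ix": ev_enc,
        "medication": ev_med,
        "order_ts": ev_order_ts.to_numpy(),
        "signed": (~fired).astype(int),
    })
    signed_ix = np.flatnonzero(has_signed)
    reorders = pd.DataFrame({
        "encounter_ix": ev_enc[fired_ix[signed_ix]],
        "medication": ev_med[fired_ix[signed_ix]],
        "order_ts": _minute(alert_ts.iloc[signed_ix]
                            + pd.to_timedelta(order_lag[signed_ix], unit="h")).to_numpy(),
        "signed": 1,
    })
    orders = pd.concat([base_orders, reorders], ignore_index=True)
    orders = orders.sort_values(["encounter_ix", "order_ts"], kind="stable").reset_index(drop=True)
    orders.insert(0, "order_id", [f"O{i:07d}" for i in range(len(orders))])
    orders.insert(1, "encounter_id", encounter_id[orders.pop("encounter_ix")])

    # administrations: for non-fired events the order is administered after a
    # short lag; for fired events per the compliance/discrepancy draw
    nonfired_ix = np.flatnonzero(~fired)
    nf_lag = rng.exponential(3.0, nonfired_ix.size)
    nf_avail = (
        discharge.iloc[ev_enc[nonfired_ix]].reset_index(drop=True).to_numpy()
        - ev_order_ts.iloc[nonfired_ix].reset_index(drop=True).to_numpy()
    ) / np.timedelta64(1, "h")
    nf_lag = np.clip(nf_lag, 0.1, 0.9 * np.maximum(nf_avail, 0.2))
    admin_nf = pd.DataFrame({
        "encounter_ix": ev_enc[nonfired_ix],
        "medication": ev_med[nonfired_ix],
        "admin_ts": _minute(ev_order_ts.iloc[nonfired_ix]
                            + pd.to_timedelta(nf_lag, unit="h")).to_numpy(),
    })
    admin_ix = np.flatnonzero(has_admin)
    admin_f = pd.DataFrame({
        "encounter_ix": ev_enc[fired_ix[admin_ix]],
        "medication": ev_med[fired_ix[admin_ix]],
        "admin_ts": _minute(alert_ts.iloc[admin_ix]
                            + pd.to_timedelta(admin_lag[admin_ix], unit="h")).to_numpy(),
    })
    administrations = pd.concat([admin_nf, admin_f], ignore_index=True)
    administrations = administrations.sort_values(
        ["encounter_ix", "admin_ts"], kind="stable"
    ).reset_index(drop=True)
    # map each administration to the earliest order of the same medication
    okey = orders.copy()
    okey["encounter_ix"] = okey["encounter_id"].str.slice(1).astype(int)
    first_order_id = okey.sort_values("order_ts").drop_duplicates(
        ["encounter_ix", "medication"]
    ).set_index(["encounter_ix", "medication"])["order_id"]
    administrations["order_id"] = first_order_id.reindex(
        pd.MultiIndex.from_arrays([administrations["encounter_ix"], administrations["medication"]])
    ).to_numpy()
    administrations.insert(1, "encounter_id", encounter_id[administrations.pop("encounter_ix")])
    administrations = administrations[["order_id", "encounter_id", "medication", "admin_ts"]]

    # ---------------- mortality ------------------------------------------
    lo = config.mortality_logodds
    frailty = 0.8 * sev_e + b_e
    p_inpt = expit(lo["inpatient"] + frailty)
    p3, p6, p12 = (expit(lo[k] + frailty) for k in ("3m", "6m", "12m"))
    u_in = rng.uniform(size=nenc)
    u_out = rng.uniform(size=nenc)
    inpatient_death = u_in < p_inpt
    death_day = np.full(nenc, np.nan)
    out3 = (~inpatient_death) & (u_out < p3)
    out6 = (~inpatient_death) & ~out3 & (u_out < p6)
    out12 = (~inpatient_death) & ~out3 & ~out6 & (u_out < p12)
    death_day[out3] = np.minimum(los_days[out3] + 1, 85) + rng.uniform(0, 3, int(out3.sum()))
    death_day[out6] = rng.uniform(93, 181, int(out6.sum()))
    death_day[out12] = rng.uniform(186, 363, int(out12.sum()))
    death_date = pd.Series(pd.NaT, index=range(nenc), dtype="datetime64[ns]")
    outpat = ~np.isnan(death_day)
    death_date[outpat] = _minute(
        admit[outpat] + pd.to_timedelta(death_day[outpat] * 24 * 60, unit="m")
    ).to_numpy()
    death_date[inpatient_death] = discharge[inpatient_death]

    # ---------------- labs ------------------------------------------------
    lab_specs = {
        "potassium": (4.0, 0.45),
        "magnesium": (2.0, 0.25),
        "creatinine": (0.95, 0.45),
    }
    lab_frames = []
    # draw lab times around the index order (not over the whole stay, which
    # would make the timing covariate a proxy for length of stay)
    for analyte, (mu, sd) in lab_specs.items():
        present = rng.uniform(size=nenc) > config.lab_missing_prob
        ix = np.flatnonzero(present)
        lab_off = rng.normal(0.0, 8.0, ix.size) * 60.0
        lo_min = -(order_off1[ix] - 1.0)
        hi_min = los_min[ix] - order_off1[ix] - 1.0
        lab_off = np.clip(lab_off, lo_min, hi_min)
        ts = _minute(
            admit.iloc[ix].reset_index(drop=True)
            + pd.to_timedelta(order_off1[ix] + lab_off, unit="m")
        )
        if analyte == "creatinine":
            value = np.exp(rng.normal(np.log(mu), sd, ix.size))
        else:
            value = np.maximum(0.5, rng.normal(mu, sd, ix.size))
        lab_frames.append(pd.DataFrame({
            "encounter_id": encounter_id[ix],
            "analyte": analyte,
            "value": np.round(value, 2),
            "ts": ts.to_numpy(),
        }))
    labs = pd.concat(lab_frames, ignore_index=True).sort_values(
        ["encounter_id", "analyte"], kind="stable"
    ).reset_index(drop=True)

    # ---------------- diagnosis / home-medication code lists -------------
    def _code_table(prefix: str, n_tokens: int, mean_n: float, ts_vals, col: str):
        n_codes = 1 + rng.poisson(mean_n + 1.5 * expit(sev_e), nenc)
        enc_rep = np.repeat(np.arange(nenc), n_codes)
        ranks = np.arange(1, n_tokens + 1)
        pz = (ranks + 10.0) ** -1.05
        pz /= pz.sum()
        toks = rng.choice(ranks, p=pz, size=enc_rep.size)
        df = pd.DataFrame({
            "encounter_id": encounter_id[enc_rep],
            col: [f"{prefix}{t:04d}" for t in toks],
            "ts": ts_vals.iloc[enc_rep].to_numpy(),
        })
        return df.drop_duplicates(["encounter_id", col]).reset_index(drop=True)

    diagnoses = _code_table("D", 600, 2.5, admit, "icd_code").rename(columns={"ts": "recorded_ts"})
    medications_list = _code_table("M", 600, 3.0, admit, "med_name").rename(columns={"ts": "ordered_ts"})

    # ---------------- assemble -------------------------------------------
    patients = pd.DataFrame({
        "patient_id": patient_id,
        "birth_year": (pd.Series(start + pd.to_timedelta(ref_day * 24 * 3600, unit="s")).dt.year
                       - np.round(age0).astype(int)),
        "sex": sex,
        "race": race,
        "ethnicity": ethnicity,
    })
    encounters = pd.DataFrame({
        "encounter_id": encounter_id,
        "patient_id": patient_id[pat_ix],
        "admit_ts": admit.to_numpy(),
        "discharge_ts": discharge.to_numpy(),
        "icu": icu.astype(int),
        "telemetry": telemetry.astype(int),
        "stepdown": stepdown.astype(int),
        "obgyn": obgyn.astype(int),
        "inpatient_death": inpatient_death.astype(int),
        "death_date": death_date.to_numpy(),
    })
    ecgs_out = pd.DataFrame({
        "ecg_id": ecgs["ecg_id"],
        "patient_id": patient_id[ecgs["patient_ix"]],
        "encounter_id": np.where(ecgs["encounter_ix"] >= 0,
                                 encounter_id[ecgs["encounter_ix"].clip(lower=0)], ""),
        "ts": ecgs["ts"].to_numpy(),
        "qt_ms": np.round(ecgs["qt_ms"].to_numpy(), 2),
        "qrs_ms": np.round(ecgs["qrs_ms"].to_numpy(), 2),
        "rr_s": np.round(ecgs["rr_s"].to_numpy(), 4),
    })

    bundle = DatasetBundle(
        patients=patients,
        encounters=encounters,
        ecgs=ecgs_out,
        orders=orders[["order_id", "encounter_id", "medication", "order_ts", "signed"]],
        administrations=administrations,
        alerts=alerts,
        labs=labs,
        diagnoses=diagnoses,
        medications_list=medications_list,
    )
    truth = GroundTruth(
        config_echo=config.to_dict(),
        true_marginal_or_alert_dilqts=true_marginal_or,
        true_irr_alert_los=float(np.exp(config.alert_los_log_irr)),
        per_medication_dilqts_logodds=med_lo_map,
        dilqts_intercept=float(intercept),
        injected_discrepancies=injected,
        n_encounters=nenc,
        n_index_events=nev,
    )
    return bundle, truth


_TS_COLUMNS = {
    "encounters": ["admit_ts", "discharge_ts", "death_date"],
    "ecgs": ["ts"],
    "orders": ["order_ts"],
    "administrations": ["admin_ts"],
    "alerts": ["alert_ts"],
    "labs": ["ts"],
    "diagnoses": ["recorded_ts"],
    "medications_list": ["ordered_ts"],
}


def write_bundle(bundle: DatasetBundle, truth: GroundTruth | None, out_dir) -> None:
    """Write all tables as headered CSV (ISO-8601 timestamps) plus the
    ground-truth registry as JSON."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for name in DatasetBundle.TABLES:
        df = getattr(bundle, name)
        df.to_csv(out / f"{name}.csv", index=False, date_format="%Y-%m-%dT%H:%M:%S")
    if truth is not None:
        truth.to_json(out / "ground_truth.json")


def read_bundle(in_dir) -> DatasetBundle:
    """Read a bundle previously written by :func:`write_bundle`."""
    src = Path(in_dir)
    tables = {}
    for name in DatasetBundle.TABLES:
        df = pd.read_csv(src / f"{name}.csv", keep_default_na=True)
        for col in _TS_COLUMNS.get(name, []):
            df[col] = pd.to_datetime(df[col])
        tables[name] = df
    return DatasetBundle(**tables)
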