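import numpy as np
import pandas as pd
import pytest

from qtalert import alert_cohort as ac
from qtalert import synthetic_ehr as se


@pytest.fixture(scope="session")
def small_bundle():
    cfg = se.GeneratorConfig(n_patients=400, seed=7, second_med_prob=0.08)
    return se.generate(cfg)


@pytest.fixture(scope="session")
def small_events(small_bundle):
    bundle, _ = small_bundle
    events, audit = ac.build_index_events(bundle)
    return events, audit


@pytest.fixture(scope="session")
def null_run():
    """Large null-effect cohort (~51k encounters) shared by calibration tests."""
    cfg = se.GeneratorConfig(
        n_patients=30_000, seed=11, alert_effect_logodds=0.0, alert_los_log_irr=0.0
    )
    bundle, truth = se.generate(cfg)
    events, audit = ac.build_index_events(bundle)
    return bundle, truth, events


def empty_table(columns):
    return pd.DataFrame({c: pd.Series(dtype=object) for c in columns})


def tiny_bundle(patients, encounters, ecgs, orders, administrations=None,
                alerts=None, labs=None, diagnoses=None, medications_list=None):
    """Assemble a hand-written bundle, filling unused tables with empty frames."""
    return se.DatasetBundle(
        patients=patients,
        encounters=encounters,
        ecgs=ecgs,
        orders=orders,
        administrations=administrations if administrations is not None else empty_table(
            ["order_id", "encounter_id", "medication", "admin_ts"]),
        alerts=alerts if alerts is not None else empty_table(
            ["alert_id", "encounter_id", "medication", "alert_ts", "provider_action"]),
        labs=labs if labs is not None else empty_table(
            ["encounter_id", "analyte", "value", "ts"]),
        diagnoses=diagnoses if diagnoses is not None else empty_table(
            ["encounter_id", "icd_code", "recorded_ts"]),
        medications_list=medications_list if medications_list is not None else empty_table(
            ["encounter_id", "med_name", "ordered_ts"]),
    )


def make_patient(pid="P1", birth_year=1960, sex="F", race="White", eth="Non-Hispanic"):
    return dict(patient_id=pid, birth_year=birth_year, sex=sex, race=race, ethnicity=eth)


def make_encounter(eid="E1", pid="P1", admit="2020-01-01 08:00", days=5.0, **flags):
    admit = pd.Timestamp(admit)
    row = dict(
        encounter_id=eid, patient_id=pid, admit_ts=admit,
        discharge_ts=admit + pd.Timedelta(days=days),
        icu=0, telemetry=0, stepdown=0, obgyn=0,
        inpatient_death=0, death_date=pd.NaT,
    )
    row.update(flags)
    return row


def make_ecg(gid, pid, eid, ts, qtc=420.0):
    # rr=1 s, qrs=90 ms -> both corrections equal qt_ms
    return dict(ecg_id=gid, patient_id=pid, encounter_id=eid,
                ts=pd.Timestamp(ts), qt_ms=qtc, qrs_ms=90.0, rr_s=1.0)


def make_order(oid, eid, med, ts, signed=1):
    return dict(order_id=oid, encounter_id=eid, medication=med,
                order_ts=pd.Timestamp(ts), signed=signed)
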