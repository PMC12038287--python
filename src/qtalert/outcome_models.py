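"""Marginal (population-averaged) regression models for the cohort.

Binary outcomes use logistic generalized estimating equations, hospital
duration uses Poisson-log GEE on fractional days (quasi-likelihood
contract); both use an exchangeable working correlation within patients and
sandwich (robust) standard errors.  The inner GEE solve is delegated to
statsmodels; this module owns the design construction (adjustment set,
reference categories, missing-indicator handling for labs and pretreatment
QTc, interaction terms), joint Wald tests, and predictive margins via
marginal standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "ModelSpec",
    "ModelFit",
    "DEFAULT_ADJUSTMENT",
    "build_design",
    "fit_marginal",
    "wald_joint_test",
    "predict_margins",
    "run_analysis_suite",
]

DEFAULT_ADJUSTMENT = (
    "age", "sex", "race", "ethnicity", "location", "cluster",
    "max_pre_qt", "labs",
)

_BINARY_OUTCOMES = ("dilqts", "inpatient_death", "death_3m", "death_6m", "death_12m")


@dataclass
class ModelSpec:
    """One marginal model: outcome, family, covariate terms, interactions."""

    outcome: str
    family: str = "auto"  # binomial-logit | poisson-log
    covariates: tuple = DEFAULT_ADJUSTMENT
    exposures: tuple = ("alert",)
    interactions: tuple = ()  # pairs of term names, e.g. (("medication", "alert"),)
    correlation: str = "exchangeable"  # or "independence"

    def resolved_family(self) -> str:
        if self.family != "auto":
            return self.family
        if self.outcome in _BINARY_OUTCOMES:
            return "binomial-logit"
        if self.outcome == "los_days":
            return "poisson-log"
        raise ValueError(f"cannot infer family for outcome {self.outcome!r}")

    def validate(self) -> None:
        fam = self.resolved_family()
        if self.outcome in _BINARY_OUTCOMES and fam != "binomial-logit":
            raise ValueError("binary outcomes require the binomial-logit family")
        if self.outcome == "los_days" and fam != "poisson-log":
            raise ValueError("hospital duration requires the poisson-log family")
        terms = set(self.covariates) | set(self.exposures)
        for pair in self.interactions:
            for t in pair:
                if t not in terms:
                    raise ValueError(f"interaction component {t!r} lacks a main effect")


@dataclass
class ModelFit:
    """Coefficients, robust covariance, and metadata from one GEE fit."""

    spec: ModelSpec
    params: pd.Series
    robust_se: pd.Series
    pvalues: pd.Series
    cov: pd.DataFrame
    n_obs: int
    n_groups: int
    converged: bool
    diagnostics: dict = field(default_factory=dict)

    @property
    def ci95(self) -> pd.DataFrame:
        lo = self.params - 1.96 * self.robust_se
        hi = self.params + 1.96 * self.robust_se
        return pd.DataFrame({"low": lo, "high": hi})

    @property
    def exponentiated(self) -> pd.Series:
        """OR (logistic) or IRR (Poisson) per coefficient."""
        return np.exp(self.params)

    def summary_frame(self) -> pd.DataFrame:
        ci = self.ci95
        return pd.DataFrame({
            "estimate": self.params,
            "robust_se": self.robust_se,
            "exp": self.exponentiated,
            "exp_ci_low": np.exp(ci["low"]),
            "exp_ci_high": np.exp(ci["high"]),
            "p": self.pvalues,
        })


def _term_frame(events: pd.DataFrame, term: str) -> pd.DataFrame:
    """Numeric design columns for one named term."""
    if term == "age":
        return pd.DataFrame({"age_years": events["age_years"].astype(float)})
    if term == "sex":
        return pd.DataFrame({"sex_F": (events["sex"] == "F").astype(float)})
    if term == "race":
        return pd.DataFrame({
            "race_Black": (events["race"] == "Black").astype(float),
            "race_Other": (events["race"] == "Other").astype(float),
        })
    if term == "ethnicity":
        return pd.DataFrame({"eth_Hispanic": (events["ethnicity"] == "Hispanic").astype(float)})
    if term == "location":
        return pd.DataFrame({
            f: events[f].astype(float) for f in ("icu", "telemetry", "stepdown", "obgyn")
        })
    if term == "cluster":
        if "cluster" not in events.columns:
            return pd.DataFrame(index=events.index)
        counts = events["cluster"].value_counts()
        ref = counts.index[0]  # largest cluster is the reference
        return pd.DataFrame({
            f"cluster_{c}": (events["cluster"] == c).astype(float)
            for c in sorted(x for x in counts.index if x != ref)
        })
    if term == "max_pre_qt":
        v = events["max_pre_qt"].astype(float)
        return pd.DataFrame({
            "max_pre_qt": v.fillna(v.mean()) / 100.0,
            "max_pre_qt_missing": v.isna().astype(float),
        })
    if term == "labs":
        out = {}
        for lab in ("potassium", "magnesium", "creatinine"):
            v = events[lab].astype(float)
            out[lab] = v.fillna(v.mean())
            out[f"{lab}_missing"] = v.isna().astype(float)
            out[f"{lab}_offset_h"] = events[f"{lab}_offset_h"].astype(float).fillna(0.0)
        return pd.DataFrame(out)
    if term == "medication":
        counts = events["medication"].value_counts()
        ref = counts.index[0]
        return pd.DataFrame({
            f"med_{m}": (events["medication"] == m).astype(float)
            for m in sorted(x for x in counts.index if x != ref)
        })
    if term == "alert":
        return pd.DataFrame({"alert": events["alert_fired"].astype(float)})
    if term == "action":
        return pd.DataFrame({"action_comply": (events["action_group"] == "comply").astype(float)})
    if term == "era":
        return pd.DataFrame({"era_post": (events["cds_era"] == "post").astype(float)})
    if term == "dilqts":
        return pd.DataFrame({"dilqts": events["dilqts"].astype(float)})
    raise ValueError(f"unknown model term {term!r}")


def build_design(
    events: pd.DataFrame, spec: ModelSpec, drop_constant: bool = True
) -> tuple[pd.DataFrame, dict]:
    """Intercept + main-effect columns + interaction products for a spec.

    Returns the design frame and a map term -> list of its column names
    (interaction groups keyed "a:b").  Zero-variance columns are dropped.
    """
    events = events.reset_index(drop=True)
    X = pd.DataFrame({"intercept": np.ones(len(events))})
    groups: dict[str, list] = {}
    for term in tuple(spec.exposures) + tuple(spec.covariates):
        tf = _term_frame(events, term).reset_index(drop=True)
        groups[term] = list(tf.columns)
        X = pd.concat([X, tf], axis=1)
    for a, b in spec.interactions:
        cols = []
        for ca in groups[a]:
            for cb in groups[b]:
                name = f"{ca}:{cb}"
                X[name] = X[ca] * X[cb]
                cols.append(name)
        groups[f"{a}:{b}"] = cols
    if not drop_constant:
        return X, {"terms": groups, "dropped": []}
    keep = [c for c in X.columns if c == "intercept" or X[c].nunique() > 1]
    dropped = [c for c in X.columns if c not in keep]
    X = X[keep]
    groups = {t: [c for c in cols if c in keep] for t, cols in groups.items()}
    return X, {"terms": groups, "dropped": dropped}


def _filter_events(events: pd.DataFrame, spec: ModelSpec) -> pd.DataFrame:
    out = events[events[spec.outcome].notna()].copy()
    if "action" in spec.exposures:
        out = out[
            out["alert_fired"].astype(bool)
            & out["action_group"].notna()
            & (out["recode_missing_reason"] == "none")
        ]
    if "dilqts" in spec.exposures:
        out = out[out["dilqts"].notna()]
    return out.reset_index(drop=True)


def fit_marginal(spec: ModelSpec, events: pd.DataFrame, maxiter: int = 100) -> ModelFit:
    """Solve the GEE for one model spec and return the fitted summary.

    Rows with a missing outcome are dropped; action-group models are
    restricted to fired alerts with a recorded response and no recode.
    Robust (sandwich) covariance is used throughout.  Non-convergence or a
    numerically singular solve is flagged in ``diagnostics`` rather than
    silently replaced.
    """
    spec.validate()
    data = _filter_events(events, spec)
    X, meta = build_design(data, spec)
    y = data[spec.outcome].astype(float).to_numpy()
    groups = data["patient_id"].to_numpy()

    fam = sm.families.Binomial() if spec.resolved_family() == "binomial-logit" else sm.families.Poisson()
    cov = sm.cov_struct.Exchangeable() if spec.correlation == "exchangeable" else sm.cov_struct.Independence()

    diagnostics = {"n_dropped_columns": len(meta["dropped"]), "terms": meta["terms"]}
    try:
        model = sm.GEE(y, X, groups=groups, family=fam, cov_struct=cov)
        res = model.fit(maxiter=maxiter, ctol=1e-6)
        converged = bool(getattr(res, "converged", True))
        params = pd.Series(res.params, index=X.columns)
        bse = pd.Series(res.bse, index=X.columns)
        pvals = pd.Series(res.pvalues, index=X.columns)
        covp = pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns)
    except (np.linalg.LinAlgError, ValueError) as err:  # separation / singular
        converged = False
        diagnostics["error"] = str(err)
        nanvec = pd.Series(np.nan, index=X.columns)
        params, bse, pvals = nanvec, nanvec.copy(), nanvec.copy()
        covp = pd.DataFrame(np.nan, index=X.columns, columns=X.columns)
    return ModelFit(
        spec=spec, params=params, robust_se=bse, pvalues=pvals, cov=covp,
        n_obs=len(data), n_groups=len(pd.unique(groups)), converged=converged,
        diagnostics=diagnostics,
    )


def wald_joint_test(fit: ModelFit, term_group) -> tuple[float, float, int]:
    """Joint Wald chi-square for a coefficient group under the robust
    covariance; uses a generalized inverse and reports the rank as df.

    ``term_group`` is a term name from the spec (e.g. ``"medication:alert"``)
    or an explicit list of coefficient names.
    """
    if isinstance(term_group, str):
        names = fit.diagnostics["terms"].get(term_group)
        if not names:
            raise ValueError(f"term group {term_group!r} not in fit")
    else:
        names = list(term_group)
        missing = [n for n in names if n not in fit.params.index]
        if missing:
            raise ValueError(f"terms not in fit: {missing}")
    b = fit.params[names].to_numpy()
    V = fit.cov.loc[names, names].to_numpy()
    rank = int(np.linalg.matrix_rank(V))
    stat = float(b @ np.linalg.pinv(V) @ b)
    p = float(stats.chi2.sf(stat, rank)) if rank > 0 else np.nan
    return stat, p, rank


def predict_margins(fit: ModelFit, events: pd.DataFrame, condition: dict):
    """Predictive margin by marginal standardization with delta-method SE.

    ``condition`` maps event columns (e.g. ``{"alert_fired": 1}``) to imposed
    values; predictions are averaged over the observed covariate
    distribution with the condition applied.  Returns ``(margin, se)``.
    """
    data = _filter_events(events, fit.spec)
    for col, value in condition.items():
        if col not in data.columns:
            raise ValueError(f"unknown covariate {col!r} in condition")
        data[col] = value
    X, _ = build_design(data, fit.spec, drop_constant=False)
    X = X.reindex(columns=fit.params.index, fill_value=0.0)
    eta = X.to_numpy() @ fit.params.to_numpy()
    if fit.spec.resolved_family() == "binomial-logit":
        mu = 1.0 / (1.0 + np.exp(-eta))
        dmu = mu * (1.0 - mu)
    else:
        mu = np.exp(eta)
        dmu = mu
    margin = float(mu.mean())
    grad = (dmu[:, None] * X.to_numpy()).mean(axis=0)
    se = float(np.sqrt(grad @ fit.cov.to_numpy() @ grad))
    return margin, se


def _suite_specs(suite: str) -> list[ModelSpec]:
    base = dict(covariates=DEFAULT_ADJUSTMENT)
    binaries = ["inpatient_death", "death_3m", "death_6m", "death_12m"]
    if suite == "alert":
        specs = [
            ModelSpec("dilqts", exposures=("alert", "medication"), **base),
            ModelSpec("dilqts", exposures=("alert", "medication"),
                      interactions=(("location", "alert"),), **base),
            ModelSpec("dilqts", exposures=("alert", "medication"),
                      interactions=(("medication", "alert"),), **base),
            ModelSpec("los_days", exposures=("alert", "medication"), **base),
        ]
        specs += [ModelSpec(o, exposures=("alert", "medication"), **base) for o in binaries]
        return specs
    if suite == "action":
        return (
            [ModelSpec("dilqts", exposures=("action", "medication"), **base),
             ModelSpec("dilqts", exposures=("action", "medication"),
                       interactions=(("medication", "action"),), **base),
             ModelSpec("los_days", exposures=("action", "medication"), **base)]
            + [ModelSpec(o, exposures=("action", "medication"), **base) for o in binaries]
        )
    if suite == "era":
        # era models omit alert terms: pre-era encounters cannot alert
        return (
            [ModelSpec("dilqts", exposures=("era", "medication"), **base),
             ModelSpec("dilqts", exposures=("era", "medication"),
                       interactions=(("medication", "era"),), **base),
             ModelSpec("los_days", exposures=("era", "medication"), **base)]
            + [ModelSpec(o, exposures=("era", "medication"), **base) for o in binaries]
        )
    if suite == "dilqts":
        return (
            [ModelSpec("los_days", exposures=("dilqts", "medication"), **base),
             ModelSpec("los_days", exposures=("dilqts", "medication"),
                       interactions=(("medication", "dilqts"),), **base)]
            + [ModelSpec(o, exposures=("dilqts", "medication"), **base) for o in binaries]
        )
    raise ValueError(f"unknown suite {suite!r}")


ERA_CAVEAT = (
    "Era contrasts compare calendar periods and are subject to secular-trend "
    "confounding; no secular-trend adjustment is applied."
)


def run_analysis_suite(events: pd.DataFrame, suite: str = "alert") -> dict:
    """Fit one model family (alert / action / era / dilqts) with its
    interaction variants.

    Returns ``{"fits": [...], "table": DataFrame, "failures": [...]}`` where
    the table consolidates exponentiated estimates with robust CIs.  A
    failing variant yields a failure entry instead of aborting the suite.
    """
    fits, failures, rows = [], [], []
    for i, spec in enumerate(_suite_specs(suite)):
        try:
            fit = fit_marginal(spec, events)
        except Exception as err:  # noqa: BLE001 - partial report by contract
            failures.append({"outcome": spec.outcome, "error": str(err)})
            continue
        fits.append(fit)
        label = f"{spec.outcome}" + (
            "+" + "x".join(spec.interactions[0]) if spec.interactions else ""
        )
        sf = fit.summary_frame()
        for name, r in sf.iterrows():
            rows.append({
                "suite": suite, "variant": label, "term": name,
                "estimate": r["estimate"], "robust_se": r["robust_se"],
                "exp": r["exp"], "exp_ci_low": r["exp_ci_low"],
                "exp_ci_high": r["exp_ci_high"], "p": r["p"],
                "converged": fit.converged,
            })
    table = pd.DataFrame(rows)
    out = {"fits": fits, "table": table, "failures": failures}
    if suite == "era":
        out["caveat"] = ERA_CAVEAT
    return out
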