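"""Prognostic screening: Q3 stratification, Kaplan–Meier/log-rank, Cox PH.

Per candidate gene, patients are split at the third quartile of its
expression (linear-interpolation quantile; strictly greater than Q3 is
"high"), survival curves are compared by log-rank, and genes passing the
screen enter a multivariate Cox proportional-hazards model alongside the
standard clinical covariates of localized prostate cancer: diagnostic
PSA, Gleason score, age at diagnosis and pathologic T stage.  Reference
levels: low expression, PSA <= 10, GS < 7, age <= 62, pT2a-b.

Model fitting is delegated to lifelines (Efron tie handling); this module
owns the covariate codings, the stratification rule and the screening
logic.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .types import (
    DegenerateStratificationError,
    SurvivalRecord,
    UndefinedTestError,
    ValidationError,
)

log = logging.getLogger("metscreen")

COX_TERMS = [
    "expression_high",
    "psa_intermediate",
    "psa_high",
    "gs_intermediate",
    "gs_high",
    "age_high",
    "pt_high",
]


def stratify_by_q3(values) -> pd.Series:
    """Binary high/low labels at the third quartile of expression.

    Q3 is the linear-interpolation (type-7) quantile; "high" means
    strictly greater than Q3.  Raises if fewer than 4 values, all values
    equal, or either group would be empty.
    """
    values = pd.Series(values, dtype=float)
    if len(values) < 4:
        raise DegenerateStratificationError("Q3 stratification needs >= 4 values")
    if values.nunique() == 1:
        raise DegenerateStratificationError("all expression values are equal")
    q3 = float(np.quantile(values.to_numpy(), 0.75))
    labels = pd.Series(np.where(values > q3, "high", "low"), index=values.index)
    if (labels == "high").sum() == 0 or (labels == "low").sum() == 0:
        raise DegenerateStratificationError("Q3 split leaves an empty group")
    return labels


def encode_covariates(record: SurvivalRecord) -> dict[str, float | None]:
    """Dummy-code one record against the model's reference levels.

    age <= 62 low; PSA <= 10 low, (10, 20) intermediate, >= 20 high;
    GS < 7 / = 7 / > 7; pT2a-b low, pT3a-b high.  A missing Gleason
    score yields None entries for the GS terms; callers exclude such
    records from the Cox fit with a count.
    """
    out: dict[str, float | None] = {
        "age_high": float(record.age > 62),
        "psa_intermediate": float(10 < record.psa < 20),
        "psa_high": float(record.psa >= 20),
        "pt_high": float(record.pt_stage in ("pT3a", "pT3b")),
    }
    if record.gleason is None:
        out["gs_intermediate"] = None
        out["gs_high"] = None
    else:
        out["gs_intermediate"] = float(record.gleason == 7)
        out["gs_high"] = float(record.gleason > 7)
    return out


@dataclass
class KMResult:
    """Two-group product-limit estimates plus the log-rank comparison."""

    survival: dict[str, pd.DataFrame]  # per group: time, survival, at_risk
    chi_square: float
    p: float


def km_logrank(records: list[SurvivalRecord], labels: pd.Series) -> KMResult:
    """Kaplan–Meier curves per label group and the two-group log-rank test."""
    by_id = {r.sample_id: r for r in records}
    groups = sorted(set(labels))
    if len(groups) != 2:
        raise ValidationError(f"km_logrank needs exactly 2 groups, got {groups}")
    times, events = {}, {}
    for g in groups:
        ids = labels.index[labels == g]
        if len(ids) == 0:
            raise ValidationError(f"group {g!r} is empty")
        times[g] = np.array([by_id[i].time for i in ids])
        events[g] = np.array([by_id[i].event for i in ids])
    if sum(events[g].sum() for g in groups) == 0:
        raise UndefinedTestError("log-rank test undefined with zero events")

    curves = {}
    for g in groups:
        kmf = KaplanMeierFitter()
        kmf.fit(times[g], events[g], label=g)
        tbl = kmf.event_table
        curves[g] = pd.DataFrame(
            {
                "time": kmf.survival_function_.index.to_numpy(),
                "survival": kmf.survival_function_[g].to_numpy(),
                "at_risk": tbl["at_risk"].reindex(kmf.survival_function_.index).to_numpy(),
            }
        )
    res = logrank_test(times[groups[0]], times[groups[1]], events[groups[0]], events[groups[1]])
    return KMResult(curves, float(res.test_statistic), float(res.p_value))


@dataclass
class CoxFit:
    """Per-term relative risks from the multivariate Cox model."""

    terms: pd.DataFrame  # index term; beta, rr, ci_low, ci_high, p
    n_used: int
    n_excluded: int
    converged: bool
    dropped: list[str] = field(default_factory=list)

    def term(self, name: str) -> pd.Series:
        return self.terms.loc[name]


def cox_multivariate(
    records: list[SurvivalRecord], expression_labels: pd.Series
) -> CoxFit:
    """Multivariate Cox PH: expression high/low plus PSA, GS, age, pT.

    Records with a missing Gleason score are excluded (counted in
    ``n_excluded``); constant covariates are dropped with a warning; a
    non-converged or separated fit is returned flagged rather than
    silently.
    """
    rows = []
    n_excluded = 0
    for r in records:
        if r.sample_id not in expression_labels.index:
            continue
        cov = encode_covariates(r)
        if cov["gs_intermediate"] is None:
            n_excluded += 1
            continue
        rows.append(
            {
                "time": r.time,
                "event": r.event,
                "expression_high": float(expression_labels[r.sample_id] == "high"),
                **cov,
            }
        )
    df = pd.DataFrame(rows)
    if df.empty or df["event"].sum() == 0:
        raise UndefinedTestError("Cox model undefined: no usable records or no events")

    dropped = [t for t in COX_TERMS if t in df.columns and df[t].nunique() == 1]
    for t in dropped:
        log.warning("covariate %s is constant; dropped from the Cox model", t)
    keep = [t for t in COX_TERMS if t not in dropped]
    cph = CoxPHFitter()
    converged = True
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df[["time", "event"] + keep],
                duration_col="time",
                event_col="event",
                fit_options={"precision": 1e-9, "max_steps": 500},
            )
    except ConvergenceError:
        converged = False
    if converged:
        summ = cph.summary
        terms = pd.DataFrame(
            {
                "beta": summ["coef"],
                "rr": summ["exp(coef)"],
                "ci_low": np.exp(summ["coef"] - 1.96 * summ["se(coef)"]),
                "ci_high": np.exp(summ["coef"] + 1.96 * summ["se(coef)"]),
                "p": summ["p"],
            }
        )
        terms.index.name = "term"
    else:
        terms = pd.DataFrame(
            np.nan, index=pd.Index(keep, name="term"),
            columns=["beta", "rr", "ci_low", "ci_high", "p"],
        )
    return CoxFit(terms, n_used=len(df), n_excluded=n_excluded, converged=converged, dropped=dropped)


def prognostic_screen(
    deg_ids: list[str],
    expression: pd.DataFrame,
    records: list[SurvivalRecord],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict[str, CoxFit], list[str]]:
    """Screen DEGs for prognostic value.

    Per gene: Q3 stratification of its expression row, log-rank test;
    genes with p < alpha proceed to the multivariate Cox model; a gene is
    an *independent* predictor when its expression term stays at Wald
    p < alpha there.  Returns (screen table, per-gene Cox fits for
    screened genes, independent predictor list).  Genes that cannot be
    stratified are excluded with a reason, never raising.
    """
    record_ids = [r.sample_id for r in records]
    shared = [s for s in expression.columns if s in set(record_ids)]
    unjoined = sorted(set(record_ids) - set(shared))
    if unjoined:
        log.warning("%d survival records have no expression column: %s", len(unjoined), unjoined[:5])
    if not shared:
        raise ValidationError("no sample ids shared between expression and survival records")
    usable = [r for r in records if r.sample_id in set(shared)]

    rows = []
    fits: dict[str, CoxFit] = {}
    independent: list[str] = []
    for gene in deg_ids:
        if gene not in expression.index:
            rows.append({"gene_id": gene, "logrank_p": np.nan, "status": "missing_expression"})
            continue
        try:
            labels = stratify_by_q3(expression.loc[gene, shared])
        except DegenerateStratificationError as exc:
            rows.append({"gene_id": gene, "logrank_p": np.nan, "status": f"not_stratifiable: {exc}"})
            continue
        km = km_logrank(usable, labels)
        rows.append({"gene_id": gene, "logrank_p": km.p, "status": "tested"})
        if km.p < alpha:
            fit = cox_multivariate(usable, labels)
            fits[gene] = fit
            if (
                fit.converged
                and "expression_high" in fit.terms.index
                and fit.terms.loc["expression_high", "p"] < alpha
            ):
                independent.append(gene)
    screen = pd.DataFrame(rows).set_index("gene_id")
    return screen, fits, independent
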