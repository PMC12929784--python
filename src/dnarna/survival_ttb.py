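"""Tumor transcriptional burden (TTB) and survival analysis.

TTB is the per-patient count of distinct genes with altered expression
(over- or under-expressed).  Patients are stratified by TTB (default
strata: 0-2, 3-5, >=6 genes) and overall survival is compared across
strata with Kaplan-Meier curves and the k-sample log-rank test, restricted
by default to treated patients.  The module also provides the
TTB-vs-PD-L1 rank comparison and Yates-corrected chi-squared tests for
baseline-characteristics tables.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

from .concordance import RankTestResult, mann_whitney_two_sided
from .io_model import Cohort

DEFAULT_TTB_BREAKS: tuple[int, ...] = (2, 5)


def stratum_labels(breaks: Sequence[int]) -> list[str]:
    """Human-readable labels for the TTB strata implied by ``breaks``.

    ``breaks`` are inclusive upper bounds, e.g. (2, 5) -> '0-2', '3-5', '>=6'.
    """
    breaks = list(breaks)
    if breaks != sorted(breaks) or len(set(breaks)) != len(breaks):
        raise ValueError(f"TTB breaks must be strictly increasing, got {breaks}")
    labels = []
    lo = 0
    for b in breaks:
        labels.append(f"{lo}-{b}")
        lo = b + 1
    labels.append(f">={lo}")
    return labels


@dataclass(frozen=True)
class TtbRecord:
    patient_id: str
    ttb: int
    stratum: str


@dataclass
class KmCurve:
    """Product-limit survival estimate for one stratum."""

    label: str
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    greenwood_se: np.ndarray
    median: float  # nan when the curve never reaches 0.5
    n: int
    n_events: int


@dataclass(frozen=True)
class LogRankResult:
    statistic: float
    df: int
    p_value: float


def compute_ttb(
    cohort: Cohort, breaks: Sequence[int] = DEFAULT_TTB_BREAKS
) -> list[TtbRecord]:
    """TTB per patient: distinct RNA-altered genes (0 when no RNA calls)."""
    labels = stratum_labels(breaks)
    rna_by_pt = cohort.rna_genes_by_patient()
    records = []
    for p in cohort.patients:
        ttb = len(rna_by_pt[p.patient_id])
        idx = int(np.searchsorted(breaks, ttb, side="left"))
        records.append(TtbRecord(patient_id=p.patient_id, ttb=ttb, stratum=labels[idx]))
    return records


def km_estimate(
    times: Sequence[float], events: Sequence[bool], label: str = ""
) -> KmCurve:
    """Kaplan-Meier product-limit estimator with Greenwood standard errors.

    Ties follow the standard convention that deaths precede censorings at
    equal times.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("km_estimate requires at least one subject")
    if times.size != events.size:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events, label=label or "KM")
    # restrict the reported grid to observed event times
    event_times = np.unique(times[events])
    surv = kmf.survival_function_at_times(event_times).to_numpy()
    # Greenwood SE of S(t): lifelines ci is log-log; recompute directly
    se = np.empty_like(surv)
    var_cum = 0.0
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = events[order]
    n_at_risk_all = len(times)
    i = 0
    k = 0
    at_risk_list = []
    for t in event_times:
        # remove subjects exiting strictly before t
        while i < len(t_sorted) and t_sorted[i] < t:
            n_at_risk_all -= 1
            i += 1
        d = int(np.sum((t_sorted == t) & e_sorted))
        r = n_at_risk_all
        at_risk_list.append(r)
        if r > d:
            var_cum += d / (r * (r - d))
            se[k] = surv[k] * np.sqrt(var_cum)
        else:
            se[k] = 0.0
        k += 1
    median = float(kmf.median_survival_time_)
    return KmCurve(
        label=label,
        event_times=event_times,
        survival=surv,
        at_risk=np.asarray(at_risk_list, dtype=int),
        greenwood_se=se,
        median=median if np.isfinite(median) else float("nan"),
        n=int(times.size),
        n_events=int(events.sum()),
    )


def logrank_test(
    groups: Sequence[tuple[Sequence[float], Sequence[bool]]]
) -> LogRankResult:
    """k-sample log-rank test over (times, events) per stratum."""
    non_empty = [(t, e) for t, e in groups if len(t) > 0]
    if len(non_empty) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    durations, observed, labels = [], [], []
    for gi, (t, e) in enumerate(non_empty):
        durations.extend(float(x) for x in t)
        observed.extend(bool(x) for x in e)
        labels.extend([gi] * len(t))
    res = multivariate_logrank_test(durations, labels, observed)
    return LogRankResult(
        statistic=float(res.test_statistic),
        df=len(non_empty) - 1,
        p_value=float(res.p_value),
    )


def ttb_survival_analysis(
    cohort: Cohort,
    breaks: Sequence[int] = DEFAULT_TTB_BREAKS,
    treated_only: bool = True,
) -> dict:
    """Stratify patients by TTB, fit per-stratum KM curves, and compare OS.

    Restricted to treated patients by default (survival was analyzed in the
    treated subset).  Returns ttb records, curves keyed by stratum label,
    and the log-rank result (None when fewer than two strata are populated).
    """
    records = compute_ttb(cohort, breaks)
    rec_by_pid = {r.patient_id: r for r in records}
    labels = stratum_labels(breaks)
    groups: dict[str, tuple[list[float], list[bool]]] = {
        lab: ([], []) for lab in labels
    }
    for p in cohort.patients:
        if treated_only and not p.treated:
            continue
        lab = rec_by_pid[p.patient_id].stratum
        groups[lab][0].append(p.os_months)
        groups[lab][1].append(p.os_event)
    curves = {
        lab: km_estimate(t, e, label=lab)
        for lab, (t, e) in groups.items()
        if len(t) > 0
    }
    populated = [(t, e) for t, e in groups.values() if len(t) > 0]
    logrank = logrank_test(populated) if len(populated) >= 2 else None
    return {"ttb": records, "curves": curves, "logrank": logrank}


def ttb_by_pdl1_test(
    cohort: Cohort, records: Sequence[TtbRecord]
) -> RankTestResult:
    """Mann-Whitney comparison of TTB: PD-L1 negative vs positive patients.

    Patients with unknown PD-L1 status are excluded from this test only.
    The U statistic reported is for the PD-L1-negative group.
    """
    ttb_by_pid = {r.patient_id: r.ttb for r in records}
    neg, pos = [], []
    for p in cohort.patients:
        if p.pdl1_status == "negative":
            neg.append(ttb_by_pid[p.patient_id])
        elif p.pdl1_status == "positive":
            pos.append(ttb_by_pid[p.patient_id])
    return mann_whitney_two_sided(neg, pos)


def baseline_chi2(
    table: Sequence[Sequence[float]], yates: bool = True
) -> tuple[float, float]:
    """Pearson chi-squared on a 2x2 table, Yates-corrected by default.

    The continuity correction shrinks |O-E| by 0.5 (floored at 0), which is
    what reproduces published baseline-characteristics p-values computed
    with standard statistical software.  Returns (statistic, p).
    """
    arr = np.asarray(table, dtype=float)
    if arr.shape != (2, 2):
        raise ValueError(f"expected a 2x2 table, got shape {arr.shape}")
    if np.any(arr < 0):
        raise ValueError("counts must be non-negative")
    if np.any(arr.sum(axis=0) == 0) or np.any(arr.sum(axis=1) == 0):
        raise ValueError("chi-squared test undefined for zero margin")
    res = stats.chi2_contingency(arr, correction=yates)
    return float(res.statistic), float(res.pvalue)


def write_survival(
    cohort: Cohort, records: Sequence[TtbRecord], path
) -> None:
    by_pid = {r.patient_id: r for r in records}
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("patient_id\tttb\tstratum\tos_months\tos_event\ttreated\n")
        for p in cohort.patients:
            r = by_pid[p.patient_id]
            fh.write(
                f"{p.patient_id}\t{r.ttb}\t{r.stratum}\t{p.os_months!r}\t"
                f"{'true' if p.os_event else 'false'}\t"
                f"{'true' if p.treated else 'false'}\n"
            )


def write_km_curves(curves: dict[str, KmCurve], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("stratum\ttime\tsurvival\tat_risk\tgreenwood_se\n")
        for lab in sorted(curves):
            c = curves[lab]
            for t, s, r, se in zip(
                c.event_times, c.survival, c.at_risk, c.greenwood_se
            ):
                fh.write(f"{lab}\t{t!r}\t{s!r}\t{int(r)}\t{se!r}\n")
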