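"""RECIST response summaries and Kaplan-Meier survival analysis.

Best response is an adjudicated label (CR/PR/SD/PD); the objective
response rate (ORR) is the CR+PR fraction and the disease control rate
(DCR) the CR+PR+SD fraction, with percentages rounded half-up to
integers as printed in clinical reports.

Survival uses the Kaplan-Meier product-limit estimator (fit via
lifelines) with the standard tie convention -- events processed before
censorings at equal times.  The median is the smallest *event* time t
with S(t) <= 0.5 (inclusive) and is undefined when S never reaches 0.5;
its 95% CI inverts the pointwise log(-log) Greenwood band
(Brookmeyer-Crowley).  Undefined medians/bounds are represented as
``inf`` and serialized to JSON as null.
"""

from __future__ import annotations

import enum
import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from lifelines.utils import median_survival_times

from .io import BestResponse, PatientOutcome, Treatment, TreatmentLine

__all__ = [
    "EfficacySummary",
    "KMEstimate",
    "response_summary",
    "km_fit",
    "subgroup",
    "efficacy_report",
    "reverse_km_followup",
    "round_half_up",
]


def round_half_up(x: float) -> int:
    """Round to nearest integer, halves away from zero (13/46 -> 28%)."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


@dataclass(frozen=True)
class EfficacySummary:
    n: int
    n_cr: int
    n_pr: int
    n_sd: int
    n_pd: int
    orr_percent: int  # 100 * (CR + PR) / n, rounded half-up
    dcr_percent: int  # 100 * (CR + PR + SD) / n, rounded half-up


def response_summary(cohort: Sequence[PatientOutcome]) -> EfficacySummary:
    """Best-response counts with ORR and DCR percentages."""
    if not cohort:
        raise ValueError("empty cohort")
    counts = {r: sum(p.best_response is r for p in cohort)
              for r in BestResponse}
    n = len(cohort)
    orr = counts[BestResponse.CR] + counts[BestResponse.PR]
    dcr = orr + counts[BestResponse.SD]
    return EfficacySummary(
        n=n,
        n_cr=counts[BestResponse.CR], n_pr=counts[BestResponse.PR],
        n_sd=counts[BestResponse.SD], n_pd=counts[BestResponse.PD],
        orr_percent=round_half_up(100.0 * orr / n),
        dcr_percent=round_half_up(100.0 * dcr / n),
    )


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve with median and its 95% CI.

    ``times`` holds the distinct observed times (events and censorings);
    ``survival`` the post-time S(t); ``n_risk``/``n_event`` the risk-set
    size and event count at each time.  Undefined medians are ``inf``.
    """

    times: tuple[float, ...]
    survival: tuple[float, ...]
    n_risk: tuple[int, ...]
    n_event: tuple[int, ...]
    n_censored: tuple[int, ...]
    median: float
    median_ci_low: float
    median_ci_high: float

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S = 1 before first time."""
        s = 1.0
        for time, surv in zip(self.times, self.survival):
            if time <= t:
                s = surv
            else:
                break
        return s

    @property
    def n_events_total(self) -> int:
        return int(sum(self.n_event))


def km_fit(times: Sequence[float], events: Sequence[bool]) -> KMEstimate:
    """Kaplan-Meier product-limit fit (see module docstring for conventions)."""
    times = np.asarray(times, dtype=float)
    ev = np.asarray(events, dtype=bool)
    if times.shape != ev.shape:
        raise ValueError("times and events must have equal length")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter()
    kmf.fit(times, ev)
    table = kmf.event_table
    # lifelines inserts a t=0 anchor row when no observation occurs at 0
    if table.index[0] == 0.0 and not np.any(times == 0.0):
        table = table.iloc[1:]
    surv = [float(kmf.predict(t)) for t in table.index]
    ci = median_survival_times(kmf.confidence_interval_)
    lo, hi = (float(ci.iloc[0, 0]), float(ci.iloc[0, 1]))
    # median: smallest event time with S(t) <= 0.5
    median = math.inf
    for t, s, d in zip(table.index, surv, table["observed"]):
        if d > 0 and s <= 0.5 + 1e-12:
            median = float(t)
            break
    return KMEstimate(
        times=tuple(float(t) for t in table.index),
        survival=tuple(surv),
        n_risk=tuple(int(x) for x in table["at_risk"]),
        n_event=tuple(int(x) for x in table["observed"]),
        n_censored=tuple(int(x) for x in table["censored"]),
        median=median,
        median_ci_low=lo,
        median_ci_high=hi,
    )


class SubgroupPredicate(str, enum.Enum):
    TREATMENT = "treatment"
    LINE = "line"
    PDL1_POSITIVE = "pdl1_positive"
    DRIVER = "driver"


def subgroup(
    cohort: Iterable[PatientOutcome],
    predicate: str,
    tps_positive: float = 1.0,
) -> dict[str, list[PatientOutcome]]:
    """Partition a cohort by a clinical predicate.

    Records with an unknown value land in an explicit ``"unknown"``
    bucket -- never silently dropped.  PD-L1 positivity is the
    qualifier-aware TPS >= ``tps_positive`` test ("<1%" is negative).
    """
    predicate = SubgroupPredicate(predicate)
    out: dict[str, list[PatientOutcome]] = {}
    for p in cohort:
        if predicate is SubgroupPredicate.TREATMENT:
            key = p.treatment.value
        elif predicate is SubgroupPredicate.LINE:
            key = p.line.value
        elif predicate is SubgroupPredicate.PDL1_POSITIVE:
            if p.pdl1_tps is None:
                key = "unknown"
            else:
                key = ("positive" if p.pdl1_tps.is_at_least(tps_positive)
                       else "negative")
        else:  # driver
            if p.driver_status is None:
                key = "unknown"
            elif p.driver_status.lower() == "wild type":
                key = "wild_type"
            else:
                key = p.driver_status.split()[0]
        out.setdefault(key, []).append(p)
    return out


def _num(x: float) -> float | None:
    return None if (x is None or math.isinf(x) or math.isnan(x)) else float(x)


def _group_block(patients: Sequence[PatientOutcome]) -> dict:
    eff = response_summary(patients)
    pfs = km_fit([p.pfs_months for p in patients],
                 [p.pfs_event for p in patients])
    os_ = km_fit([p.os_months for p in patients],
                 [p.os_event for p in patients])
    return {
        "n": eff.n,
        "response": {
            "CR": eff.n_cr, "PR": eff.n_pr, "SD": eff.n_sd, "PD": eff.n_pd,
            "orr_percent": eff.orr_percent, "dcr_percent": eff.dcr_percent,
        },
        "pfs": {
            "median_months": _num(pfs.median),
            "ci95": [_num(pfs.median_ci_low), _num(pfs.median_ci_high)],
            "n_events": pfs.n_events_total,
        },
        "os": {
            "median_months": _num(os_.median),
            "ci95": [_num(os_.median_ci_low), _num(os_.median_ci_high)],
            "n_events": os_.n_events_total,
        },
    }


def efficacy_report(
    cohort: Sequence[PatientOutcome],
    groupings: Sequence[str] = (),
    tps_positive: float = 1.0,
) -> dict:
    """Structured efficacy report: overall block plus one per grouping.

    Deterministic field order; identical cohorts and groupings produce
    byte-identical JSON.
    """
    report: dict = {"overall": _group_block(cohort)}
    for predicate in groupings:
        groups = subgroup(cohort, predicate, tps_positive=tps_positive)
        report[predicate] = {
            key: _group_block(members)
            for key, members in sorted(groups.items())
        }
    report["median_followup_months_reverse_km"] = _num(
        reverse_km_followup(cohort))
    return report


def write_report(report: dict, json_path: str | Path,
                 tsv_path: str | Path | None = None) -> None:
    Path(json_path).write_text(json.dumps(report, indent=2, sort_keys=False)
                               + "\n")
    if tsv_path is None:
        return
    lines = ["group\tsubgroup\tn\torr_percent\tdcr_percent\t"
             "pfs_median\tos_median\tpfs_events\tos_events"]
    def row(group, sub, block):
        fmt = lambda v: "NA" if v is None else f"{v:g}"
        lines.append("\t".join([
            group, sub, str(block["n"]),
            str(block["response"]["orr_percent"]),
            str(block["response"]["dcr_percent"]),
            fmt(block["pfs"]["median_months"]),
            fmt(block["os"]["median_months"]),
            str(block["pfs"]["n_events"]),
            str(block["os"]["n_events"]),
        ]))
    row("overall", "-", report["overall"])
    for group, subs in report.items():
        if group in ("overall", "median_followup_months_reverse_km"):
            continue
        for sub, block in subs.items():
            row(group, sub, block)
    Path(tsv_path).write_text("\n".join(lines) + "\n")


def reverse_km_followup(cohort: Sequence[PatientOutcome]) -> float:
    """Median follow-up by reverse Kaplan-Meier on OS (censoring as event).

    A labeled estimate only; the underlying study does not state its
    follow-up method.
    """
    est = km_fit([p.os_months for p in cohort],
                 [not p.os_event for p in cohort])
    return est.median
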