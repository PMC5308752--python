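"""Kaplan-Meier disease-free survival and the log-rank test.

Disease-free survival (DFS) is the time from diagnosis to relapse or death,
censored at last follow-up.  Groups are defined by mutation status of a
chosen gene; the product-limit estimator and the two-group log-rank test are
implemented directly from their defining formulas:

    S(t) = prod_{t_i <= t} (1 - d_i / n_i)

with Greenwood's variance for the standard error, and the log-rank
chi-square (1 df) from observed-minus-expected event counts with the
hypergeometric variance at each distinct event time.  Ties between events
and censorings at the same time are resolved events-first (the censored
subject is still at risk at that time).
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.stats import chi2

from .cohort_stats import CohortMatrix
from .io_formats import PatientRecord

__all__ = [
    "SurvivalRecord",
    "KMEstimate",
    "km_estimate",
    "logrank_test",
    "dfs_by_mutation",
    "write_km_table",
]


@dataclass
class SurvivalRecord:
    patient_id: str
    time_months: float
    event: bool  # True = relapse or death observed; False = censored
    group: str

    def __post_init__(self) -> None:
        if self.time_months <= 0:
            raise ValueError(f"{self.patient_id}: non-positive survival time")
        if not self.group:
            raise ValueError(f"{self.patient_id}: empty group label")


@dataclass
class KMEstimate:
    """Product-limit estimate at the observed event times of one group."""

    group: str
    event_times: np.ndarray  # distinct times with >= 1 event
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    greenwood_se: np.ndarray
    n_subjects: int = 0

    def survival_at(self, t: float) -> float:
        """S(t), right-continuous step function; 1 before the first event."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    @property
    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, NaN if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.event_times[below[0]]) if below.size else float("nan")


def km_estimate(records: Sequence[SurvivalRecord]) -> KMEstimate:
    """Kaplan-Meier product-limit estimator for one group."""
    if not records:
        raise ValueError("km_estimate needs >= 1 record")
    group = records[0].group
    times = np.array([r.time_months for r in records])
    events = np.array([r.event for r in records], dtype=bool)
    if not events.any():
        warnings.warn(f"group {group!r}: no events; S(t) = 1 throughout",
                      stacklevel=2)
        return KMEstimate(group, np.array([]), np.array([]), np.array([]),
                          np.array([]), np.array([]), n_subjects=len(records))
    event_times = np.unique(times[events])
    at_risk = np.array([(times >= t).sum() for t in event_times])
    n_events = np.array([((times == t) & events).sum() for t in event_times])
    survival = np.cumprod(1.0 - n_events / at_risk)
    # Greenwood: var(S) = S^2 * cumsum(d / (n (n - d)))
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = n_events / (at_risk * (at_risk - n_events))
        terms[at_risk == n_events] = 0.0  # S = 0 there; SE reported as 0
        se = survival * np.sqrt(np.cumsum(terms))
    return KMEstimate(group, event_times, at_risk, n_events, survival, se,
                      n_subjects=len(records))


def logrank_test(
    group_a: Sequence[SurvivalRecord], group_b: Sequence[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p, 1 df)."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    times = np.array([r.time_months for r in group_a] +
                     [r.time_months for r in group_b])
    events = np.array([r.event for r in group_a] +
                      [r.event for r in group_b], dtype=bool)
    labels = np.array([0] * len(group_a) + [1] * len(group_b))
    if not events.any():
        raise ValueError("log-rank test needs >= 1 event")
    obs_minus_exp = 0.0
    variance = 0.0
    for t in np.unique(times[events]):
        at_risk = times >= t
        n = at_risk.sum()
        n1 = (at_risk & (labels == 0)).sum()
        d = (events & (times == t)).sum()
        d1 = (events & (times == t) & (labels == 0)).sum()
        obs_minus_exp += d1 - d * n1 / n
        if n > 1:
            variance += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if variance == 0.0:
        warnings.warn("log-rank variance is zero; p = 1", stacklevel=2)
        return 0.0, 1.0
    stat = obs_minus_exp**2 / variance
    return float(stat), float(chi2.sf(stat, df=1))


def dfs_by_mutation(
    matrix: CohortMatrix,
    clinical: Sequence[PatientRecord],
    gene: str,
    event_mode: str = "relapse_or_death",
) -> dict:
    """Compare DFS between mutated and wild-type patients for one gene.

    Patients missing from the clinical table are dropped and reported.  With
    an empty mutated (or wild-type) group only the single available curve is
    returned and no test is run.  ``event_mode`` is "relapse_or_death"
    (default) or "relapse_only".
    """
    if gene not in matrix.genes:
        raise ValueError(f"gene {gene!r} not in panel")
    if event_mode not in ("relapse_or_death", "relapse_only"):
        raise ValueError(f"unknown event_mode {event_mode!r}")
    clin = {p.patient_id: p for p in clinical}
    dropped = [pid for pid in matrix.patients if pid not in clin]
    mutated, wildtype = [], []
    for pid in matrix.patients:
        p = clin.get(pid)
        if p is None:
            continue
        event = p.relapse or (p.death and event_mode == "relapse_or_death")
        is_mut = bool(matrix.indicator.loc[pid, gene])
        rec = SurvivalRecord(
            patient_id=pid,
            time_months=p.followup_months,
            event=event,
            group=f"{gene} mutated" if is_mut else "wild type",
        )
        (mutated if is_mut else wildtype).append(rec)
    out: dict = {"gene": gene, "dropped_patients": dropped,
                 "n_mutated": len(mutated), "n_wildtype": len(wildtype)}
    if mutated:
        out["km_mutated"] = km_estimate(mutated)
    if wildtype:
        out["km_wildtype"] = km_estimate(wildtype)
    if mutated and wildtype and any(r.event for r in mutated + wildtype):
        stat, p = logrank_test(mutated, wildtype)
        out["logrank_chi2"] = stat
        out["logrank_p"] = p
    return out


def write_km_table(estimates: Iterable[KMEstimate], path: str | Path) -> None:
    """KM curves as TSV: group, time, at-risk, events, survival, SE."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(["group", "time_months", "at_risk", "n_events",
                         "survival", "greenwood_se"])
        for est in estimates:
            for t, n, d, s, se in zip(est.event_times, est.at_risk,
                                      est.n_events, est.survival,
                                      est.greenwood_se):
                writer.writerow([est.group, f"{t:g}", int(n), int(d),
                                 f"{s:.6g}", f"{se:.6g}"])
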