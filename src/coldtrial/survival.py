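"""Time-to-event and response endpoints.

Kaplan-Meier product-limit estimation with Greenwood variance, medians
and milestone rates with log(-log)-transformed pointwise bands,
best-overall-response tallies, duration of response, and the
growth-modulation index (ratio of current-line to prior-line PFS).

Times are in months throughout; ``MONTH_DAYS = 365 / 12`` fixes the
months-to-days conversion used for the "disease control >= 6 months"
count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy import stats

from .design import TrialState, ValidationError

__all__ = [
    "SurvivalRecord",
    "KMCurve",
    "MedianEstimate",
    "MilestoneEstimate",
    "ResponseRecord",
    "ResponseSummary",
    "GMIRecord",
    "GMISummary",
    "km_fit",
    "km_median",
    "milestone",
    "summarize_response",
    "duration_of_response",
    "gmi_compute",
    "round_half_up",
]

MONTH_DAYS = 365.0 / 12.0
Z95 = stats.norm.ppf(0.975)


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero (reporting convention)."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class SurvivalRecord:
    """One right-censored time-to-event observation (months)."""

    patient_id: str
    time: float
    event: bool
    endpoint: str = "PFS"

    def __post_init__(self) -> None:
        if not math.isfinite(self.time) or self.time < 0:
            raise ValidationError(
                f"time must be finite and >= 0, got {self.time} "
                f"for patient {self.patient_id}"
            )
        if self.endpoint not in ("PFS", "OS", "DOR"):
            raise ValidationError(f"unknown endpoint {self.endpoint!r}")


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate at the distinct event times.

    ``survival[i]`` is S(t) just after ``event_times[i]``;
    ``greenwood_se`` is the Greenwood standard error of S at that time.
    """

    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    greenwood_se: np.ndarray
    n_total: int
    endpoint: str = "PFS"
    max_follow_up: float = 0.0

    def survival_at(self, t: float) -> float:
        """Step-function value S(t), right-continuous."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def _loglog_se_at(self, idx: int) -> float:
        s = self.survival[idx]
        if s <= 0.0 or s >= 1.0:
            return float("nan")
        # variance of log(-log S) by the delta method on Greenwood
        return float(self.greenwood_se[idx] / (abs(math.log(s)) * s))

    def ci_at(self, t: float, level: float = 0.95) -> tuple[float, float]:
        """Pointwise log(-log)-transformed confidence band at time t."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        if idx < 0:
            return (1.0, 1.0)
        s = float(self.survival[idx])
        if s in (0.0, 1.0):
            return (s, s)
        z = stats.norm.ppf(0.5 + level / 2.0)
        se_ll = self._loglog_se_at(idx)
        theta = math.exp(z * se_ll)
        return (s ** theta, s ** (1.0 / theta))


def km_fit(records: Sequence[SurvivalRecord]) -> KMCurve:
    """Fit the Kaplan-Meier product-limit estimator.

    Ties between events and censorings at the same time are resolved
    events-first (the censored subject is still at risk at that time).
    """
    if len(records) == 0:
        raise ValidationError("cannot fit a survival curve to zero records")
    endpoints = {r.endpoint for r in records}
    if len(endpoints) > 1:
        raise ValidationError(f"mixed endpoints in one fit: {sorted(endpoints)}")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=bool)

    order = np.argsort(times, kind="stable")
    times, events = times[order], events[order]
    n = len(times)

    uniq_event_times = np.unique(times[events])
    survival = np.empty(len(uniq_event_times))
    at_risk = np.empty(len(uniq_event_times), dtype=int)
    n_events = np.empty(len(uniq_event_times), dtype=int)
    se = np.empty(len(uniq_event_times))

    s = 1.0
    greenwood_sum = 0.0
    for i, t in enumerate(uniq_event_times):
        # events-first tie rule: at risk = everyone with time >= t
        n_i = int(np.sum(times >= t))
        d_i = int(np.sum(events & (times == t)))
        s *= 1.0 - d_i / n_i
        if n_i > d_i:
            greenwood_sum += d_i / (n_i * (n_i - d_i))
            se[i] = s * math.sqrt(greenwood_sum)
        else:
            se[i] = 0.0  # curve hits zero; variance degenerate
        survival[i] = s
        at_risk[i] = n_i
        n_events[i] = d_i

    return KMCurve(
        event_times=uniq_event_times,
        survival=survival,
        at_risk=at_risk,
        n_events=n_events,
        greenwood_se=se,
        n_total=n,
        endpoint=records[0].endpoint,
        max_follow_up=float(times.max()),
    )


@dataclass(frozen=True)
class MedianEstimate:
    """Median survival with 95% CI; ``None`` encodes "not reached"."""

    median: Optional[float]
    ci_low: Optional[float]
    ci_high: Optional[float]
    not_reached: bool = False


def _first_crossing(times: np.ndarray, values: np.ndarray, level: float) -> Optional[float]:
    below = values <= level
    if not below.any():
        return None
    return float(times[int(np.argmax(below))])


def km_median(curve: KMCurve, ci_method: str = "loglog") -> MedianEstimate:
    """Median survival time and its 95% CI.

    The median is the smallest event time with S(t) <= 0.5.  The CI is
    obtained by intersecting the pointwise 95% band with the 0.5 line
    (lower bound from the lower band, upper bound from the upper band);
    a band that never drops to 0.5 yields a "not reached" bound.
    """
    if ci_method not in ("loglog", "linear"):
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    t = curve.event_times
    s = curve.survival
    med = _first_crossing(t, s, 0.5)
    if ci_method == "loglog":
        bands = np.array([curve.ci_at(ti) for ti in t])
        lcl, ucl = bands[:, 0] if len(t) else np.array([]), bands[:, 1] if len(t) else np.array([])
    else:
        half = Z95 * curve.greenwood_se
        lcl, ucl = np.clip(s - half, 0, 1), np.clip(s + half, 0, 1)
    lo = _first_crossing(t, lcl, 0.5) if len(t) else None
    hi = _first_crossing(t, ucl, 0.5) if len(t) else None
    return MedianEstimate(
        median=med, ci_low=lo, ci_high=hi, not_reached=med is None
    )


@dataclass(frozen=True)
class MilestoneEstimate:
    estimate: float
    ci_low: float
    ci_high: float
    time: float
    truncated: bool = False  # t beyond the last follow-up


def milestone(curve: KMCurve, t: float, ci_method: str = "loglog") -> MilestoneEstimate:
    """Survival probability at a landmark time with pointwise 95% CI."""
    if t < 0:
        raise ValidationError(f"milestone time must be >= 0, got {t}")
    s = curve.survival_at(t)
    if ci_method == "loglog":
        lo, hi = curve.ci_at(t)
    elif ci_method == "linear":
        idx = np.searchsorted(curve.event_times, t, side="right") - 1
        se = 0.0 if idx < 0 else float(curve.greenwood_se[idx])
        lo, hi = max(0.0, s - Z95 * se), min(1.0, s + Z95 * se)
    else:
        raise ValidationError(f"unknown ci_method {ci_method!r}")
    return MilestoneEstimate(
        estimate=s,
        ci_low=lo,
        ci_high=hi,
        time=t,
        truncated=t > curve.max_follow_up,
    )


# ---------------------------------------------------------------------------
# response endpoints
# ---------------------------------------------------------------------------

BOR_CATEGORIES = ("CR", "PR", "SD", "PD", "NE")


@dataclass(frozen=True)
class ResponseRecord:
    patient_id: str
    best_overall_response: str
    progression_or_censor_time: float
    progressed: bool
    response_onset_time: Optional[float] = None

    def __post_init__(self) -> None:
        if self.best_overall_response not in BOR_CATEGORIES:
            raise ValidationError(
                f"best_overall_response must be one of {BOR_CATEGORIES}, "
                f"got {self.best_overall_response!r}"
            )
        is_responder = self.best_overall_response in ("CR", "PR")
        if is_responder and self.response_onset_time is None:
            raise ValidationError(
                f"responder {self.patient_id} lacks a response onset time"
            )
        if not is_responder and self.response_onset_time is not None:
            raise ValidationError(
                f"non-responder {self.patient_id} carries an onset time"
            )


@dataclass(frozen=True)
class ResponseSummary:
    counts: dict[str, int]
    rates: dict[str, float]
    n_evaluable: int
    n_responders: int
    orr: Optional[float]
    orr_undefined: bool
    disease_control_6mo: int
    trial_state: Optional[TrialState]


def summarize_response(records: Sequence[ResponseRecord]) -> ResponseSummary:
    """Tally best-overall-response categories.

    Evaluable = records with a determinate category (not NE); ORR is
    (CR + PR) / evaluable.  "Disease control >= 6 months" counts
    patients with CR/PR/SD and at least 6 months (182.5 days) on study
    without progression.
    """
    counts = {c: 0 for c in BOR_CATEGORIES}
    for r in records:
        counts[r.best_overall_response] += 1
    n_eval = sum(counts[c] for c in ("CR", "PR", "SD", "PD"))
    n_resp = counts["CR"] + counts["PR"]
    orr = n_resp / n_eval if n_eval else None
    rates = {
        c: (counts[c] / n_eval if n_eval else 0.0)
        for c in ("CR", "PR", "SD", "PD")
    }
    dc6 = sum(
        1
        for r in records
        if r.best_overall_response in ("CR", "PR", "SD")
        and (r.progression_or_censor_time * MONTH_DAYS) >= 182.5
    )
    return ResponseSummary(
        counts=counts,
        rates=rates,
        n_evaluable=n_eval,
        n_responders=n_resp,
        orr=orr,
        orr_undefined=n_eval == 0,
        disease_control_6mo=dc6,
        trial_state=TrialState(n_eval, n_resp) if n_eval else None,
    )


def duration_of_response(
    records: Sequence[ResponseRecord],
) -> tuple[list[SurvivalRecord], MedianEstimate]:
    """Duration of response among responders: onset to progression or
    censoring.  Returns the derived records and the KM median (flagged
    undefined when there are no responders)."""
    responders = [r for r in records if r.best_overall_response in ("CR", "PR")]
    out: list[SurvivalRecord] = []
    for r in responders:
        if r.response_onset_time is None:  # unreachable via the dataclass
            raise ValidationError(f"responder {r.patient_id} lacks onset time")
        dur = r.progression_or_censor_time - r.response_onset_time
        if dur < 0:
            raise ValidationError(
                f"negative duration of response for {r.patient_id}"
            )
        out.append(
            SurvivalRecord(
                patient_id=r.patient_id, time=dur, event=r.progressed, endpoint="DOR"
            )
        )
    if not out:
        return [], MedianEstimate(None, None, None, not_reached=True)
    return out, km_median(km_fit(out))


# ---------------------------------------------------------------------------
# growth-modulation index
# ---------------------------------------------------------------------------

GMI_THRESHOLD = 1.33


@dataclass(frozen=True)
class GMIRecord:
    patient_id: str
    pfs_current: float
    pfs_prior: float
    pfs_current_censored: bool = False

    def __post_init__(self) -> None:
        if self.pfs_prior <= 0:
            raise ValidationError(
                f"prior-line PFS must be > 0, got {self.pfs_prior} "
                f"for patient {self.patient_id}"
            )
        if self.pfs_current <= 0:
            raise ValidationError(
                f"current-line PFS must be > 0, got {self.pfs_current} "
                f"for patient {self.patient_id}"
            )

    @property
    def gmi(self) -> float:
        return self.pfs_current / self.pfs_prior


@dataclass(frozen=True)
class GMISummary:
    gmis: dict[str, float]
    n: int
    median_gmi: float
    n_at_threshold: int
    fraction_at_threshold: float
    percent_at_threshold: float
    threshold: float = GMI_THRESHOLD
    n_censored_included: int = 0


def gmi_compute(
    records: Sequence[GMIRecord],
    threshold: float = GMI_THRESHOLD,
    include_censored: bool = True,
) -> GMISummary:
    """Per-patient GMI with the fraction at or above ``threshold``
    (inclusive comparison), as a percentage rounded half-up to one
    decimal.

    Pairs whose current-line PFS is censored are included with the
    observed censored time by default; ``include_censored=False``
    restricts to pairs with observed progression (sensitivity analysis).
    """
    kept = [
        r for r in records if include_censored or not r.pfs_current_censored
    ]
    if not kept:
        raise ValidationError("no GMI pairs after censoring filter")
    gmis = {r.patient_id: r.gmi for r in kept}
    vals = np.array(list(gmis.values()))
    n_hit = int(np.sum(vals >= threshold))
    frac = n_hit / len(vals)
    return GMISummary(
        gmis=gmis,
        n=len(vals),
        median_gmi=float(np.median(vals)),
        n_at_threshold=n_hit,
        fraction_at_threshold=frac,
        percent_at_threshold=round_half_up(100.0 * frac, 1),
        threshold=threshold,
        n_censored_included=sum(1 for r in kept if r.pfs_current_censored),
    )
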