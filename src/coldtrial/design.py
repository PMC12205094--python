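"""Beta-binomial Bayesian adaptive monitoring for a single-arm phase-II trial.

The design places a conjugate Beta prior on the response probability and
re-examines the accumulating responder count at scheduled interim looks.
Two stopping events are monitored:

* **futility** — the response rate is at or below ``p_futility``;
* **efficacy** — the response rate is at or above ``p_efficacy``.

Each event can be evaluated under two interpretations of the monitoring
rule, selected by ``TrialDesign.rule_interpretation``:

``posterior``
    the event probability is the posterior probability of the parameter
    event given the data observed so far (the literal event reading);
``predictive``
    the event probability is the predictive probability, marginalised
    over all future enrolments up to ``n_max``, that the *final* posterior
    would declare the event with probability at least the decision
    threshold (the textbook predictive-probability design).

A Monte-Carlo engine simulates whole trials under either rule and
summarises operating characteristics over a grid of true response rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
from scipy import optimize, stats

__all__ = [
    "ValidationError",
    "TrialDesign",
    "TrialState",
    "PosteriorSummary",
    "InterimDecision",
    "TrialTrajectory",
    "OperatingCharacteristics",
    "update_posterior",
    "posterior_tail_prob",
    "predictive_prob_success",
    "predictive_prob_event",
    "interim_decision",
    "interim_schedule",
    "simulate_trial",
    "operating_characteristics",
]


class ValidationError(ValueError):
    """Raised when an input violates a domain-type invariant."""


RuleInterpretation = Literal["posterior", "predictive"]


@dataclass(frozen=True)
class TrialDesign:
    """All constants of the adaptive monitoring scheme.

    Defaults reproduce the published scheme: uniform Beta(1, 1) prior,
    futility boundary at a 10% response rate, efficacy boundary at 25%,
    both with an 80% decision threshold, a first look after 10 evaluable
    patients then every 5 up to a maximum of 50, with a 16-week
    evaluability window.
    """

    prior_alpha: float = 1.0
    prior_beta: float = 1.0
    p_futility: float = 0.10
    p_efficacy: float = 0.25
    threshold_futility: float = 0.80
    threshold_efficacy: float = 0.80
    n_first_interim: int = 10
    cohort_step: int = 5
    n_max: int = 50
    evaluation_window_weeks: float = 16.0
    rule_interpretation: RuleInterpretation = "posterior"

    def __post_init__(self) -> None:
        if not (self.prior_alpha > 0 and self.prior_beta > 0):
            raise ValidationError("prior pseudo-counts must be positive")
        if not (0 < self.p_futility < self.p_efficacy < 1):
            raise ValidationError(
                "need 0 < p_futility < p_efficacy < 1, got "
                f"({self.p_futility}, {self.p_efficacy})"
            )
        for name in ("threshold_futility", "threshold_efficacy"):
            t = getattr(self, name)
            if not (0.5 <= t < 1):
                raise ValidationError(f"{name} must lie in [0.5, 1), got {t}")
        if not (0 < self.n_first_interim <= self.n_max):
            raise ValidationError("need 0 < n_first_interim <= n_max")
        if self.cohort_step < 1:
            raise ValidationError("cohort_step must be >= 1")
        if self.evaluation_window_weeks < 0:
            raise ValidationError("evaluation_window_weeks must be >= 0")
        if self.rule_interpretation not in ("posterior", "predictive"):
            raise ValidationError(
                f"unknown rule_interpretation {self.rule_interpretation!r}"
            )


@dataclass(frozen=True)
class TrialState:
    """Accumulated evaluable patients and responders."""

    n_evaluable: int
    n_responders: int

    def __post_init__(self) -> None:
        if self.n_evaluable < 0 or self.n_responders < 0:
            raise ValidationError("counts must be non-negative")
        if self.n_responders > self.n_evaluable:
            raise ValidationError(
                f"responders ({self.n_responders}) exceed evaluable "
                f"({self.n_evaluable})"
            )


@dataclass(frozen=True)
class PosteriorSummary:
    """Conjugate beta posterior with mean and credible interval."""

    alpha_post: float
    beta_post: float
    mean: float
    ci_low: float
    ci_high: float
    ci_level: float = 0.95

    def tail_prob(self, threshold: float, direction: str) -> float:
        return posterior_tail_prob(self, threshold, direction)


@dataclass(frozen=True)
class InterimDecision:
    """Outcome of one interim look."""

    action: Literal["continue", "stop_futility", "stop_efficacy"]
    prob_futility_event: float
    prob_efficacy_event: float
    interim_n: int


@dataclass(frozen=True)
class TrialTrajectory:
    """One simulated trial: the per-look states and decisions."""

    looks: tuple[tuple[TrialState, InterimDecision], ...]
    final_action: str
    final_n: int
    responses: tuple[int, ...]


@dataclass(frozen=True)
class OperatingCharacteristics:
    true_orr: float
    n_sims: int
    prob_stop_futility: float
    prob_stop_efficacy: float
    prob_run_to_n_max: float
    expected_n: float
    stop_stage_distribution: dict[int, float] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# posterior machinery
# ---------------------------------------------------------------------------


def update_posterior(
    design: TrialDesign,
    state: TrialState,
    ci_level: float = 0.95,
    hpd: bool = False,
) -> PosteriorSummary:
    """Conjugate update of the beta prior with the observed counts.

    Parameters
    ----------
    design
        Supplies the prior pseudo-counts.
    state
        Observed ``(n_evaluable, n_responders)``.
    ci_level
        Credible level of the reported interval.
    hpd
        If true, report the highest-posterior-density interval instead of
        the default equal-tailed (``alpha/2``, ``1 - alpha/2``) quantiles.
    """
    if not (0 < ci_level < 1):
        raise ValidationError(f"ci_level must be in (0, 1), got {ci_level}")
    a = design.prior_alpha + state.n_responders
    b = design.prior_beta + (state.n_evaluable - state.n_responders)
    dist = stats.beta(a, b)
    if hpd:
        lo, hi = _hpd_interval(a, b, ci_level)
    else:
        tail = (1.0 - ci_level) / 2.0
        lo, hi = dist.ppf(tail), dist.ppf(1.0 - tail)
    return PosteriorSummary(
        alpha_post=a,
        beta_post=b,
        mean=a / (a + b),
        ci_low=float(lo),
        ci_high=float(hi),
        ci_level=ci_level,
    )


def _hpd_interval(a: float, b: float, level: float) -> tuple[float, float]:
    """Shortest interval of posterior mass ``level`` for a Beta(a, b)."""
    dist = stats.beta(a, b)
    # degenerate monotone densities: HPD abuts the support boundary
    if a <= 1 < b:
        return 0.0, float(dist.ppf(level))
    if b <= 1 < a:
        return float(dist.ppf(1.0 - level)), 1.0

    def width(lo_mass: float) -> float:
        return dist.ppf(lo_mass + level) - dist.ppf(lo_mass)

    res = optimize.minimize_scalar(
        width, bounds=(1e-12, 1.0 - level - 1e-12), method="bounded"
    )
    lo_mass = float(res.x)
    return float(dist.ppf(lo_mass)), float(dist.ppf(lo_mass + level))


def posterior_tail_prob(
    summary: PosteriorSummary, threshold: float, direction: str
) -> float:
    """``P(p <= threshold)`` (``at_most``) or ``P(p >= threshold)``
    (``at_least``) under the beta posterior."""
    if not (0 <= threshold <= 1):
        raise ValidationError(f"threshold must lie in [0, 1], got {threshold}")
    cdf = stats.beta.cdf(threshold, summary.alpha_post, summary.beta_post)
    if direction == "at_most":
        return float(cdf)
    if direction == "at_least":
        return float(1.0 - cdf)
    raise ValidationError(f"direction must be at_most/at_least, got {direction!r}")


# ---------------------------------------------------------------------------
# predictive probabilities
# ---------------------------------------------------------------------------


def _final_event_met(
    design: TrialDesign,
    r_final: int,
    p_threshold: float,
    direction: str,
    decision_threshold: float,
) -> bool:
    """Would the posterior at (n_max, r_final) declare the event?"""
    post = update_posterior(design, TrialState(design.n_max, r_final))
    return posterior_tail_prob(post, p_threshold, direction) >= decision_threshold


def predictive_prob_event(
    design: TrialDesign,
    state: TrialState,
    p_threshold: float,
    direction: str,
    decision_threshold: float,
) -> float:
    """Probability, under the beta-binomial predictive law for the
    ``m = n_max - n`` future patients, that the end-of-trial posterior
    declares the event ``{p <=/>= p_threshold}`` with posterior
    probability at least ``decision_threshold``.

    At ``n == n_max`` this degenerates to the 0/1 indicator of the final
    posterior criterion.
    """
    if state.n_evaluable > design.n_max:
        raise ValidationError("state exceeds the design's maximum sample size")
    n, r = state.n_evaluable, state.n_responders
    m = design.n_max - n
    a = design.prior_alpha + r
    b = design.prior_beta + (n - r)
    if m == 0:
        return float(
            _final_event_met(design, r, p_threshold, direction, decision_threshold)
        )
    k = np.arange(m + 1)
    pmf = stats.betabinom.pmf(k, m, a, b)
    met = np.array(
        [
            _final_event_met(
                design, r + int(ki), p_threshold, direction, decision_threshold
            )
            for ki in k
        ]
    )
    return float(pmf[met].sum())


def predictive_prob_success(design: TrialDesign, state: TrialState) -> float:
    """Predictive probability that the trial ends declaring efficacy,
    i.e. that the final posterior satisfies
    ``P(p >= p_efficacy) >= threshold_efficacy``."""
    return predictive_prob_event(
        design,
        state,
        design.p_efficacy,
        "at_least",
        design.threshold_efficacy,
    )


# ---------------------------------------------------------------------------
# interim decisions
# ---------------------------------------------------------------------------


def interim_decision(design: TrialDesign, state: TrialState) -> InterimDecision:
    """Evaluate both stopping events at the current state and decide.

    Futility is checked first: if its event probability reaches
    ``threshold_futility`` the trial stops for inefficacy regardless of
    the efficacy probability (conservative precedence; with the default
    thresholds both events cannot fire simultaneously for n >= 10).
    """
    if state.n_evaluable > design.n_max:
        raise ValidationError("state exceeds the design's maximum sample size")
    if design.rule_interpretation == "posterior":
        post = update_posterior(design, state)
        p_fut = posterior_tail_prob(post, design.p_futility, "at_most")
        p_eff = posterior_tail_prob(post, design.p_efficacy, "at_least")
    else:
        p_fut = predictive_prob_event(
            design, state, design.p_futility, "at_most", design.threshold_futility
        )
        p_eff = predictive_prob_event(
            design, state, design.p_efficacy, "at_least", design.threshold_efficacy
        )
    if p_fut >= design.threshold_futility:
        action = "stop_futility"
    elif p_eff >= design.threshold_efficacy:
        action = "stop_efficacy"
    else:
        action = "continue"
    return InterimDecision(
        action=action,
        prob_futility_event=p_fut,
        prob_efficacy_event=p_eff,
        interim_n=state.n_evaluable,
    )


def interim_schedule(design: TrialDesign) -> list[int]:
    """Scheduled interim sample sizes: first look, then every
    ``cohort_step`` patients, capped at and always including ``n_max``."""
    looks = list(range(design.n_first_interim, design.n_max + 1, design.cohort_step))
    if looks[-1] != design.n_max:
        looks.append(design.n_max)
    return looks


def decision_table(design: TrialDesign) -> dict[int, list[str]]:
    """Action for every (scheduled n, responder count r) pair.

    Precomputing the table makes trial simulation a pure lookup; it also
    exposes the monotone structure of the rule (low r stops for
    futility, high r for efficacy) for testing.
    """
    table: dict[int, list[str]] = {}
    for n in interim_schedule(design):
        table[n] = [
            interim_decision(design, TrialState(n, r)).action for r in range(n + 1)
        ]
    return table


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------


def simulate_trial(
    design: TrialDesign, true_orr: float, seed: int
) -> TrialTrajectory:
    """Simulate one trial: i.i.d. Bernoulli(true_orr) responses examined
    at each scheduled look until a stop fires or ``n_max`` is reached."""
    if not (0 <= true_orr <= 1):
        raise ValidationError(f"true_orr must lie in [0, 1], got {true_orr}")
    rng = np.random.default_rng(seed)
    responses = (rng.random(design.n_max) < true_orr).astype(int)
    looks: list[tuple[TrialState, InterimDecision]] = []
    final_action = "continue"
    final_n = design.n_max
    for n in interim_schedule(design):
        state = TrialState(n, int(responses[:n].sum()))
        decision = interim_decision(design, state)
        looks.append((state, decision))
        if decision.action != "continue":
            final_action = decision.action
            final_n = n
            break
    else:
        final_action = looks[-1][1].action if looks else "continue"
        final_n = design.n_max
    return TrialTrajectory(
        looks=tuple(looks),
        final_action=final_action,
        final_n=final_n,
        responses=tuple(int(x) for x in responses[:final_n]),
    )


def operating_characteristics(
    design: TrialDesign,
    orr_grid: Sequence[float],
    n_sims: int,
    seed: int,
) -> list[OperatingCharacteristics]:
    """Monte-Carlo operating characteristics over a grid of true ORRs.

    Each simulated trial gets its own counter-based seed (``seed`` +
    running index) so results are reproducible and independent of
    execution order.  Decisions are served from a precomputed lookup
    table, so the cost per trial is O(number of looks).
    """
    if n_sims < 1:
        raise ValidationError("n_sims must be >= 1")
    table = decision_table(design)
    schedule = interim_schedule(design)
    out: list[OperatingCharacteristics] = []
    counter = 0
    for true_orr in orr_grid:
        if not (0 <= true_orr <= 1):
            raise ValidationError(f"true_orr must lie in [0, 1], got {true_orr}")
        n_fut = n_eff = n_full = 0
        total_n = 0
        stage_counts: dict[int, int] = {n: 0 for n in schedule}
        for _ in range(n_sims):
            rng = np.random.default_rng(seed + counter)
            counter += 1
            responses = rng.random(design.n_max) < true_orr
            cum = np.cumsum(responses)
            action = "continue"
            stop_n = design.n_max
            for n in schedule:
                action = table[n][int(cum[n - 1])]
                if action != "continue":
                    stop_n = n
                    break
            if action == "stop_futility":
                n_fut += 1
            elif action == "stop_efficacy":
                n_eff += 1
            else:
                n_full += 1
                stop_n = design.n_max
            total_n += stop_n
            stage_counts[stop_n] += 1
        out.append(
            OperatingCharacteristics(
                true_orr=float(true_orr),
                n_sims=n_sims,
                prob_stop_futility=n_fut / n_sims,
                prob_stop_efficacy=n_eff / n_sims,
                prob_run_to_n_max=n_full / n_sims,
                expected_n=total_n / n_sims,
                stop_stage_distribution={
                    n: c / n_sims for n, c in stage_counts.items() if c
                },
            )
        )
    return out
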