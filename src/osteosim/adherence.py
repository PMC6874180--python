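"""Persistence/adherence curves and effective treatment efficacy.

Trial relative risks are attenuated for real-world adherence assuming a
linear relationship between relative risk reduction and adherence:
with community adherence a and trial-reference adherence 0.80, the
community RR is 1 - (a/0.80) * (1 - RR_trial), with the scaling factor
capped at 1 so above-trial adherence cannot amplify efficacy.

Persistence and adherence are observed at 12 and 24 months; both
decline linearly on the 12->24-month slope out to 60 months (clamped at
0) and stay flat afterwards.  Each individual's discontinuation time is
drawn once at treatment start by inverting the persistence curve.

After stopping, protection fades linearly back to no effect over a
washout window proportional to the fraction of the planned course
completed (offset effect): 10 years after a full 10-year alendronate
course, 1 year after a full 2-year teriparatide course.
"""

from __future__ import annotations

import math

from .parameters import AdherenceSchedule

#: month at which the linear persistence/adherence extrapolation stops
_EXTENSION_END_MONTHS = 60.0


def persistence_at(schedule: AdherenceSchedule, months: float) -> float:
    """Fraction still on therapy at a given month since initiation.

    Piecewise linear through (0, 1), (12, p12), (24, p24); the
    12->24-month slope extends to month 60, clamped at 0; constant
    thereafter.
    """
    if months < 0:
        raise ValueError("months must be >= 0")
    p12, p24 = schedule.persistence_12m, schedule.persistence_24m
    m = min(months, _EXTENSION_END_MONTHS)
    if m <= 12.0:
        value = 1.0 + (p12 - 1.0) * m / 12.0
    else:
        value = p12 + (p24 - p12) * (m - 12.0) / 12.0
    return max(0.0, value)


def adherence_at(schedule: AdherenceSchedule, year_index: int) -> float:
    """Adherence applying to the given treatment year (1-based).

    Year 1 and 2 take the observed 12- and 24-month values; years 3-5
    continue the linear decline (clamped at 0); from year 6 onward the
    year-5 value applies.
    """
    if year_index < 1:
        raise ValueError("year_index must be >= 1")
    a12, a24 = schedule.adherence_12m, schedule.adherence_24m
    y = min(year_index, 5)
    value = a12 + (a24 - a12) * (y - 1)
    return min(1.0, max(0.0, value))


def efficacy_scaling_factor(adherence_community: float,
                            adherence_trial: float = 0.80) -> float:
    """Fraction of the trial risk reduction realised in the community."""
    if adherence_trial <= 0:
        raise ValueError("trial adherence must be > 0")
    if adherence_community < 0:
        raise ValueError("community adherence must be >= 0")
    return min(1.0, adherence_community / adherence_trial)


def community_rr(rr_trial: float, factor: float) -> float:
    """Community relative risk: 1 - factor * (1 - RR_trial)."""
    if rr_trial <= 0:
        raise ValueError("rr_trial must be > 0")
    if not (0.0 <= factor <= 1.0):
        raise ValueError("factor must be in [0, 1]")
    return 1.0 - factor * (1.0 - rr_trial)


def offset_rr(rr_at_stop: float, years_since_stop: float,
              washout_years: float) -> float:
    """Relative risk during washout: linear return from rr_at_stop to 1."""
    if years_since_stop < 0 or washout_years < 0:
        raise ValueError("times must be >= 0")
    if washout_years == 0 or years_since_stop >= washout_years:
        return 1.0
    frac = years_since_stop / washout_years
    return rr_at_stop + (1.0 - rr_at_stop) * frac


def effective_washout_years(planned_washout: float, years_completed: float,
                            planned_duration: float) -> float:
    """Washout window prorated by the fraction of the course completed."""
    if planned_duration <= 0:
        raise ValueError("planned_duration must be > 0")
    if not (0 <= years_completed <= planned_duration):
        raise ValueError("years_completed must be in [0, planned_duration]")
    return planned_washout * years_completed / planned_duration


def sample_discontinuation(schedule: AdherenceSchedule,
                           planned_duration_years: int,
                           u: float) -> float | None:
    """Invert the persistence curve at uniform draw ``u``.

    Returns the discontinuation month, or ``None`` if the individual
    persists through the full planned course.  The individual persists
    past month m exactly when u <= S(m), where S is the persistence
    curve from :func:`persistence_at`.
    """
    if not (0.0 <= u <= 1.0):
        raise ValueError("u must be in [0, 1]")
    end = min(12.0 * planned_duration_years, _EXTENSION_END_MONTHS)
    # survival at the course end: persists through full course
    if u <= persistence_at(schedule, 12.0 * planned_duration_years):
        return None
    p12, p24 = schedule.persistence_12m, schedule.persistence_24m
    if u > p12:
        # within the first year: S(m) = 1 + (p12 - 1) m / 12
        if p12 >= 1.0:
            return None
        return 12.0 * (1.0 - u) / (1.0 - p12)
    # beyond month 12 on the (p24 - p12) slope
    slope = p24 - p12  # per 12 months
    if slope >= 0.0:
        # flat persistence beyond 12 months: curve never crosses u < p12
        return None
    m = 12.0 + 12.0 * (u - p12) / slope
    return min(m, end)


def years_fully_persisted(months: float | None,
                          planned_duration_years: int) -> int:
    """Whole treatment years completed before discontinuation."""
    if months is None:
        return planned_duration_years
    return min(planned_duration_years, int(math.floor(months / 12.0)))
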