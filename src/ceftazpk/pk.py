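"""Closed-form one-compartment kinetics under sequences of zero-order infusions.

Ceftazidime disposition in critically ill adults is well described by a
one-compartment model with first-order elimination (rate constant
``k = CL/V``).  Every dosing event is a zero-order input: a constant-rate
infusion of ``amount`` mg over ``duration`` h, with ``duration = 0`` taken as
the instantaneous-bolus limit.  Because the model is linear, the
concentration under an arbitrary regimen is the superposition of
single-event solutions:

* during an infusion of rate ``R0`` started at ``t0``::

      C(t) = R0/CL * (1 - exp(-k*(t - t0)))

* after it ends at ``t0 + D``::

      C(t) = R0/CL * (1 - exp(-k*D)) * exp(-k*(t - t0 - D))

* a bolus contributes ``amount/V * exp(-k*(t - t0))``.

An infusion with ``duration = math.inf`` models an open-ended maintenance
infusion (continuous infusion with no scheduled stop).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "DoseEvent",
    "Regimen",
    "IndividualParameters",
    "NEVER",
    "concentration",
    "concentration_matrix",
    "half_life",
    "steady_state_concentration",
    "time_to_threshold",
]

#: Sentinel returned by :func:`time_to_threshold` when the threshold is never
#: attained.  ``math.inf`` so that medians over populations naturally treat
#: never-reachers as right-censored beyond any horizon.
NEVER = math.inf


@dataclass(frozen=True)
class DoseEvent:
    """One zero-order input: ``amount`` mg infused over ``duration`` h.

    ``duration = 0`` is an instantaneous bolus; ``duration = math.inf`` an
    open-ended constant-rate infusion.
    """

    start_time: float  # h
    amount: float  # mg; for open-ended events interpreted as mg per hour*inf -> use rate
    duration: float  # h
    rate: float | None = None  # mg/h, required (and only allowed) when duration is inf

    def __post_init__(self) -> None:
        if self.start_time < 0:
            raise ValueError(f"start_time must be >= 0, got {self.start_time}")
        if self.duration < 0:
            raise ValueError(f"duration must be >= 0, got {self.duration}")
        if math.isinf(self.duration):
            if self.rate is None or self.rate <= 0:
                raise ValueError("open-ended infusion requires a positive rate")
        else:
            if self.rate is not None:
                raise ValueError("rate is only meaningful for open-ended infusions")
            if not self.amount > 0:
                raise ValueError(f"amount must be > 0, got {self.amount}")

    @property
    def infusion_rate(self) -> float:
        """mg/h during the event; undefined (returns inf) for a bolus."""
        if math.isinf(self.duration):
            return float(self.rate)  # type: ignore[arg-type]
        if self.duration == 0:
            return math.inf
        return self.amount / self.duration

    @property
    def end_time(self) -> float:
        return self.start_time + self.duration


@dataclass(frozen=True)
class Regimen:
    """An ordered dosing schedule; overlapping infusions are allowed (rates add)."""

    events: tuple[DoseEvent, ...]

    def __init__(self, events: Sequence[DoseEvent]):
        object.__setattr__(self, "events", tuple(sorted(events, key=lambda e: e.start_time)))

    def __len__(self) -> int:
        return len(self.events)

    def scaled(self, factor: float) -> "Regimen":
        """Regimen with every amount (and open-ended rate) multiplied by ``factor``."""
        out = []
        for e in self.events:
            if math.isinf(e.duration):
                out.append(DoseEvent(e.start_time, e.amount, e.duration, rate=e.rate * factor))
            else:
                out.append(DoseEvent(e.start_time, e.amount * factor, e.duration))
        return Regimen(out)

    def asymptotic_rate(self) -> float:
        """Total mg/h delivered as t -> inf (open-ended infusions only)."""
        return sum(e.rate for e in self.events if math.isinf(e.duration) and e.rate)

    @staticmethod
    def loading_plus_continuous(
        loading_mg: float,
        daily_mg: float,
        ld_duration_h: float = 0.5,
        ci_start: float | None = None,
        ci_duration_h: float = math.inf,
    ) -> "Regimen":
        """Loading dose then constant-rate continuous infusion.

        The loading dose is given as a short zero-order infusion
        (``ld_duration_h`` defaults to 0.5 h, usual cephalosporin practice);
        the maintenance infusion starts when it ends unless ``ci_start`` is
        given, runs at ``daily_mg/24`` mg/h, and is open-ended by default.
        """
        events = []
        if loading_mg > 0:
            events.append(DoseEvent(0.0, loading_mg, ld_duration_h))
        start = ld_duration_h if ci_start is None else ci_start
        rate = daily_mg / 24.0
        if daily_mg > 0:
            if math.isinf(ci_duration_h):
                events.append(DoseEvent(start, math.inf, math.inf, rate=rate))
            else:
                events.append(DoseEvent(start, rate * ci_duration_h, ci_duration_h))
        return Regimen(events)


@dataclass(frozen=True)
class IndividualParameters:
    """Realized clearance (L/h) and apparent volume of distribution (L)."""

    CL: float
    V: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.CL) and self.CL > 0):
            raise ValueError(f"CL must be positive and finite, got {self.CL}")
        if not (math.isfinite(self.V) and self.V > 0):
            raise ValueError(f"V must be positive and finite, got {self.V}")


def _event_concentration(
    event: DoseEvent, k: np.ndarray, CL: np.ndarray, V: np.ndarray, t: np.ndarray
) -> np.ndarray:
    """Contribution of one event, broadcasting over parameter arrays and times."""
    rel = t - event.start_time
    active = rel > 0
    c = np.zeros(np.broadcast_shapes(k.shape, t.shape))
    if event.duration == 0:
        c = np.where(rel >= 0, (event.amount / V) * np.exp(-k * np.maximum(rel, 0.0)), 0.0)
        return c
    rate = event.rate if math.isinf(event.duration) else event.amount / event.duration
    during = active & (rel <= event.duration)
    after = rel > event.duration
    css = rate / CL
    c = np.where(during, css * (-np.expm1(-k * np.maximum(rel, 0.0))), c)
    if not math.isinf(event.duration):
        tail = css * (-np.expm1(-k * event.duration)) * np.exp(-k * np.maximum(rel - event.duration, 0.0))
        c = np.where(after, tail, c)
    return c


def concentration(
    regimen: Regimen, params: IndividualParameters, times: Sequence[float] | np.ndarray
) -> np.ndarray:
    """Plasma concentration (mg/L) at each time (h) under ``regimen``.

    Times must be nonnegative and nondecreasing.  The result is nonnegative,
    continuous in time and linear in every event amount.
    """
    t = np.asarray(times, dtype=float)
    if t.size and (t < 0).any():
        raise ValueError("times must be nonnegative")
    if t.size > 1 and (np.diff(t) < 0).any():
        raise ValueError("times must be nondecreasing")
    k = np.asarray(params.CL / params.V)
    CL = np.asarray(float(params.CL))
    V = np.asarray(float(params.V))
    total = np.zeros_like(t)
    for event in regimen.events:
        total = total + _event_concentration(event, k, CL, V, t)
    return total


def concentration_matrix(
    regimen: Regimen, CL: np.ndarray, V: np.ndarray, times: np.ndarray
) -> np.ndarray:
    """Vectorized concentration for many subjects under one regimen.

    ``CL`` and ``V`` are 1-D arrays of length n; returns an (n, m) matrix for
    the m grid times.  Used by the Monte Carlo regimen simulator.
    """
    CL = np.asarray(CL, dtype=float)[:, None]
    V = np.asarray(V, dtype=float)[:, None]
    t = np.asarray(times, dtype=float)[None, :]
    k = CL / V
    total = np.zeros((CL.shape[0], t.shape[1]))
    for event in regimen.events:
        total = total + _event_concentration(event, k, CL, V, t)
    return total


def half_life(params: IndividualParameters) -> float:
    """Elimination half-life, ln(2) * V / CL, in hours."""
    return math.log(2.0) * params.V / params.CL


def steady_state_concentration(rate: float, CL: float) -> float:
    """Css = rate/CL for a constant-rate infusion (mg/L)."""
    if rate < 0:
        raise ValueError("rate must be >= 0")
    if CL <= 0:
        raise ValueError("CL must be > 0")
    return rate / CL


def time_to_threshold(
    regimen: Regimen,
    params: IndividualParameters,
    threshold: float,
    grid_step: float = 0.1,
    horizon: float = 72.0,
    tol: float = 0.01,
) -> float:
    """First time (h) at which C(t) >= threshold, or :data:`NEVER`.

    The profile is scanned on a uniform grid of ``grid_step`` h over
    ``[0, horizon]`` and the bracketing interval refined by bisection to
    ``tol`` h, so the answer does not depend on the grid.  If the threshold is
    not attained on the horizon, the search is extended (doubling the
    horizon) as long as the asymptotic steady-state concentration of the
    open-ended infusions exceeds the threshold; otherwise :data:`NEVER`.
    """
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    if len(regimen) == 0:
        raise ValueError("regimen must contain at least one dose event")

    css = regimen.asymptotic_rate() / params.CL

    lo, hi = 0.0, float(horizon)
    for _ in range(32):
        t = np.arange(lo, hi + grid_step, grid_step)
        c = concentration(regimen, params, t)
        above = c >= threshold
        if above.any():
            i = int(np.argmax(above))
            if i == 0 and lo == 0.0:
                return 0.0
            return _bisect_crossing(regimen, params, threshold, t[i - 1] if i > 0 else lo - grid_step, t[i], tol)
        # not attained on this window: extend only if still approaching a
        # sufficient steady state
        if css < threshold or hi > 1e6:
            return NEVER
        lo, hi = hi, hi * 2.0
    return NEVER


def _bisect_crossing(
    regimen: Regimen,
    params: IndividualParameters,
    threshold: float,
    lo: float,
    hi: float,
    tol: float,
) -> float:
    lo = max(lo, 0.0)
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if concentration(regimen, params, [mid])[0] >= threshold:
            hi = mid
        else:
            lo = mid
    return hi
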