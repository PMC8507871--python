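"""Time-dependent linear-quadratic radiosensitivity with resensitization kinetics.

An initially hypoxic (radioresistant) tumor progressively reoxygenates during
a fractionated course, so its LQ sensitivity parameters rise with time:

    alpha(t) = alpha0 * exp(-b t^2 / 2) + alpha_m * (1 - exp(-b t^2 / 2))

with ``alpha0`` the hypoxic starting value, ``alpha_m`` the fully oxygenated
asymptote and ``b`` (day^-2) the resensitization rate.  The quadratic
coefficient is tied to alpha through the oxygen enhancement ratio,

    beta(t) = beta0 * (alpha(t) / alpha0)^2,

so the instantaneous alpha/beta ratio alpha0^2 / (beta0 * alpha(t)) falls as
the tumor resensitizes.  Cell survival across a schedule is the product of
per-fraction LQ survivals, each evaluated at that fraction's delivery time
(complete inter-fraction repair of sublethal damage is assumed); it is carried
on the natural-log scale because survival after two 14 Gy fractions is of
order e^-29 and would underflow long before the TCP formula needs it.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "ResensitizationParams",
    "FractionationSchedule",
    "alpha_at",
    "beta_at",
    "cumulative_log_survival",
    "per_fraction_log_survival",
    "time_mean_alpha_beta",
]


@dataclass(frozen=True)
class ResensitizationParams:
    """One individual's radiosensitivity state.

    Parameters
    ----------
    alpha0 : float
        Initial (hypoxic) linear sensitivity, Gy^-1.  Must be > 0.
    alpha_m : float
        Asymptotic (fully resensitized) linear sensitivity, Gy^-1.
        Must satisfy ``alpha_m >= alpha0``: resensitization can only
        increase sensitivity.
    beta0 : float
        Initial quadratic sensitivity, Gy^-2.  Must be > 0.
    b : float
        Resensitization rate, day^-2.  Must be >= 0; ``b = 0`` freezes the
        sensitivities at their initial values.
    """

    alpha0: float
    alpha_m: float
    beta0: float
    b: float

    def __post_init__(self) -> None:
        if not self.alpha0 > 0:
            raise ValueError(f"alpha0 must be > 0, got {self.alpha0}")
        if not self.beta0 > 0:
            raise ValueError(f"beta0 must be > 0, got {self.beta0}")
        if self.b < 0:
            raise ValueError(f"b must be >= 0, got {self.b}")
        if self.alpha_m < self.alpha0:
            raise ValueError(
                f"alpha_m ({self.alpha_m}) must be >= alpha0 ({self.alpha0}); "
                "resensitization is non-decreasing"
            )

    @property
    def beta_m(self) -> float:
        """Asymptotic quadratic sensitivity via the OER relation."""
        return self.beta0 * (self.alpha_m / self.alpha0) ** 2


@dataclass(frozen=True)
class FractionationSchedule:
    """Ordered fraction delivery times (days from first fraction) and doses (Gy)."""

    times: tuple[float, ...]
    doses: tuple[float, ...]

    def __init__(self, times: Sequence[float], doses: Sequence[float]) -> None:
        object.__setattr__(self, "times", tuple(float(t) for t in times))
        object.__setattr__(self, "doses", tuple(float(d) for d in doses))
        self._validate()

    def _validate(self) -> None:
        if len(self.times) != len(self.doses):
            raise ValueError("times and doses must have equal length")
        if len(self.times) < 1:
            raise ValueError("schedule needs at least one fraction")
        if self.times[0] != 0.0:
            raise ValueError("first fraction time must be 0")
        if any(t2 <= t1 for t1, t2 in zip(self.times, self.times[1:])):
            raise ValueError("fraction times must be strictly increasing")
        if any(d <= 0 for d in self.doses):
            raise ValueError("all doses must be > 0")

    @property
    def n_fractions(self) -> int:
        return len(self.times)

    @property
    def total_time(self) -> float:
        """Total treatment time: time of the last fraction, days."""
        return self.times[-1]

    def with_dose(self, dose_per_fraction: float) -> "FractionationSchedule":
        """Same fraction times with a uniform dose per fraction."""
        return FractionationSchedule(self.times, [dose_per_fraction] * len(self.times))

    def to_dict(self) -> dict:
        return {"times_days": list(self.times), "doses_gy": list(self.doses)}

    @classmethod
    def from_dict(cls, d: dict) -> "FractionationSchedule":
        return cls(d["times_days"], d["doses_gy"])


def _check_time(t) -> np.ndarray:
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("time must be >= 0")
    return t


def _alpha(t: np.ndarray, alpha0, alpha_m, b) -> np.ndarray:
    # broadcastable core kernel; hypoxic weight exp(-b t^2/2) decays to 0
    w = np.exp(-b * t**2 / 2.0)
    return alpha0 * w + alpha_m * (1.0 - w)


def alpha_at(t: float, p: ResensitizationParams) -> float:
    """Linear sensitivity alpha(t) at time ``t`` days, Gy^-1."""
    t = _check_time(t)
    return float(_alpha(t, p.alpha0, p.alpha_m, p.b))


def beta_at(t: float, p: ResensitizationParams) -> float:
    """Quadratic sensitivity beta(t) = beta0 (alpha(t)/alpha0)^2, Gy^-2."""
    t = _check_time(t)
    a = _alpha(t, p.alpha0, p.alpha_m, p.b)
    return float(p.beta0 * (a / p.alpha0) ** 2)


def per_fraction_log_survival(
    s: FractionationSchedule, p: ResensitizationParams
) -> np.ndarray:
    """Natural-log survival of each fraction, evaluated at its delivery time."""
    t = np.asarray(s.times)
    d = np.asarray(s.doses)
    a = _alpha(t, p.alpha0, p.alpha_m, p.b)
    beta = p.beta0 * (a / p.alpha0) ** 2
    return -(a * d + beta * d**2)


def cumulative_log_survival(
    s: FractionationSchedule, p: ResensitizationParams, k: int
) -> float:
    """ln of the surviving fraction after the first ``k`` fractions (1-based).

    Equals -sum_{i=1..k} [alpha(T_i) d_i + beta(T_i) d_i^2]; monotone
    non-increasing in ``k``.
    """
    if not 1 <= k <= s.n_fractions:
        raise ValueError(f"k must be in [1, {s.n_fractions}], got {k}")
    return float(per_fraction_log_survival(s, p)[:k].sum())


def time_mean_alpha_beta(
    s: FractionationSchedule, p: ResensitizationParams
) -> float:
    """Arithmetic mean of alpha(T_i)/beta(T_i) over the schedule's fraction times, Gy.

    Since beta(t) = beta0 (alpha(t)/alpha0)^2 the instantaneous ratio is
    alpha0^2 / (beta0 alpha(t)), which is non-increasing in time.
    """
    t = np.asarray(s.times)
    a = _alpha(t, p.alpha0, p.alpha_m, p.b)
    return float((p.alpha0**2 / (p.beta0 * a)).mean())
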