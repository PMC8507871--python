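"""Synthetic clinical cohorts and cohort summary statistics.

Emulates the structure of the retrospective registry outcomes the model is
calibrated to: each patient has an individual TCP drawn from the population
radiosensitivity spread, and treatment failure (biochemical relapse, equated
with loss of local control) is Bernoulli with probability 1 - TCP.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binomtest
from statsmodels.stats.proportion import proportion_confint

from .population import PopulationDistribution, sample_individuals
from .radiosensitivity import FractionationSchedule
from .tcp import TumorKinetics, _log_survival_matrix, _zm_tcp_from_cumlog

__all__ = [
    "CohortOutcome",
    "summarize_cohort",
    "generate_cohort",
    "compare_to_clinical",
]

# Observed registry outcomes: 3 x 11 Gy / 28 d and 2 x 14 Gy / 14 d arms.
CLINICAL_3F = (107, 5)
CLINICAL_2F = (103, 15)


@dataclass(frozen=True)
class CohortOutcome:
    """Failure/control summary of one treatment arm."""

    n_patients: int
    n_failures: int
    control_rate: float
    failure_rate: float
    ci95: tuple[float, float]  # exact (Clopper-Pearson) CI on the failure rate


def summarize_cohort(n_patients: int, n_failures: int) -> CohortOutcome:
    """Exact failure/control rates with a Clopper-Pearson 95% CI."""
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if not 0 <= n_failures <= n_patients:
        raise ValueError(
            f"n_failures must be in [0, {n_patients}], got {n_failures}"
        )
    lo, hi = proportion_confint(n_failures, n_patients, alpha=0.05, method="beta")
    failure = n_failures / n_patients
    return CohortOutcome(
        n_patients=n_patients,
        n_failures=n_failures,
        control_rate=1.0 - failure,
        failure_rate=failure,
        ci95=(float(lo), float(hi)),
    )


def generate_cohort(
    pop: PopulationDistribution,
    s: FractionationSchedule,
    k: TumorKinetics,
    b: float,
    n_patients: int,
    seed: int,
) -> tuple[CohortOutcome, pd.DataFrame]:
    """Simulate one clinical-style cohort of ``n_patients``.

    Samples individuals (with the alpha/beta acceptance window), computes
    each TCP, draws failure ~ Bernoulli(1 - TCP).  Returns the outcome
    summary and a per-patient table.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    cohort = sample_individuals(pop.with_(n_samples=n_patients), s, b, seed=seed)
    cumlog = _log_survival_matrix(
        s.times, s.doses, cohort.alpha0, cohort.alpha_m, cohort.beta0, b
    )
    tcps = _zm_tcp_from_cumlog(s.times, cumlog, k.n0, k.lam)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))
    failed = rng.random(n_patients) >= tcps
    table = pd.DataFrame(
        {
            "patient_id": np.arange(n_patients),
            "alpha0": cohort.alpha0,
            "alpha_m": cohort.alpha_m,
            "beta0": cohort.beta0,
            "tcp": tcps,
            "failed": failed.astype(int),
        }
    )
    return summarize_cohort(n_patients, int(failed.sum())), table


def compare_to_clinical(
    simulated: "CohortOutcome | float", clinical: CohortOutcome
) -> tuple[float, float]:
    """Exact two-sided binomial test of a clinical arm against the model.

    Tests the observed clinical failure count against the simulated failure
    probability (a :class:`CohortOutcome`'s failure rate, or directly
    1 - population TCP).  Returns (p_value, rate_difference) where
    rate_difference = clinical failure rate - simulated probability.
    """
    if isinstance(simulated, CohortOutcome):
        simulated_failure_prob = simulated.failure_rate
    else:
        simulated_failure_prob = float(simulated)
    if not 0 <= simulated_failure_prob <= 1:
        raise ValueError("simulated failure probability must be in [0, 1]")
    test = binomtest(
        clinical.n_failures, clinical.n_patients, simulated_failure_prob,
        alternative="two-sided",
    )
    return float(test.pvalue), clinical.failure_rate - simulated_failure_prob
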