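"""The HDR mono-brachytherapy scenario grid.

Stock scenarios compare the two clinical schedules (3 x 11 Gy over 28 days,
2 x 14 Gy over 14 days) and their hypothetically shortened counterparts
(7-day inter-fraction intervals) under slow (b = 0.066 d^-2) and fast
(b = 1 d^-2) resensitization.  Also provides the dose-per-fraction sweep for
the two-fraction regimen, the no-resensitization anti-hypotheses (b = 0 with
sensitivities frozen either hypoxic or fully oxygenated), and a parameter
sensitivity grid over the population means/SDs of alpha0 and alpha_m.

All scenario contrasts use common random numbers: scenarios sharing a
population distribution are sampled with the same seed, so raw parameter
draws are paired and schedule contrasts are low-variance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .population import (
    PopulationDistribution,
    PopulationTCPResult,
    population_tcp,
)
from .radiosensitivity import FractionationSchedule
from .tcp import TumorKinetics

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "clinical_schedules",
    "stock_population",
    "stock_kinetics",
    "stock_scenarios",
    "run_matrix",
    "dose_sweep",
    "find_iso_tcp_dose",
    "no_resensitization",
    "sensitivity_grid",
]

B_SLOW = 0.066  # d^-2, slow resensitization (prostate estimate)
B_FAST = 1.0    # d^-2, effectively complete resensitization between fractions


def clinical_schedules() -> dict[str, FractionationSchedule]:
    """Named stock schedules (equal inter-fraction spacing)."""
    return {
        "2F/14d": FractionationSchedule([0, 14], [14, 14]),
        "2F/7d": FractionationSchedule([0, 7], [14, 14]),
        "3F/28d": FractionationSchedule([0, 14, 28], [11, 11, 11]),
        "3F/14d": FractionationSchedule([0, 7, 14], [11, 11, 11]),
    }


def stock_population(n_samples: int = 10_000, seed: int = 0) -> PopulationDistribution:
    """The calibrated population spread (see docs/methods.md)."""
    return PopulationDistribution(n_samples=n_samples, seed=seed)


def stock_kinetics() -> TumorKinetics:
    """Fixed tumor kinetics: N0 = 1e8 clonogens, lam = 0.02 d^-1."""
    return TumorKinetics(n0=1e8, lam=0.02)


@dataclass(frozen=True)
class ScenarioSpec:
    label: str
    schedule: FractionationSchedule
    b: float
    population: PopulationDistribution
    kinetics: TumorKinetics


@dataclass(frozen=True)
class ScenarioResult:
    label: str
    population_tcp: float
    se: float
    acceptance_rate: float
    result: PopulationTCPResult


def stock_scenarios(
    pop: PopulationDistribution | None = None,
    kinetics: TumorKinetics | None = None,
) -> list[ScenarioSpec]:
    """The eight stock combinations: 4 schedules x {slow, fast} resensitization."""
    pop = pop or stock_population()
    kinetics = kinetics or stock_kinetics()
    scheds = clinical_schedules()
    return [
        ScenarioSpec(f"{name} b={b}", sched, b, pop, kinetics)
        for b in (B_SLOW, B_FAST)
        for name, sched in scheds.items()
    ]


def run_matrix(specs: list[ScenarioSpec]) -> pd.DataFrame:
    """Population TCP for each scenario; one row per spec.

    Scenarios sharing a population distribution reuse its seed, so their
    parameter draws are common random numbers.
    """
    if not specs:
        raise ValueError("empty scenario list")
    labels = [sp.label for sp in specs]
    if len(set(labels)) != len(labels):
        raise ValueError("scenario labels must be unique within a batch")
    rows = []
    for sp in specs:
        res = population_tcp(sp.population, sp.schedule, sp.kinetics, sp.b)
        rows.append(
            {
                "label": sp.label,
                "b": sp.b,
                "n_fractions": sp.schedule.n_fractions,
                "total_time_days": sp.schedule.total_time,
                "population_tcp": res.population_tcp,
                "se": res.se,
                "acceptance_rate": res.acceptance_rate,
            }
        )
    return pd.DataFrame(rows)


def _cohort_tcps(cohort, schedule, kinetics, b):
    from .tcp import _log_survival_matrix, _zm_tcp_from_cumlog

    cumlog = _log_survival_matrix(
        schedule.times, schedule.doses, cohort.alpha0, cohort.alpha_m, cohort.beta0, b
    )
    return _zm_tcp_from_cumlog(schedule.times, cumlog, kinetics.n0, kinetics.lam)


def dose_sweep(
    schedule_template: FractionationSchedule,
    doses: list[float],
    pop: PopulationDistribution,
    kinetics: TumorKinetics,
    b: float,
) -> pd.DataFrame:
    """Population TCP as a function of (uniform) dose per fraction.

    The alpha/beta acceptance window depends only on fraction times, so one
    cohort is sampled and reused across all doses: the dose -> TCP map is then
    deterministic given the seed and monotone non-decreasing exactly.
    """
    if len(doses) == 0:
        raise ValueError("empty dose list")
    if any(d <= 0 for d in doses):
        raise ValueError("doses must be > 0")
    from .population import sample_individuals

    cohort = sample_individuals(pop, schedule_template, b)
    rows = []
    for d in doses:
        sched = schedule_template.with_dose(d)
        tcps = _cohort_tcps(cohort, sched, kinetics, b)
        rows.append(
            {
                "dose_per_fraction_gy": d,
                "population_tcp": float(tcps.mean()),
                "se": float(tcps.std(ddof=1) / np.sqrt(len(tcps))),
            }
        )
    return pd.DataFrame(rows)


def find_iso_tcp_dose(
    schedule_template: FractionationSchedule,
    target_tcp: float,
    pop: PopulationDistribution,
    kinetics: TumorKinetics,
    b: float,
    bracket: tuple[float, float] = (10.0, 16.0),
    resolution: float = 0.1,
) -> float:
    """Smallest dose per fraction (to ``resolution`` Gy) reaching ``target_tcp``.

    Bisection on the common-random-number dose -> population-TCP map, which is
    monotone and deterministic for a fixed population seed.
    """
    from .population import sample_individuals

    cohort = sample_individuals(pop, schedule_template, b)

    def tcp_at(d: float) -> float:
        return float(
            _cohort_tcps(cohort, schedule_template.with_dose(d), kinetics, b).mean()
        )

    lo, hi = bracket
    f_lo, f_hi = tcp_at(lo), tcp_at(hi)
    if f_lo >= target_tcp:
        return lo
    if f_hi < target_tcp:
        raise ValueError(
            f"target TCP {target_tcp} not reachable in bracket {bracket} "
            f"(TCP at {hi} Gy = {f_hi:.4f})"
        )
    while hi - lo > resolution / 2:
        mid = 0.5 * (lo + hi)
        if tcp_at(mid) >= target_tcp:
            hi = mid
        else:
            lo = mid
    return round(round(hi / resolution) * resolution, 6)


def no_resensitization(
    pop: PopulationDistribution,
    schedules: dict[str, FractionationSchedule],
    kinetics: TumorKinetics,
    mode: str,
) -> pd.DataFrame:
    """Anti-hypothesis: b = 0 with sensitivities frozen.

    mode="hypoxic": sensitivities stay at their initial (hypoxic) values.
    mode="sensitive": no initial hypoxia — alpha frozen at the fully
    oxygenated mean alpha_m, beta at alpha_m/4.5.
    """
    if mode == "hypoxic":
        frozen = pop
    elif mode == "sensitive":
        # alpha frozen at the oxygenated level: alpha0 ~ N(mean_alpha_m, sd).
        # alpha_m is inert at b=0; its mean is lifted well above alpha0 so the
        # ordering constraint alpha_m >= alpha0 does not truncate the draw.
        frozen = pop.with_(
            mean_alpha0=pop.mean_alpha_m,
            sd_alpha0=pop.sd_alpha_m,
            mean_alpha_m=pop.mean_alpha_m + 0.12,
            mean_beta0=pop.mean_alpha_m / 4.5,
            sd_beta0=pop.sd_beta0,
        )
    else:
        raise ValueError(f"mode must be 'hypoxic' or 'sensitive', got {mode!r}")
    rows = []
    for name, sched in schedules.items():
        res = population_tcp(frozen, sched, kinetics, b=0.0)
        rows.append(
            {
                "label": f"{name} {mode} b=0",
                "schedule": name,
                "mode": mode,
                "population_tcp": res.population_tcp,
                "se": res.se,
                "acceptance_rate": res.acceptance_rate,
            }
        )
    return pd.DataFrame(rows)


def default_perturbations() -> list[tuple[str, float]]:
    """Perturbed population configurations for the sensitivity grid."""
    return [
        ("mean_alpha0", 0.10),
        ("mean_alpha0", 0.14),
        ("mean_alpha_m", 0.21),
        ("mean_alpha_m", 0.25),
        ("sd_alpha0", 0.01),
        ("sd_alpha0", 0.03),
        ("sd_alpha_m", 0.01),
        ("sd_alpha_m", 0.03),
    ]


def sensitivity_grid(
    base_pop: PopulationDistribution,
    perturbations: list[tuple[str, float]] | None = None,
    kinetics: TumorKinetics | None = None,
    b: float = B_SLOW,
) -> pd.DataFrame:
    """(TCP_3F, TCP_2F) for the clinical schedules under perturbed populations.

    Each row perturbs one population mean/SD of alpha0 or alpha_m from the
    base configuration; the base point itself is the first row.
    """
    if perturbations is None:
        perturbations = default_perturbations()
    allowed = {"mean_alpha0", "sd_alpha0", "mean_alpha_m", "sd_alpha_m"}
    bad = {p for p, _ in perturbations} - allowed
    if bad:
        raise ValueError(f"perturbable parameters are {sorted(allowed)}, got {bad}")
    kinetics = kinetics or stock_kinetics()
    scheds = clinical_schedules()
    configs = [("base", None, base_pop)] + [
        (f"{param}={value}", (param, value), base_pop.with_(**{param: value}))
        for param, value in perturbations
    ]
    rows = []
    for label, pert, pop in configs:
        # mean_beta0 stays tied to mean_alpha0/4.5 when mean_alpha0 moves
        if pert is not None and pert[0] == "mean_alpha0":
            pop = pop.with_(mean_beta0=pert[1] / 4.5)
        tcp3 = population_tcp(pop, scheds["3F/28d"], kinetics, b).population_tcp
        tcp2 = population_tcp(pop, scheds["2F/14d"], kinetics, b).population_tcp
        rows.append(
            {
                "label": label,
                "parameter": pert[0] if pert else "",
                "value": pert[1] if pert else np.nan,
                "tcp_3f": tcp3,
                "tcp_2f": tcp2,
            }
        )
    return pd.DataFrame(rows)
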