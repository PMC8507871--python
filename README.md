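# zmtcp

Tumor-control-probability (TCP) modelling of high-dose-rate (HDR) prostate
mono-brachytherapy schedules when the tumor starts out hypoxic and
resensitizes during treatment.

Clinical registries report that low- to intermediate-risk prostate cancer
treated with three HDR implants of 11 Gy over 28 days is controlled more
often (95.3%, 5/107 failures) than with two implants of 14 Gy over 14 days
(85.4%, 15/103 failures) — even though the two-fraction regimen's
biologically effective dose is comparable.  `zmtcp` implements the
mechanistic explanation: a tumor that is initially hypoxic (radioresistant)
and progressively reoxygenates, so later fractions hit a more sensitive
target and *longer* schedules win.  The package is aimed at radiotherapy
physicists and radiobiology modellers who want to compare fractionation
schedules, calibrate population radiosensitivity to observed control rates,
or stress-test the hypoxia/resensitization hypothesis.

## Model

Individual TCP is the extinction probability of a birth-death process of
`N₀` clonogens proliferating at rate `λ` between fractions and killed by the
fractions (Zaider-Minerbo solution for fractionated delivery):

    TCP = [ 1 − S e^{λT} / (1 + S e^{λT} Σₖ Sₖ⁻¹ (e^{−λT_{k−1}} − e^{−λT_k}) ) ]^{N₀}

where `Sₖ` is the cumulative linear-quadratic survival after `k` fractions.
Radiosensitivity rises during treatment (reoxygenation):

    α(t) = α₀ e^{−b t²/2} + α_m (1 − e^{−b t²/2}),   β(t) = β₀ (α(t)/α₀)²

Population TCP is the mean individual TCP over a cohort with normal
inter-patient spread on (α₀, α_m, β₀), filtered by a prostate α/β
plausibility window of 3.5–6 Gy on the fraction-time-mean α(t)/β(t).
Defaults: α₀ ~ N(0.12, 0.02) Gy⁻¹, α_m ~ N(0.23, 0.02) Gy⁻¹,
β₀ ~ N(0.12/4.5, 0.01) Gy⁻², N₀ = 10⁸, λ = 0.02 d⁻¹, b = 0.066 d⁻².
See `docs/methods.md` for assumptions, numerics and known limitations.

## Worked example

```python
import zmtcp as z

p = z.ResensitizationParams(alpha0=0.12, alpha_m=0.23, beta0=0.12/4.5, b=0.066)
k = z.stock_kinetics()                      # N0 = 1e8, lam = 0.02/day
sched_2f = z.clinical_schedules()["2F/14d"]  # 2 x 14 Gy, days 0 and 14

print(z.alpha_at(14, p))                            # 0.2298  (nearly resensitized)
print(z.cumulative_log_survival(sched_2f, p, 2))    # -29.3   (ln survival)
print(z.zm_tcp(sched_2f, p, k))                     # 0.99997 (mean patient is cured)

pop = z.stock_population(n_samples=10_000, seed=1)
for name in ("3F/28d", "2F/14d", "2F/7d"):
    res = z.population_tcp(pop, z.clinical_schedules()[name], k, b=0.066)
    frac0 = z.tcp_histogram(res).fraction_below_005
    print(name, round(100 * res.population_tcp, 1), "%", round(frac0, 3))
```

prints

```
3F/28d 93.3 %  0.011
2F/14d 89.8 %  0.021
2F/7d  78.3 %  0.067
```

The mean patient is cured under every schedule; the population TCP is set by
the resistant minority (the "mass below TCP = 0.05" column), which grows as
the schedule shortens — the dichotomous-distribution effect.  Although
individual entries sit a few points from the originally reported matrix (see
`docs/methods.md`, *Fidelity to the published results*), every qualitative
finding holds: the three-fraction/28-day schedule beats the two-fraction one
for all examined populations, shortening schedules is only safe if
resensitization is fast, and dose escalation of the two-fraction arm to
~14.6-14.8 Gy/fraction restores ≈96% control:

```python
z.find_iso_tcp_dose(sched_2f, 0.96, pop, k, b=0.066)   # 14.6 Gy
```

## Command line

```bash
zmtcp reproduce --out results/paper       # full pipeline + manifest
zmtcp scenario matrix --config run.yaml   # the 8-scenario TCP matrix
zmtcp scenario dose-sweep --config run.yaml
zmtcp calibrate --budget 500 --seed 1     # random-search calibration
zmtcp cohort simulate --config run.yaml --n 107 --seed 1 --out results/cohort
```

Configs are flat YAML (see `zmtcp.stock_config()` for the shipped default);
every stochastic stage is seeded and outputs carry a config hash.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

recomputes, from scratch at 10,000 sampled individuals per scenario: the
eight population TCPs of the schedule × resensitization-rate matrix, the
two-fraction schedule escalated to 14.8 Gy/fraction, and the
no-resensitization fully-sensitive anti-hypothesis on both clinical
schedules.  Values are percentages; each entry records the Monte-Carlo
sample size used.
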