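"""Seeded simulator for NACC-like longitudinal cognitive cohorts.

The restricted-access registry data this package targets cannot be bundled,
so every downstream stage is exercised on simulated cohorts that reproduce
its *structure*: multi-visit records spanning roughly 2-11 years with
approximately annual visits, two feature groups (per-visit cognitive scores
and largely static health/history variables), strictly positive raw coding,
visit-level missingness, and three outcome trajectories — stable Control,
conversion to aMCI, and conversion to AD (via aMCI where the record is long
enough).

Generative model
----------------
Raw feature values are shifted log-normal (guaranteeing positivity with
realistic right skew).  On the log scale each patient carries a stable
trait component plus per-visit noise; ``reliability`` (the intraclass
correlation, default 0.75) sets their variance split while the population
marginal stays fixed, mimicking the high test-retest reliability of
neuropsychological scores — without it, intrapersonal change carries no
usable signal.

Converters' dynamic cognition features carry a preclinical signal with two
parts: their first-visit mean already sits half an effect below the control
mean (cognitive decline precedes the diagnostic label by years), and they
decline linearly in time so the mean first-to-last-visit drop equals
``effect_size`` population SDs.  aMCI converters receive half the AD effect
(their trajectories sit between stable controls and AD converters).  Each
converter's diagnostic label flips at a change-point visit drawn uniformly
within the record — later than the feature decline begins, which is what
makes future status predictable from earlier visits.  Decline is floored at
5% of the population mean so positivity is never violated.  Health features
carry no class signal.  Static features are drawn once per patient and held
constant.

With ``effect_size = 0`` the three trajectory groups are exchangeable in
every feature — the null cohort used to check that models score at chance.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, replace

import numpy as np

from .cohort import AD, AMCI, CONTROL, Cohort, FeatureSpec, PatientRecord, Visit

__all__ = ["SimulationConfig", "simulate_cohort", "null_cohort", "inject_missingness"]

_TRAJECTORIES = (CONTROL, AMCI, AD)
_LOGNORM_SIGMA = 0.4
_FLOOR_FRACTION = 0.05
#: aMCI converters decline at this fraction of the AD effect size.
AMCI_EFFECT_FRACTION = 0.5
#: converters' first-visit cognition already sits this many effect-SDs
#: below the control mean (preclinical offset).
_BASELINE_SHIFT_FRACTION = 0.5


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the cohort generator.

    ``class_mix`` orders trajectories as (stable Control, conversion to aMCI,
    conversion to AD).  ``effect_size`` is the mean first-to-last-visit drop
    of an AD converter's cognition features, in population-SD units.
    ``visits_per_patient`` and ``span_years`` are inclusive ranges; the span
    range deliberately straddles the 3-10 year eligibility window so the
    filtering stage has real work to do.
    """

    n_patients: int = 300
    n_cognition: int = 10
    n_health: int = 6
    n_static: int = 4
    class_mix: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    effect_size: float = 1.0
    reliability: float = 0.75
    missing_rate: float = 0.1
    visits_per_patient: tuple[int, int] = (2, 8)
    span_years: tuple[float, float] = (2.0, 11.0)
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients <= 0:
            raise ValueError("n_patients must be positive")
        if self.n_cognition <= 0 or self.n_health <= 0:
            raise ValueError("need at least one feature per group")
        if not 0 <= self.n_static <= self.n_health:
            raise ValueError("n_static must lie within the health group")
        if len(self.class_mix) != 3 or any(p < 0 for p in self.class_mix):
            raise ValueError("class_mix must be three non-negative proportions")
        if abs(sum(self.class_mix) - 1.0) > 1e-9:
            raise ValueError("class_mix must sum to 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0.0 <= self.reliability < 1.0:
            raise ValueError("reliability (ICC) must be in [0, 1)")
        lo, hi = self.span_years
        if not (0.0 < lo <= hi <= 12.0):
            raise ValueError("span_years range must lie within (0, 12]")
        vlo, vhi = self.visits_per_patient
        if not (1 <= vlo <= vhi):
            raise ValueError("invalid visits_per_patient range")


def default_feature_specs(config: SimulationConfig) -> list[FeatureSpec]:
    """Cognition features are dynamic; the last n_static health features are
    static (family-history-like)."""
    specs = [FeatureSpec(f"cog_{i:02d}", "cognition") for i in range(config.n_cognition)]
    n_dynamic_health = config.n_health - config.n_static
    specs += [FeatureSpec(f"hlt_{i:02d}", "health") for i in range(n_dynamic_health)]
    specs += [FeatureSpec(f"hist_{i:02d}", "health", static=True)
              for i in range(config.n_static)]
    return specs


def _population_params(config: SimulationConfig, rng: np.random.Generator):
    n = config.n_cognition + config.n_health
    loc = rng.uniform(1.0, 5.0, size=n)          # shift keeping values > 0
    mu = rng.uniform(0.0, 1.0, size=n)           # log-normal log-mean
    ln_mean = np.exp(mu + _LOGNORM_SIGMA**2 / 2)
    ln_sd = ln_mean * np.sqrt(np.exp(_LOGNORM_SIGMA**2) - 1.0)
    mean = loc + ln_mean
    return loc, mu, mean, ln_sd


def _visit_dates(rng: np.random.Generator, config: SimulationConfig) -> list[dt.date]:
    vlo, vhi = config.visits_per_patient
    n_visits = int(rng.integers(vlo, vhi + 1))
    start = dt.date(2000, 1, 1) + dt.timedelta(days=int(rng.integers(0, 3653)))
    if n_visits == 1:
        return [start]
    span = rng.uniform(*config.span_years)
    # relative gap variation follows the ~annual [0.8, 1.5]-year convention,
    # rescaled so the record hits the drawn span exactly
    raw_gaps = rng.uniform(0.8, 1.5, size=n_visits - 1)
    gaps = span * raw_gaps / raw_gaps.sum()
    dates = [start]
    offset = 0.0
    for g in gaps:
        offset += g
        d = start + dt.timedelta(days=max(1, round(offset * 365.25)))
        if d <= dates[-1]:  # guard against degenerate rounding
            d = dates[-1] + dt.timedelta(days=1)
        dates.append(d)
    return dates


def _labels_for(trajectory: str, n_visits: int, cp: int,
                rng: np.random.Generator) -> list[str]:
    """Monotone label sequence with conversion starting at visit index cp."""
    if trajectory == CONTROL:
        return [CONTROL] * n_visits
    if n_visits == 1:
        return [trajectory]
    if trajectory == AMCI:
        return [CONTROL] * cp + [AMCI] * (n_visits - cp)
    # AD conversion passes through aMCI when the record leaves room
    if cp < n_visits - 1:
        cp2 = int(rng.integers(cp + 1, n_visits))
        return [CONTROL] * cp + [AMCI] * (cp2 - cp) + [AD] * (n_visits - cp2)
    return [CONTROL] * cp + [AD] * (n_visits - cp)


def simulate_cohort(config: SimulationConfig) -> Cohort:
    """Generate a cohort; deterministic for a fixed config (incl. seed)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    specs = default_feature_specs(config)
    loc, mu, mean, ln_sd = _population_params(config, rng)
    names = [s.name for s in specs]
    is_static = np.array([s.static for s in specs])
    is_cognition = np.array([s.group == "cognition" for s in specs])

    patients = []
    for idx in range(config.n_patients):
        trajectory = _TRAJECTORIES[int(rng.choice(3, p=np.asarray(config.class_mix)))]
        dates = _visit_dates(rng, config)
        n_visits = len(dates)
        # one change point drives both the label sequence and the decline
        cp = int(rng.integers(1, n_visits)) if n_visits >= 2 else 0
        labels = _labels_for(trajectory, n_visits, cp, rng)

        # log-scale person-level trait + visit noise; their variances sum to
        # _LOGNORM_SIGMA^2 so the marginal matches, while the reliability
        # (ICC) sets how repeatable a person's scores are across visits
        sd_trait = _LOGNORM_SIGMA * np.sqrt(config.reliability)
        sd_visit = _LOGNORM_SIGMA * np.sqrt(1.0 - config.reliability)
        trait = rng.normal(0.0, sd_trait, size=len(names))
        static_draw = loc + np.exp(mu + trait + rng.normal(0.0, sd_visit,
                                                           size=len(names)))
        values = np.empty((n_visits, len(names)))
        for t in range(n_visits):
            draw = loc + np.exp(mu + trait + rng.normal(0.0, sd_visit,
                                                        size=len(names)))
            values[t] = np.where(is_static, static_draw, draw)

        if trajectory != CONTROL and config.effect_size > 0:
            # Preclinical signal, two parts: (1) converters already sit below
            # the control mean at their first visit (pathology precedes the
            # label change by years), and (2) cognition declines linearly in
            # time so the first-to-last mean drop equals effect * SD.
            effect = config.effect_size * (
                1.0 if trajectory == AD else AMCI_EFFECT_FRACTION)
            offset = _BASELINE_SHIFT_FRACTION * effect * ln_sd
            drift = effect * ln_sd
            t0, t_end = dates[0], dates[-1]
            affected = is_cognition & ~is_static
            for t in range(n_visits):
                progress = 0.0 if t_end == t0 else \
                    (dates[t] - t0).days / (t_end - t0).days
                target = np.maximum(mean - offset - drift * progress,
                                    _FLOOR_FRACTION * mean)
                values[t] = np.where(affected, values[t] * (target / mean),
                                     values[t])

        visits = [Visit(dates[t], dict(zip(names, values[t])), labels[t])
                  for t in range(n_visits)]
        patients.append(PatientRecord(f"P{idx:05d}", visits))

    cohort = Cohort(patients, specs)
    if config.missing_rate > 0:
        cohort = inject_missingness(cohort, config.missing_rate, "MCAR",
                                    seed=config.seed + 1)
    return cohort


def null_cohort(config: SimulationConfig) -> Cohort:
    """Same generator with the class signal forced to zero: trajectory labels
    are assigned but features are exchangeable across groups, so a model
    trained on this cohort should score at chance."""
    return simulate_cohort(replace(config, effect_size=0.0))


def inject_missingness(cohort: Cohort, rate: float,
                       mechanism: str = "MCAR", seed: int = 0) -> Cohort:
    """Blank feature cells at the given rate; labels and dates are never
    dropped.

    ``MCAR`` drops each cell independently.  ``visit_block`` additionally
    drops a feature for *all* of a patient's visits with the same
    probability, emulating variables that were systematically never
    collected for a participant.
    """
    if not 0.0 <= rate < 1.0:
        raise ValueError("missingness rate must be in [0, 1)")
    if mechanism not in ("MCAR", "visit_block"):
        raise ValueError(f"unknown missingness mechanism {mechanism!r}")
    if rate == 0.0:
        return cohort.copy()
    rng = np.random.default_rng(seed)
    out = cohort.copy()
    names = out.feature_names
    for p in out.patients:
        blocked = (rng.random(len(names)) < rate) if mechanism == "visit_block" \
            else np.zeros(len(names), dtype=bool)
        for v in p.visits:
            cell = rng.random(len(names)) < rate
            for j, name in enumerate(names):
                if blocked[j] or cell[j]:
                    v.values[name] = np.nan
    return out
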