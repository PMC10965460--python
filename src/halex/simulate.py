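"""Synthetic two-wave cohort generation from a known illness-death process.

The generator is the testing twin of the fitted model: subjects evolve
through disease-free → diseased → dead under Gompertz transition
intensities, are enrolled at a baseline age (left-truncated on survival to
enrolment), and are re-observed once a few years later. Disease onset is
therefore interval-censored exactly as in a real two-wave cohort, death ages
are exact (register linkage), and a fraction of survivors is lost to
follow-up completely at random.

Defaults emulate a rural Chinese cohort of ~10,318 adults aged 65-79 with
baseline T2DM prevalence ≈13% (higher in women), a follow-up wave 2-4 years
after baseline, and ≈11.5% loss to follow-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .multistate import GompertzIntensities

__all__ = [
    "DEFAULT_INTENSITIES",
    "SimulationConfig",
    "simulate_cohort",
    "aggregate_counts",
    "expected_mortality_schedule",
    "henan_cohort_margins",
    "CohortMargins",
]

#: Intensities used by default, on the scale of a rural 65+ population:
#: onset rises ~7.5%/year of age and is lower in men; mortality rises
#: ~10%/year, is higher in men, and roughly 1.8-fold higher with disease.
#: Covariate is the male indicator (female is the baseline level).
DEFAULT_INTENSITIES = GompertzIntensities(
    alpha=np.log([0.0090, 0.0072, 0.0130]),
    xi=np.array([0.075, 0.098, 0.098]),
    beta=np.array([[-0.42], [0.48], [0.48]]),
    reference_age=65.0,
    covariate_names=("sex_male",),
)

PANEL_COLUMNS = ["subject_id", "sex", "entry_age", "entry_state",
                 "exit_age", "exit_kind", "exit_state"]


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design knobs of the synthetic cohort.

    ``burn_in_start_age`` is the age at which every subject starts
    disease-free; running the process from there to the baseline age is what
    produces a realistic mix of prevalent cases whose onset age is unknown.
    ``followup_gap`` is (mean, half-width) of the per-subject uniform gap in
    years between the two waves.
    """

    cohort_size: int = 10318
    baseline_age_range: tuple = (65.0, 79.0)
    burn_in_start_age: float = 50.0
    followup_gap: tuple = (3.0, 1.0)
    loss_to_followup_prob: float = 0.115
    intensity_params: GompertzIntensities = field(default=DEFAULT_INTENSITIES)
    sex_ratio: float = 0.4527      # probability of male
    seed: int = 0
    max_age: float = 110.0

    def __post_init__(self):
        if self.cohort_size <= 0:
            raise ValueError("cohort_size must be positive")
        for p, name in [(self.loss_to_followup_prob, "loss_to_followup_prob"),
                        (self.sex_ratio, "sex_ratio")]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        lo, hi = self.baseline_age_range
        if not self.burn_in_start_age < lo <= hi < self.max_age:
            raise ValueError("require burn_in_start_age < baseline range <= max_age")
        gap_mean, gap_jitter = self.followup_gap
        if gap_mean <= 0 or gap_jitter < 0 or gap_jitter >= gap_mean:
            raise ValueError("followup_gap mean must be positive and exceed the jitter")


def _gompertz_time(rng: np.random.Generator, model: GompertzIntensities,
                   transition: int, a0: float, z: np.ndarray) -> float:
    """Event time after age a0 for one cause-specific Gompertz hazard.

    Inverse-transform on the closed-form cumulative hazard
    H(t) = c (e^{xi t} - 1)/xi with c the intensity at a0; returns inf when
    the total hazard mass is below the exponential draw (xi < 0 tails).
    """
    xi = model.xi[transition]
    c = float(model.rates(a0, z)[transition])
    e = rng.exponential()
    if c == 0.0:
        return np.inf
    if xi == 0.0:
        return e / c
    arg = 1.0 + xi * e / c
    if arg <= 0.0:
        return np.inf
    return float(np.log(arg) / xi)


def _simulate_trajectory(rng, model, start_age, z):
    """(onset_age, death_age) of one path started disease-free at start_age.

    Competing risks out of the disease-free state are resolved as the minimum
    of the two cause-specific event times; onset_age is inf when death comes
    first.
    """
    t12 = _gompertz_time(rng, model, 0, start_age, z)
    t13 = _gompertz_time(rng, model, 1, start_age, z)
    if t12 < t13:
        onset = start_age + t12
        t23 = _gompertz_time(rng, model, 2, onset, z)
        return onset, onset + t23
    return np.inf, start_age + t13


def simulate_cohort(config: SimulationConfig) -> pd.DataFrame:
    """Simulate a two-wave panel cohort; reproducible given ``config.seed``.

    Each subject gets a deterministic random substream keyed by the master
    seed and the subject index, so record i is invariant to cohort size.
    Subjects whose simulated death precedes their drawn baseline age have
    their trajectory redrawn (left truncation at enrolment: the baseline age
    and sex are kept, survival to enrolment is conditioned on).

    Returns a DataFrame with one row per subject and columns
    ``subject_id, sex, entry_age, entry_state, exit_age, exit_kind,
    exit_state`` (``exit_state`` is missing unless ``exit_kind`` is
    ``alive_observed``).
    """
    model = config.intensity_params
    if np.any(np.isnan(model.alpha)) or not np.all(np.isfinite(model.xi)):
        raise ValueError("non-finite intensity parameters")
    lo, hi = config.baseline_age_range
    gap_mean, gap_jitter = config.followup_gap

    rows = []
    for i in range(config.cohort_size):
        rng = np.random.default_rng([config.seed, i])
        male = rng.random() < config.sex_ratio
        z = np.array([1.0]) if male else np.array([0.0])
        if model.n_covariates == 0:
            z = np.zeros(0)
        entry_age = lo + (hi - lo) * rng.random()
        onset, death = _simulate_trajectory(rng, model, config.burn_in_start_age, z)
        while death <= entry_age:   # redraw until alive at enrolment
            onset, death = _simulate_trajectory(rng, model, config.burn_in_start_age, z)
        entry_state = 2 if onset <= entry_age else 1

        gap = gap_mean + gap_jitter * (2.0 * rng.random() - 1.0)
        followup_age = min(entry_age + gap, config.max_age)
        # dropout is decided independently of the outcome (missing completely
        # at random): a lost subject's vital status is never observed, so
        # excluding the lost from analysis stays unbiased
        lost = rng.random() < config.loss_to_followup_prob
        if lost:
            exit_age, exit_kind, exit_state = followup_age, "lost", np.nan
        elif death <= followup_age:
            exit_age, exit_kind, exit_state = death, "death_exact", np.nan
        else:
            exit_age = followup_age
            exit_kind = "alive_observed"
            exit_state = 2 if onset <= followup_age else 1
        rows.append((i, "male" if male else "female", entry_age, entry_state,
                     exit_age, exit_kind, exit_state))

    df = pd.DataFrame(rows, columns=PANEL_COLUMNS)
    df["exit_state"] = df["exit_state"].astype("Int64")
    return df


def aggregate_counts(records: pd.DataFrame, age_intervals) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate panel records into mortality exposure and baseline prevalence tables.

    ``age_intervals`` is a list of (age_start, age_width) pairs, contiguous
    and non-overlapping, with one open-ended terminal interval (width inf or
    NaN). Exposure (person-years) per interval is each subject's time in the
    interval between entry and exit age; deaths are counted in the interval
    containing the death age; prevalence is the baseline cases / subjects
    whose entry age falls in the interval.

    Returns ``(counts, prevalence)`` DataFrames with columns
    (age_start, age_width, population, deaths) and
    (age_start, age_width, n, cases).
    """
    iv = sorted((float(s), float(w) if np.isfinite(w) else np.inf)
                for s, w in age_intervals)
    starts = np.array([s for s, _ in iv])
    widths = np.array([w for _, w in iv])
    if np.isfinite(widths[-1]) or np.any(~np.isfinite(widths[:-1])):
        raise ValueError("exactly the last interval must be open-ended")
    if not np.allclose(starts[1:], starts[:-1] + widths[:-1]):
        raise ValueError("age intervals must be contiguous and non-overlapping")
    ends = np.append(starts[1:], np.inf)

    entry = records["entry_age"].to_numpy(dtype=float)
    exit_ = records["exit_age"].to_numpy(dtype=float)
    if entry.size and (entry.min() < starts[0]):
        raise ValueError("records fall below the first age interval")

    py = np.zeros(len(iv))
    deaths = np.zeros(len(iv), dtype=int)
    for g, (s, e) in enumerate(zip(starts, ends)):
        py[g] = np.clip(np.minimum(exit_, e) - np.maximum(entry, s), 0.0, None).sum()
    death_ages = records.loc[records["exit_kind"] == "death_exact", "exit_age"]
    idx = np.searchsorted(starts, death_ages.to_numpy(dtype=float), side="right") - 1
    for g in idx:
        deaths[g] += 1

    counts = pd.DataFrame({"age_start": starts, "age_width": widths,
                           "population": py, "deaths": deaths})

    gidx = np.searchsorted(starts, entry, side="right") - 1
    n = np.zeros(len(iv), dtype=int)
    cases = np.zeros(len(iv), dtype=int)
    entry_state = records["entry_state"].to_numpy(dtype=int)
    for g, st in zip(gidx, entry_state):
        n[g] += 1
        if st == 2:
            cases[g] += 1
    prevalence = pd.DataFrame({"age_start": starts, "age_width": widths,
                               "n": n, "cases": cases})
    return counts, prevalence


def expected_mortality_schedule(model: GompertzIntensities, age_intervals,
                                strata=((np.zeros(0), 1.0),),
                                start_age: float = 50.0, step: float = 0.05,
                                horizon: float = 130.0,
                                ref_population: float = 1e5) -> pd.DataFrame:
    """Deterministic age-grouped mortality schedule implied by the process.

    Stands in for an external period mortality data set (the surveillance
    population whose deaths feed the Sullivan life table): for each age band
    it returns the expected person-years and deaths of a stationary cohort
    that starts disease-free at ``start_age`` and evolves under ``model``,
    so each band's central death rate is the exact marginal (all-state)
    mortality of the process at those ages.

    ``strata`` is a sequence of (covariate row, weight) pairs, e.g. female
    and male intensities mixed at the population sex ratio. ``ref_population``
    only sets the output scale; life-table columns built from the schedule
    are invariant to it.
    """
    iv = sorted((float(s), float(w) if np.isfinite(w) else np.inf)
                for s, w in age_intervals)
    starts = np.array([s for s, _ in iv])
    ends = np.append(starts[1:], horizon)
    if starts[0] < start_age:
        raise ValueError("age intervals must start at or after start_age")

    ages = np.arange(start_age, horizon + step / 2, step)
    py = np.zeros(len(iv))
    deaths = np.zeros(len(iv))
    total_weight = sum(w for _, w in strata)
    for z, weight in strata:
        z = np.asarray(z, dtype=float)
        if z.size == 0 and model.n_covariates:
            z = np.zeros(model.n_covariates)   # reference level of every covariate
        p1, p2 = np.empty(ages.size), np.empty(ages.size)
        p1[0], p2[0] = 1.0, 0.0
        from .multistate import _step_factors
        for k in range(ages.size - 1):
            dt = ages[k + 1] - ages[k]
            q12, q13, q23 = model.rates(ages[k] + 0.5 * dt, z)
            f11, f12, f22 = _step_factors(q12, q13, q23, dt)
            p1[k + 1] = p1[k] * f11
            p2[k + 1] = p1[k] * f12 + p2[k] * f22
        q12, q13, q23 = model.rates(ages, z)
        alive = p1 + p2
        death_flux = p1 * q13 + p2 * q23
        for g, (s, e) in enumerate(zip(starts, ends)):
            sel = (ages >= s) & (ages <= e)
            py[g] += weight / total_weight * np.trapezoid(alive[sel], ages[sel])
            deaths[g] += weight / total_weight * np.trapezoid(death_flux[sel], ages[sel])

    scale = ref_population / py[0] * (ends[0] - starts[0]) if py[0] > 0 else 1.0
    return pd.DataFrame({
        "age_start": starts,
        "age_width": [w for _, w in iv],
        "population": py * scale,
        "deaths": deaths * scale,
    })


# ---------------------------------------------------------------------------
# reference margins of the source cohort
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortMargins:
    """Published marginal counts of the Henan Rural Cohort T2DM analysis.

    Deterministic accounting used as a fixture: the screening/exclusion
    cascade, the analytic sample by sex, baseline and incident case counts,
    and loss to follow-up. These are aggregate counts, not individual data.
    """

    screened: int = 10350
    excluded_t1dm: int = 2
    excluded_gdm: int = 11
    excluded_missing: int = 19
    men: int = 4671
    women: int = 5647
    baseline_cases_men: int = 481
    baseline_cases_women: int = 844
    lost_to_followup: int = 1185
    incident_men: int = 163
    incident_women: int = 231

    @property
    def analytic(self) -> int:
        return self.screened - self.excluded_t1dm - self.excluded_gdm - self.excluded_missing

    @property
    def baseline_cases(self) -> int:
        return self.baseline_cases_men + self.baseline_cases_women

    @property
    def incident(self) -> int:
        return self.incident_men + self.incident_women

    @property
    def multistate_analytic(self) -> int:
        return self.analytic - self.lost_to_followup

    def cascade(self) -> list[tuple[str, int]]:
        """Participant accounting from screening to the panel analysis."""
        return [
            ("screened_65_plus", self.screened),
            ("excluded_t1dm", self.excluded_t1dm),
            ("excluded_gdm", self.excluded_gdm),
            ("excluded_missing_t2dm_status", self.excluded_missing),
            ("analytic_sample", self.analytic),
            ("lost_to_followup", self.lost_to_followup),
            ("multistate_analytic_sample", self.multistate_analytic),
        ]

    def prevalence_table(self) -> pd.DataFrame:
        """Baseline T2DM counts by stratum, ready for Wilson intervals."""
        return pd.DataFrame(
            {"stratum": ["total", "men", "women"],
             "n": [self.men + self.women, self.men, self.women],
             "cases": [self.baseline_cases, self.baseline_cases_men,
                       self.baseline_cases_women]})


def henan_cohort_margins() -> CohortMargins:
    """The fixed marginal counts of the source cohort analysis."""
    return CohortMargins()
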