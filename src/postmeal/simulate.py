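"""Synthetic four-arm crossover postprandial CGM simulator.

Generates seeded flash-glucose traces with the structure of a two-meal ×
two-algorithm crossover breakfast trial: a 15-min sampling grid over
0–300 min, an early carbohydrate-driven rise, a delayed and protracted
protein/fat-driven rise, dose-dependent insulin lowering, between-subject
heterogeneity and autocorrelated sensor noise.

The model is a phenomenological linear superposition of gamma-like
response kernels, not a mechanistic insulin–glucose ODE:

    G(t) = baseline
           + carb_g   · s_carb · r_c(t)
           + pf_kcal  · s_pf   · r_p(t)
           − dose_U   · s_ins  · r_i(t)
           + ε(t)

with unit kernels r(t) = (t/t_peak)^k · exp(k·(1 − t/t_peak)) (zero at
t = 0, unique maximum 1 at t_peak) and AR(1) sensor noise ε.  If a
reading falls below 3.9 mmol/L, a 15-g carbohydrate rescue response is
superimposed from that reading's time onward (one rescue per
below-threshold run), mirroring the juice-per-event protocol; a
truncate-and-flag mode is available instead.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .dosing import BolusResult, PatientParams, cc_bolus, fpu_bolus
from .meals import HPFM, NPM, MealComposition
from .trace import ARMS, GlucoseTrace

HYPO_THRESHOLD = 3.9


@dataclass(frozen=True)
class ResponseKernel:
    """Unit postprandial response curve with a single peak."""

    peak_time: float
    shape: float

    def __post_init__(self) -> None:
        if self.peak_time <= 0:
            raise ValueError("peak_time must be positive")
        if self.shape <= 1:
            raise ValueError("shape must exceed 1")

    def __call__(self, t: np.ndarray | float) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        x = np.clip(t, 0.0, None) / self.peak_time
        with np.errstate(divide="ignore"):
            r = np.where(x > 0, x**self.shape * np.exp(self.shape * (1.0 - x)), 0.0)
        return r


@dataclass(frozen=True)
class SubjectProfile:
    """Effective per-subject parameters (population base × lognormal
    multipliers, already folded in)."""

    subject_id: str
    baseline_mmol_l: float
    carb_sensitivity: float  # mmol/L per g carbohydrate
    pf_sensitivity: float  # mmol/L per kcal protein/fat
    insulin_sensitivity: float  # mmol/L per insulin unit
    tdd_units: float

    def __post_init__(self) -> None:
        for f in ("carb_sensitivity", "pf_sensitivity", "insulin_sensitivity"):
            if getattr(self, f) <= 0:
                raise ValueError(f"{f} must be positive")
        if not (3.9 <= self.baseline_mmol_l <= 10.0):
            # trial exclusion window for fasting glucose on the test day
            raise ValueError("baseline must lie in [3.9, 10] mmol/L")
        if self.tdd_units <= 0:
            raise ValueError("tdd_units must be positive")


@dataclass(frozen=True)
class SimConfig:
    n_subjects: int = 30
    dt: float = 15.0
    horizon: float = 300.0
    noise_sd: float = 0.35
    ar1_rho: float = 0.5
    carb_kernel: ResponseKernel = field(default_factory=lambda: ResponseKernel(130.0, 5.0))
    pf_kernel: ResponseKernel = field(default_factory=lambda: ResponseKernel(260.0, 12.0))
    insulin_kernel: ResponseKernel = field(default_factory=lambda: ResponseKernel(250.0, 2.5))
    hypo_action: str = "rescue"  # "rescue" | "truncate" | "none"
    rescue_carb_g: float = 15.0
    glucose_floor: float = 2.2

    def __post_init__(self) -> None:
        if self.dt <= 0 or self.horizon % self.dt != 0:
            raise ValueError("dt must be positive and divide the horizon")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.ar1_rho < 1):
            raise ValueError("ar1_rho must lie in [0, 1)")
        if self.hypo_action not in ("rescue", "truncate", "none"):
            raise ValueError("hypo_action must be 'rescue', 'truncate' or 'none'")


@dataclass(frozen=True)
class PopulationParams:
    """Sampling distribution for subject profiles.

    Baselines are normal (clipped to the trial's fasting admission window),
    the TDD is lognormal, and each sensitivity carries an independent
    lognormal multiplier of the given log-scale SD.
    """

    baseline_mean: float = 6.5
    baseline_sd: float = 0.4
    tdd_mean: float = 31.8
    tdd_cv: float = 0.29
    carb_sensitivity: float = 0.160
    pf_sensitivity: float = 0.0167
    insulin_sensitivity: float = 1.86
    multiplier_log_sd: float = 0.25


def default_calibration() -> tuple[SimConfig, PopulationParams]:
    """Shipped default configuration and population.

    Kernel timings place the carbohydrate rise at ~2 h, the protein/fat
    rise at ~4.3 h, and the bolus's cumulative glycemic depression at
    ~4 h (the level deficit from a rapid-acting analog accumulates well
    after its plasma peak, and must outlast the late protein/fat rise
    for a larger dose to pull the peak of a high protein-fat meal back
    to the carbohydrate peak).  The three base sensitivities are a
    penalized fit of the noise-free superposition to the four printed
    0–300 min arm means (each within 1 mmol/L) and the printed arm
    peaks, subject to the observed peak-time ordering and the absence
    of deterministic hypoglycemia in the carbohydrate-counting arms.
    """
    return SimConfig(), PopulationParams()


def sample_population(
    pop: PopulationParams, n: int, rng: np.random.Generator
) -> list[SubjectProfile]:
    """Draw ``n`` subject profiles."""
    profiles = []
    for i in range(n):
        baseline = float(
            np.clip(rng.normal(pop.baseline_mean, pop.baseline_sd), 3.9, 10.0)
        )
        sigma = math.sqrt(math.log(1.0 + pop.tdd_cv**2))
        tdd = float(rng.lognormal(math.log(pop.tdd_mean) - 0.5 * sigma**2, sigma))
        mults = rng.lognormal(0.0, pop.multiplier_log_sd, size=3)
        profiles.append(
            SubjectProfile(
                subject_id=f"S{i + 1:02d}",
                baseline_mmol_l=baseline,
                carb_sensitivity=pop.carb_sensitivity * float(mults[0]),
                pf_sensitivity=pop.pf_sensitivity * float(mults[1]),
                insulin_sensitivity=pop.insulin_sensitivity * float(mults[2]),
                tdd_units=tdd,
            )
        )
    return profiles


def _ar1_noise(n: int, sd: float, rho: float, rng: np.random.Generator) -> np.ndarray:
    if sd == 0:
        return np.zeros(n)
    eps = np.empty(n)
    eps[0] = rng.normal(0.0, sd)
    innov_sd = sd * math.sqrt(1.0 - rho**2)
    for i in range(1, n):
        eps[i] = rho * eps[i - 1] + rng.normal(0.0, innov_sd)
    return eps


def simulate_subject(
    profile: SubjectProfile,
    meal: MealComposition,
    dose_units: float,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    arm: str = "",
) -> GlucoseTrace:
    """One postprandial trace for one subject, meal and delivered dose.

    With ``rng=None`` or ``noise_sd=0`` the trace is the deterministic
    kernel superposition.
    """
    times = np.arange(0.0, config.horizon + config.dt, config.dt)
    det = (
        profile.baseline_mmol_l
        + meal.carb_g * profile.carb_sensitivity * config.carb_kernel(times)
        + meal.protein_fat_kcal * profile.pf_sensitivity * config.pf_kernel(times)
        - dose_units * profile.insulin_sensitivity * config.insulin_kernel(times)
    )
    if rng is not None and config.noise_sd > 0:
        values = det + _ar1_noise(times.size, config.noise_sd, config.ar1_rho, rng)
    else:
        values = det.copy()

    if config.hypo_action == "rescue":
        # one superimposed 15-g carbohydrate response per below-threshold run
        in_hypo = False
        for i in range(values.size):
            if values[i] < HYPO_THRESHOLD and not in_hypo:
                in_hypo = True
                bump = (
                    config.rescue_carb_g
                    * profile.carb_sensitivity
                    * config.carb_kernel(times - times[i])
                )
                values = values + bump  # bump is 0 for t <= onset
            elif values[i] >= HYPO_THRESHOLD:
                in_hypo = False
    elif config.hypo_action == "truncate":
        below = np.flatnonzero(values < HYPO_THRESHOLD)
        if below.size > 0 and below[0] > 0:
            times = times[: below[0] + 1]
            values = values[: below[0] + 1]

    values = np.clip(values, config.glucose_floor, None)
    return GlucoseTrace(times=times, values=values, subject_id=profile.subject_id, arm=arm)


_ARM_DEFS = {
    "NPM-CC": (NPM, "cc"),
    "NPM-FPU": (NPM, "fpu"),
    "HPFM-CC": (HPFM, "cc"),
    "HPFM-FPU": (HPFM, "fpu"),
}


@dataclass
class TrialDataset:
    traces: list[GlucoseTrace]
    manifest: dict


def simulate_trial(
    config: SimConfig,
    pop: PopulationParams,
    seed: int,
    dosing_policies: dict[str, object] | None = None,
) -> TrialDataset:
    """Simulate a full four-arm crossover trial.

    Each subject keeps one profile across all four arms (within-subject
    crossover); the per-arm dose is computed from the subject's own ICR
    (500 rule on their TDD) with the arm's algorithm — carbohydrate
    counting for the -CC arms, the modified 200-kcal FPU rule for the
    -FPU arms — unless ``dosing_policies`` overrides an arm with a
    callable ``(meal, PatientParams) -> BolusResult``.
    """
    rng = np.random.default_rng(seed)
    profiles = sample_population(pop, config.n_subjects, rng)
    policies = {
        arm: (
            dosing_policies[arm]
            if dosing_policies and arm in dosing_policies
            else (cc_bolus if kind == "cc" else fpu_bolus)
        )
        for arm, (_, kind) in _ARM_DEFS.items()
    }
    traces: list[GlucoseTrace] = []
    subjects_meta = []
    for profile in profiles:
        params = PatientParams(tdd_units=profile.tdd_units)
        doses: dict[str, BolusResult] = {}
        for arm in ARMS:
            meal, _ = _ARM_DEFS[arm]
            bolus: BolusResult = policies[arm](meal, params)
            doses[arm] = bolus
            traces.append(
                simulate_subject(
                    profile, meal, bolus.delivered_units, config, rng=rng, arm=arm
                )
            )
        subjects_meta.append(
            {
                "subject_id": profile.subject_id,
                "baseline_mmol_l": profile.baseline_mmol_l,
                "carb_sensitivity": profile.carb_sensitivity,
                "pf_sensitivity": profile.pf_sensitivity,
                "insulin_sensitivity": profile.insulin_sensitivity,
                "tdd_units": profile.tdd_units,
                "icr_g_per_unit": params.icr_g_per_unit,
                "doses": {
                    arm: {
                        "algorithm": doses[arm].algorithm.value,
                        "total_units": doses[arm].total_units,
                        "delivered_units": doses[arm].delivered_units,
                    }
                    for arm in ARMS
                },
            }
        )
    manifest = {
        "seed": seed,
        "n_subjects": config.n_subjects,
        "arms": list(ARMS),
        "config": {
            "dt": config.dt,
            "horizon": config.horizon,
            "noise_sd": config.noise_sd,
            "ar1_rho": config.ar1_rho,
            "hypo_action": config.hypo_action,
            "rescue_carb_g": config.rescue_carb_g,
            "glucose_floor": config.glucose_floor,
            "carb_kernel": [config.carb_kernel.peak_time, config.carb_kernel.shape],
            "pf_kernel": [config.pf_kernel.peak_time, config.pf_kernel.shape],
            "insulin_kernel": [
                config.insulin_kernel.peak_time,
                config.insulin_kernel.shape,
            ],
        },
        "subjects": subjects_meta,
    }
    return TrialDataset(traces=traces, manifest=manifest)
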