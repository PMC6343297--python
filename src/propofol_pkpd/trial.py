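"""Synthetic trial generator emulating the adolescent scoliosis study design.

Fourteen adolescents receive a 4 mg/kg propofol induction bolus over
10 s, a titrated maintenance infusion (2-10 mg/kg/h, piecewise with a
few dose adjustments), an intraoperative wake-up test (infusion stopped
for a median ~21.5 min), a 3-5 mg/kg reinduction bolus, and a final
stop after 200-460 min of infusion.  Blood sampling follows the
clinical template (pre-induction, early venous, scheduled arterial
samples, around the wake-up test and each dose adjustment, and during
emergence; at most 25 samples).  BIS and cAAI are observed on a
regular grid, giving on the order of 100+ index values per subject.

Observations are simulated from the final population estimates
(defaults in :func:`default_truth`) with log-normal inter-individual
variability and the study's residual error models, so every pipeline
stage is testable without external data.  Dose adjustments are random
within the protocol range (the anesthesiologist was blinded to the
indices, so dosing is exogenous to the simulated PD signal).
"""

from __future__ import annotations

import math
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np

from .biophase import effect_site_from_states, pd_response
from .data import LLOQ, Observation, StudyDataset, Subject
from .params import BiophaseParameters, PDParameters, PKParameters
from .pk import BOLUS_DURATION_MIN, DoseEvent, solve_pk


@dataclass(frozen=True)
class TrialDesignConfig:
    """Design of one synthetic trial; defaults are the study protocol."""

    n_subjects: int = 14
    # covariates: median (min-max) from the study population
    weight_range: tuple[float, float] = (36.6, 82.0)
    weight_median: float = 51.0
    age_range: tuple[float, float] = (9.8, 20.1)
    age_median: float = 14.7
    male_fraction: float = 2.0 / 14.0
    remi_rate_range: tuple[float, float] = (0.2, 1.0)  # mcg/kg/min maintenance
    # dosing protocol
    induction_bolus_mg_per_kg: float = 4.0
    bolus_duration: float = BOLUS_DURATION_MIN
    maintenance_rate_range: tuple[float, float] = (2.0, 10.0)  # mg/kg/h
    n_adjust_range: tuple[int, int] = (1, 3)
    reinduction_bolus_mg_per_kg: tuple[float, float] = (3.0, 5.0)
    infusion_duration_range: tuple[float, float] = (200.0, 460.0)  # min
    infusion_duration_median: float = 410.0
    wakeup_window_frac: tuple[float, float] = (0.45, 0.65)
    wakeup_duration_range: tuple[float, float] = (7.6, 42.4)  # min
    wakeup_duration_median: float = 21.5
    roc_range: tuple[float, float] = (22.6, 116.33)  # return of consciousness, min
    roc_median: float = 52.2
    # observation design
    pd_interval: float = 4.0  # min between index observations
    pd_types: tuple[str, ...] = ("BIS", "cAAI")
    max_blood_samples: int = 25
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("weight_range", "age_range", "maintenance_rate_range",
                     "reinduction_bolus_mg_per_kg", "infusion_duration_range",
                     "wakeup_duration_range", "roc_range", "remi_rate_range"):
            lo, hi = getattr(self, name)
            if not (0 < lo <= hi):
                raise ValueError(f"{name} must be positive and ordered, got {(lo, hi)}")
        if not (0.0 < self.wakeup_window_frac[0] <= self.wakeup_window_frac[1] < 1.0):
            raise ValueError("wakeup window fractions must lie in (0, 1) and be ordered")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class TrueParameterSet:
    """Simulation truth: structural parameters, IIV and residual error."""

    pk: PKParameters
    omega2_pk: dict[str, float]
    sigma_log_conc: float  # residual SD on the log-concentration scale
    biophase: dict[str, BiophaseParameters]
    pd: dict[str, PDParameters]
    omega2_pd: dict[str, dict[str, float]]
    sigma2_pd: dict[str, float]


def default_truth() -> TrueParameterSet:
    """Final population estimates of the study (the simulation defaults).

    PK: CL 1.37 L/min, Q 1.15 L/min, V1 3.6 L, V2 76.8 L, IIV on CL
    22.1% CV, proportional residual SD 0.19 on the log scale.  BIS:
    two-compartment biophase (ke0 0.102, ke12 0.121, ke21 0.172 min^-1),
    E0 = Emax = 100, EC50 3.51 mg/L, gamma 1.43, additive sigma^2 59.5.
    cAAI: one-compartment biophase (ke0 0.067 min^-1), E0 63.4,
    Emax = 0.786*E0, EC50 2.14 mg/L, gamma 6.85, additive sigma^2 133.
    """
    omega2_cl = math.log(1.0 + 0.221**2)  # 22.1% CV on the log-normal scale
    return TrueParameterSet(
        pk=PKParameters(CL=1.37, Q=1.15, V1=3.6, V2=76.8),
        omega2_pk={"CL": omega2_cl},
        sigma_log_conc=0.19,
        biophase={
            "BIS": BiophaseParameters(ke0=0.102, ke12=0.121, ke21=0.172, order=2),
            "cAAI": BiophaseParameters(ke0=0.067, order=1),
        },
        pd={
            "BIS": PDParameters(E0=100.0, Emax=100.0, EC50=3.51, gamma=1.43),
            "cAAI": PDParameters(E0=63.4, Emax=0.786 * 63.4, EC50=2.14, gamma=6.85),
        },
        omega2_pd={
            "BIS": {"EC50": 0.059, "gamma": 0.117, "ke0": 0.192},
            "cAAI": {"EC50": 0.159, "gamma": 0.952, "ke0": 0.498},
        },
        sigma2_pd={"BIS": 59.5, "cAAI": 133.0},
    )


def _beta_params_from_median(lo: float, hi: float, median: float, a: float = 2.0):
    """Shape (a, b) of a scaled Beta with (approximately) the given median."""
    m = (median - lo) / (hi - lo)
    if not (0.0 < m < 1.0):
        raise ValueError("median must lie strictly inside the range")
    # Beta median ~ (a - 1/3) / (a + b - 2/3)
    b = (a - 1.0 / 3.0) / m - a + 2.0 / 3.0
    if b <= 0:
        raise ValueError("median too close to the range maximum for shape a")
    return a, b


def _draw_scaled_beta(rng, lo, hi, median, size=None):
    if hi == lo:
        return lo if size is None else np.full(size, lo)
    a, b = _beta_params_from_median(lo, hi, median)
    return lo + (hi - lo) * rng.beta(a, b, size=size)


def wakeup_segment(config: TrialDesignConfig, seed_or_rng) -> tuple[float, float]:
    """Draw the wake-up test (infusion stop, infusion resume) times.

    The stop time falls within the configured fraction of the infusion
    duration; the stop length follows a scaled Beta with median ~21.5
    min, truncated by construction to the configured range.
    """
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    duration = _draw_scaled_beta(
        rng, *config.infusion_duration_range, config.infusion_duration_median
    )
    frac = rng.uniform(*config.wakeup_window_frac)
    stop = frac * duration
    length = _draw_scaled_beta(
        rng, *config.wakeup_duration_range, config.wakeup_duration_median
    )
    return float(stop), float(stop + length)


def _wakeup_length(config: TrialDesignConfig, rng) -> float:
    lo, hi = config.wakeup_duration_range
    if lo == hi:
        return lo
    return float(_draw_scaled_beta(rng, lo, hi, config.wakeup_duration_median))


def _build_schedule(config: TrialDesignConfig, weight: float, rng):
    """Dose events plus the schedule landmarks for one subject."""
    rate_lo, rate_hi = config.maintenance_rate_range
    duration = float(_draw_scaled_beta(rng, *config.infusion_duration_range,
                                       config.infusion_duration_median))
    wake_start = float(rng.uniform(*config.wakeup_window_frac)) * duration
    wake_len = _wakeup_length(config, rng)
    wake_end = wake_start + wake_len
    if wake_end >= duration - 20.0:  # keep reinduction + final segment feasible
        wake_start = max(duration - 20.0 - wake_len, 1.0)
        wake_end = wake_start + wake_len
        if wake_end >= duration:
            raise ValueError("infeasible schedule: wake-up test does not fit inside the infusion")

    doses = [DoseEvent(start=0.0, amount=config.induction_bolus_mg_per_kg * weight,
                       duration=config.bolus_duration)]

    n_adjust = int(rng.integers(config.n_adjust_range[0], config.n_adjust_range[1] + 1))
    # adjustment times outside the wake-up gap, away from the edges
    adjustments = []
    tries = 0
    while len(adjustments) < n_adjust and tries < 100:
        t = float(rng.uniform(30.0, duration - 30.0))
        tries += 1
        if wake_start - 5.0 < t < wake_end + 5.0:
            continue
        if any(abs(t - u) < 15.0 for u in adjustments):
            continue
        adjustments.append(t)
    adjustments.sort()

    breaks = sorted({config.bolus_duration, *adjustments, wake_start, wake_end, duration})
    segments = []  # (start, end, rate mg/min) for the maintenance infusion
    rate = float(rng.uniform(rate_lo, rate_hi)) * weight / 60.0
    t0 = config.bolus_duration
    for t1 in breaks:
        if t1 <= t0:
            continue
        if not (wake_start <= t0 < wake_end):  # infusion off during wake-up
            segments.append((t0, t1, rate))
        if t1 in adjustments or t1 == wake_end:
            rate = float(rng.uniform(rate_lo, rate_hi)) * weight / 60.0
        t0 = t1
    for s, e, r in segments:
        if e > s and r > 0:
            doses.append(DoseEvent(start=s, amount=r * (e - s), duration=e - s))

    reinduction = config.reinduction_bolus_mg_per_kg
    doses.append(DoseEvent(start=wake_end, amount=float(rng.uniform(*reinduction)) * weight,
                           duration=config.bolus_duration))
    doses.sort(key=lambda d: d.start)
    return doses, dict(duration=duration, wake_start=wake_start, wake_end=wake_end,
                       adjustments=adjustments)


def _blood_sample_times(config: TrialDesignConfig, landmarks: dict, rng) -> list[float]:
    """Sampling template: venous pre/early samples then scheduled arterial ones."""
    D = landmarks["duration"]
    ws, we = landmarks["wake_start"], landmarks["wake_end"]
    times = [0.0]  # pre-induction (below LOQ by construction)
    times.append(float(rng.choice([15.0, 30.0])))
    for pair in ([45.0, 60.0], [120.0, 180.0], [240.0, 360.0]):
        t = float(rng.choice(pair))
        if t < D:
            times.append(t)
    times.append(ws + float(rng.uniform(5.0, 15.0)))  # after stopping for the wake-up
    times.append(we)  # at patient movement / end of the wake-up test
    if we + 60.0 < D:
        times.append(we + 60.0)  # 1 h after the reinduction dose change
    for t_adj in landmarks["adjustments"]:
        times.append(max(t_adj - 0.5, 0.0))  # just before the adjustment
        if t_adj + 60.0 < D:
            times.append(t_adj + 60.0)  # one hour after
    times.append(D - 0.5)  # just before stopping
    times.append(D + float(rng.choice([15.0, 30.0])))
    times.append(D + float(rng.choice([45.0, 60.0])))
    times.append(D + 120.0)
    times = sorted(set(round(t, 3) for t in times if t >= 0.0))
    return times[: config.max_blood_samples]


def generate_trial(
    config: Optional[TrialDesignConfig] = None,
    truth: Optional[TrueParameterSet] = None,
    seed: Optional[int] = None,
    return_truth: bool = False,
):
    """Simulate a full synthetic trial; fully reproducible from the seed.

    Per subject: covariates drawn within the study ranges, the dosing
    schedule built from the protocol template, true individual
    parameters drawn log-normally, concentrations and index values
    simulated through the PK and biophase/Emax models, and residual
    noise added per the residual error models (proportional on the log
    concentration scale; additive in index units).

    With ``return_truth=True`` also returns a record of the realized
    individual parameters (one dict per subject), useful for
    parameter-recovery experiments against the drawn truth.
    """
    config = config or TrialDesignConfig()
    truth = truth or default_truth()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    truth_log: list[dict] = []
    subjects = []
    for i in range(config.n_subjects):
        weight = float(_draw_scaled_beta(rng, *config.weight_range, config.weight_median))
        age = float(_draw_scaled_beta(rng, *config.age_range, config.age_median))
        sex = "M" if rng.uniform() < config.male_fraction else "F"
        remi = float(rng.uniform(*config.remi_rate_range))
        doses, landmarks = _build_schedule(config, weight, rng)

        # individual parameters (log-normal IIV)
        eta_cl = rng.normal(0.0, math.sqrt(truth.omega2_pk.get("CL", 0.0)))
        pk_i = truth.pk.replace(CL=truth.pk.CL * math.exp(eta_cl))
        subj_truth: dict = {"id": f"S{i + 1:02d}", "CL": pk_i.CL}

        obs: list[Observation] = []
        # blood samples
        t_blood = np.array(_blood_sample_times(config, landmarks, rng))
        conc = solve_pk(pk_i, doses, t_blood).cb
        for t, c in zip(t_blood, conc):
            if c < LLOQ:
                obs.append(Observation(time=float(t), value=float(c), obs_type="conc",
                                       below_loq=True))
            else:
                noisy = math.exp(math.log(c) + rng.normal(0.0, truth.sigma_log_conc))
                obs.append(Observation(time=float(t), value=float(noisy), obs_type="conc",
                                       below_loq=noisy < LLOQ))

        # depth-of-anesthesia indices on a regular grid
        roc = float(_draw_scaled_beta(rng, *config.roc_range, config.roc_median))
        for index in config.pd_types:
            bp_t, pd_t = truth.biophase[index], truth.pd[index]
            om = truth.omega2_pd.get(index, {})
            ec50_i = pd_t.EC50 * math.exp(rng.normal(0.0, math.sqrt(om.get("EC50", 0.0))))
            gamma_i = pd_t.gamma * math.exp(rng.normal(0.0, math.sqrt(om.get("gamma", 0.0))))
            ke0_i = bp_t.ke0 * math.exp(rng.normal(0.0, math.sqrt(om.get("ke0", 0.0))))
            bp_i = BiophaseParameters(ke0=ke0_i, ke12=bp_t.ke12, ke21=bp_t.ke21, order=bp_t.order)
            pd_i = PDParameters(E0=pd_t.E0, Emax=pd_t.Emax, EC50=ec50_i, gamma=gamma_i)
            subj_truth[f"EC50_{index}"] = ec50_i
            subj_truth[f"gamma_{index}"] = gamma_i
            subj_truth[f"ke0_{index}"] = ke0_i
            # monitored from before induction (awake baseline at t=0);
            # cAAI until the end of infusion, BIS also during emergence
            t_end = landmarks["duration"] + (roc if index == "BIS" else 0.0)
            t_grid = np.arange(0.0, t_end, config.pd_interval)
            ce = effect_site_from_states(pk_i, bp_i, doses, t_grid)
            signal = pd_response(ce, pd_i)
            sd = math.sqrt(truth.sigma2_pd.get(index, 0.0))
            noise = rng.normal(0.0, sd, size=t_grid.size) if sd > 0 else np.zeros(t_grid.size)
            for t, v in zip(t_grid, signal + noise):
                obs.append(Observation(time=float(t), value=float(v), obs_type=index))

        obs.sort(key=lambda o: (o.time, o.obs_type))
        truth_log.append(subj_truth)
        subjects.append(
            Subject(id=f"S{i + 1:02d}", weight=weight, age=age, sex=sex, remi_rate=remi,
                    doses=doses, observations=obs)
        )
    dataset = StudyDataset(subjects)
    if return_truth:
        return dataset, truth_log
    return dataset
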