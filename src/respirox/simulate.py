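"""Synthetic closed-chamber respirometry traces with known ground truth.

The chamber model: a sealed acrylic chamber of volume V (L) holds an
exercised animal whose oxygen demand decays exponentially from a
post-chase peak toward a resting floor, while realised uptake is capped
by an oxygen-supply line proportional to ambient PO2:

    demand(t)   = smr + (mmr0 - smr) * exp(-t / recovery_tau)
    uptake(t,P) = min(demand(t), alpha_true * P)

Sealed-phase dynamics (P in kPa, beta the oxygen capacitance umol/L/kPa,
V_eff = V - mass/1000):

    dP/dt = -(uptake * mass + microbial_rate * V_eff) / (beta * V_eff)

Flush phases relax P exponentially toward the trial's start PO2
(time constant 60 s by default). Sensor noise is additive Gaussian in
% air-saturation space, matching the probe's native units.

Integration is classical RK4 on the sample grid; the linear/exponential
regimes are reproduced to ~1e-9 relative at a 1 s step.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigError
from .traces import Trace, UNIT_PERCENT_SAT, effective_volume
from .units import WaterConditions, kpa_to_percent_sat, po2_at_saturation, solubility_per_kpa

__all__ = [
    "AnimalModel",
    "TrialProtocol",
    "ChamberSpec",
    "TrialTruth",
    "SimulatedTrial",
    "GroupSpec",
    "CohortConfig",
    "Cohort",
    "simulate_trial",
    "simulate_microbial_check",
    "simulate_cohort",
]

TRIAL_TYPES = ("mmr", "hypoxia", "blank")


@dataclass(frozen=True)
class AnimalModel:
    """Ground-truth physiology of one simulated animal.

    Rates are mass-specific (umol O2 g-1 h-1); ``alpha_true`` is the
    oxygen supply capacity (umol O2 g-1 h-1 kPa-1); ``recovery_tau`` (h)
    controls the exponential decay of excess post-exercise demand.
    """

    mass: float
    smr: float
    mmr0: float
    alpha_true: float
    recovery_tau: float = 1.5
    animal_id: str = ""

    def __post_init__(self) -> None:
        if not self.mass > 0:
            raise ConfigError(f"mass={self.mass} must be > 0")
        if not 0 < self.smr < self.mmr0:
            raise ConfigError(
                f"need 0 < smr < mmr0 (got smr={self.smr}, mmr0={self.mmr0})"
            )
        if not self.alpha_true > 0:
            raise ConfigError(f"alpha_true={self.alpha_true} must be > 0")
        if not self.recovery_tau > 0:
            raise ConfigError(f"recovery_tau={self.recovery_tau} must be > 0")

    def demand(self, t_h: float) -> float:
        return self.smr + (self.mmr0 - self.smr) * math.exp(-t_h / self.recovery_tau)


@dataclass(frozen=True)
class TrialProtocol:
    trial_type: str               # mmr | hypoxia | blank
    start_po2: float              # kPa
    n_measure_periods: int = 3
    measure_duration: float = 15.0   # min
    flush_duration: float = 4.0      # min
    end_po2_floor: float = 2.0       # kPa, hypoxia stop
    sample_interval: float = 1.0     # s
    noise_sd: float = 0.1            # % air saturation
    flush_tau: float = 60.0          # s
    max_duration_h: float = 8.0      # safety cap on total trial length

    def __post_init__(self) -> None:
        if self.trial_type not in TRIAL_TYPES:
            raise ConfigError(f"trial_type must be one of {TRIAL_TYPES}")
        if not self.start_po2 > self.end_po2_floor >= 0:
            raise ConfigError("need start_po2 > end_po2_floor >= 0")
        for name in ("n_measure_periods", "measure_duration", "flush_duration",
                     "sample_interval", "flush_tau"):
            if not getattr(self, name) > 0:
                raise ConfigError(f"{name} must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ChamberSpec:
    volume: float                 # L
    microbial_rate: float = 0.0   # umol O2 L-1 h-1, volumetric background

    def __post_init__(self) -> None:
        if not self.volume > 0:
            raise ConfigError(f"volume={self.volume} must be > 0")
        if self.microbial_rate < 0:
            raise ConfigError("microbial_rate must be >= 0")


@dataclass
class TrialTruth:
    """Noise-free state recorded alongside a simulated trace."""

    time_s: np.ndarray
    po2_kpa: np.ndarray            # true chamber PO2
    mo2_umol_g_h: np.ndarray       # realised animal uptake
    demand_umol_g_h: np.ndarray
    phase: np.ndarray
    supply_limited_onset_po2: float | None
    animal: AnimalModel | None
    protocol: TrialProtocol
    chamber: ChamberSpec
    cond: WaterConditions


@dataclass
class SimulatedTrial:
    trace: Trace
    truth: TrialTruth


def _rk4_sealed(p, t_h, dt_h, uptake, mass, microbial, beta, veff):
    denom = beta * veff

    def rhs(th, pp):
        return -(uptake(th, max(pp, 0.0)) * mass + microbial * veff) / denom

    k1 = rhs(t_h, p)
    k2 = rhs(t_h + dt_h / 2, p + dt_h / 2 * k1)
    k3 = rhs(t_h + dt_h / 2, p + dt_h / 2 * k2)
    k4 = rhs(t_h + dt_h, p + dt_h * k3)
    return max(p + dt_h / 6 * (k1 + 2 * k2 + 2 * k3 + k4), 0.0)


def simulate_trial(
    animal: AnimalModel | None,
    protocol: TrialProtocol,
    chamber: ChamberSpec,
    cond: WaterConditions,
    seed,
) -> SimulatedTrial:
    """Simulate one chamber trial and return the noisy trace plus truth.

    ``mmr`` trials run ``n_measure_periods`` sealed periods separated by
    flushes; ``hypoxia`` trials keep the chamber sealed after the last
    period until PO2 reaches ``end_po2_floor``; ``blank`` trials carry no
    animal and decline only through the microbial rate.
    """
    blank = protocol.trial_type == "blank"
    if not blank and animal is None:
        raise ConfigError("non-blank trials need an AnimalModel")
    mass = 0.0 if blank or animal is None else animal.mass
    if mass / 1000.0 >= chamber.volume:
        raise ConfigError(
            f"animal volume ({mass / 1000.0} L) >= chamber volume "
            f"({chamber.volume} L)"
        )
    veff = effective_volume(chamber.volume, mass) if mass else chamber.volume
    beta = solubility_per_kpa(cond)

    if blank or animal is None:
        def uptake(t_h, p):  # noqa: ARG001 - signature shared with animal case
            return 0.0
        def demand(t_h):  # noqa: ARG001
            return 0.0
    else:
        alpha = animal.alpha_true
        def uptake(t_h, p):
            return min(animal.demand(t_h), alpha * p)
        demand = animal.demand

    dt = protocol.sample_interval
    dt_h = dt / 3600.0
    n_meas = max(1, int(round(protocol.measure_duration * 60.0 / dt)))
    n_flush = max(1, int(round(protocol.flush_duration * 60.0 / dt)))
    max_steps = int(protocol.max_duration_h * 3600.0 / dt)
    flush_decay = math.exp(-dt / protocol.flush_tau)

    t, p = 0.0, protocol.start_po2
    times = [t]
    po2 = [p]
    phases = ["sealed_0"]
    step = 0
    for period in range(protocol.n_measure_periods):
        label = f"sealed_{period}"
        last = period == protocol.n_measure_periods - 1
        n_steps = n_meas
        k = 0
        while k < n_steps or (
            last
            and protocol.trial_type == "hypoxia"
            and p > protocol.end_po2_floor
            and step < max_steps
        ):
            p = _rk4_sealed(p, t / 3600.0, dt_h, uptake, mass,
                            chamber.microbial_rate, beta, veff)
            t += dt
            times.append(t)
            po2.append(p)
            phases.append(label)
            k += 1
            step += 1
        if not last:
            label = f"flush_{period}"
            for _ in range(n_flush):
                p = protocol.start_po2 + (p - protocol.start_po2) * flush_decay
                t += dt
                times.append(t)
                po2.append(p)
                phases.append(label)
                step += 1

    time_s = np.asarray(times)
    po2_true = np.asarray(po2)
    phase = np.asarray(phases, dtype=object)
    t_h_arr = time_s / 3600.0
    demand_arr = np.array([demand(th) for th in t_h_arr])
    mo2_arr = np.minimum(demand_arr, (animal.alpha_true if not blank and animal else 0.0) * po2_true) \
        if not blank and animal else np.zeros_like(po2_true)

    onset = None
    if not blank and animal is not None:
        sealed = np.char.startswith(phase.astype(str), "sealed")
        limited = (animal.alpha_true * po2_true < demand_arr) & sealed
        idx = np.flatnonzero(limited)
        if idx.size:
            onset = float(po2_true[idx[0]])

    rng = np.random.default_rng(seed)
    obs_pct = kpa_to_percent_sat(po2_true, cond)
    if protocol.noise_sd > 0:
        obs_pct = obs_pct + rng.normal(0.0, protocol.noise_sd, obs_pct.size)
    obs_pct = np.maximum(obs_pct, 0.0)

    trace = Trace(time_s=time_s, o2=obs_pct, unit=UNIT_PERCENT_SAT,
                  cond=cond, phase=phase.copy())
    truth = TrialTruth(
        time_s=time_s.copy(),
        po2_kpa=po2_true,
        mo2_umol_g_h=mo2_arr,
        demand_umol_g_h=demand_arr,
        phase=phase,
        supply_limited_onset_po2=onset,
        animal=animal,
        protocol=protocol,
        chamber=chamber,
        cond=cond,
    )
    return SimulatedTrial(trace=trace, truth=truth)


def simulate_microbial_check(
    chamber: ChamberSpec,
    cond: WaterConditions,
    duration_h: float,
    seed,
    sample_interval: float = 1.0,
    noise_sd: float = 0.1,
    start_po2: float | None = None,
) -> SimulatedTrial:
    """Blank (empty, sealed chamber) trace over ``duration_h`` hours."""
    if not duration_h > 0:
        raise ConfigError("duration_h must be > 0")
    start = po2_at_saturation(cond) if start_po2 is None else start_po2
    protocol = TrialProtocol(
        trial_type="blank",
        start_po2=start,
        n_measure_periods=1,
        measure_duration=duration_h * 60.0,
        sample_interval=sample_interval,
        noise_sd=noise_sd,
        max_duration_h=duration_h + 1.0,
    )
    return simulate_trial(None, protocol, chamber, cond, seed)


# ---------------------------------------------------------------------------
# cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupSpec:
    """Distributional description of one salinity treatment group."""

    salinity_psu: float
    alpha_mean: float            # group-level supply capacity at common mass
    mass_median: float           # g, lognormal median
    n: int = 6
    alpha_sd: float = 0.05
    mass_sigma: float = 0.45     # lognormal shape

    def __post_init__(self) -> None:
        if self.n < 1 or self.alpha_mean <= 0 or self.alpha_sd < 0:
            raise ConfigError("invalid group distribution parameters")
        if self.mass_median <= 0 or self.mass_sigma < 0:
            raise ConfigError("invalid mass distribution parameters")


# Group alpha means follow the observed per-salinity supply capacities
# (0.56 / 0.60 / 0.68 for 32 / 16 / 6 psu); group mass medians follow the
# per-group mean masses; peak demand is shared across groups.
DEFAULT_GROUPS = (
    GroupSpec(salinity_psu=32.0, alpha_mean=0.56, mass_median=477.67),
    GroupSpec(salinity_psu=16.0, alpha_mean=0.60, mass_median=407.33),
    GroupSpec(salinity_psu=6.0, alpha_mean=0.68, mass_median=807.11),
)


@dataclass(frozen=True)
class CohortConfig:
    groups: tuple[GroupSpec, ...] = DEFAULT_GROUPS
    mmr0_mean: float = 9.0        # umol O2 g-1 h-1 at the common mass
    mmr0_sd: float = 1.0
    smr_ratio: float = 1.0 / 3.0  # smr = smr_ratio * mmr0 (placeholder; no
                                  # measured resting rate exists for this species)
    scaling_b: float = -0.1       # mass exponent applied to mmr0 and alpha
    common_mass: float = 594.1    # g
    recovery_tau: float = 1.5     # h
    microbial_rate: float = 1.5   # umol O2 L-1 h-1 (~2 % of total uptake)
    temperature_c: float = 26.0
    pressure_kpa: float = 101.325
    mass_range: tuple[float, float] = (160.0, 1036.0)
    mmr_start_po2: tuple[float, ...] = (21.0, 27.0)
    hypoxia_start_po2: float = 11.7
    blank_duration_h: float = 1.0
    sample_interval: float = 1.0
    noise_sd: float = 0.1
    chamber_volumes: tuple[float, ...] = (9.0, 25.0, 40.0)
    chamber_mass_cutoffs: tuple[float, ...] = (250.0, 550.0)

    def __post_init__(self) -> None:
        if self.mmr0_mean <= 0 or self.mmr0_sd < 0:
            raise ConfigError("invalid mmr0 distribution parameters")
        if not 0 < self.smr_ratio < 1:
            raise ConfigError("smr_ratio must be in (0, 1)")
        if self.microbial_rate < 0:
            raise ConfigError("microbial_rate must be >= 0")
        if len(self.chamber_volumes) != len(self.chamber_mass_cutoffs) + 1:
            raise ConfigError("need one more chamber volume than mass cutoff")


@dataclass
class Cohort:
    manifest: pd.DataFrame
    traces: dict[str, Trace]
    truth: pd.DataFrame
    params: dict


def _pick_chamber(config: CohortConfig, mass: float) -> float:
    for cutoff, vol in zip(config.chamber_mass_cutoffs, config.chamber_volumes):
        if mass <= cutoff:
            return vol
    return config.chamber_volumes[-1]


def simulate_cohort(config: CohortConfig, seed) -> Cohort:
    """Generate a full cohort: manifest, traces and ground-truth table.

    Per animal: one MMR trial per entry of ``mmr_start_po2``, one hypoxia
    trial starting at ``hypoxia_start_po2`` (whose first measurement
    periods double as the low-PO2 MMR trial), and one blank. Group-level
    alpha and mmr0 draws are scaled by ``(mass / common_mass)**scaling_b``
    so mass re-scaling to the common mass recovers the group values.
    """
    root = np.random.SeedSequence(seed) if not isinstance(seed, np.random.SeedSequence) else seed
    n_total = sum(g.n for g in config.groups)
    children = root.spawn(n_total + 1)
    draw_rng = np.random.default_rng(children[0])

    manifest_rows = []
    truth_rows = []
    traces: dict[str, Trace] = {}
    animal_idx = 0
    for group in config.groups:
        cond = WaterConditions(
            temperature_c=config.temperature_c,
            salinity_psu=group.salinity_psu,
            pressure_kpa=config.pressure_kpa,
        )
        for i in range(group.n):
            animal_id = f"s{int(group.salinity_psu):02d}_{i + 1:02d}"
            mass = float(np.clip(
                draw_rng.lognormal(math.log(group.mass_median), group.mass_sigma),
                *config.mass_range,
            ))
            alpha_base = max(float(draw_rng.normal(group.alpha_mean, group.alpha_sd)), 0.05)
            mmr0_base = max(float(draw_rng.normal(config.mmr0_mean, config.mmr0_sd)), 2.0)
            scale = (mass / config.common_mass) ** config.scaling_b
            alpha_true = alpha_base * scale
            mmr0 = mmr0_base * scale
            smr = config.smr_ratio * mmr0
            animal = AnimalModel(
                mass=mass, smr=smr, mmr0=mmr0, alpha_true=alpha_true,
                recovery_tau=config.recovery_tau, animal_id=animal_id,
            )
            volume = _pick_chamber(config, mass)
            chamber = ChamberSpec(volume=volume, microbial_rate=config.microbial_rate)
            trial_seeds = children[1 + animal_idx].spawn(
                len(config.mmr_start_po2) + 2
            )

            specs = [
                (f"{animal_id}_mmr{po2:g}", "mmr", po2)
                for po2 in config.mmr_start_po2
            ]
            specs.append((f"{animal_id}_hyp", "hypoxia", config.hypoxia_start_po2))
            for (trial_id, ttype, start), tseed in zip(specs, trial_seeds):
                protocol = TrialProtocol(
                    trial_type=ttype,
                    start_po2=start,
                    sample_interval=config.sample_interval,
                    noise_sd=config.noise_sd,
                )
                sim = simulate_trial(animal, protocol, chamber, cond, tseed)
                traces[trial_id] = sim.trace
                manifest_rows.append(
                    dict(
                        trial_id=trial_id,
                        animal_id=animal_id,
                        group_psu=group.salinity_psu,
                        salinity_psu=group.salinity_psu,
                        temp_C=config.temperature_c,
                        chamber_volume_L=volume,
                        animal_mass_g=mass,
                        trial_type=ttype,
                        start_po2_kpa=start,
                        trace_file=f"traces/{trial_id}.csv",
                    )
                )
            blank_id = f"{animal_id}_blank"
            sim = simulate_microbial_check(
                chamber, cond, config.blank_duration_h, trial_seeds[-1],
                sample_interval=config.sample_interval, noise_sd=config.noise_sd,
            )
            traces[blank_id] = sim.trace
            manifest_rows.append(
                dict(
                    trial_id=blank_id,
                    animal_id=animal_id,
                    group_psu=group.salinity_psu,
                    salinity_psu=group.salinity_psu,
                    temp_C=config.temperature_c,
                    chamber_volume_L=volume,
                    animal_mass_g=mass,
                    trial_type="blank",
                    start_po2_kpa=float(po2_at_saturation(cond)),
                    trace_file=f"traces/{blank_id}.csv",
                )
            )
            truth_rows.append(
                dict(
                    animal_id=animal_id,
                    group_psu=group.salinity_psu,
                    mass_g=mass,
                    chamber_volume_L=volume,
                    alpha_group_draw=alpha_base,
                    alpha_true=alpha_true,
                    mmr0=mmr0,
                    smr=smr,
                    recovery_tau_h=config.recovery_tau,
                    pc_true=mmr0 / alpha_true,
                )
            )
            animal_idx += 1

    from dataclasses import asdict

    params = asdict(config)
    params["seed"] = str(seed)
    return Cohort(
        manifest=pd.DataFrame(manifest_rows),
        traces=traces,
        truth=pd.DataFrame(truth_rows),
        params=params,
    )
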