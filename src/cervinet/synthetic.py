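"""Synthetic whiplash cohorts with a known ground-truth recovery model.

No public recording of the clinical cohort exists, so this module
generates data with the statistical structure the analysis assumes:

* five severity profiles in which mean ROM and speed decrease — and ROM
  CV increases — with severity type, and rotation is always the fastest
  movement, followed by flexion-extension, then lateral bending;
* baseline type proportions 3.69 / 16.82 / 24.67 / 31.23 / 23.56 %;
* demographics: age 37 +/- 12.88 y, 55.1 % female, height 1.67 +/- 0.09 m,
  mass 72.41 +/- 15.47 kg;
* 45-s self-paced oscillatory traces per movement, built cycle by cycle
  as a raised-cosine oscillation with lognormal per-cycle amplitude
  jitter (controlling ROM CV) and +/-10 % period jitter;
* a tunable linear-with-saturation recovery model mapping standardized
  baseline predictors to the true NFHAS change, plus Gaussian noise,
  whose coefficients are stored so parameter recovery can be tested.

All randomness derives from one global seed through counter-based
substreams (patient index, movement index), so any patient's data is
reproducible independent of generation order.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from .kinematics import (
    DEFAULT_NORMATIVE_ROM,
    AngleTrace,
    MovementSummary,
    normative_rom,
)
from .nfhas import MOVEMENTS, nfhas_score
from .preprocessing import FEATURE_NAMES, AssessmentRecord, records_to_frame

__all__ = [
    "SeverityProfile",
    "RecoveryModelSpec",
    "SyntheticConfig",
    "SyntheticCohort",
    "default_severity_profiles",
    "default_recovery_spec",
    "generate_trace",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

#: Baseline severity-type proportions reported for the clinical cohort
#: (3.69/16.82/24.67/31.23/23.56 %; renormalized — the printed values sum
#: to 99.97 % from rounding).
_RAW_PROPS = np.array([0.0369, 0.1682, 0.2467, 0.3123, 0.2356])
BASELINE_TYPE_PROPORTIONS = tuple(float(p) for p in _RAW_PROPS / _RAW_PROPS.sum())

#: Per-axis peak-speed scale (deg/s) at full mobility; rotation fastest,
#: then flexion-extension, then lateral bending.
_SPEED_SCALE = {"F": 75.0, "E": 75.0, "Llb": 55.0, "Rlb": 55.0, "Lrt": 95.0, "Rrt": 95.0}

#: Reference normative ROM (degrees) used to anchor profile means; the
#: 35-49 band of the shipped normative table.
_REFERENCE_ROM = DEFAULT_NORMATIVE_ROM["35-49"]


@dataclass(frozen=True)
class SeverityProfile:
    """Kinematic population means for one NFHAS severity type."""

    nfhas_type: int
    mean_rom_by_movement: dict[str, float]  # degrees
    mean_speed_by_movement: dict[str, float]  # deg/s
    mean_cv_by_movement: dict[str, float]  # percent
    rom_dispersion: float = 0.08  # lognormal sigma of between-patient ROM
    speed_dispersion: float = 0.10
    cv_dispersion: float = 0.15

    def __post_init__(self) -> None:
        if self.nfhas_type not in (1, 2, 3, 4, 5):
            raise ValueError("nfhas_type must be 1..5")
        for d in (
            self.mean_rom_by_movement,
            self.mean_speed_by_movement,
            self.mean_cv_by_movement,
        ):
            if set(d) != set(MOVEMENTS):
                raise ValueError("profile must cover all six movements")
            if any(v <= 0 for v in d.values()):
                raise ValueError("profile means must be strictly positive")


@dataclass(frozen=True)
class RecoveryModelSpec:
    """Ground-truth mapping from baseline predictors to true NFHAS change.

    true_change = intercept + sum_i coefficients[i] * z_i + noise, where
    z_i standardizes the i-th raw predictor with the *population*
    reference scale implied by the severity profiles (not the realized
    sample), then saturated so the follow-up NFHAS stays in [0, 100].
    """

    coefficients: tuple[float, ...]
    intercept: float = 10.0
    nonlinearity: str = "saturating"  # "none" | "saturating"
    noise_sd: float = 27.0  # NFHAS points
    group_proportions: tuple[float, ...] = BASELINE_TYPE_PROPORTIONS

    def __post_init__(self) -> None:
        if len(self.coefficients) != len(FEATURE_NAMES):
            raise ValueError(f"need {len(FEATURE_NAMES)} coefficients")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        p = np.asarray(self.group_proportions, dtype=float)
        if p.shape != (5,) or (p < 0).any() or (p > 1).any():
            raise ValueError("five proportions in [0, 1] required")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("group proportions must sum to 1")


@dataclass(frozen=True)
class SyntheticConfig:
    n_patients: int
    seed: int = 0
    severity_profiles: tuple[SeverityProfile, ...] = None  # type: ignore[assignment]
    recovery: RecoveryModelSpec = None  # type: ignore[assignment]
    age_mean: float = 37.0
    age_sd: float = 12.88
    fraction_female: float = 0.551
    height_mean: float = 1.67
    height_sd: float = 0.09
    mass_mean: float = 72.41
    mass_sd: float = 15.47
    trace_duration: float = 45.0
    trace_rate: float = 50.0  # Hz
    period_jitter: float = 0.10  # +/- fraction of the base period

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if self.trace_duration <= 0 or self.trace_rate <= 0:
            raise ValueError("trace duration and rate must be positive")
        if self.severity_profiles is None:
            object.__setattr__(
                self, "severity_profiles", default_severity_profiles()
            )
        if self.recovery is None:
            object.__setattr__(self, "recovery", default_recovery_spec())
        if len(self.severity_profiles) != 5:
            raise ValueError("exactly five severity profiles required")


def default_severity_profiles() -> tuple[SeverityProfile, ...]:
    """Five evenly graded profiles from full mobility to severe limitation.

    ROM spans 100 % -> 30 % of normative across types 1 -> 5, speed falls
    with the same factor, and ROM CV climbs from 4 % to 16 %.
    """
    rom_fractions = (1.00, 0.825, 0.65, 0.475, 0.30)
    cv_means = (4.0, 7.0, 10.0, 13.0, 16.0)
    profiles = []
    for k in range(5):
        f = rom_fractions[k]
        profiles.append(
            SeverityProfile(
                nfhas_type=k + 1,
                mean_rom_by_movement={m: f * _REFERENCE_ROM[m] for m in MOVEMENTS},
                mean_speed_by_movement={m: f * _SPEED_SCALE[m] for m in MOVEMENTS},
                mean_cv_by_movement={m: cv_means[k] for m in MOVEMENTS},
            )
        )
    return tuple(profiles)


def default_recovery_spec(noise_sd: float = 27.0) -> RecoveryModelSpec:
    """Default ground truth: patients with less baseline mobility improve more.

    Normalized-ROM predictors carry negative weights (room to improve),
    ROM CV a small positive weight (inconsistent movers regress toward
    cleaner movement), speed a small negative weight.  The default noise
    level places the predictor's held-out correlation in the moderate
    range clinical cohorts show (R around 0.5).
    """
    coeffs = []
    for name in FEATURE_NAMES:
        if name.startswith("rom_normalized"):
            coeffs.append(-1.6)
        elif name.startswith("cv"):
            coeffs.append(0.5)
        else:  # speed_to_peak
            coeffs.append(-0.4)
    return RecoveryModelSpec(
        coefficients=tuple(coeffs), intercept=10.0, noise_sd=noise_sd
    )


# ---------------------------------------------------------------------------
# Counter-based substreams: reproducibility independent of generation order.

def _rng(seed: int, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


# stream ids for spawn keys
_S_TYPE, _S_DEMOG, _S_KINE, _S_NOISE, _S_TRACE = 0, 1, 2, 3, 4


def generate_trace(
    movement: str,
    profile: SeverityProfile,
    duration: float = 45.0,
    rate: float = 50.0,
    seed: int = 0,
    period_jitter: float = 0.10,
) -> AngleTrace:
    """One self-paced oscillatory recording for a movement.

    The trace is a concatenation of raised-cosine cycles 0 -> R_k -> 0.
    Per-cycle excursions R_k are lognormal with the profile's mean ROM and
    ROM CV for the movement; cycle periods take the base period implied by
    the profile's mean speed (peak speed of a raised cosine of excursion R
    and period T is pi*R/T) jittered uniformly by +/- ``period_jitter``.
    Deterministic given the seed.
    """
    if duration <= 0 or rate <= 0:
        raise ValueError("duration and rate must be positive")
    if movement not in MOVEMENTS:
        raise ValueError(f"unknown movement {movement!r}")
    rng = _rng(seed, _S_TRACE)
    mean_rom = profile.mean_rom_by_movement[movement]
    mean_speed = profile.mean_speed_by_movement[movement]
    cv = profile.mean_cv_by_movement[movement] / 100.0
    base_period = np.pi * mean_rom / mean_speed

    t = np.arange(0.0, duration, 1.0 / rate)
    angle = np.zeros_like(t)
    start = 0.0
    while start < duration:
        period = base_period * (1.0 + rng.uniform(-period_jitter, period_jitter))
        if cv > 0:
            sigma = np.sqrt(np.log1p(cv * cv))
            rom_k = mean_rom * np.exp(rng.normal(-0.5 * sigma * sigma, sigma))
        else:
            rom_k = mean_rom
        in_cycle = (t >= start) & (t < start + period)
        tau = t[in_cycle] - start
        angle[in_cycle] = 0.5 * rom_k * (1.0 - np.cos(2.0 * np.pi * tau / period))
        start += period
    return AngleTrace(movement=movement, time=t, angle=np.clip(angle, -180.0, 180.0))


def _population_reference_scale(
    config: SyntheticConfig,
) -> tuple[np.ndarray, np.ndarray]:
    """Population mean and sd of each raw predictor implied by the config.

    Mixture moments over severity types (weighted by the group
    proportions) of the per-type lognormal patient-mean distributions.
    Normalized ROM uses the reference normative table band, matching the
    anchor of the profile means.
    """
    props = np.asarray(config.recovery.group_proportions, dtype=float)
    means = np.zeros(len(FEATURE_NAMES))
    second = np.zeros(len(FEATURE_NAMES))
    for prof, w in zip(config.severity_profiles, props):
        mu = []
        var = []
        for block, disp in (
            ("rom", prof.rom_dispersion),
            ("cv", prof.cv_dispersion),
            ("speed", prof.speed_dispersion),
        ):
            for m in MOVEMENTS:
                if block == "rom":
                    base = 100.0 * prof.mean_rom_by_movement[m] / _REFERENCE_ROM[m]
                elif block == "cv":
                    base = prof.mean_cv_by_movement[m]
                else:
                    base = prof.mean_speed_by_movement[m]
                mu.append(base)
                var.append((base * disp) ** 2)  # lognormal ~ base*(1+disp*N) to 1st order
        mu = np.asarray(mu)
        var = np.asarray(var)
        # reorder rom, cv, speed blocks to FEATURE_NAMES order (already matches)
        means += w * mu
        second += w * (var + mu * mu)
    sds = np.sqrt(np.maximum(second - means * means, 1e-12))
    return means, sds


def _draw_patient_kinematics(
    profile: SeverityProfile, rng: np.random.Generator
) -> dict[str, tuple[float, float, float]]:
    """Patient-level (mean ROM, CV, speed) per movement around the profile."""
    out = {}
    for m in MOVEMENTS:
        rom = profile.mean_rom_by_movement[m] * np.exp(
            rng.normal(0.0, profile.rom_dispersion)
        )
        speed = profile.mean_speed_by_movement[m] * np.exp(
            rng.normal(0.0, profile.speed_dispersion)
        )
        cv = profile.mean_cv_by_movement[m] * np.exp(
            rng.normal(0.0, profile.cv_dispersion)
        )
        out[m] = (rom, cv, speed)
    return out


def _summaries_from_kinematics(
    kine: dict[str, tuple[float, float, float]],
    age: float,
    n_repetitions: int = 15,
) -> dict[str, MovementSummary]:
    return {
        m: MovementSummary(
            movement=m,
            mean_rom=rom,
            rom_normalized=100.0 * rom / normative_rom(m, age),
            cv=cv,
            speed_to_peak=speed,
            n_repetitions=n_repetitions,
        )
        for m, (rom, cv, speed) in kine.items()
    }


@dataclass
class SyntheticCohort:
    """Paired baseline/follow-up records plus the generating ground truth."""

    baseline: list[AssessmentRecord]
    followup: list[AssessmentRecord]
    true_change: np.ndarray  # noiseless model output + noise actually applied
    noiseless_change: np.ndarray
    nfhas_baseline: np.ndarray
    nfhas_followup: np.ndarray
    severity_types: np.ndarray
    config: SyntheticConfig


def generate_cohort(config: SyntheticConfig) -> SyntheticCohort:
    """Generate a paired cohort under the configured ground-truth model.

    Per patient: a severity type is drawn from the group proportions,
    baseline kinematics from that type's profile, the true NFHAS change
    from the recovery model applied to the baseline predictors (plus
    Gaussian noise, saturated so the follow-up score stays in [0, 100]),
    and a follow-up record consistent with that change is constructed by
    scaling the six normalized ROMs (score scales with the square of a
    uniform ROM scaling), speeding movements up proportionally and
    tightening CV.
    """
    seed = config.seed
    n = config.n_patients
    props = np.asarray(config.recovery.group_proportions, dtype=float)
    ref_mean, ref_sd = _population_reference_scale(config)
    coeffs = np.asarray(config.recovery.coefficients, dtype=float)

    baseline: list[AssessmentRecord] = []
    followup: list[AssessmentRecord] = []
    types = np.empty(n, dtype=int)
    true_change = np.empty(n)
    noiseless = np.empty(n)
    s1 = np.empty(n)
    s2 = np.empty(n)

    for i in range(n):
        rng_type = _rng(seed, _S_TYPE, i)
        rng_demog = _rng(seed, _S_DEMOG, i)
        rng_kine = _rng(seed, _S_KINE, i)
        rng_noise = _rng(seed, _S_NOISE, i)

        k = int(rng_type.choice(5, p=props))
        types[i] = k + 1
        profile = config.severity_profiles[k]

        age = float(np.clip(rng_demog.normal(config.age_mean, config.age_sd), 18.0, 90.0))
        sex = "F" if rng_demog.uniform() < config.fraction_female else "M"
        height = float(rng_demog.normal(config.height_mean, config.height_sd))
        mass = float(rng_demog.normal(config.mass_mean, config.mass_sd))

        kine = _draw_patient_kinematics(profile, rng_kine)
        movements = _summaries_from_kinematics(kine, age)
        rec = AssessmentRecord(
            patient_id=f"P{i:05d}",
            time_point="baseline",
            movements=movements,
            age=age,
            sex=sex,
            height=height,
            mass=mass,
        )
        baseline.append(rec)

        z = (rec.raw_features() - ref_mean) / ref_sd
        linear = config.recovery.intercept + float(coeffs @ z)
        score1 = nfhas_score(rec.normalized_roms())
        noise = (
            float(rng_noise.normal(0.0, config.recovery.noise_sd))
            if config.recovery.noise_sd > 0
            else 0.0
        )
        change = linear + noise
        if config.recovery.nonlinearity == "saturating":
            change = float(np.clip(change, -score1, 100.0 - score1))
        noiseless_i = linear
        if config.recovery.nonlinearity == "saturating":
            noiseless_i = float(np.clip(linear, -score1, 100.0 - score1))
        score2 = score1 + change

        # follow-up: uniform ROM scaling k with k^2 = score2/score1; a
        # negative unconstrained score (possible only without saturation)
        # clamps to zero mobility
        scale = float(np.sqrt(max(score2, 0.0) / score1)) if score1 > 0 else 1.0
        kine_fu = {
            m: (rom * scale, cv / max(scale, 1e-6), speed * scale)
            for m, (rom, cv, speed) in kine.items()
        }
        followup.append(
            AssessmentRecord(
                patient_id=rec.patient_id,
                time_point="followup",
                movements=_summaries_from_kinematics(kine_fu, age),
                age=age,
                sex=sex,
                height=height,
                mass=mass,
            )
        )
        true_change[i] = change
        noiseless[i] = noiseless_i
        s1[i] = score1
        s2[i] = score2

    return SyntheticCohort(
        baseline=baseline,
        followup=followup,
        true_change=true_change,
        noiseless_change=noiseless,
        nfhas_baseline=s1,
        nfhas_followup=s2,
        severity_types=types,
        config=config,
    )


def generate_patient_traces(
    config: SyntheticConfig, patient_index: int, severity_type: int
) -> dict[str, AngleTrace]:
    """Raw 45-s traces for one patient, one per movement."""
    profile = config.severity_profiles[severity_type - 1]
    traces = {}
    for j, m in enumerate(MOVEMENTS):
        sub = _rng(config.seed, _S_TRACE, patient_index, j)
        traces[m] = generate_trace(
            m,
            profile,
            duration=config.trace_duration,
            rate=config.trace_rate,
            seed=int(sub.integers(0, 2**31 - 1)),
            period_jitter=config.period_jitter,
        )
    return traces


# ---------------------------------------------------------------------------
# Disk round trip

def write_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> None:
    """Two CSV tables (baseline, follow-up) plus a JSON ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records_to_frame(cohort.baseline).to_csv(out / "baseline.csv", index=False)
    records_to_frame(cohort.followup).to_csv(out / "followup.csv", index=False)
    cfg = asdict(cohort.config)
    sidecar = {
        "config": cfg,
        "true_change": cohort.true_change.tolist(),
        "noiseless_change": cohort.noiseless_change.tolist(),
        "nfhas_baseline": cohort.nfhas_baseline.tolist(),
        "nfhas_followup": cohort.nfhas_followup.tolist(),
        "severity_types": cohort.severity_types.tolist(),
    }
    (out / "ground_truth.json").write_text(json.dumps(sidecar, indent=1))


def read_cohort(out_dir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    out = Path(out_dir)
    baseline = pd.read_csv(out / "baseline.csv")
    followup = pd.read_csv(out / "followup.csv")
    sidecar = json.loads((out / "ground_truth.json").read_text())
    return baseline, followup, sidecar
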