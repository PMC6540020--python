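"""Synthetic impedance transients and athlete cohorts.

No measurement data ship with this package, so downstream stages are exercised
on simulated inputs with the statistical structure the pipeline assumes:

* first-order contact transients ``b + c*exp(-a*t)`` with additive Gaussian
  noise, sampled at one-second intervals (five samples by default);
* a cohort of sport/gender groups whose anthropometric means and standard
  deviations match the published summary statistics of the amateur-athlete
  study population (12 groups, 102 males + 61 females);
* a ground-truth percent-body-fat (PBF) rule that is deliberately nonlinear in
  the waist-to-hip ratio, so the contrast between linear and neural-network
  regressors is exercisable;
* whole-body 50 kHz impedance from the cylinder model (R50 proportional to
  height squared over fat-free mass) and an upper-body reading contaminated by
  a large index-finger impedance offset (585.06 +/- 102.67 ohms).

Everything is driven by a single integer seed; identical configuration and
seed reproduce the cohort bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .calibration import ImpedanceSeries
from .errors import ConfigError

__all__ = [
    "TransientParams",
    "GroupStats",
    "CohortConfig",
    "SubjectRecord",
    "simulate_transient",
    "default_cohort_config",
    "default_groups",
    "simulate_cohort",
]

# slope of PBF on BMI inside each group (percent per BMI unit)
_PBF_BMI_SLOPE = 0.8
# scale of the cubic waist/hip term in the ground-truth PBF rule
_WHR_CUBIC_SCALE = 25.0

# physiologic clipping bounds applied after +/-3 sd truncation
_BOUNDS = {
    "height_cm": (140.0, 210.0),
    "age_yr": (15.0, 60.0),
    "weight_kg": (35.0, 200.0),
    "waist_cm": (50.0, 140.0),
    "hip_cm": (70.0, 140.0),
}


@dataclass(frozen=True)
class TransientParams:
    """Parameters of one simulated contact transient."""

    baseline_ohms: float
    amplitude: float
    decay_rate: float
    noise_sd: float = 0.0
    n_samples: int = 5
    delta_s: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.decay_rate > 0:
            raise ConfigError("decay_rate must be > 0")
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.n_samples < 3:
            raise ConfigError("n_samples must be >= 3")


@dataclass(frozen=True)
class GroupStats:
    """Mean/sd anthropometry of one sport/gender group."""

    label: str
    gender: str  # "male" | "female"
    n_weight: int
    height_mean: float
    height_sd: float
    age_mean: float
    age_sd: float
    weight_mean: float
    weight_sd: float
    waist_mean: float
    waist_sd: float
    hip_mean: float
    hip_sd: float
    pbf_mean: float
    pbf_sd: float

    def __post_init__(self) -> None:
        for name in ("height_sd", "age_sd", "weight_sd", "waist_sd", "hip_sd", "pbf_sd"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 140.0 <= self.height_mean <= 210.0:
            raise ConfigError("height_mean outside physiologic range")
        if not 3.0 <= self.pbf_mean <= 50.0:
            raise ConfigError("pbf_mean outside physiologic range")


def default_groups() -> tuple[GroupStats, ...]:
    """The 12 sport/gender groups of the study population."""
    male = [
        # label, n, height, age, weight, waist, hip, pbf  (mean, sd pairs)
        ("Basketball", 9, 190.0, 7.2, 20.3, 1.6, 84.6, 10.6, 79.0, 3.6, 97.8, 8.6, 10.0, 2.7),
        ("Kendo", 13, 172.0, 7.7, 19.1, 0.6, 70.5, 8.3, 78.5, 5.2, 94.6, 4.5, 15.3, 3.7),
        ("Ice Hockey", 10, 176.9, 3.7, 20.1, 1.1, 81.7, 4.8, 83.1, 4.0, 102.8, 1.8, 18.1, 2.9),
        ("Baseball", 22, 176.4, 4.7, 21.0, 3.1, 79.4, 10.4, 82.2, 7.7, 99.4, 5.2, 17.3, 4.2),
        ("Rugby", 32, 179.6, 6.4, 20.1, 1.4, 93.1, 15.0, 86.2, 14.0, 104.4, 6.8, 21.6, 6.8),
        ("General", 16, 174.5, 5.7, 26.2, 3.0, 78.7, 9.8, 81.4, 6.7, 99.2, 5.0, 18.3, 5.1),
    ]
    female = [
        ("Basketball", 8, 167.0, 4.6, 20.9, 1.7, 66.2, 9.5, 73.3, 6.5, 100.0, 5.9, 26.8, 7.6),
        ("Kendo", 4, 166.0, 3.0, 20.0, 1.4, 62.6, 3.1, 71.8, 3.5, 95.0, 2.5, 21.4, 4.2),
        ("Taekwondo", 14, 167.3, 5.1, 19.1, 1.2, 61.1, 9.4, 70.4, 6.9, 96.8, 5.4, 23.2, 5.4),
        ("Judo", 23, 163.8, 8.0, 20.0, 1.4, 72.0, 17.7, 77.9, 10.0, 99.8, 7.9, 26.8, 6.7),
        ("Table Tennis", 6, 161.6, 3.5, 20.2, 1.3, 55.8, 6.0, 73.6, 5.9, 92.9, 5.0, 25.8, 4.8),
        ("General", 6, 166.9, 4.2, 24.6, 6.1, 62.4, 4.6, 73.7, 13.2, 95.4, 3.3, 23.5, 4.5),
    ]
    groups = []
    for gender, rows in (("male", male), ("female", female)):
        for (label, n, h, hs, a, as_, w, ws, wa, was, hp, hps, p, ps) in rows:
            groups.append(
                GroupStats(
                    label=label, gender=gender, n_weight=n,
                    height_mean=h, height_sd=hs, age_mean=a, age_sd=as_,
                    weight_mean=w, weight_sd=ws, waist_mean=wa, waist_sd=was,
                    hip_mean=hp, hip_sd=hps, pbf_mean=p, pbf_sd=ps,
                )
            )
    return tuple(groups)


@dataclass(frozen=True)
class CohortConfig:
    """Generator settings for a synthetic cohort.

    ``wholebody_k`` (ohm*kg/cm^2) scales the cylinder-model whole-body
    impedance ``k * height^2 / FFM``; 1.167 puts a 175 cm / 65 kg-FFM subject
    near 550 ohms.  ``upper_fraction`` is the upper-body share of whole-body
    impedance seen by the wrist-finger path before the finger offset is added.
    ``nonlinearity_strength`` scales the cubic waist/hip term of the
    ground-truth PBF rule; 0 makes the rule affine in BMI.
    """

    groups: tuple[GroupStats, ...] = field(default_factory=default_groups)
    finger_mean_ohms: float = 585.06
    finger_sd_ohms: float = 102.67
    wholebody_k: float = 1.167
    upper_fraction: float = 1.10
    meas_noise_sd: float = 2.0
    pbf_noise_sd: float = 1.5
    nonlinearity_strength: float = 58.0
    r50_rel_noise_sd: float = 0.03
    anthro_corr: float = 0.6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.finger_sd_ohms < 0:
            raise ConfigError("finger_sd_ohms must be >= 0")
        if not self.upper_fraction > 0:
            raise ConfigError("upper_fraction must be > 0")
        if self.meas_noise_sd < 0 or self.pbf_noise_sd < 0 or self.r50_rel_noise_sd < 0:
            raise ConfigError("noise sds must be >= 0")
        if not 0 <= self.anthro_corr < 1:
            raise ConfigError("anthro_corr must be in [0, 1)")
        if not self.groups:
            raise ConfigError("groups must be non-empty")


def default_cohort_config() -> CohortConfig:
    """Cohort configuration populated from the published group statistics."""
    return CohortConfig()


@dataclass(frozen=True)
class SubjectRecord:
    """One synthetic subject: anthropometrics, reference values and raw series.

    ``gender`` is encoded female=1, male=0.  ``ref_wholebody_r50_ohms`` is the
    reference whole-body 50 kHz impedance; ``ref_h2r`` the cylinder index
    height^2 / R50 (cm^2/ohm).  ``true_pbf_pct`` is the generative ground
    truth in percent.  ``upper_series`` is the raw five-sample wrist-finger
    transient whose settled value the calibration stage must recover.
    """

    id: str
    group: str
    gender: int
    height_cm: float
    age_yr: float
    weight_kg: float
    waist_cm: float
    hip_cm: float
    true_pbf_pct: float
    ref_wholebody_r50_ohms: float
    ref_h2r: float
    finger_ohms: float
    upper_series: ImpedanceSeries


def simulate_transient(params: TransientParams) -> ImpedanceSeries:
    """Sample ``b + c*exp(-a*t) + noise`` at t = delta_s, 2*delta_s, ..."""
    rng = np.random.default_rng(params.seed)
    t = params.delta_s * np.arange(1, params.n_samples + 1)
    values = params.baseline_ohms + params.amplitude * np.exp(-params.decay_rate * t)
    if params.noise_sd > 0:
        values = values + rng.normal(0.0, params.noise_sd, size=len(t))
    return ImpedanceSeries(times=t, values=values, delta_s=params.delta_s)


def _draw_anthro(group: GroupStats, n: int, corr: float, rng: np.random.Generator):
    """Truncated-normal anthropometrics; weight/waist/hip share a latent factor."""
    z_h = np.clip(rng.standard_normal(n), -3, 3)
    z_a = np.clip(rng.standard_normal(n), -3, 3)
    shared = rng.standard_normal(n)
    lam, res = np.sqrt(corr), np.sqrt(1.0 - corr)
    z_w = np.clip(lam * shared + res * rng.standard_normal(n), -3, 3)
    z_wa = np.clip(lam * shared + res * rng.standard_normal(n), -3, 3)
    z_hp = np.clip(lam * shared + res * rng.standard_normal(n), -3, 3)

    def scale(z, mean, sd, key):
        lo, hi = _BOUNDS[key]
        return np.clip(mean + sd * z, lo, hi)

    return {
        "height_cm": scale(z_h, group.height_mean, group.height_sd, "height_cm"),
        "age_yr": scale(z_a, group.age_mean, group.age_sd, "age_yr"),
        "weight_kg": scale(z_w, group.weight_mean, group.weight_sd, "weight_kg"),
        "waist_cm": scale(z_wa, group.waist_mean, group.waist_sd, "waist_cm"),
        "hip_cm": scale(z_hp, group.hip_mean, group.hip_sd, "hip_cm"),
    }


def simulate_cohort(
    config: CohortConfig,
    n_per_group: int | None = None,
    seed: int | None = None,
) -> list[SubjectRecord]:
    """Draw a full synthetic cohort.

    With ``n_per_group=None`` each group contributes its study head count
    (163 subjects in total for the default groups); an integer gives every
    group the same size.  ``seed`` overrides ``config.seed``.

    The ground-truth PBF of a subject in group ``g`` is::

        clip(pbf_mean_g + 0.8*(BMI - 24)
             + nonlinearity_strength * 25 * (waist/hip - whr_mean_g)**3
             + Normal(0, pbf_noise_sd^2), 3, 50)

    Fat-free mass FFM = weight * (1 - PBF/100) then sets the reference
    whole-body impedance ``k * height^2 / FFM * (1 + eta)`` with eta a 3%
    relative noise, and the raw upper-body transient settles at
    ``upper_fraction * R50 + finger + Normal(0, meas_noise_sd^2)``.
    """
    if n_per_group is not None and n_per_group < 1:
        raise ConfigError("n_per_group must be >= 1")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    records: list[SubjectRecord] = []
    idx = 0
    for group in config.groups:
        n = group.n_weight if n_per_group is None else n_per_group
        anthro = _draw_anthro(group, n, config.anthro_corr, rng)
        whr_mean = group.waist_mean / group.hip_mean
        bmi = anthro["weight_kg"] / (anthro["height_cm"] / 100.0) ** 2
        whr = anthro["waist_cm"] / anthro["hip_cm"]
        eps = rng.normal(0.0, config.pbf_noise_sd, n) if config.pbf_noise_sd > 0 else np.zeros(n)
        pbf = np.clip(
            group.pbf_mean
            + _PBF_BMI_SLOPE * (bmi - 24.0)
            + config.nonlinearity_strength * _WHR_CUBIC_SCALE * (whr - whr_mean) ** 3
            + eps,
            3.0,
            50.0,
        )
        ffm = anthro["weight_kg"] * (1.0 - pbf / 100.0)
        eta = (
            rng.normal(0.0, config.r50_rel_noise_sd, n)
            if config.r50_rel_noise_sd > 0
            else np.zeros(n)
        )
        r50 = config.wholebody_k * anthro["height_cm"] ** 2 / ffm * (1.0 + eta)
        finger = rng.normal(config.finger_mean_ohms, config.finger_sd_ohms, n)
        base_noise = (
            rng.normal(0.0, config.meas_noise_sd, n) if config.meas_noise_sd > 0 else np.zeros(n)
        )
        a_draw = rng.uniform(0.2, 1.2, n)
        c_draw = rng.uniform(50.0, 400.0, n)
        series_seeds = rng.integers(0, 2**31 - 1, n)
        gender_code = 1 if group.gender == "female" else 0
        for i in range(n):
            baseline = config.upper_fraction * r50[i] + finger[i] + base_noise[i]
            series = simulate_transient(
                TransientParams(
                    baseline_ohms=float(baseline),
                    amplitude=float(c_draw[i]),
                    decay_rate=float(a_draw[i]),
                    noise_sd=config.meas_noise_sd,
                    seed=int(series_seeds[i]),
                )
            )
            sid = f"S{idx:04d}"
            series = replace(series, subject_id=sid)
            records.append(
                SubjectRecord(
                    id=sid,
                    group=f"{group.gender}:{group.label}",
                    gender=gender_code,
                    height_cm=float(anthro["height_cm"][i]),
                    age_yr=float(anthro["age_yr"][i]),
                    weight_kg=float(anthro["weight_kg"][i]),
                    waist_cm=float(anthro["waist_cm"][i]),
                    hip_cm=float(anthro["hip_cm"][i]),
                    true_pbf_pct=float(pbf[i]),
                    ref_wholebody_r50_ohms=float(r50[i]),
                    ref_h2r=float(anthro["height_cm"][i] ** 2 / r50[i]),
                    finger_ohms=float(finger[i]),
                    upper_series=series,
                )
            )
            idx += 1
    return records
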