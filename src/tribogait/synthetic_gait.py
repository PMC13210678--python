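"""Synthetic cohorts and 2-minute-walk sensor streams with known ground truth.

The generator emulates the statistical structure the downstream analysis
assumes, at the study conditions of a mixed rehabilitation cohort:

* demographics drawn from sex-specific height/mass/age distributions
  (females 1.63 +/- 0.08 m, 66.3 +/- 18.3 kg, age 34 +/- 17.5 y; males
  1.79 +/- 0.07 m, 75.9 +/- 11.9 kg, age 27 +/- 8.7 y; ages truncated to
  the 9-68 y recruitment range),
* walking cadence declining with age, calibrated to a population
  correlation of about -0.31 around a 100.6 +/- 10.1 steps/min mean,
  clipped to the 80-130 steps/min walking band,
* a signed left-right amplitude asymmetry ~ Normal(-1.4, 18.7)% truncated
  to [-100, 100] (positive = right-dominant),
* flatfoot-type loading (probability 0.547) shifting load toward the
  midfoot, and
* free-text condition histories assembled from the seven keyword pools used
  by the categorizer, with 37.7% multimorbidity.

Per-trial streams follow the physics of the insole: each stance phase is a
double-bump vertical-load curve (weight-acceptance and push-off peaks)
partitioned across the four plantar regions by a stance-phase timing
template (heel early, midfoot mid, forefoot/big-toe late).  Regional forces
are transduced to volts through the two-regime TENG response model and
digitized to 12-bit ADC counts; ankle IMU channels carry one angular-
velocity pulse per ipsilateral step at 10 dB peak SNR.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .cohort_analysis import categorize_history
from .sensor_model import (REGIONS, SensorGeometry, TengResponseParams,
                           N_PER_CM2_TO_KPA, voltage_from_pressure)

__all__ = [
    "ParticipantProfile",
    "TrialGroundTruth",
    "CohortConfig",
    "TrialConfig",
    "simulate_cohort",
    "simulate_trial",
    "write_fixture_set",
]

ADC_MAX = 4095          # 12-bit full scale
ADC_VREF_V = 10.0       # volts mapped to full scale
FLATFOOT_STATES = ("none", "left", "right", "bilateral")

#: Condition-history keyword pools, one per category (mirrors the
#: categorizer's keyword sets so generated texts are recoverable).
CATEGORY_KEYWORD_POOLS = {
    "spine_back": ["scoliosis", "lumbar hernia", "disc protrusion",
                   "spine injury", "vertebrae compression"],
    "knee": ["knee pain", "meniscus tear", "gonarthrosis",
             "ligament rupture"],
    "ankle_foot": ["ankle sprain", "flatfeet", "plantar fasciitis",
                   "ankle instability"],
    "hip": ["hip displacement", "hip dysplasia", "labrum tear"],
    "fractures_breaks": ["fibula fracture", "tibia fracture", "bone break"],
    "arthritis_joint": ["arthrosis", "arthritis", "osteochondrosis"],
    "other": ["shoulder strain", "wrist pain", "elbow tendinitis"],
}

#: Category sampling weights from the unique-patient prevalence of the
#: seven groups in a 53-patient mixed rehabilitation cohort.
CATEGORY_WEIGHTS = {
    "spine_back": 22, "ankle_foot": 19, "knee": 16, "fractures_breaks": 7,
    "hip": 6, "arthritis_joint": 3, "other": 3,
}


@dataclass(frozen=True)
class ParticipantProfile:
    participant_id: str
    age: float
    sex: str
    height_m: float
    mass_kg: float
    history_text: str
    true_cadence: float
    true_asymmetry_pct: float
    flatfoot: str
    category_truth: frozenset

    def __post_init__(self) -> None:
        if self.sex not in ("F", "M"):
            raise ValueError("sex must be 'F' or 'M'")
        if self.flatfoot not in FLATFOOT_STATES:
            raise ValueError(f"flatfoot must be one of {FLATFOOT_STATES}")
        if not (-100.0 <= self.true_asymmetry_pct <= 100.0):
            raise ValueError("true_asymmetry_pct must lie in [-100, 100]")
        bmi = self.mass_kg / self.height_m ** 2
        if not np.isfinite(bmi) or bmi <= 0:
            raise ValueError("BMI must be finite and positive")

    @property
    def bmi(self) -> float:
        return self.mass_kg / self.height_m ** 2


@dataclass(frozen=True)
class TrialGroundTruth:
    """What the generator injected; the recovery target for gait_metrics."""
    step_times_left: np.ndarray
    step_times_right: np.ndarray
    load_shares_left: dict
    load_shares_right: dict
    asymmetry_pct: float
    cadence: float


# ---------------------------------------------------------------------------
# Cohort generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for the synthetic cohort (units in field names)."""

    p_male: float = 31 / 53
    age_mean_f: float = 34.0
    age_sd_f: float = 17.5
    age_mean_m: float = 27.0
    age_sd_m: float = 8.7
    age_range: tuple[float, float] = (9.0, 68.0)
    height_mean_f: float = 1.63
    height_sd_f: float = 0.08
    height_mean_m: float = 1.79
    height_sd_m: float = 0.07
    mass_mean_f: float = 66.3
    mass_sd_f: float = 18.3
    mass_mean_m: float = 75.9
    mass_sd_m: float = 11.9
    cadence_mean: float = 100.6
    cadence_sd: float = 10.1
    age_cadence_r: float = -0.306
    cadence_range: tuple[float, float] = (80.0, 130.0)
    asym_mean_pct: float = -1.4
    asym_sd_pct: float = 18.7
    flatfoot_prob: float = 0.547
    flatfoot_side_probs: tuple[float, float, float] = (0.5, 0.25, 0.25)  # bilateral, left, right
    #: distribution of the number of condition categories per participant
    #: (1, 2, 3, 4): 62.3% single-category, 37.7% multimorbid.
    n_category_probs: tuple[float, ...] = (0.623, 0.28, 0.08, 0.017)


def _trunc_normal(rng: np.random.Generator, mean: float, sd: float,
                  lo: float, hi: float, size: int) -> np.ndarray:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    return truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def simulate_cohort(n: int, seed: int, config: CohortConfig | None = None
                    ) -> list[ParticipantProfile]:
    """Draw ``n`` participant profiles with ground-truth gait parameters.

    Cadence is generated as beta0 + beta1*age + eps with beta1 < 0 set from
    the realized age spread so the population age-cadence correlation hits
    the configured target; the residual SD preserves the configured total
    cadence SD.
    """
    if n < 2:
        raise ValueError("need n >= 2 participants")
    cfg = config or CohortConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    male = rng.random(n) < cfg.p_male
    lo, hi = cfg.age_range
    ages = np.where(
        male,
        _trunc_normal(rng, cfg.age_mean_m, cfg.age_sd_m, lo, hi, n),
        _trunc_normal(rng, cfg.age_mean_f, cfg.age_sd_f, lo, hi, n))
    heights = np.where(male,
                       rng.normal(cfg.height_mean_m, cfg.height_sd_m, n),
                       rng.normal(cfg.height_mean_f, cfg.height_sd_f, n))
    heights = np.clip(heights, 1.2, 2.2)
    masses = np.where(male,
                      rng.normal(cfg.mass_mean_m, cfg.mass_sd_m, n),
                      rng.normal(cfg.mass_mean_f, cfg.mass_sd_f, n))
    masses = np.clip(masses, 25.0, 180.0)

    age_sd = float(np.std(ages)) if n > 2 else max(float(np.std(ages)), 1.0)
    beta1 = cfg.age_cadence_r * cfg.cadence_sd / max(age_sd, 1e-9)
    resid_sd = cfg.cadence_sd * np.sqrt(max(1.0 - cfg.age_cadence_r ** 2, 0.0))
    beta0 = cfg.cadence_mean - beta1 * float(np.mean(ages))
    cadences = beta0 + beta1 * ages + rng.normal(0.0, resid_sd, n)
    cadences = np.clip(cadences, *cfg.cadence_range)

    asym = np.clip(rng.normal(cfg.asym_mean_pct, cfg.asym_sd_pct, n),
                   -100.0, 100.0)

    flat = rng.random(n) < cfg.flatfoot_prob
    side_draw = rng.choice(["bilateral", "left", "right"], size=n,
                           p=cfg.flatfoot_side_probs)
    flatfoot = np.where(flat, side_draw, "none")

    cats = list(CATEGORY_WEIGHTS)
    weights = np.array([CATEGORY_WEIGHTS[c] for c in cats], dtype=float)
    weights /= weights.sum()
    n_cat_choices = np.arange(1, len(cfg.n_category_probs) + 1)

    profiles = []
    for i in range(n):
        k = int(rng.choice(n_cat_choices, p=cfg.n_category_probs))
        chosen = list(rng.choice(cats, size=min(k, len(cats)), replace=False,
                                 p=weights))
        # 'other' is a residual tag: it only applies when nothing else
        # matches, so it cannot co-occur with a named category
        if "other" in chosen and len(chosen) > 1:
            chosen.remove("other")
        phrases = [str(rng.choice(CATEGORY_KEYWORD_POOLS[c])) for c in chosen]
        text = "; ".join(phrases)
        # ground truth is what the categorization rule yields for the text:
        # some phrases are legitimately multi-tagged (gonarthrosis is both a
        # knee condition and an arthrosis)
        truth_cats = categorize_history(text).categories
        profiles.append(ParticipantProfile(
            participant_id=f"P{i:03d}",
            age=float(ages[i]),
            sex="M" if male[i] else "F",
            height_m=float(heights[i]),
            mass_kg=float(masses[i]),
            history_text=text,
            true_cadence=float(cadences[i]),
            true_asymmetry_pct=float(asym[i]),
            flatfoot=str(flatfoot[i]),
            category_truth=truth_cats,
        ))
    return profiles


# ---------------------------------------------------------------------------
# Trial simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TrialConfig:
    """Physics and template parameters for one simulated 2MWT trial."""

    #: per-foot peak vertical load delivered to the insole electrodes, N.
    #: The electrodes capture a fraction of body load; this default keeps
    #: regional pressures in the characterized sub-saturation band.
    peak_force_n: float = 30.0
    stance_fraction: float = 0.6     # stance = 60% of the gait cycle
    bump_centers: tuple[float, float] = (0.25, 0.75)  # fractions of stance
    bump_width: float = 0.10         # SD as fraction of stance duration
    #: baseline region load shares (sum to 1) and stance-phase timing of
    #: each region's activation (center, width as fractions of stance).
    region_weights: dict = field(default_factory=lambda: {
        "big_toe": 0.26, "forefoot": 0.24, "medial_arch": 0.10, "heel": 0.40})
    region_timing: dict = field(default_factory=lambda: {
        "heel": (0.22, 0.20), "medial_arch": (0.50, 0.22),
        "forefoot": (0.72, 0.18), "big_toe": (0.85, 0.15)})
    #: flatfoot loading shifts: extra share moved to the midfoot and a
    #: lateral big_toe -> forefoot transfer of the loading resultant.
    flatfoot_arch_boost: float = 0.12
    flatfoot_lateral_transfer: float = 0.05
    gyro_amplitude: float = 2.0      # rad/s peak per step
    gyro_pulse_sd_s: float = 0.05
    imu_peak_snr_db: float = 10.0
    acc_amplitude: float = 1.5       # arbitrary accelerometer units
    start_offset_s: float = 0.3


def _region_weights_for_foot(cfg: TrialConfig, flat: bool) -> dict:
    w = dict(cfg.region_weights)
    if flat:
        d = min(cfg.flatfoot_lateral_transfer, w["big_toe"])
        w["big_toe"] -= d
        w["forefoot"] += d
        boost = cfg.flatfoot_arch_boost
        others = [r for r in REGIONS if r != "medial_arch"]
        total_others = sum(w[r] for r in others)
        for r in others:
            w[r] -= boost * w[r] / total_others
        w["medial_arch"] += boost
    return w


def _stance_profile(t: np.ndarray, strikes: np.ndarray, stride_s: float,
                    cfg: TrialConfig):
    """Total foot load F(t) in [0, 1] of peak, and stance phase s in [0, 1].

    tau = time since the most recent ipsilateral strike; samples with
    tau >= stance duration carry zero load (swing).
    """
    stance_s = cfg.stance_fraction * stride_s
    tau = (t - strikes[0]) % stride_s
    in_walk = (t >= strikes[0]) & (t <= strikes[-1] + stance_s)
    s = tau / stance_s
    in_stance = (s < 1.0) & in_walk
    c1, c2 = cfg.bump_centers
    w = cfg.bump_width
    force = np.exp(-0.5 * ((s - c1) / w) ** 2) + np.exp(-0.5 * ((s - c2) / w) ** 2)
    # subtract the edge value so the load rises from and returns to zero at
    # foot contact and toe-off (keeps the template continuous at the
    # stance/swing boundary)
    edge = float(np.exp(-0.5 * (c1 / w) ** 2) + np.exp(-0.5 * ((1.0 - c1) / w) ** 2))
    force = np.clip(force - edge, 0.0, None) / (1.0 - edge)
    force = np.where(in_stance, force, 0.0)
    return force, s, in_stance


def _region_shares(s: np.ndarray, in_stance: np.ndarray, weights: dict,
                   cfg: TrialConfig) -> dict:
    """Region load shares at each stance sample; sum to 1 within stance."""
    act = {}
    for region in REGIONS:
        center, width = cfg.region_timing[region]
        act[region] = weights[region] * np.exp(-0.5 * ((s - center) / width) ** 2)
    total = sum(act.values())
    shares = {}
    with np.errstate(invalid="ignore", divide="ignore"):
        for region in REGIONS:
            shares[region] = np.where(in_stance & (total > 0),
                                      act[region] / np.where(total > 0, total, 1.0),
                                      0.0)
    return shares


def simulate_trial(profile: ParticipantProfile, geometry: SensorGeometry,
                   params: TengResponseParams, duration_s: float = 120.0,
                   sample_rate: float = 100.0, seed: int = 0,
                   config: TrialConfig | None = None, noise_scale: float = 1.0
                   ) -> tuple[pd.DataFrame, pd.DataFrame, TrialGroundTruth]:
    """Simulate one 2MWT: insole ADC stream, IMU stream, and ground truth.

    Left/right stance amplitudes are scaled by (1 -/+ a/100) for injected
    asymmetry ``a`` (positive = right-dominant).  ``noise_scale`` multiplies
    every noise SD (0 gives a noise-free trial).  Stream frames follow the
    fixture CSV schemas: insole (timestamp_s, ch0..ch7), IMU (timestamp_s,
    gyro_l, gyro_r, acc_l, acc_r).
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    cadence = profile.true_cadence
    if not (40.0 <= cadence <= 200.0):
        raise ValueError(f"cadence {cadence:.1f} outside supported 40-200 steps/min")
    cfg = config or TrialConfig()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    stride_s = 120.0 / cadence                 # per-foot stride period
    n = int(round(duration_s * sample_rate))
    t = np.arange(n) / sample_rate
    # exactly round(duration * cadence / 60) ground-truth steps, split
    # between the feet (left leads when the total is odd)
    total_steps = int(round(duration_s * cadence / 60.0))
    n_left = (total_steps + 1) // 2
    n_right = total_steps // 2
    last_rel = stride_s / 2.0 + max(n_right - 1, 0) * stride_s
    t0 = min(cfg.start_offset_s, max(duration_s - 0.15 - last_rel, 0.05))
    strikes_left = t0 + np.arange(n_left) * stride_s
    strikes_right = t0 + stride_s / 2.0 + np.arange(n_right) * stride_s

    a = profile.true_asymmetry_pct
    amp = {"left": 1.0 - a / 100.0, "right": 1.0 + a / 100.0}
    strikes = {"left": strikes_left, "right": strikes_right}
    step_freq_hz = cadence / 120.0             # per-foot contact frequency

    insole = {"timestamp_s": t}
    shares_truth = {}
    for side in ("left", "right"):
        flat = profile.flatfoot in (side, "bilateral")
        weights = _region_weights_for_foot(cfg, flat)
        force_rel, s, in_stance = _stance_profile(t, strikes[side], stride_s, cfg)
        force_total = cfg.peak_force_n * force_rel
        shares = _region_shares(s, in_stance, weights, cfg)
        # force-weighted mean region share = ground-truth loading pattern
        denom = float(force_total.sum())
        shares_truth[side] = {
            r: float((shares[r] * force_total).sum() / denom) if denom > 0 else 0.0
            for r in REGIONS}
        for region in REGIONS:
            ch = geometry.channel(side, region)
            force_region = force_total * shares[region]
            pressure_kpa = N_PER_CM2_TO_KPA * force_region / ch.area_cm2
            volts = voltage_from_pressure(params, pressure_kpa, step_freq_hz,
                                          ch.area_cm2)
            # asymmetry is injected as a recorded-signal amplitude scale,
            # the quantity the amplitude-based asymmetry index measures
            # (the concave transduction would otherwise compress a
            # force-domain scale into a smaller signal-domain one)
            volts = np.minimum(volts * amp[side], params.v_max)
            if noise_scale > 0 and params.noise_sd > 0:
                volts = volts + rng.normal(
                    0.0, noise_scale * params.noise_sd, size=n)
            adc = np.clip(np.rint(volts / ADC_VREF_V * ADC_MAX), 0, ADC_MAX)
            insole[f"ch{ch.channel_id}"] = adc.astype(np.int64)

    imu = {"timestamp_s": t}
    noise_sd = cfg.gyro_amplitude / 10 ** (cfg.imu_peak_snr_db / 20.0)
    for side, label in (("left", "l"), ("right", "r")):
        gyro = np.zeros(n)
        acc = np.zeros(n)
        for tk in strikes[side]:
            pulse = np.exp(-0.5 * ((t - tk) / cfg.gyro_pulse_sd_s) ** 2)
            gyro += cfg.gyro_amplitude * pulse
            acc += cfg.acc_amplitude * pulse
        if noise_scale > 0:
            gyro = gyro + rng.normal(0.0, noise_scale * noise_sd, size=n)
            acc = acc + rng.normal(0.0, noise_scale * noise_sd, size=n)
        imu[f"gyro_{label}"] = gyro
        imu[f"acc_{label}"] = acc

    truth = TrialGroundTruth(
        step_times_left=strikes_left,
        step_times_right=strikes_right,
        load_shares_left=shares_truth["left"],
        load_shares_right=shares_truth["right"],
        asymmetry_pct=a,
        cadence=cadence,
    )
    return pd.DataFrame(insole), pd.DataFrame(imu), truth


# ---------------------------------------------------------------------------
# Fixture sets
# ---------------------------------------------------------------------------

def write_fixture_set(cohort: list[ParticipantProfile], out_dir,
                      seed: int, geometry: SensorGeometry | None = None,
                      params: TengResponseParams | None = None,
                      duration_s: float = 120.0, sample_rate: float = 100.0,
                      config: TrialConfig | None = None) -> dict:
    """Write per-participant stream CSVs + metadata + ground truth + manifest.

    All randomness descends from ``seed`` via a splittable seed sequence, so
    regeneration with the same seed is byte-identical.  Returns the manifest
    (also written as JSON).
    """
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as exc:
        raise OSError(f"cannot create fixture directory {out}: {exc}") from exc
    geometry = geometry or SensorGeometry.default()
    params = params or TengResponseParams()

    child_seeds = np.random.SeedSequence(seed).generate_state(max(len(cohort), 1))
    meta_rows, truth_rows, entries = [], [], []
    for profile, child in zip(cohort, child_seeds):
        trial_seed = int(child % (2 ** 31))
        insole, imu, truth = simulate_trial(
            profile, geometry, params, duration_s=duration_s,
            sample_rate=sample_rate, seed=trial_seed, config=config)
        insole_path = out / f"{profile.participant_id}_insole.csv"
        imu_path = out / f"{profile.participant_id}_imu.csv"
        insole.to_csv(insole_path, index=False, float_format="%.4f")
        imu.to_csv(imu_path, index=False, float_format="%.6f")
        entries.append({"participant_id": profile.participant_id,
                        "insole": insole_path.name, "imu": imu_path.name,
                        "seed": trial_seed})
        meta_rows.append({
            "participant_id": profile.participant_id, "age": profile.age,
            "sex": profile.sex, "height_m": profile.height_m,
            "mass_kg": profile.mass_kg, "history_text": profile.history_text,
        })
        truth_rows.append({
            "participant_id": profile.participant_id,
            "true_cadence": truth.cadence,
            "true_asymmetry_pct": truth.asymmetry_pct,
            "flatfoot": profile.flatfoot,
            **{f"share_left_{r}": truth.load_shares_left[r] for r in REGIONS},
            **{f"share_right_{r}": truth.load_shares_right[r] for r in REGIONS},
        })

    meta_cols = ["participant_id", "age", "sex", "height_m", "mass_kg",
                 "history_text"]
    pd.DataFrame(meta_rows, columns=meta_cols).to_csv(
        out / "metadata.csv", index=False, float_format="%.6f")
    if truth_rows:
        pd.DataFrame(truth_rows).to_csv(out / "ground_truth.csv", index=False,
                                        float_format="%.6f")
    manifest = {
        "seed": seed,
        "n_participants": len(cohort),
        "duration_s": duration_s,
        "sample_rate": sample_rate,
        "metadata": "metadata.csv",
        "ground_truth": "ground_truth.csv" if truth_rows else None,
        "trials": entries,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest
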