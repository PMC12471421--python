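"""Synthetic cohort generator for conscious porcine trauma studies.

Emulates the data a 72-h conscious swine study of penetrating abdominal
trauma (PAT) with fecal peritonitis produces: continuous telemetry (heart
rate, respiration rate, temperature, arterial pressures, activity) on a
12-h light cycle, 8-hourly blood panels (counts, chemistry, cytokines),
8-hourly neurological SNORT assessments, and a mortality process.

Control animals fluctuate around phase-specific (day/night) baseline means
with AR(1) noise.  Injured animals superpose a phenomenological injury
response on that baseline: a normalized gamma-kernel impulse

    g(t) = (t / tau)^k * exp(k * (1 - t / tau)),   g(tau) = 1, g(0) = 0,

so a channel with amplitude ``A`` peaks at exactly ``baseline + A`` at
``t = tau`` hours post-injury and relaxes back at a rate set by the shape
``k`` (small k: long plateau; large k: sharp transient).  Biphasic
channels (WBC, glucose) use a sum of two kernels of opposite sign.  No
mechanistic hemodynamics are modeled; trajectories are calibrated to the
group-level kinetics a fecal-peritonitis insult produces (tachycardia
peaking at 8 h, biphasic leukopenia, thrombocytopenia nadir at 32 h,
creatinine peak at 24 h, delayed bilirubin peak, acute hyperlactatemia,
biphasic glucose, cytokine impulses, SNORT depression).

Mortality: each injured animal dies with probability ``mortality_prob``;
death times follow a log-normal truncated to early protocol hours, and all
records are censored at death.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps
from scipy.signal import lfilter

from . import reference

logger = logging.getLogger(__name__)

CONTROL = "control"
PAT = "pat"

#: Epoch mapped to injury time; simulated timestamps are
#: ``INJURY_DATE + injury_clock_hour + time_h``.
INJURY_DATE = pd.Timestamp("2024-01-08")


# ---------------------------------------------------------------------------
# channel specification and injury kinetics


@dataclass(frozen=True)
class ChannelSpec:
    """Baseline statistics plus injury-response kinetics for one channel.

    ``day_mean``/``day_sd`` and ``night_mean``/``night_sd`` describe the
    healthy baseline in channel units over the two 12-h light phases (lab
    analytes have no diurnal split: day == night).  ``amplitude`` is the
    peak deviation from baseline after injury (may be negative), reached at
    ``peak_time_h`` hours post-injury; ``recovery_shape`` is the gamma-
    kernel shape.  A second kernel (``amplitude2`` / ``peak_time2_h`` /
    ``recovery_shape2``) models biphasic responses.  ``noise_sd`` is the
    marginal SD of the stochastic fluctuation (AR(1) for telemetry with
    lag-1 correlation ``noise_autocorr`` at the telemetry step; independent
    per draw for labs); ``None`` defaults to the day/night SD average.
    ``floor`` is a physical lower bound; values are clipped there and the
    clipping is logged.
    """

    name: str
    day_mean: float
    day_sd: float
    night_mean: float
    night_sd: float
    amplitude: float = 0.0
    peak_time_h: float = 8.0
    recovery_shape: float = 1.0
    amplitude2: float = 0.0
    peak_time2_h: float | None = None
    recovery_shape2: float = 1.0
    noise_sd: float | None = None
    noise_autocorr: float = 0.0
    floor: float | None = None
    kind: str = "telemetry"  # "telemetry" or "lab"

    def __post_init__(self) -> None:
        if self.day_sd < 0 or self.night_sd < 0:
            raise ValueError(f"{self.name}: baseline SDs must be >= 0")
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError(f"{self.name}: noise_sd must be >= 0")
        if self.peak_time_h <= 0:
            raise ValueError(f"{self.name}: peak_time_h must be > 0")
        if self.peak_time2_h is not None and self.peak_time2_h <= 0:
            raise ValueError(f"{self.name}: peak_time2_h must be > 0")
        if self.recovery_shape <= 0 or self.recovery_shape2 <= 0:
            raise ValueError(f"{self.name}: recovery shapes must be > 0")
        if not 0.0 <= self.noise_autocorr < 1.0:
            raise ValueError(f"{self.name}: noise_autocorr must be in [0, 1)")
        if self.kind not in ("telemetry", "lab"):
            raise ValueError(f"{self.name}: kind must be 'telemetry' or 'lab'")

    @property
    def effective_noise_sd(self) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return 0.5 * (self.day_sd + self.night_sd)


def gamma_kernel(t, peak_time_h: float, shape: float):
    """Normalized gamma impulse: 0 at t<=0, exactly 1 at the peak, -> 0."""
    if peak_time_h <= 0:
        raise ValueError("peak_time_h must be > 0")
    if shape <= 0:
        raise ValueError("shape must be > 0")
    t = np.asarray(t, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(t > 0, t / peak_time_h, 0.0)
        g = np.where(t > 0, rel**shape * np.exp(shape * (1.0 - rel)), 0.0)
    return g if g.ndim else float(g)


def injury_response(t, spec: ChannelSpec, baseline: float):
    """Deterministic post-injury value of a channel at ``t`` hours.

    Returns ``baseline + amplitude * g(t)`` (plus the second kernel for
    biphasic channels); equals ``baseline`` at t = 0 and peaks at
    ``baseline + amplitude`` at ``t = peak_time_h``.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("t must be >= 0 (hours post-injury)")
    out = baseline + spec.amplitude * gamma_kernel(t, spec.peak_time_h, spec.recovery_shape)
    if spec.amplitude2 and spec.peak_time2_h is not None:
        out = out + spec.amplitude2 * gamma_kernel(t, spec.peak_time2_h, spec.recovery_shape2)
    return out if np.ndim(out) else float(out)


def default_channels() -> dict[str, ChannelSpec]:
    """Default channel parameterization.

    Baseline means/SDs for HR, RR, temperature, WBC and SBP are the healthy
    48-animal reference statistics (:mod:`swinescore.reference`); injury
    amplitudes and peak times reproduce the group-level extrema of the
    penetrating-abdominal-trauma course (HR 201 bpm at 8 h, WBC nadir
    3.9 at 8 h recovering by ~40 h, platelet nadir 132.2 at 32 h,
    creatinine peak 2.0 at 24 h, delayed bilirubin peak 0.53, lactate 6.3
    at 8 h, glucose 174 then hypoglycemia, cytokine impulses at 8 h with
    TNF-alpha at 16 h, P/F drifting from ~449 toward ~418 but never below
    400).  Channels without printed baselines use values a veterinary
    clinician would call normal for 50-kg Yorkshire swine.
    """
    s = reference.BASELINE_STATS
    specs = [
        ChannelSpec("hr", *s[("hr", "day")], *s[("hr", "night")],
                    amplitude=101.0, peak_time_h=8.0, recovery_shape=0.3,
                    noise_autocorr=0.9, floor=30.0),
        ChannelSpec("rr", *s[("rr", "day")], *s[("rr", "night")],
                    amplitude=0.0, noise_autocorr=0.9, floor=4.0),
        ChannelSpec("temp", *s[("temp", "day")], *s[("temp", "night")],
                    amplitude=0.8, peak_time_h=8.0, recovery_shape=0.2,
                    noise_autocorr=0.95, floor=35.0),
        ChannelSpec("map", 106.0, 5.0, 102.0, 5.0,
                    amplitude=-10.0, peak_time_h=24.0, recovery_shape=0.5,
                    noise_autocorr=0.9, floor=25.0),
        ChannelSpec("sbp", *s[("sbp", "day")], *s[("sbp", "night")],
                    amplitude=-12.0, peak_time_h=24.0, recovery_shape=0.5,
                    noise_autocorr=0.9, floor=50.0),
        ChannelSpec("activity", 8.0, 2.5, 2.0, 1.0,
                    amplitude=-6.0, peak_time_h=8.0, recovery_shape=0.2,
                    noise_autocorr=0.8, floor=0.0),
        # labs: one draw every blood-draw interval, independent noise
        ChannelSpec("wbc", 19.1, 3.5, 19.1, 3.5,
                    amplitude=-15.2, peak_time_h=8.0, recovery_shape=2.0,
                    amplitude2=-4.0, peak_time2_h=48.0, recovery_shape2=0.5,
                    noise_sd=2.5, floor=0.1, kind="lab"),
        ChannelSpec("platelets", 350.0, 60.0, 350.0, 60.0,
                    amplitude=-218.0, peak_time_h=32.0, recovery_shape=1.5,
                    noise_sd=30.0, floor=5.0, kind="lab"),
        ChannelSpec("creatinine", 1.0, 0.15, 1.0, 0.15,
                    amplitude=1.0, peak_time_h=24.0, recovery_shape=8.0,
                    noise_sd=0.1, floor=0.05, kind="lab"),
        ChannelSpec("bilirubin", 0.11, 0.03, 0.11, 0.03,
                    amplitude=0.42, peak_time_h=40.0, recovery_shape=3.0,
                    noise_sd=0.03, floor=0.01, kind="lab"),
        ChannelSpec("lactate", 1.4, 0.3, 1.4, 0.3,
                    amplitude=4.9, peak_time_h=8.0, recovery_shape=3.0,
                    noise_sd=0.25, floor=0.2, kind="lab"),
        ChannelSpec("glucose", 100.0, 12.0, 100.0, 12.0,
                    amplitude=74.0, peak_time_h=8.0, recovery_shape=3.0,
                    amplitude2=-35.0, peak_time2_h=32.0, recovery_shape2=2.0,
                    noise_sd=10.0, floor=25.0, kind="lab"),
        ChannelSpec("pf_ratio", 448.6, 18.0, 448.6, 18.0,
                    amplitude=-40.0, peak_time_h=24.0, recovery_shape=0.5,
                    noise_sd=15.0, floor=60.0, kind="lab"),
        ChannelSpec("il6", 20.0, 8.0, 20.0, 8.0,
                    amplitude=1800.0, peak_time_h=8.0, recovery_shape=1.5,
                    noise_sd=8.0, floor=0.0, kind="lab"),
        ChannelSpec("tnfa", 60.0, 20.0, 60.0, 20.0,
                    amplitude=250.0, peak_time_h=16.0, recovery_shape=1.0,
                    noise_sd=20.0, floor=0.0, kind="lab"),
        ChannelSpec("il10", 15.0, 6.0, 15.0, 6.0,
                    amplitude=400.0, peak_time_h=8.0, recovery_shape=2.0,
                    noise_sd=6.0, floor=0.0, kind="lab"),
        ChannelSpec("il1b", 30.0, 10.0, 30.0, 10.0,
                    amplitude=180.0, peak_time_h=8.0, recovery_shape=0.5,
                    noise_sd=10.0, floor=0.0, kind="lab"),
    ]
    return {c.name: c for c in specs}


# ---------------------------------------------------------------------------
# death process


@dataclass(frozen=True)
class LogNormalDeathTimes:
    """Log-normal death-time distribution truncated to ``(0, upper_h]``.

    Defaults put deaths in the first two protocol days (truncated mean
    ~17.9 h), so a 25%-mortality cohort of eight has an expected mean
    survival of ~58.5 h over a 72-h protocol.
    """

    meanlog: float = 2.83
    sdlog: float = 0.45
    upper_h: float = 40.0

    def __post_init__(self) -> None:
        if self.sdlog <= 0:
            raise ValueError("sdlog must be > 0")
        if self.upper_h <= 0:
            raise ValueError("death-time distribution has empty support")

    @property
    def mean(self) -> float:
        """Closed-form mean of the truncated distribution."""
        a = (np.log(self.upper_h) - self.meanlog - self.sdlog**2) / self.sdlog
        b = (np.log(self.upper_h) - self.meanlog) / self.sdlog
        untrunc = np.exp(self.meanlog + 0.5 * self.sdlog**2)
        return float(untrunc * sps.norm.cdf(a) / sps.norm.cdf(b))

    def sample(self, n: int, rng: np.random.Generator) -> np.ndarray:
        if n < 0:
            raise ValueError("n must be >= 0")
        out = np.empty(0)
        while out.size < n:
            draw = np.exp(rng.normal(self.meanlog, self.sdlog, size=max(n, 8)))
            out = np.concatenate([out, draw[draw <= self.upper_h]])
        return out[:n]


def sample_death_times(n_deaths: int, distribution: LogNormalDeathTimes,
                       seed_or_rng) -> np.ndarray:
    """Draw ``n_deaths`` death times (hours post-injury) from ``distribution``."""
    rng = np.random.default_rng(seed_or_rng) if not isinstance(
        seed_or_rng, np.random.Generator) else seed_or_rng
    return distribution.sample(n_deaths, rng)


# ---------------------------------------------------------------------------
# SNORT process


@dataclass(frozen=True)
class SnortSpec:
    """Neurological SNORT trajectory: a bounded integer process.

    Healthy animals sit at the rubric ceiling (11).  Post-injury the score
    is pulled down along a gamma-kernel target (depression ``amplitude``,
    deepest near ``peak_time_h``, slow recovery for small
    ``recovery_shape``), with a mean-reverting AR(1) residual, rounded to
    an integer and clipped to the rubric range [2, 11].
    """

    amplitude: float = -4.6
    peak_time_h: float = 8.0
    recovery_shape: float = 0.08
    resid_sd: float = 0.35
    resid_autocorr: float = 0.5
    healthy: int = 11
    lo: int = 2
    hi: int = 11

    def __post_init__(self) -> None:
        if self.peak_time_h <= 0 or self.recovery_shape <= 0:
            raise ValueError("SNORT kinetics must have positive peak/shape")
        if not 0.0 <= self.resid_autocorr < 1.0:
            raise ValueError("resid_autocorr must be in [0, 1)")


# ---------------------------------------------------------------------------
# configuration and course containers


@dataclass(frozen=True)
class SimulationConfig:
    """Full study-design configuration for one simulated cohort."""

    n_control: int = 4
    n_pat: int = 8
    duration_h: float = 72.0
    baseline_h: float = 48.0
    telemetry_step_min: float = 5.0
    blooddraw_interval_h: float = 8.0
    lights_on_hour: float = 6.0
    lights_off_hour: float = 18.0
    injury_clock_hour: float = 6.0
    channels: Mapping[str, ChannelSpec] = field(default_factory=default_channels)
    snort: SnortSpec = field(default_factory=SnortSpec)
    mortality_prob: float = 0.25
    death_times: LogNormalDeathTimes = field(default_factory=LogNormalDeathTimes)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_control < 0 or self.n_pat < 0:
            raise ValueError("group sizes must be >= 0")
        if not 0.0 <= self.mortality_prob <= 1.0:
            raise ValueError("mortality_prob must be in [0, 1]")
        if (self.lights_off_hour - self.lights_on_hour) % 24 != 12:
            raise ValueError("light cycle must define two 12-h phases")
        if self.duration_h <= 0 or self.baseline_h < 0:
            raise ValueError("durations must be positive")
        if self.telemetry_step_min <= 0 or self.blooddraw_interval_h <= 0:
            raise ValueError("sampling steps must be positive")


@dataclass
class AnimalCourse:
    """One animal's simulated records, all times in hours relative to injury."""

    animal_id: str
    group: str
    telemetry: pd.DataFrame  # columns: time_h, timestamp, channel, value
    labs: pd.DataFrame       # columns: time_h, analyte, value
    snort: pd.DataFrame      # columns: time_h, score
    death_time_h: float | None = None

    @property
    def alive_at_end(self) -> bool:
        return self.death_time_h is None


# ---------------------------------------------------------------------------
# simulation


def _ar1(n: int, sd: float, phi: float, rng: np.random.Generator) -> np.ndarray:
    """Stationary AR(1) series with marginal SD ``sd`` and lag-1 corr ``phi``."""
    if n == 0:
        return np.empty(0)
    e = rng.standard_normal(n)
    if sd == 0.0:
        return np.zeros(n)
    if phi == 0.0:
        return sd * e
    x = np.empty(n)
    x[0] = sd * e[0]
    if n > 1:
        innov = sd * np.sqrt(1.0 - phi**2) * e[1:]
        x[1:] = lfilter([1.0], [1.0, -phi], innov, zi=np.array([phi * x[0]]))[0]
    return x


def _phase_mask(clock_hours: np.ndarray, lights_on: float, lights_off: float) -> np.ndarray:
    h = np.asarray(clock_hours) % 24.0
    on, off = lights_on % 24.0, lights_off % 24.0
    if on < off:
        return (h >= on) & (h < off)
    return (h >= on) | (h < off)


def draw_survival(config: SimulationConfig, rng: np.random.Generator) -> np.ndarray:
    """Death times for the injured group (NaN = survived to protocol end).

    This is the exact survival component :func:`simulate_cohort` uses:
    per-animal Bernoulli(``mortality_prob``) death indicator, death times
    from ``config.death_times``.
    """
    died = rng.random(config.n_pat) < config.mortality_prob
    times = np.full(config.n_pat, np.nan)
    n_dead = int(died.sum())
    if n_dead:
        times[died] = config.death_times.sample(n_dead, rng)
    return times


def _simulate_animal(animal_id: str, group: str, config: SimulationConfig,
                     rng: np.random.Generator,
                     death_time_h: float | None) -> AnimalCourse:
    step_h = config.telemetry_step_min / 60.0
    t_tel = np.arange(-config.baseline_h, config.duration_h + step_h / 2, step_h)
    clock = (config.injury_clock_hour + t_tel) % 24.0
    is_day = _phase_mask(clock, config.lights_on_hour, config.lights_off_hour)
    injured = group == PAT
    post = np.clip(t_tel, 0.0, None)

    tel_frames = []
    n_clipped = 0
    for name, spec in config.channels.items():
        if spec.kind != "telemetry":
            continue
        base = np.where(is_day, spec.day_mean, spec.night_mean)
        vals = base + _ar1(t_tel.size, spec.effective_noise_sd,
                           spec.noise_autocorr, rng)
        if injured:
            vals = vals + (injury_response(post, spec, 0.0) - 0.0)
        if spec.floor is not None:
            below = vals < spec.floor
            n_clipped += int(below.sum())
            vals = np.where(below, spec.floor, vals)
        tel_frames.append(pd.DataFrame({
            "time_h": t_tel, "channel": name, "value": vals}))
    telemetry = pd.concat(tel_frames, ignore_index=True) if tel_frames else \
        pd.DataFrame(columns=["time_h", "channel", "value"])
    telemetry["timestamp"] = (INJURY_DATE
                              + pd.to_timedelta(config.injury_clock_hour, "h")
                              + pd.to_timedelta(telemetry["time_h"], "h"))
    telemetry = telemetry[["time_h", "timestamp", "channel", "value"]]

    # blood panels on the draw grid, pre-injury draws included
    t_lab = np.arange(-config.baseline_h, config.duration_h
                      + config.blooddraw_interval_h / 2,
                      config.blooddraw_interval_h)
    post_lab = np.clip(t_lab, 0.0, None)
    lab_frames = []
    for name, spec in config.channels.items():
        if spec.kind != "lab":
            continue
        vals = spec.day_mean + rng.normal(0.0, spec.effective_noise_sd, t_lab.size)
        if injured:
            vals = vals + (injury_response(post_lab, spec, 0.0))
        if spec.floor is not None:
            below = vals < spec.floor
            n_clipped += int(below.sum())
            vals = np.where(below, spec.floor, vals)
        lab_frames.append(pd.DataFrame({
            "time_h": t_lab, "analyte": name, "value": vals}))
    labs = pd.concat(lab_frames, ignore_index=True) if lab_frames else \
        pd.DataFrame(columns=["time_h", "analyte", "value"])

    # SNORT on the same assessment grid
    sn = config.snort
    target = np.full(t_lab.size, float(sn.healthy))
    if injured:
        target = target + sn.amplitude * gamma_kernel(
            post_lab, sn.peak_time_h, sn.recovery_shape)
    resid = _ar1(t_lab.size, sn.resid_sd, sn.resid_autocorr, rng)
    scores = np.clip(np.round(target + resid), sn.lo, sn.hi).astype(int)
    snort = pd.DataFrame({"time_h": t_lab, "score": scores})

    if n_clipped:
        logger.info("animal %s: clipped %d samples at physical floors",
                    animal_id, n_clipped)

    if death_time_h is not None:
        telemetry = telemetry[telemetry["time_h"] < death_time_h].reset_index(drop=True)
        labs = labs[labs["time_h"] < death_time_h].reset_index(drop=True)
        snort = snort[snort["time_h"] < death_time_h].reset_index(drop=True)

    return AnimalCourse(animal_id=animal_id, group=group, telemetry=telemetry,
                        labs=labs, snort=snort, death_time_h=death_time_h)


def simulate_cohort(config: SimulationConfig) -> list[AnimalCourse]:
    """Simulate one full cohort; reproducible given ``config.seed``."""
    root = np.random.SeedSequence(config.seed)
    n_animals = config.n_control + config.n_pat
    children = root.spawn(n_animals + 1)
    death_times = draw_survival(config, np.random.default_rng(children[0]))

    courses: list[AnimalCourse] = []
    for i in range(config.n_control):
        rng = np.random.default_rng(children[1 + i])
        courses.append(_simulate_animal(f"con{i + 1:02d}", CONTROL, config, rng, None))
    for j in range(config.n_pat):
        rng = np.random.default_rng(children[1 + config.n_control + j])
        dt = death_times[j]
        courses.append(_simulate_animal(
            f"pat{j + 1:02d}", PAT, config, rng,
            None if np.isnan(dt) else float(dt)))
    return courses


# ---------------------------------------------------------------------------
# cohort I/O: one telemetry CSV per animal, cohort-wide labs/SNORT CSVs and
# a YAML manifest echoing the configuration and seed.


def _config_to_dict(config: SimulationConfig) -> dict:
    d = dataclasses.asdict(config)
    d["channels"] = {k: dataclasses.asdict(v) for k, v in config.channels.items()}
    return d


def config_from_dict(d: Mapping) -> SimulationConfig:
    d = dict(d)
    if "channels" in d:
        d["channels"] = {k: ChannelSpec(**v) for k, v in d["channels"].items()}
    if "snort" in d and not isinstance(d["snort"], SnortSpec):
        d["snort"] = SnortSpec(**d["snort"])
    if "death_times" in d and not isinstance(d["death_times"], LogNormalDeathTimes):
        d["death_times"] = LogNormalDeathTimes(**d["death_times"])
    return SimulationConfig(**d)


def load_config(path: str | Path) -> SimulationConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh) or {})


def write_cohort(courses: Sequence[AnimalCourse], outdir: str | Path,
                 config: SimulationConfig | None = None) -> Path:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    labs_all, snort_all, roster = [], [], []
    for c in courses:
        tel = c.telemetry.copy()
        tel["timestamp"] = tel["timestamp"].dt.strftime("%Y-%m-%dT%H:%M:%S")
        tel.to_csv(outdir / f"telemetry_{c.animal_id}.csv", index=False)
        labs_all.append(c.labs.assign(animal_id=c.animal_id))
        snort_all.append(c.snort.assign(animal_id=c.animal_id))
        roster.append({"animal_id": c.animal_id, "group": c.group,
                       "death_time_h": c.death_time_h})
    cols = ["animal_id", "time_h", "analyte", "value"]
    pd.concat(labs_all, ignore_index=True)[cols].to_csv(outdir / "labs.csv", index=False)
    pd.concat(snort_all, ignore_index=True)[
        ["animal_id", "time_h", "score"]].to_csv(outdir / "snort.csv", index=False)
    manifest = {"roster": roster}
    if config is not None:
        manifest["config"] = json.loads(json.dumps(_config_to_dict(config)))
    with open(outdir / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return outdir


def read_cohort(indir: str | Path) -> tuple[list[AnimalCourse], SimulationConfig | None]:
    indir = Path(indir)
    with open(indir / "manifest.yaml") as fh:
        manifest = yaml.safe_load(fh)
    config = config_from_dict(manifest["config"]) if "config" in manifest else None
    labs = pd.read_csv(indir / "labs.csv")
    snort = pd.read_csv(indir / "snort.csv")
    courses = []
    for row in manifest["roster"]:
        aid = row["animal_id"]
        tel = pd.read_csv(indir / f"telemetry_{aid}.csv", parse_dates=["timestamp"])
        dt = row.get("death_time_h")
        courses.append(AnimalCourse(
            animal_id=aid, group=row["group"], telemetry=tel,
            labs=labs[labs["animal_id"] == aid].drop(columns="animal_id").reset_index(drop=True),
            snort=snort[snort["animal_id"] == aid].drop(columns="animal_id").reset_index(drop=True),
            death_time_h=None if dt is None else float(dt)))
    return courses, config
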