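"""Synthetic cohorts of fixational eye-tracking recordings.

The generator emulates the statistical structure the downstream analysis
assumes: 300 Hz binocular recordings of a 2-minute fixation task, with

* gaze = Ornstein-Uhlenbeck drift + renewal-process microsaccades
  (instantaneous step displacements that relax exponentially; inter-saccade
  intervals Gamma-distributed with a tunable coefficient of variation) +
  sinusoidal high-frequency tremor + white tracker noise;
* pupil = baseline + slow hippus oscillation + per-eye noise, with blinks
  inserted as binocular invalid spans (Poisson onsets, uniform duration);
* a cohort manifest with group label, medication status and covariates
  (age, sex, ADHD self-report scores) drawn from group-matched
  distributions.

The clinical contrast is built in by construction: the ADHD-like group has
a higher microsaccade rate with more regular timing (lower inter-saccade
interval CV) and more stereotyped amplitudes — a more predictable, lower-
entropy trace — and a larger pupil baseline.  These are mechanistic
stand-ins chosen to carry the direction of the group effects, not a
physiological eye model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import signal as _signal

from .preprocessing import GazeRecording

__all__ = [
    "SimulationParams",
    "CohortConfig",
    "TD_PARAMS",
    "ADHD_PARAMS",
    "generate_fixation_trace",
    "generate_pupil_trace",
    "generate_recording",
    "generate_cohort",
]


@dataclass(frozen=True)
class SimulationParams:
    """Mechanistic parameters of one group's simulated recordings.

    Gaze components (degrees of visual angle):
      drift_diffusion  OU diffusion constant, deg^2/s
      drift_reversion  OU mean-reversion rate, 1/s
      microsaccade_rate       events/s
      microsaccade_amp_mean   deg
      microsaccade_amp_cv     amplitude CV (0 = stereotyped)
      isi_regularity          CV of inter-saccade intervals (lower = more
                              regular timing, entropy-lowering)
      saccade_relax_tau_s     decay constant of the post-step relaxation, s
      tremor_amp, tremor_freq sinusoidal tremor (freq must exceed 30 Hz so
                              the 0.1-30 Hz band-pass attenuates it, as for
                              real ocular tremor)
      noise_sd                white tracker noise, deg

    Pupil components (mm):
      pupil_baseline, hippus_amp, hippus_freq, pupil_noise_sd
      blink_rate (events/min), blink_dur_range (ms)
    """

    drift_diffusion: float = 0.01
    drift_reversion: float = 5.0
    microsaccade_rate: float = 1.2
    microsaccade_amp_mean: float = 0.3
    microsaccade_amp_cv: float = 0.5
    isi_regularity: float = 0.6
    saccade_relax_tau_s: float = 0.08
    tremor_amp: float = 0.004
    tremor_freq: float = 80.0
    noise_sd: float = 0.05
    pupil_baseline: float = 4.0
    hippus_amp: float = 0.10
    hippus_freq: float = 0.2
    pupil_noise_sd: float = 0.05
    blink_rate: float = 8.0
    blink_dur_range: tuple[float, float] = (100.0, 300.0)
    # between-participant heterogeneity: additive SD of the individual pupil
    # baseline (mm; 0.4 reproduces a ~1 SD group effect at a 0.4 mm offset)
    # and multiplicative lognormal jitter (CV) on the oculomotor parameters
    pupil_between_sd: float = 0.4
    param_jitter_cv: float = 0.2

    def __post_init__(self) -> None:
        nonneg = (
            "drift_diffusion", "drift_reversion", "microsaccade_rate",
            "microsaccade_amp_mean", "microsaccade_amp_cv", "isi_regularity",
            "tremor_amp", "noise_sd", "hippus_amp", "hippus_freq",
            "pupil_noise_sd", "blink_rate", "pupil_between_sd", "param_jitter_cv",
        )
        for name in nonneg:
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.pupil_baseline <= 0:
            raise ValueError("pupil_baseline must be > 0")
        if self.tremor_amp > 0 and self.tremor_freq <= 30.0:
            raise ValueError(
                "tremor_freq must exceed 30 Hz so the gaze band-pass attenuates it"
            )
        lo, hi = self.blink_dur_range
        if not (0 < lo <= hi):
            raise ValueError("blink_dur_range must satisfy 0 < lo <= hi")


#: typical-development defaults: irregular microsaccade timing and amplitude
TD_PARAMS = SimulationParams()

#: ADHD-like defaults: more frequent, temporally regular, stereotyped
#: microsaccades (lower-entropy trace) and a larger pupil baseline
ADHD_PARAMS = SimulationParams(
    microsaccade_rate=1.8,
    microsaccade_amp_mean=0.45,
    microsaccade_amp_cv=0.10,
    isi_regularity=0.15,
    pupil_baseline=4.4,
)


@dataclass(frozen=True)
class CohortConfig:
    """Layout of a simulated cohort (defaults mirror the 20/16/11 study groups)."""

    n_td: int = 20
    n_adhd: int = 16
    n_drug_naive: int = 11
    duration_s: float = 120.0
    fs_hz: float = 300.0
    group_params: dict[str, SimulationParams] = field(
        default_factory=lambda: {"TD": TD_PARAMS, "ADHD": ADHD_PARAMS}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_td < 0 or self.n_adhd < 0 or self.n_drug_naive < 0:
            raise ValueError("group sizes must be non-negative")
        if self.n_drug_naive > self.n_adhd:
            raise ValueError(
                f"n_drug_naive ({self.n_drug_naive}) cannot exceed n_adhd ({self.n_adhd})"
            )
        n = self.duration_s * self.fs_hz
        if abs(n - round(n)) > 1e-9:
            raise ValueError("duration_s * fs_hz must be an integer sample count")
        for grp in ("TD", "ADHD"):
            if grp not in self.group_params:
                raise ValueError(f"group_params missing entry for {grp!r}")


def _renewal_event_times(
    rate: float, cv: float, duration_s: float, rng: np.random.Generator
) -> np.ndarray:
    """Event onsets of a renewal process with Gamma inter-event intervals.

    mean ISI = 1/rate; CV controls regularity (cv -> 0 gives a clock-like
    train, cv = 1 recovers a Poisson process)."""
    if rate <= 0:
        return np.empty(0)
    mean_isi = 1.0 / rate
    # draw enough intervals to cover the recording with margin
    n_draw = max(16, int(duration_s * rate * 2 + 20))
    times: list[float] = []
    t = 0.0
    while True:
        if cv <= 1e-9:
            isis = np.full(n_draw, mean_isi)
        else:
            shape = 1.0 / cv**2
            isis = rng.gamma(shape, mean_isi / shape, size=n_draw)
        for isi in isis:
            t += isi
            if t >= duration_s:
                return np.asarray(times)
            times.append(t)


def generate_fixation_trace(
    params: SimulationParams,
    duration_s: float,
    fs_hz: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Simulate horizontal and vertical gaze series plus a microsaccade log.

    Returns ``(gaze_h, gaze_v, events)`` where ``events`` has columns
    onset_s, amplitude_deg, direction_rad.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    dt = 1.0 / fs_hz

    # exact OU discretization: x_{t+1} = a x_t + s N(0,1)
    a = np.exp(-params.drift_reversion * dt)
    if params.drift_reversion > 0:
        s = np.sqrt(
            params.drift_diffusion / (2 * params.drift_reversion) * (1 - a**2)
        )
    else:
        s = np.sqrt(params.drift_diffusion * dt)
    drift = np.zeros((n, 2))
    if params.drift_diffusion > 0:
        shocks = rng.standard_normal((n, 2)) * s
        for axis in range(2):
            drift[:, axis] = _signal.lfilter([1.0], [1.0, -a], shocks[:, axis])

    onsets = _renewal_event_times(
        params.microsaccade_rate, params.isi_regularity, duration_s, rng
    )
    amps = np.empty(0)
    angles = np.empty(0)
    sacc = np.zeros((n, 2))
    if onsets.size:
        if params.microsaccade_amp_cv <= 1e-9:
            amps = np.full(onsets.size, params.microsaccade_amp_mean)
        else:
            shape = 1.0 / params.microsaccade_amp_cv**2
            amps = rng.gamma(
                shape, params.microsaccade_amp_mean / shape, size=onsets.size
            )
        angles = rng.uniform(0, 2 * np.pi, size=onsets.size)
        impulses = np.zeros((n, 2))
        idx = np.minimum((onsets * fs_hz).astype(int), n - 1)
        np.add.at(impulses[:, 0], idx, amps * np.cos(angles))
        np.add.at(impulses[:, 1], idx, amps * np.sin(angles))
        # step + exponential relaxation = first-order IIR response
        decay = np.exp(-dt / params.saccade_relax_tau_s)
        for axis in range(2):
            sacc[:, axis] = _signal.lfilter([1.0], [1.0, -decay], impulses[:, axis])

    t = np.arange(n) * dt
    tremor = np.zeros((n, 2))
    if params.tremor_amp > 0:
        for axis in range(2):
            phase = rng.uniform(0, 2 * np.pi)
            tremor[:, axis] = params.tremor_amp * np.sin(
                2 * np.pi * params.tremor_freq * t + phase
            )

    noise = (
        rng.standard_normal((n, 2)) * params.noise_sd
        if params.noise_sd > 0
        else np.zeros((n, 2))
    )

    gaze = drift + sacc + tremor + noise
    events = pd.DataFrame(
        {"onset_s": onsets, "amplitude_deg": amps, "direction_rad": angles}
    )
    return gaze[:, 0], gaze[:, 1], events


def generate_pupil_trace(
    params: SimulationParams,
    duration_s: float,
    fs_hz: float,
    seed: int | np.random.SeedSequence,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate left/right pupil series and a shared blink mask.

    Both eyes share the baseline + hippus component and the blink spans
    (blinks are binocular); they differ only by independent measurement
    noise.  Returns ``(pupil_l, pupil_r, blink)`` with ``blink`` a boolean
    mask of invalid samples.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be > 0")
    rng = np.random.default_rng(seed)
    n = int(round(duration_s * fs_hz))
    t = np.arange(n) / fs_hz

    base = params.pupil_baseline * np.ones(n)
    if params.hippus_amp > 0:
        phase = rng.uniform(0, 2 * np.pi)
        base = base + params.hippus_amp * np.sin(
            2 * np.pi * params.hippus_freq * t + phase
        )
    if params.pupil_noise_sd > 0:
        left = base + rng.standard_normal(n) * params.pupil_noise_sd
        right = base + rng.standard_normal(n) * params.pupil_noise_sd
    else:
        left = base.copy()
        right = base.copy()

    blink = np.zeros(n, dtype=bool)
    if params.blink_rate > 0:
        onsets = _renewal_event_times(params.blink_rate / 60.0, 1.0, duration_s, rng)
        lo_ms, hi_ms = params.blink_dur_range
        for onset in onsets:
            dur_s = rng.uniform(lo_ms, hi_ms) / 1000.0
            i0 = int(onset * fs_hz)
            i1 = min(n, i0 + max(1, int(round(dur_s * fs_hz))))
            blink[i0:i1] = True
    # tracker reports no diameter during a blink
    left[blink] = 0.0
    right[blink] = 0.0
    return left, right, blink


_JITTERED_FIELDS = (
    "drift_diffusion", "microsaccade_rate", "microsaccade_amp_mean",
    "isi_regularity", "noise_sd",
)


def _individualize(params: SimulationParams, rng: np.random.Generator) -> SimulationParams:
    """Draw one participant's parameters around the group values."""
    updates: dict[str, float] = {}
    cv = params.param_jitter_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1 + cv**2))
        for name in _JITTERED_FIELDS:
            base = getattr(params, name)
            if base > 0:
                updates[name] = float(base * rng.lognormal(-sigma**2 / 2, sigma))
    if params.pupil_between_sd > 0:
        updates["pupil_baseline"] = float(
            max(0.5, rng.normal(params.pupil_baseline, params.pupil_between_sd))
        )
    return replace(params, **updates) if updates else params


def generate_recording(
    participant_id: str,
    params: SimulationParams,
    duration_s: float,
    fs_hz: float,
    seed: int | np.random.SeedSequence,
) -> GazeRecording:
    """One participant's full synthetic recording (gaze + pupil + validity).

    Between-participant heterogeneity is applied here (not in the trace
    generators): the participant's pupil baseline is drawn around the group
    baseline with SD ``pupil_between_sd``, and the oculomotor parameters
    receive multiplicative lognormal jitter with CV ``param_jitter_cv``.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    jitter_seed, gaze_seed, pupil_seed = ss.spawn(3)
    params = _individualize(params, np.random.default_rng(jitter_seed))
    gaze_h, gaze_v, _ = generate_fixation_trace(params, duration_s, fs_hz, gaze_seed)
    pupil_l, pupil_r, blink = generate_pupil_trace(params, duration_s, fs_hz, pupil_seed)
    n = gaze_h.size
    valid = ~blink
    return GazeRecording(
        participant_id=participant_id,
        time=np.arange(n) / fs_hz,
        gaze_h=gaze_h,
        gaze_v=gaze_v,
        pupil_l=pupil_l,
        pupil_r=pupil_r,
        valid_l=valid.copy(),
        valid_r=valid.copy(),
        fs_hz=fs_hz,
    )


# Covariate distributions per group: (age mean, sd), ASRS subscale (mean, sd)
# pairs matched to the study cohort's demographics; ASRS total = IN + Hyp/I.
_AGE_DIST = {"TD": (37.0, 7.90), "ADHD_NAIVE": (28.5, 4.41), "ADHD_MED": (39.7, 8.0)}
_ASRS_IN_DIST = {"TD": (12.5, 6.64), "ADHD": (25.5, 6.86)}
_ASRS_HYPI_DIST = {"TD": (8.30, 5.42), "ADHD": (17.6, 6.86)}
_MALE_FRACTION = {"TD": 8 / 20, "ADHD_NAIVE": 4 / 11, "ADHD_MED": 4 / 5}


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float, size: int
) -> np.ndarray:
    return np.clip(rng.normal(mean, sd, size=size), lo, hi)


def generate_cohort(
    config: CohortConfig = CohortConfig(),
) -> tuple[list[GazeRecording], pd.DataFrame]:
    """Simulate a full cohort: one recording and one manifest row per participant.

    Fully reproducible from ``config.seed``: every participant gets a child
    stream of a single seeded generator hierarchy, so cohorts are stable
    regardless of generation order.
    """
    root = np.random.SeedSequence(config.seed)
    n_total = config.n_td + config.n_adhd
    child_seeds = root.spawn(n_total + 1)
    cov_rng = np.random.default_rng(child_seeds[-1])

    rows = []
    recordings: list[GazeRecording] = []
    specs: list[tuple[str, str, bool]] = []  # (pid, group, drug_naive)
    for i in range(config.n_td):
        specs.append((f"TD{i + 1:03d}", "TD", False))
    for i in range(config.n_adhd):
        specs.append((f"ADHD{i + 1:03d}", "ADHD", i < config.n_drug_naive))

    for k, (pid, group, naive) in enumerate(specs):
        params = config.group_params[group]
        rec = generate_recording(
            pid, params, config.duration_s, config.fs_hz, child_seeds[k]
        )
        recordings.append(rec)

        subgroup = "TD" if group == "TD" else ("ADHD_NAIVE" if naive else "ADHD_MED")
        age_mu, age_sd = _AGE_DIST[subgroup]
        age = float(_truncated_normal(cov_rng, age_mu, age_sd, 18.0, 65.0, 1)[0])
        in_mu, in_sd = _ASRS_IN_DIST[group]
        hy_mu, hy_sd = _ASRS_HYPI_DIST[group]
        asrs_in = int(round(_truncated_normal(cov_rng, in_mu, in_sd, 0.0, 36.0, 1)[0]))
        asrs_hypi = int(round(_truncated_normal(cov_rng, hy_mu, hy_sd, 0.0, 36.0, 1)[0]))
        rows.append(
            {
                "participant_id": pid,
                "group": group,
                "drug_naive": int(naive),
                "age_years": round(age, 1),
                "sex": "",  # assigned below to match group sex ratios
                "asrs_total": asrs_in + asrs_hypi,
                "asrs_in": asrs_in,
                "asrs_hypi": asrs_hypi,
                "_subgroup": subgroup,
            }
        )

    manifest = pd.DataFrame(
        rows,
        columns=[
            "participant_id", "group", "drug_naive", "age_years", "sex",
            "asrs_total", "asrs_in", "asrs_hypi", "_subgroup",
        ],
    )
    # deterministic sex assignment matching each subgroup's male fraction
    for subgroup, frac in _MALE_FRACTION.items():
        idx = manifest.index[manifest["_subgroup"] == subgroup]
        n_male = int(round(frac * len(idx)))
        sexes = ["M"] * n_male + ["F"] * (len(idx) - n_male)
        manifest.loc[idx, "sex"] = sexes
    manifest = manifest.drop(columns="_subgroup")
    return recordings, manifest
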