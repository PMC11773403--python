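"""Synthetic cohorts with the statistical structure the pipeline assumes.

No participant-level data from the underlying trial are public, so every
downstream stage is exercised on simulated cohorts that emulate the study
design: 63-channel eyes-closed resting EEG with a 1/f background and a
participant-specific alpha oscillation with a sensorimotor-weighted
topography; 1 cm-spaced TMS motor maps on day 0/2/5 with planted
facilitation or depression; and twice-daily 30-day pain diaries drawn from
two latent trajectory classes. Class membership is statistically coupled to
PAF (high-pain participants have slower alpha) and to corticomotor change
(high-pain participants are more often depressors), with the coupling
strengths fully configurable — including a null configuration with no
coupling at all.

EEG is held lazily: each participant record stores per-session seeds and
regenerates the recording deterministically on demand, so a full cohort
never needs all recordings in memory at once.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .cme import MapGrid
from .layout import SENSORIMOTOR_CHANNELS, STANDARD_63, positions_for
from .paf import EEGRecording
from .trajectory import HIGH, LOW, TIME_OFFSETS


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class TrajectoryParams:
    """Polynomial mean trajectory of one latent pain class (0-20 scale)."""

    intercept: float
    slope: float = 0.0
    quadratic: float = 0.0
    within_noise_sd: float = 1.0
    between_sd: float = 1.0

    def __post_init__(self) -> None:
        if self.intercept < 0:
            raise ValueError("TrajectoryParams.intercept must be >= 0")
        if self.within_noise_sd <= 0:
            raise ValueError("TrajectoryParams.within_noise_sd must be > 0")
        if self.between_sd < 0:
            raise ValueError("TrajectoryParams.between_sd must be >= 0")

    def mean(self, day: np.ndarray) -> np.ndarray:
        day = np.asarray(day, dtype=float)
        return self.intercept + self.slope * day + self.quadratic * day**2


@dataclass(frozen=True)
class EEGSimParams:
    """Resting-EEG simulation settings (defaults emulate the protocol:
    5-minute eyes-closed recording from 63 electrodes)."""

    n_channels: int = 63
    duration: float = 300.0          # seconds
    sfreq: float = 250.0             # Hz
    aperiodic_exponent: float = 1.0  # 1/f^x background slope
    alpha_amplitude_snr: float = 20.0  # alpha/background band-power ratio
    alpha_bandwidth: float = 1.0     # Hz
    sensorimotor_channels: tuple[str, ...] = tuple(SENSORIMOTOR_CHANNELS)
    topography_sigma: float = 0.35   # spatial falloff of the alpha gain
    off_source_gain_floor: float = 0.05

    def __post_init__(self) -> None:
        if self.alpha_amplitude_snr < 0:
            raise ValueError("EEGSimParams.alpha_amplitude_snr must be >= 0 "
                             "(0 simulates an alpha-free recording)")
        if self.duration * self.sfreq < 2 * 4 * self.sfreq:
            raise ValueError("EEGSimParams.duration must cover >= 2 "
                             "spectral segments (8 s)")
        if self.n_channels < len(self.sensorimotor_channels):
            raise ValueError("EEGSimParams.n_channels smaller than the "
                             "sensorimotor channel set")
        if self.n_channels > len(STANDARD_63):
            raise ValueError(f"EEGSimParams.n_channels must be <= "
                             f"{len(STANDARD_63)}")

    @property
    def ch_names(self) -> list[str]:
        # keep the sensorimotor channels in every reduced montage
        keep = [c for c in STANDARD_63 if c in self.sensorimotor_channels]
        rest = [c for c in STANDARD_63 if c not in self.sensorimotor_channels]
        return sorted(keep + rest[: self.n_channels - len(keep)],
                      key=STANDARD_63.index)


@dataclass(frozen=True)
class MapSimParams:
    """TMS motor-map simulation settings (1 cm grid convention)."""

    grid_shape: tuple[int, int] = (9, 9)
    hotspot_center: tuple[float, float] = (4.0, 4.0)
    spatial_sd: float = 1.5          # cm
    base_amplitude: float = 1.0      # mV at the hotspot
    facilitation_factor_range: tuple[float, float] = (1.2, 1.8)
    depression_factor_range: tuple[float, float] = (0.45, 0.8)
    trial_noise_sd: float = 0.08     # mV
    trials_per_site: int = 3
    day2_carryover: float = 0.6      # fraction of the day-5 log-modulation
                                     # already present on day 2

    def __post_init__(self) -> None:
        if self.depression_factor_range[1] >= 1.0:
            raise ValueError("depression factors must be < 1")
        if self.facilitation_factor_range[0] <= 1.0:
            raise ValueError("facilitation factors must be > 1")
        if self.base_amplitude <= 0 or self.trial_noise_sd < 0:
            raise ValueError("map amplitudes must be positive")
        if self.trials_per_site < 1:
            raise ValueError("trials_per_site must be >= 1")


#: default class trajectories: progressively developing pain peaking within
#: the first week, substantially higher in the high-sensitivity class
DEFAULT_HIGH_TRAJECTORY = TrajectoryParams(
    intercept=2.0, slope=2.4, quadratic=-0.20,
    within_noise_sd=1.5, between_sd=1.2)
DEFAULT_LOW_TRAJECTORY = TrajectoryParams(
    intercept=0.5, slope=0.7, quadratic=-0.06,
    within_noise_sd=1.5, between_sd=1.0)


@dataclass(frozen=True)
class CohortConfig:
    """Everything needed to generate one synthetic cohort."""

    n_participants: int = 150
    train_fraction: float = 2.0 / 3.0
    seed: int = 0
    p_high: float = 0.5
    paf_mean_high: float = 9.5       # Hz, high-pain class
    paf_mean_low: float = 10.5       # Hz, low-pain class
    paf_sd: float = 0.5
    p_depressor_given_high: float = 0.75
    p_depressor_given_low: float = 0.25
    diary_high: TrajectoryParams = DEFAULT_HIGH_TRAJECTORY
    diary_low: TrajectoryParams = DEFAULT_LOW_TRAJECTORY
    diary_missing_rate: float = 0.05
    diary_days: int = 30
    covariate_class_coupling: float = 0.0  # 0 = covariates independent of class
    eeg: EEGSimParams = EEGSimParams()
    map: MapSimParams = MapSimParams()
    eeg_session_days: tuple[int, ...] = (0, 2, 5)
    map_session_days: tuple[int, ...] = (0, 2, 5)

    def __post_init__(self) -> None:
        for name in ("train_fraction", "p_high", "p_depressor_given_high",
                     "p_depressor_given_low", "diary_missing_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"CohortConfig.{name} must be in [0, 1]")
        if not 0 < self.train_fraction < 1:
            raise ValueError("CohortConfig.train_fraction must be in (0, 1)")
        if self.diary_missing_rate >= 1:
            raise ValueError("CohortConfig.diary_missing_rate must be < 1")
        for name in ("paf_mean_high", "paf_mean_low"):
            v = getattr(self, name)
            if not 8.0 <= v <= 12.0:
                raise ValueError(f"CohortConfig.{name} must lie in the "
                                 "8-12 Hz alpha band")
        if self.n_participants < 10:
            raise ValueError("CohortConfig.n_participants must be >= 10")
        if not 0 in self.map_session_days or 5 not in self.map_session_days:
            raise ValueError("map_session_days must include day 0 and day 5")

    @property
    def n_train(self) -> int:
        return int(round(self.n_participants * self.train_fraction))

    @property
    def n_test(self) -> int:
        return self.n_participants - self.n_train

    def null(self) -> "CohortConfig":
        """A no-signal variant: no PAF gap, equal depressor probability,
        identical trajectory classes."""
        mid = 0.5 * (self.paf_mean_high + self.paf_mean_low)
        return replace(self, paf_mean_high=mid, paf_mean_low=mid,
                       p_depressor_given_high=0.5, p_depressor_given_low=0.5,
                       diary_high=self.diary_low)


# ---------------------------------------------------------------------------
# EEG simulation

def _aperiodic_background(rng, n_channels, n_samples, sfreq, exponent):
    """1/f^exponent Gaussian background, unit variance per channel."""
    white = rng.standard_normal((n_channels, n_samples))
    spec = np.fft.rfft(white, axis=1)
    freqs = np.fft.rfftfreq(n_samples, d=1.0 / sfreq)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape[None, :], n=n_samples, axis=1)
    x /= x.std(axis=1, keepdims=True)
    return x


def _bursty_alpha_source(rng, n_samples, sfreq, center, bandwidth):
    """Amplitude-modulated narrowband oscillation at the planted PAF.

    Narrowband-filtered noise gives a realistic peak with spectral width;
    the slow waxing-and-waning envelope makes the source leptokurtic so
    that ICA can isolate it from the Gaussian background.
    """
    carrier = rng.standard_normal(n_samples)
    lo = max(center - bandwidth / 2.0, 0.5)
    hi = min(center + bandwidth / 2.0, sfreq / 2.0 - 0.5)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=sfreq,
                        output="sos")
    carrier = signal.sosfiltfilt(sos, carrier)
    env_noise = rng.standard_normal(n_samples)
    sos_env = signal.butter(2, 0.3, btype="lowpass", fs=sfreq, output="sos")
    env = signal.sosfiltfilt(sos_env, env_noise)
    env = 0.25 + np.abs(env) / np.abs(env).std()
    src = carrier * env
    return src / src.std()


def _alpha_gain(params: EEGSimParams) -> np.ndarray:
    """Per-channel gain of the alpha source, peaking over the ROI."""
    names = params.ch_names
    pos = positions_for(names)
    roi_pos = positions_for(list(params.sensorimotor_channels))
    d2 = ((pos[:, None, :] - roi_pos[None, :, :]) ** 2).sum(axis=2).min(axis=1)
    gain = np.exp(-d2 / (2.0 * params.topography_sigma**2))
    return np.maximum(gain, params.off_source_gain_floor)


def generate_eeg(participant_paf: float, params: EEGSimParams,
                 seed: int | np.random.Generator) -> EEGRecording:
    """Simulate one resting recording with an alpha peak at the planted PAF.

    The background is channel-independent 1/f noise; the alpha oscillation
    is a single bursty narrowband source mixed through a sensorimotor-
    weighted gain vector. ``alpha_amplitude_snr`` is the alpha-to-background
    band-power ratio at a full-gain channel; 0 omits the oscillation.
    """
    if not 8.0 <= participant_paf <= 12.0:
        raise ValueError("participant_paf must lie in the 8-12 Hz band")
    if params.alpha_amplitude_snr < 0:
        raise ValueError("alpha_amplitude_snr must be >= 0")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    n_samples = int(round(params.duration * params.sfreq))
    names = params.ch_names
    bg = _aperiodic_background(rng, len(names), n_samples, params.sfreq,
                               params.aperiodic_exponent)
    data = bg
    if params.alpha_amplitude_snr > 0:
        src = _bursty_alpha_source(rng, n_samples, params.sfreq,
                                   participant_paf, params.alpha_bandwidth)
        # scale so alpha band power / background band power = SNR at gain 1
        sos = signal.butter(4, [8.0, 12.0], btype="bandpass",
                            fs=params.sfreq, output="sos")
        bg_band = signal.sosfiltfilt(sos, bg[0])
        scale = np.sqrt(params.alpha_amplitude_snr) * bg_band.std()
        gain = _alpha_gain(params)
        data = bg + gain[:, None] * (scale * src)[None, :]
    return EEGRecording(10.0 * data, params.sfreq, names,
                        positions_for(names))


# ---------------------------------------------------------------------------
# TMS map simulation

def _map_surface(params: MapSimParams) -> tuple[np.ndarray, np.ndarray]:
    rows, cols = params.grid_shape
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    coords = np.stack([rr.ravel(), cc.ravel()], axis=1)
    d2 = ((coords - np.asarray(params.hotspot_center)) ** 2).sum(axis=1)
    surface = params.base_amplitude * np.exp(-d2 / (2 * params.spatial_sd**2))
    return coords, surface


def generate_maps(is_depressor: bool, params: MapSimParams,
                  seed: int | np.random.Generator,
                  session_days: tuple[int, ...] = (0, 2, 5)
                  ) -> dict[int, MapGrid]:
    """Simulate motor maps with a persistent planted modulation.

    The day-5 map scales the day-0 amplitude surface by a factor drawn from
    the depression (< 1) or facilitation (> 1) range; day 2 carries a
    configurable fraction of the same modulation (on the log scale), so the
    planted direction persists across sessions.
    """
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    lo, hi = (params.depression_factor_range if is_depressor
              else params.facilitation_factor_range)
    factor5 = rng.uniform(lo, hi)
    coords, surface = _map_surface(params)
    out: dict[int, MapGrid] = {}
    for day in session_days:
        if day == 0:
            f = 1.0
        elif day == 5:
            f = factor5
        else:
            f = float(np.exp(params.day2_carryover * np.log(factor5)))
        trials = (f * surface)[:, None] + params.trial_noise_sd * \
            rng.standard_normal((surface.size, params.trials_per_site))
        amps = np.maximum(trials, 0.0).mean(axis=1)
        out[day] = MapGrid(coords, amps, session_day=day)
    return out


# ---------------------------------------------------------------------------
# pain diary simulation

def generate_pain_diary(participant: str, true_class: str,
                        high: TrajectoryParams, low: TrajectoryParams,
                        missing_rate: float,
                        seed: int | np.random.Generator,
                        days: int = 30) -> pd.DataFrame:
    """Twice-daily chewing/yawning diary for days 1..``days``.

    The summed (0-20) score follows the class polynomial plus a participant
    random intercept plus noise, rounded and clipped; it is then split into
    the two integer 0-10 activity scores. Missing timepoints are flagged
    with NaN scores, never zero-filled; both activities of a timepoint go
    missing together (missing completely at random).
    """
    if not 0 <= missing_rate < 1:
        raise ValueError("missing_rate must be in [0, 1)")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    params = high if true_class == HIGH else low
    b = rng.normal(0.0, params.between_sd)
    rows = []
    for day in range(1, days + 1):
        for tlabel in TIME_OFFSETS:
            t = day + TIME_OFFSETS[tlabel]
            total = params.mean(t) + b + rng.normal(0, params.within_noise_sd)
            total = int(np.clip(np.round(total), 0, 20))
            chewing = total - total // 2      # chewing rated slightly higher
            yawning = total // 2
            miss = rng.random() < missing_rate
            for activity, score in (("chewing", chewing),
                                    ("yawning", yawning)):
                rows.append({"participant": participant, "day": day,
                             "time": tlabel, "activity": activity,
                             "score": np.nan if miss else float(score),
                             "missing": bool(miss)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# cohort assembly

@dataclass
class Participant:
    """One synthetic participant; EEG is regenerated lazily from seeds."""

    pid: str
    true_class: str
    paf_true: float
    is_depressor_true: bool
    sex: str                     # "F" | "M"
    pcs_total: int
    pcs_helplessness: int
    maps: dict[int, MapGrid]
    diary: pd.DataFrame
    eeg_seeds: dict[int, int]
    eeg_params: EEGSimParams

    def eeg(self, day: int = 0) -> EEGRecording:
        if day not in self.eeg_seeds:
            raise KeyError(f"no EEG session simulated for day {day}")
        return generate_eeg(self.paf_true, self.eeg_params,
                            self.eeg_seeds[day])


@dataclass
class SyntheticCohort:
    config: CohortConfig
    participants: list[Participant]

    def __iter__(self):
        return iter(self.participants)

    def __len__(self) -> int:
        return len(self.participants)

    @property
    def train(self) -> list[Participant]:
        return self.participants[: self.config.n_train]

    @property
    def test(self) -> list[Participant]:
        return self.participants[self.config.n_train:]

    def diaries(self) -> pd.DataFrame:
        return pd.concat([p.diary for p in self.participants],
                         ignore_index=True)

    def truth_frame(self) -> pd.DataFrame:
        return pd.DataFrame([
            {"participant": p.pid, "true_class": p.true_class,
             "paf_true": p.paf_true,
             "is_depressor_true": p.is_depressor_true}
            for p in self.participants])


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Generate a deterministic cohort from a config.

    Participants are enrolled in order ``P001..`` and split into training
    and test sets by enrollment position (the nested control-test scheme).
    All randomness flows from ``config.seed`` through per-participant
    spawned substreams, so identical configs give bit-identical cohorts and
    participant *i* is unchanged by what was drawn for participant *j*.
    """
    root = np.random.SeedSequence(config.seed)
    part_seqs = root.spawn(config.n_participants)
    width = len(str(config.n_participants))
    participants = []
    for i, seq in enumerate(part_seqs):
        class_seq, map_seq, diary_seq, cov_seq, *eeg_seqs = seq.spawn(
            4 + len(config.eeg_session_days))
        rng = np.random.default_rng(class_seq)
        true_class = HIGH if rng.random() < config.p_high else LOW
        mean = (config.paf_mean_high if true_class == HIGH
                else config.paf_mean_low)
        paf = float(np.clip(rng.normal(mean, config.paf_sd), 8.05, 11.95))
        p_dep = (config.p_depressor_given_high if true_class == HIGH
                 else config.p_depressor_given_low)
        is_depressor = bool(rng.random() < p_dep)

        pid = f"P{i + 1:0{width}d}"
        maps = generate_maps(is_depressor, config.map,
                             np.random.default_rng(map_seq),
                             session_days=config.map_session_days)
        diary = generate_pain_diary(pid, true_class, config.diary_high,
                                    config.diary_low,
                                    config.diary_missing_rate,
                                    np.random.default_rng(diary_seq),
                                    days=config.diary_days)
        crng = np.random.default_rng(cov_seq)
        shift = config.covariate_class_coupling if true_class == HIGH else 0.0
        sex = "F" if crng.random() < 0.47 else "M"
        pcs_total = int(np.clip(round(crng.normal(14 + 4 * shift, 8)), 0, 52))
        pcs_help = int(np.clip(round(pcs_total * 0.35
                                     + crng.normal(0, 1.5)), 0, 24))
        eeg_seeds = {day: int(s.generate_state(1)[0] % (2**31))
                     for day, s in zip(config.eeg_session_days, eeg_seqs)}
        participants.append(Participant(
            pid=pid, true_class=true_class, paf_true=paf,
            is_depressor_true=is_depressor, sex=sex, pcs_total=pcs_total,
            pcs_helplessness=pcs_help, maps=maps, diary=diary,
            eeg_seeds=eeg_seeds, eeg_params=config.eeg))
    return SyntheticCohort(config=config, participants=participants)


# ---------------------------------------------------------------------------
# on-disk layout (schema version 1)

SCHEMA_VERSION = 1


def write_cohort(cohort: SyntheticCohort, out_dir: str | Path,
                 include_eeg: bool = False) -> Path:
    """Write a cohort to a directory: maps and diaries as CSV, ground truth
    and config as JSON, EEG (optionally) as .npy arrays with JSON sidecars.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cohort.diaries().to_csv(out / "diaries.csv", index=False)
    map_rows = []
    for p in cohort:
        for day, grid in p.maps.items():
            for (r, c), a in zip(grid.site_coords, grid.site_amplitude):
                map_rows.append({"participant": p.pid, "day": day,
                                 "row": int(r), "col": int(c),
                                 "amplitude_mv": float(a)})
    pd.DataFrame(map_rows).to_csv(out / "maps.csv", index=False)
    truth = cohort.truth_frame().to_dict(orient="records")
    meta = {"schema_version": SCHEMA_VERSION,
            "n_participants": len(cohort),
            "seed": cohort.config.seed,
            "truth": truth}
    (out / "ground_truth.json").write_text(json.dumps(meta, indent=2))
    if include_eeg:
        eeg_dir = out / "eeg"
        eeg_dir.mkdir(exist_ok=True)
        for p in cohort:
            for day in p.eeg_seeds:
                rec = p.eeg(day)
                stem = eeg_dir / f"{p.pid}_day{day}"
                np.save(f"{stem}.npy", rec.data)
                sidecar = {"sfreq": rec.sfreq, "ch_names": rec.ch_names,
                           "units": "uV", "schema_version": SCHEMA_VERSION}
                Path(f"{stem}.json").write_text(json.dumps(sidecar))
    return out
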