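"""Synthetic EEG cohorts with a controllable happy/unhappy band-power contrast.

The study protocol this emulates: 10 subjects, 5 trials each; every trial is a
60 s "happy" stimulus period and a 60 s "unhappy" stimulus period separated by
12 s of rest, recorded on the 14-channel EMOTIV montage at 128 Hz.  No real
recordings are available, so each channel is synthesised as a sum over the five
classical EEG bands of band-limited Gaussian noise whose amplitude is modulated
by the emotion class: during a labelled segment the band amplitude at a channel
is ``noise_floor * (1 + attenuation * (gain - 1))``, during rest all gains
are 1.  Band power is the only signal property the downstream pipeline
consumes, so this is the minimal generative model that exercises it.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

__all__ = [
    "EMOTIV_CHANNELS",
    "BAND_NAMES",
    "BAND_EDGES",
    "Segment",
    "EEGRecording",
    "CohortSpec",
    "generate_trial",
    "generate_cohort",
    "study_spec",
    "null_spec",
    "strong_effect_spec",
]

#: The 14-channel EMOTIV montage, fixed order (10-20 system labels).
EMOTIV_CHANNELS: tuple[str, ...] = (
    "AF3", "AF4", "F3", "F4", "F7", "F8", "FC5", "FC6",
    "P7", "P8", "T7", "T8", "O1", "O2",
)

#: Band order used everywhere downstream (low to high frequency).
BAND_NAMES: tuple[str, ...] = ("delta", "theta", "alpha", "beta", "gamma")

#: Nominal band edges in Hz at 128 Hz sampling (dyadic halving of [0, 64]).
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 16.0),
    "beta": (16.0, 32.0),
    "gamma": (32.0, 64.0),
}

HAPPY = "happy"
UNHAPPY = "unhappy"
REST = "rest"

#: 1/f-like per-band RMS amplitude floor, microvolt-ish units.
DEFAULT_NOISE_FLOOR: dict[str, float] = {
    "delta": 20.0, "theta": 10.0, "alpha": 8.0, "beta": 5.0, "gamma": 3.0,
}


@dataclass(frozen=True)
class Segment:
    """Half-open sample interval [start, stop) with an emotion label."""

    start: int
    stop: int
    label: str

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.stop):
            raise ValueError(f"invalid segment bounds [{self.start}, {self.stop})")
        if self.label not in (HAPPY, UNHAPPY, REST):
            raise ValueError(f"unknown segment label {self.label!r}")

    @property
    def n_samples(self) -> int:
        return self.stop - self.start


@dataclass
class EEGRecording:
    """One trial of multichannel EEG with labelled stimulus segments."""

    subject_id: int
    trial_id: int
    signal: np.ndarray  # (n_channels, n_samples)
    sampling_rate: float
    channel_names: tuple[str, ...]
    segments: list[Segment]

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValueError("signal must be a channels x samples matrix")
        if self.signal.shape[0] != len(self.channel_names):
            raise ValueError(
                f"signal has {self.signal.shape[0]} rows but "
                f"{len(self.channel_names)} channel names"
            )
        n = self.signal.shape[1]
        prev_stop = 0
        prev_label = None
        for seg in self.segments:
            if seg.start < prev_stop or seg.stop > n:
                raise ValueError("segments must be sorted, non-overlapping, in range")
            if seg.label != REST:
                if prev_label == seg.label:
                    raise ValueError("labelled segments must alternate happy/unhappy")
                prev_label = seg.label
            prev_stop = seg.stop

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate

    def labelled_segments(self) -> list[Segment]:
        return [s for s in self.segments if s.label != REST]

    def copy_with(self, signal: np.ndarray) -> "EEGRecording":
        return EEGRecording(
            subject_id=self.subject_id,
            trial_id=self.trial_id,
            signal=signal,
            sampling_rate=self.sampling_rate,
            channel_names=self.channel_names,
            segments=list(self.segments),
        )


# band gains are nested mappings {class: {channel: {band: linear gain}}};
# anything absent defaults to 1 (no effect).
BandGains = Mapping[str, Mapping[str, Mapping[str, float]]]


@dataclass
class CohortSpec:
    """Generative parameters of a synthetic study cohort."""

    n_subjects: int = 10
    n_trials_per_subject: int = 5
    sampling_rate: float = 128.0
    channel_names: tuple[str, ...] = EMOTIV_CHANNELS
    stimulus_duration: float = 60.0
    rest_duration: float = 12.0
    band_gains: BandGains = field(default_factory=dict)
    subject_band_gains: dict[int, BandGains] = field(default_factory=dict)
    attenuation_factors: dict[int, float] = field(default_factory=dict)
    noise_floor: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_NOISE_FLOOR)
    )
    seed: int = 0

    def __post_init__(self) -> None:
        self.channel_names = tuple(self.channel_names)
        self.validate()

    def validate(self) -> None:
        if self.n_subjects < 1 or self.n_trials_per_subject < 1:
            raise ValueError("need at least one subject and one trial")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.stimulus_duration <= 0 or self.rest_duration <= 0:
            raise ValueError("stimulus and rest durations must be positive")
        if len(self.channel_names) != len(set(self.channel_names)):
            raise ValueError("channel names must be distinct")
        if self.seed < 0:
            raise ValueError("seed must be non-negative")
        for gains in (self.band_gains, *self.subject_band_gains.values()):
            for cls, per_ch in gains.items():
                if cls not in (HAPPY, UNHAPPY):
                    raise ValueError(f"unknown emotion class {cls!r} in band_gains")
                for ch, per_band in per_ch.items():
                    if ch not in self.channel_names:
                        raise ValueError(f"unknown channel {ch!r} in band_gains")
                    for band, g in per_band.items():
                        if band not in BAND_NAMES:
                            raise ValueError(f"unknown band {band!r} in band_gains")
                        if g < 0:
                            raise ValueError("band gains must be >= 0")
        for sid, a in self.attenuation_factors.items():
            if a < 0:
                raise ValueError("attenuation factors must be >= 0")
        for band in BAND_NAMES:
            if self.noise_floor.get(band, 0.0) < 0:
                raise ValueError("noise floor amplitudes must be >= 0")

    def attenuation(self, subject_id: int) -> float:
        return float(self.attenuation_factors.get(subject_id, 1.0))

    def gains_for(self, subject_id: int) -> BandGains:
        return self.subject_band_gains.get(subject_id, self.band_gains)

    def gain(self, subject_id: int, cls: str, channel: str, band: str) -> float:
        gains = self.gains_for(subject_id)
        return float(gains.get(cls, {}).get(channel, {}).get(band, 1.0))


def _band_sos(band: str, fs: float, order: int = 4) -> np.ndarray:
    lo, hi_nominal = BAND_EDGES[band]
    nyq = fs / 2.0
    hi = min(hi_nominal, nyq)
    if lo <= 0:
        return sps.butter(order, hi, btype="lowpass", fs=fs, output="sos")
    if hi >= nyq:
        return sps.butter(order, lo, btype="highpass", fs=fs, output="sos")
    return sps.butter(order, (lo, hi), btype="bandpass", fs=fs, output="sos")


def _trial_layout(spec: CohortSpec) -> tuple[int, list[Segment]]:
    fs = spec.sampling_rate
    n_stim = round(spec.stimulus_duration * fs)
    n_rest = round(spec.rest_duration * fs)
    segments = [
        Segment(0, n_stim, HAPPY),
        Segment(n_stim, n_stim + n_rest, REST),
        Segment(n_stim + n_rest, 2 * n_stim + n_rest, UNHAPPY),
    ]
    return 2 * n_stim + n_rest, segments


def generate_trial(
    spec: CohortSpec, subject_id: int, trial_id: int, seed_offset: int = 0
) -> EEGRecording:
    """Generate one trial: stimulus, rest, stimulus (happy first).

    Per channel the signal is a sum over the five bands of zero-phase
    band-pass-filtered white Gaussian noise, rescaled to unit RMS and then
    multiplied by a piecewise-constant amplitude envelope
    ``noise_floor[band] * effect`` where ``effect = 1`` during rest and
    ``1 + attenuation * (gain - 1)`` during a labelled segment.  Deterministic
    given ``(spec.seed, subject_id, trial_id, seed_offset)``.
    """
    if not (0 <= subject_id < spec.n_subjects):
        raise ValueError(f"subject_id {subject_id} out of range")
    if not (0 <= trial_id < spec.n_trials_per_subject):
        raise ValueError(f"trial_id {trial_id} out of range")
    n_samples, segments = _trial_layout(spec)
    rng = np.random.default_rng([spec.seed, seed_offset, subject_id, trial_id])
    attn = spec.attenuation(subject_id)

    sig = np.zeros((len(spec.channel_names), n_samples))
    for b_idx, band in enumerate(BAND_NAMES):
        floor = float(spec.noise_floor.get(band, 0.0))
        sos = _band_sos(band, spec.sampling_rate)
        white = rng.standard_normal((len(spec.channel_names), n_samples))
        white -= white.mean(axis=1, keepdims=True)  # zero-DC source
        comp = sps.sosfiltfilt(sos, white, axis=1)
        rms = comp.std(axis=1, keepdims=True)
        rms[rms == 0] = 1.0
        comp /= rms
        env = np.full((len(spec.channel_names), n_samples), floor)
        for seg in segments:
            if seg.label == REST:
                continue
            for c_idx, ch in enumerate(spec.channel_names):
                g = spec.gain(subject_id, seg.label, ch, band)
                effect = 1.0 + attn * (g - 1.0)
                env[c_idx, seg.start:seg.stop] = floor * effect
        sig += env * comp

    return EEGRecording(
        subject_id=subject_id,
        trial_id=trial_id,
        signal=sig,
        sampling_rate=spec.sampling_rate,
        channel_names=spec.channel_names,
        segments=segments,
    )


def generate_cohort(spec: CohortSpec, seed_offset: int = 0) -> list[EEGRecording]:
    """All trials of all subjects, reproducible from ``spec.seed``."""
    spec.validate()
    return [
        generate_trial(spec, s, t, seed_offset)
        for s in range(spec.n_subjects)
        for t in range(spec.n_trials_per_subject)
    ]


# ---------------------------------------------------------------------------
# Ready-made cohort specifications
# ---------------------------------------------------------------------------

#: Subjects whose emotional band-power response is attenuated (models the
#: reduced physiological response magnitude of the three oldest subjects;
#: 0-based ids 1, 3, 9 correspond to subjects 2, 4, 10 in 1-based numbering).
ATTENUATED_SUBJECTS: tuple[int, ...] = (1, 3, 9)

# Happy-class amplitude gains of the default study cohort.  The contrast is
# concentrated in the high-frequency bands at the temporal pair (T7/T8) with
# weaker secondary effects at neighbouring sites, i.e. the topography the
# classification experiments are expected to recover.  Magnitudes are small:
# a 10% amplitude gain is a ~21% band-power shift, which against the ~18%
# sampling noise of a 1 s band-power estimate yields modest, non-saturated
# single-window discriminability.
_STUDY_HAPPY_GAINS: dict[str, dict[str, float]] = {
    "T7": {"gamma": 1.10, "beta": 1.08},
    "T8": {"gamma": 1.10, "beta": 1.08},
    "P7": {"gamma": 1.04},
    "P8": {"gamma": 1.04},
    "FC5": {"beta": 1.03},
    "FC6": {"beta": 1.03},
}


def study_spec(
    seed: int = 0,
    *,
    heterogeneous: bool = True,
    attenuation: float = 0.3,
) -> CohortSpec:
    """The default synthetic study cohort: 10 subjects x 5 trials.

    ``heterogeneous=True`` applies a per-subject multiplicative jitter
    (uniform on [0.5, 1.5], drawn once from ``seed``) to the excess gain of
    every effect entry, modelling individually different response
    topographies; this is what makes subject-independent (LOSO) accuracy fall
    below subject-dependent (LOTO) accuracy.  Three of the ten subjects get
    attenuated effects (older-subject emulation).
    """
    base: BandGains = {HAPPY: copy.deepcopy(_STUDY_HAPPY_GAINS)}
    subject_gains: dict[int, BandGains] = {}
    if heterogeneous:
        jrng = np.random.default_rng([seed, 7919])
        for s in range(10):
            per_subject: dict[str, dict[str, dict[str, float]]] = {HAPPY: {}}
            for ch, per_band in _STUDY_HAPPY_GAINS.items():
                per_subject[HAPPY][ch] = {
                    band: 1.0 + float(jrng.uniform(0.5, 1.5)) * (g - 1.0)
                    for band, g in per_band.items()
                }
            subject_gains[s] = per_subject
    return CohortSpec(
        band_gains=base,
        subject_band_gains=subject_gains,
        attenuation_factors={s: attenuation for s in ATTENUATED_SUBJECTS},
        seed=seed,
    )


def null_spec(seed: int = 0, n_subjects: int = 1, **kwargs) -> CohortSpec:
    """A cohort with no class effect anywhere: every gain is 1."""
    return CohortSpec(n_subjects=n_subjects, seed=seed, **kwargs)


def strong_effect_spec(
    seed: int = 0,
    n_subjects: int = 1,
    gain: float = 3.0,
    channels: Sequence[str] = ("T7", "T8"),
    bands: Sequence[str] = ("gamma",),
    **kwargs,
) -> CohortSpec:
    """A cohort with a strong localized happy-class effect (default: gamma
    amplitude tripled at T7/T8), used for separability checks."""
    gains = {HAPPY: {ch: {b: gain for b in bands} for ch in channels}}
    return CohortSpec(n_subjects=n_subjects, band_gains=gains, seed=seed, **kwargs)
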