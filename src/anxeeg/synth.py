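"""Synthetic 14-channel EEG generator shaped like the DASPS anxiety-elicitation study.

Emulates 23 subjects x 6 trials x 30 s of Emotiv EPOC EEG at 128 Hz, with a
per-subject latent anxiety level in {0,1,2,3} that (a) elevates theta/beta band
power at six fronto-parietal channels and (b) drives the subjective SAM
(valence/arousal) and HAM-A scores. Background activity is 1/f ("pink") noise
plus one band-limited oscillator per canonical EEG band; blink (<4 Hz), EMG
(>30 Hz) and 50 Hz line-noise artifacts can be injected on top.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Emotiv EPOC electrode montage, in headset order.
CHANNELS_14: tuple[str, ...] = (
    "AF3", "F7", "F3", "FC5", "T7", "P7", "O1",
    "O2", "P8", "T8", "FC6", "F4", "F8", "AF4",
)

#: Channels carrying the anxiety effect (fronto-parietal, three homologous pairs).
EFFECT_CHANNELS: tuple[str, ...] = ("AF3", "AF4", "FC5", "FC6", "P7", "P8")

#: Frontal channels that receive blink transients.
FRONTAL_CHANNELS: tuple[str, ...] = ("AF3", "AF4", "F7", "F8", "F3", "F4")

#: EEG band edges (Hz), inclusive.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (2.0, 4.0),
    "theta": (5.0, 7.0),
    "alpha": (8.0, 12.0),
    "beta": (13.0, 29.0),
    "gamma": (30.0, 45.0),
}

#: Four-level class prevalence implied by the HAM-A instance counts
#: 360:900:540:2340 (normal:light:moderate:severe).
HAMA_PREVALENCE: tuple[float, ...] = (360 / 4140, 900 / 4140, 540 / 4140, 2340 / 4140)

#: Baseline oscillator amplitudes (uV) per band: alpha-dominant resting EEG.
DEFAULT_OSC_AMPLITUDE: dict[str, float] = {
    "delta": 4.0, "theta": 4.0, "alpha": 6.0, "beta": 3.0, "gamma": 1.5,
}


class ConfigurationError(ValueError):
    """Raised when a generator config field is invalid; names the field."""


@dataclass
class ArtifactRates:
    """Artifact intensities: event rates in events/min, amplitudes in uV."""

    blink_rate: float = 10.0
    blink_amplitude: float = 80.0
    emg_rate: float = 4.0
    emg_amplitude: float = 20.0
    line_amplitude: float = 1.0

    def is_zero(self) -> bool:
        return (self.blink_rate == 0 and self.emg_rate == 0
                and self.line_amplitude == 0)


@dataclass
class GeneratorConfig:
    """Study-shaped generation parameters.

    Defaults reproduce the source study's protocol: 23 subjects, 6 trials of
    30 s analyzed EEG each, 128 Hz, 14 Emotiv channels, with the class effect
    (multiplicative band-power elevation ``effect_size**level``) on theta and
    beta at AF3/AF4/FC5/FC6/P7/P8.
    """

    n_subjects: int = 23
    n_trials: int = 6
    trial_seconds: float = 30.0
    fs: float = 128.0
    channels: tuple[str, ...] = CHANNELS_14
    effect_channels: tuple[str, ...] = EFFECT_CHANNELS
    effect_bands: tuple[str, ...] = ("theta", "beta")
    effect_size: float = 1.5
    class_prevalence: tuple[float, ...] = HAMA_PREVALENCE
    pink_exponent: float = 1.0
    pink_sigma: float = 6.0          # uV RMS of the 1/f background
    osc_amplitude: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_OSC_AMPLITUDE))
    osc_log_sigma: float = 0.3       # log-normal spread of oscillator amplitudes
    artifact_rates: ArtifactRates = field(default_factory=ArtifactRates)
    sam_jitter: float = 0.0          # >0 blurs SAM scores across label boundaries
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_trials < 1:
            raise ConfigurationError("n_trials must be >= 1")
        if self.trial_seconds <= 0:
            raise ConfigurationError("trial_seconds must be > 0")
        highest = max(BANDS[b][1] for b in self.effect_bands) if self.effect_bands else 0.0
        if self.fs <= 2 * highest:
            raise ConfigurationError("fs must exceed twice the highest band edge")
        if len(set(self.channels)) != len(self.channels):
            raise ConfigurationError("channels contains duplicates")
        if not set(self.effect_channels) <= set(self.channels):
            raise ConfigurationError("effect_channels must be a subset of channels")
        for b in self.effect_bands:
            if b not in BANDS:
                raise ConfigurationError(f"effect_bands: unknown band {b!r}")
        if self.effect_size < 1:
            raise ConfigurationError("effect_size must be >= 1")
        if len(self.class_prevalence) != 4 or abs(sum(self.class_prevalence) - 1) > 1e-9:
            raise ConfigurationError("class_prevalence must be 4 probabilities summing to 1")
        if self.pink_sigma < 0:
            raise ConfigurationError("pink_sigma must be >= 0")

    @property
    def n_samples(self) -> int:
        return int(round(self.trial_seconds * self.fs))


@dataclass
class TrialScores:
    """Subjective scores for one trial: SAM valence/arousal plus the subject's
    post-experiment HAM-A total (shared across a subject's trials)."""

    valence: float
    arousal: float
    ham_a: int

    def validate(self) -> None:
        if not (0 <= self.valence <= 9 and 0 <= self.arousal <= 9):
            raise ValueError("SAM scores must lie in [0, 9]")
        if not (0 <= self.ham_a <= 56):
            raise ValueError("ham_a must lie in [0, 56]")


@dataclass
class Recording:
    """One subject-trial of multi-channel EEG (uV) plus metadata."""

    subject_id: str
    trial_id: str
    signal: np.ndarray            # (n_channels, n_samples)
    fs: float
    channels: tuple[str, ...]
    scores: TrialScores
    ground_truth_level: int | None = None   # simulation only

    def validate(self) -> None:
        if self.signal.ndim != 2 or self.signal.shape[0] != len(self.channels):
            raise ValueError("signal must be (n_channels, n_samples)")
        if not np.all(np.isfinite(self.signal)):
            raise ValueError("signal contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]


# SAM score regions per latent level, at exact fidelity. Each region lies
# strictly inside the corresponding labeling rule's acceptance set, so
# relabeling recovers the level with probability 1 when sam_jitter == 0.
_SAM_REGIONS = {
    0: ((0.2, 2.0), (5.2, 6.9)),   # Normal: V<5, A>5 catch-all (avoids other rules)
    1: ((4.1, 5.0), (5.1, 6.0)),   # Light: V in (4,5], A in (5,6]
    2: ((2.1, 4.0), (6.1, 6.9)),   # Moderate: V in (2,4], A in (6,7)
    3: ((0.0, 2.0), (7.1, 9.0)),   # Severe: V in [0,2], A in [7,9]
}

#: HAM-A score bins per level (inclusive integer ranges).
_HAMA_BINS = {0: (0, 12), 1: (13, 20), 2: (21, 25), 3: (26, 56)}


def assign_subjective_scores(level: int, rng: np.random.Generator,
                             jitter: float = 0.0,
                             ham_a: int | None = None) -> TrialScores:
    """Draw SAM valence/arousal and a HAM-A total consistent with ``level``.

    With ``jitter == 0`` (exact fidelity) the scores land strictly inside the
    level's labeling region, so relabeling them recovers ``level``. Positive
    jitter adds Gaussian noise (clipped to the scales) and may cross label
    boundaries. Pass ``ham_a`` to reuse a subject-level HAM-A total.
    """
    if level not in _SAM_REGIONS:
        raise ValueError(f"level must be in {{0,1,2,3}}, got {level!r}")
    (v_lo, v_hi), (a_lo, a_hi) = _SAM_REGIONS[level]
    valence = rng.uniform(v_lo, v_hi)
    arousal = rng.uniform(a_lo, a_hi)
    if jitter > 0:
        valence = float(np.clip(valence + rng.normal(0, jitter), 0, 9))
        arousal = float(np.clip(arousal + rng.normal(0, jitter), 0, 9))
    if ham_a is None:
        ham_a = draw_ham_a(level, rng)
    return TrialScores(valence=float(valence), arousal=float(arousal), ham_a=int(ham_a))


def draw_ham_a(level: int, rng: np.random.Generator) -> int:
    """Draw a HAM-A total uniformly inside the level's severity bin."""
    if level not in _HAMA_BINS:
        raise ValueError(f"level must be in {{0,1,2,3}}, got {level!r}")
    lo, hi = _HAMA_BINS[level]
    return int(rng.integers(lo, hi + 1))


def _pink_noise(rng: np.random.Generator, n: int, fs: float,
                exponent: float, sigma: float) -> np.ndarray:
    """1/f^exponent noise of length n with RMS ``sigma``, via spectral shaping."""
    freqs = np.fft.rfftfreq(n, 1 / fs)
    amp = np.zeros_like(freqs)
    amp[1:] = freqs[1:] ** (-exponent / 2)
    spec = amp * (rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs)))
    x = np.fft.irfft(spec, n=n)
    rms = np.sqrt(np.mean(x ** 2))
    if rms > 0:
        x *= sigma / rms
    return x


def _clean_signal(config: GeneratorConfig, level: int,
                  rng: np.random.Generator) -> np.ndarray:
    """Pink background plus per-band oscillators; effect bands on effect
    channels have their oscillator power scaled by effect_size**level.

    Oscillator amplitude, frequency and phase are redrawn every second
    (rhythms wax and wane), so the band power of disjoint 1-s segments is
    independent both within and across trials.
    """
    n = config.n_samples
    fs_i = int(round(config.fs))
    n_sec = -(-n // fs_i)                      # ceil
    t_local = np.arange(fs_i) / config.fs      # time within one second
    sig = np.empty((len(config.channels), n))
    effect = set(config.effect_channels)
    amp_gain = np.sqrt(config.effect_size ** level)   # amplitude^2 carries power
    for ci, ch in enumerate(config.channels):
        x = _pink_noise(rng, n, config.fs, config.pink_exponent, config.pink_sigma)
        osc = np.zeros((n_sec, fs_i))
        for band, (lo, hi) in BANDS.items():
            base = config.osc_amplitude.get(band, 0.0)
            if base <= 0:
                continue
            amps = base * rng.lognormal(0.0, config.osc_log_sigma, size=n_sec)
            if ch in effect and band in config.effect_bands:
                amps *= amp_gain
            f0 = rng.uniform(lo, hi, size=n_sec)
            phase = rng.uniform(0, 2 * np.pi, size=n_sec)
            osc += amps[:, None] * np.sin(
                2 * np.pi * f0[:, None] * t_local[None, :] + phase[:, None])
        sig[ci] = x + osc.reshape(-1)[:n]
    return sig


def _blink_kernel(fs: float, width_s: float = 0.5) -> np.ndarray:
    """Raised-cosine blink transient; spectral content essentially < 4 Hz."""
    n = max(3, int(round(width_s * fs)))
    return 0.5 * (1 - np.cos(2 * np.pi * np.arange(n) / (n - 1)))


def inject_artifacts(recording: Recording, config: GeneratorConfig,
                     rng: np.random.Generator) -> Recording:
    """Return a new recording with blink, EMG-burst and 50 Hz artifacts added.

    Blinks are high-amplitude <4 Hz raised-cosine transients weighted toward
    frontal channels; EMG bursts are >30 Hz band-limited noise on a random
    channel subset; line noise is a 50 Hz sinusoid on every channel. All rates
    set to zero returns an identical copy.
    """
    rates = config.artifact_rates
    sig = recording.signal.copy()
    n = sig.shape[1]
    duration_min = n / recording.fs / 60.0
    ch_index = {c: i for i, c in enumerate(recording.channels)}

    # blinks: frontal, with smaller leakage elsewhere
    n_blinks = rng.poisson(rates.blink_rate * duration_min) if rates.blink_rate > 0 else 0
    kernel = _blink_kernel(recording.fs)
    for _ in range(n_blinks):
        start = int(rng.integers(0, max(1, n - len(kernel))))
        amp = rates.blink_amplitude * rng.lognormal(0, 0.2)
        for ch, w in ((c, 1.0) for c in FRONTAL_CHANNELS if c in ch_index):
            jit = w * amp * rng.uniform(0.7, 1.0)
            sig[ch_index[ch], start:start + len(kernel)] += jit * kernel

    # EMG bursts: >30 Hz noise, 0.5 s, random channel subset
    n_bursts = rng.poisson(rates.emg_rate * duration_min) if rates.emg_rate > 0 else 0
    burst_len = int(round(0.5 * recording.fs))
    for _ in range(n_bursts):
        start = int(rng.integers(0, max(1, n - burst_len)))
        n_ch = int(rng.integers(1, max(2, len(recording.channels) // 2)))
        chans = rng.choice(len(recording.channels), size=n_ch, replace=False)
        noise = rng.standard_normal(burst_len)
        spec = np.fft.rfft(noise)
        f = np.fft.rfftfreq(burst_len, 1 / recording.fs)
        spec[f < 30] = 0
        noise = np.fft.irfft(spec, n=burst_len)
        rms = np.sqrt(np.mean(noise ** 2))
        if rms > 0:
            noise *= rates.emg_amplitude / rms
        for c in chans:
            sig[c, start:start + burst_len] += noise

    # 50 Hz line interference, per-channel random phase
    if rates.line_amplitude > 0:
        t = np.arange(n) / recording.fs
        for c in range(len(recording.channels)):
            phase = rng.uniform(0, 2 * np.pi)
            sig[c] += rates.line_amplitude * np.sin(2 * np.pi * 50.0 * t + phase)

    return replace(recording, signal=sig)


def generate_dataset(config: GeneratorConfig | None = None) -> list[Recording]:
    """Generate ``n_subjects * n_trials`` labelled recordings.

    Each subject receives a latent anxiety level drawn from
    ``config.class_prevalence`` and a single HAM-A total inside that level's
    bin; each trial gets fresh SAM scores inside the level's label region and
    an independent EEG realization. Deterministic given ``config.seed``.
    """
    config = config or GeneratorConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    recordings: list[Recording] = []
    for s in range(config.n_subjects):
        level = int(rng.choice(4, p=np.asarray(config.class_prevalence)))
        ham_a = draw_ham_a(level, rng)
        sid = f"S{s + 1:02d}"
        for tr in range(config.n_trials):
            scores = assign_subjective_scores(level, rng, jitter=config.sam_jitter,
                                              ham_a=ham_a)
            rec = Recording(
                subject_id=sid,
                trial_id=f"T{tr + 1:02d}",
                signal=_clean_signal(config, level, rng),
                fs=config.fs,
                channels=tuple(config.channels),
                scores=scores,
                ground_truth_level=level,
            )
            if not config.artifact_rates.is_zero():
                rec = inject_artifacts(rec, config, rng)
            recordings.append(rec)
    return recordings
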