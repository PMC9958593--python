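"""Synthetic four-state EEG cohort generation.

Each attention state is parameterized by the fraction of oscillatory power
carried by the four classical rhythms (δ, θ, α, β).  Stronger attention is
encoded as a larger β fraction together with smaller θ and α fractions.
Band-limited components are filtered white noise rather than sinusoids, so
windows vary and complexity features remain informative.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from scipy import signal as sps

from .io import DEFAULT_CHANNELS, Recording, write_edf

#: Rhythm band edges in Hz.
BAND_EDGES: dict[str, tuple[float, float]] = {
    "delta": (0.5, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
}

BAND_NAMES = tuple(BAND_EDGES)

ANSWER_SCORES = {"A": 1, "B": 2, "C": 3, "D": 4, "E": 5}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class StateProfile:
    """Spectral/amplitude signature of one attention state."""

    state_id: int
    band_fractions: Mapping[str, float]
    noise_mix: float = 0.1
    region_gains: Mapping[str, float] = field(default_factory=dict)
    amplitude_uV: float = 15.0

    def __post_init__(self):
        if self.state_id not in (1, 2, 3, 4):
            raise ConfigurationError(f"state_id must be 1..4, got {self.state_id}")
        fracs = dict(self.band_fractions)
        if set(fracs) != set(BAND_NAMES):
            raise ConfigurationError(
                f"band_fractions must cover exactly {BAND_NAMES}"
            )
        if any(v < 0 for v in fracs.values()):
            raise ConfigurationError("band fractions must be non-negative")
        if abs(sum(fracs.values()) - 1.0) > 1e-8:
            raise ConfigurationError(
                f"band fractions must sum to 1, got {sum(fracs.values()):.6f}"
            )
        if not 0.0 <= self.noise_mix <= 1.0:
            raise ConfigurationError("noise_mix must be in [0, 1]")
        if not self.amplitude_uV > 0:
            raise ConfigurationError("amplitude_uV must be positive")

    def gain(self, channel: str) -> float:
        return float(self.region_gains.get(channel, 1.0))


def default_profiles() -> tuple[StateProfile, ...]:
    """Four profiles with β strictly decreasing and θ+α strictly increasing
    from state 1 (high attention) to state 4 (non-externally directed)."""
    return (
        StateProfile(1, {"delta": 0.14, "theta": 0.12, "alpha": 0.18, "beta": 0.56},
                     noise_mix=0.10, amplitude_uV=12.0),
        StateProfile(2, {"delta": 0.14, "theta": 0.16, "alpha": 0.26, "beta": 0.44},
                     noise_mix=0.12, amplitude_uV=14.0),
        StateProfile(3, {"delta": 0.14, "theta": 0.22, "alpha": 0.32, "beta": 0.32},
                     noise_mix=0.14, amplitude_uV=16.0),
        StateProfile(4, {"delta": 0.14, "theta": 0.28, "alpha": 0.38, "beta": 0.20},
                     noise_mix=0.16, amplitude_uV=18.0),
    )


@dataclass(frozen=True)
class CohortConfig:
    n_subjects: int = 14
    n_sessions: int = 2
    fs: float = 512.0
    task_duration_s: float = 130.0
    channel_labels: tuple[str, ...] = DEFAULT_CHANNELS
    subject_sd: float = 0.08
    session_sd: float = 0.03
    amplitude_sd: float = 0.05
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        if self.n_sessions < 1:
            raise ConfigurationError("n_sessions must be >= 1")
        if not self.fs > 60.0:
            raise ConfigurationError("fs must exceed twice the 30 Hz upper band")
        if len(set(self.channel_labels)) != len(self.channel_labels):
            raise ConfigurationError("duplicate channel labels")
        if self.task_duration_s < 4.0:
            raise ConfigurationError("task_duration_s must be >= 4 s")

    @classmethod
    def from_dict(cls, d: Mapping) -> "CohortConfig":
        d = dict(d)
        if "channel_labels" in d:
            d["channel_labels"] = tuple(d["channel_labels"])
        return cls(**d)


def _pink_noise(n: int, fs: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS 1/f (power) noise, flattened below 0.5 Hz to stay finite."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shaping = np.ones_like(freqs)
    positive = freqs > 0
    shaping[positive] = 1.0 / np.sqrt(np.maximum(freqs[positive], 0.5))
    spec *= shaping
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    return x / x.std()


def _band_noise(n: int, fs: float, band: tuple[float, float],
                rng: np.random.Generator) -> np.ndarray:
    """Band-limited noise (order-4 Butterworth, zero-phase) normalized so the
    power *inside* [lo, hi) is 1; leakage outside the band (a few percent at
    the narrow delta band) then cannot bias configured band fractions."""
    lo, hi = band
    hi = min(hi, 0.49 * fs)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfiltfilt(sos, rng.standard_normal(n))
    spec = np.abs(np.fft.rfft(x)) ** 2
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    in_band = float(spec[(freqs >= lo) & (freqs < hi)].sum() / spec.sum())
    return x / (x.std() * np.sqrt(in_band))


def synthesize_state_signal(
    profile: StateProfile,
    n_channels: int,
    duration_s: float,
    fs: float,
    rng: np.random.Generator,
    channel_labels: Sequence[str] | None = None,
) -> np.ndarray:
    """Generate a ``(n_channels, n_samples)`` µV block for one state.

    Each channel mixes 1/f background (weight ``noise_mix``) with independent
    band-limited processes whose powers follow ``band_fractions``, then is
    rescaled so its RMS equals ``amplitude_uV`` times the channel gain.
    """
    if duration_s < 4.0:
        raise ConfigurationError("duration_s must be >= 4 s")
    if fs < 64.0:
        raise ConfigurationError("fs must be >= 64 Hz")
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_channels)]

    n = int(round(duration_s * fs))
    out = np.empty((n_channels, n))
    for c in range(n_channels):
        x = np.zeros(n)
        if profile.noise_mix > 0:
            x += np.sqrt(profile.noise_mix) * _pink_noise(n, fs, rng)
        osc_weight = 1.0 - profile.noise_mix
        if osc_weight > 0:
            for band in BAND_NAMES:
                frac = float(profile.band_fractions[band])
                if frac <= 0:
                    continue
                x += np.sqrt(osc_weight * frac) * _band_noise(
                    n, fs, BAND_EDGES[band], rng
                )
        target = profile.amplitude_uV * profile.gain(str(channel_labels[c]))
        x *= target / x.std()
        out[c] = x
    return out


def _jitter_fractions(
    fractions: Mapping[str, float], sd: float, rng: np.random.Generator
) -> dict[str, float]:
    """Log-normal multiplicative jitter followed by renormalization."""
    jittered = {
        band: float(fractions[band]) * float(np.exp(rng.normal(0.0, sd)))
        for band in BAND_NAMES
    }
    total = sum(jittered.values())
    return {band: v / total for band, v in jittered.items()}


def make_cohort(
    config: CohortConfig,
    profiles: Sequence[StateProfile] | None = None,
) -> list[Recording]:
    """Generate ``n_subjects x n_sessions x 4`` labelled recordings.

    Reproducible: the stream for each (subject, session, task) cell is seeded
    from ``(config.seed, subject, session, task)``, so identical inputs give
    bit-identical cohorts.
    """
    if profiles is None:
        profiles = default_profiles()
    profiles = tuple(profiles)
    if sorted(p.state_id for p in profiles) != [1, 2, 3, 4]:
        raise ConfigurationError("need exactly one profile per state 1..4")
    by_state = {p.state_id: p for p in profiles}

    recordings: list[Recording] = []
    for subj in range(1, config.n_subjects + 1):
        subj_rng = np.random.default_rng(
            np.random.SeedSequence([config.seed, subj])
        )
        amp_factor = float(np.exp(subj_rng.normal(0.0, config.amplitude_sd)))
        subj_fracs = {
            state: _jitter_fractions(
                by_state[state].band_fractions, config.subject_sd, subj_rng
            )
            for state in (1, 2, 3, 4)
        }
        for sess in range(1, config.n_sessions + 1):
            sess_rng = np.random.default_rng(
                np.random.SeedSequence([config.seed, subj, sess])
            )
            for task in (1, 2, 3, 4):
                base = by_state[task]
                profile = StateProfile(
                    state_id=task,
                    band_fractions=_jitter_fractions(
                        subj_fracs[task], config.session_sd, sess_rng
                    ),
                    noise_mix=base.noise_mix,
                    region_gains=base.region_gains,
                    amplitude_uV=base.amplitude_uV * amp_factor,
                )
                cell_rng = np.random.default_rng(
                    np.random.SeedSequence([config.seed, subj, sess, task])
                )
                data = synthesize_state_signal(
                    profile,
                    len(config.channel_labels),
                    config.task_duration_s,
                    config.fs,
                    cell_rng,
                    channel_labels=config.channel_labels,
                )
                recordings.append(
                    Recording(
                        data=data,
                        fs=config.fs,
                        channel_labels=config.channel_labels,
                        subject_id=f"S{subj:02d}",
                        session_id=sess,
                        task_id=task,
                    )
                )
    return recordings


def write_cohort(recordings: Sequence[Recording], outdir) -> Path:
    """Write one EDF per recording plus a TSV manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = outdir / "manifest.tsv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter="\t")
        writer.writerow(["subject", "session", "task", "path"])
        for rec in recordings:
            name = f"{rec.subject_id}_ses{rec.session_id}_task{rec.task_id}.edf"
            write_edf(rec, outdir / name)
            writer.writerow([rec.subject_id, rec.session_id, rec.task_id, name])
    return manifest


def read_cohort(manifest_path) -> list[Recording]:
    from .io import read_edf

    manifest_path = Path(manifest_path)
    recordings = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            recordings.append(read_edf(manifest_path.parent / row["path"]))
    return recordings


# ---------------------------------------------------------------------------
# Questionnaire screening
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class QuestionnaireResponse:
    """Three A-E answers to the post-task self-evaluation scale."""

    task_id: int
    answers: tuple[str, str, str]

    def __post_init__(self):
        if self.task_id not in (1, 2, 3, 4):
            raise ValueError(f"task_id must be 1..4, got {self.task_id}")
        if len(self.answers) != 3:
            raise ValueError("exactly 3 answers required")
        for a in self.answers:
            if a not in ANSWER_SCORES:
                raise ValueError(f"answer {a!r} not in A..E")


def score_questionnaire(resp: QuestionnaireResponse) -> tuple[int, int | None]:
    """Score a response (A=1 ... E=5) and map the total to the matched task.

    On the scale used after tasks 1/2: total > 12 matches task 1 and
    9 <= total <= 12 matches task 2.  The scale used after tasks 3/4 maps the
    same bands to tasks 3 and 4.  Totals below 9 match nothing (screened out).
    """
    total = sum(ANSWER_SCORES[a] for a in resp.answers)
    high, mid = (1, 2) if resp.task_id in (1, 2) else (3, 4)
    if total > 12:
        return total, high
    if total >= 9:
        return total, mid
    return total, None


def inject_artifacts(
    recording: Recording,
    spike_amp_uV: float = 500.0,
    n_spikes: int = 3,
    rng: np.random.Generator | None = None,
    spike_width_s: float = 0.05,
) -> tuple[Recording, list[int]]:
    """Add transient high-amplitude excursions; returns (copy, spike centers).

    Spikes are half-sine pulses on every channel, emulating gross movement
    artifacts for testing amplitude-based rejection.
    """
    if spike_amp_uV <= 0:
        raise ValueError("spike_amp_uV must be positive")
    if n_spikes < 0:
        raise ValueError("n_spikes must be >= 0")
    if rng is None:
        rng = np.random.default_rng()
    out = recording.copy()
    if n_spikes == 0:
        return out, []
    width = max(3, int(round(spike_width_s * recording.fs)))
    half = width // 2
    n = recording.n_samples
    if n <= 2 * width:
        raise ValueError("recording too short for spike injection")
    centers = sorted(
        int(c) for c in rng.integers(width, n - width, size=n_spikes)
    )
    pulse = np.sin(np.linspace(0.0, np.pi, width)) * spike_amp_uV
    for c in centers:
        out.data[:, c - half : c - half + width] += pulse
    return out, centers
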