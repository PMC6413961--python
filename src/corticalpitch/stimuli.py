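"""Stimulus synthesis: iterated rippled noise (IRN), IRN dyads, and auxiliary tones.

Iterated rippled noise is produced by a delay-and-add filter applied
repeatedly to a white-noise token ``s0``::

    s(t) = sum_{n=0}^{its-1} g^n s0(t - n*T)

which elicits a pitch at 1/T with a salience that grows with the number of
iterations.  A dyad is built from *the same* noise token delayed at two
different lags T0 and T1, one per note.  Experimental sequences consist of an
energy-balanced noise precursor cross-faded into the pitch segment, so that
the pitch onset is not confounded by an energy onset.

All synthesis is deterministic given the spec's seed.  Amplitude convention:
1.0 full scale corresponds to 1 Pa, so a waveform calibrated to 80 dB SPL has
an RMS of 0.2 Pa.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from fractions import Fraction
from pathlib import Path

import numpy as np
from scipy import signal
from scipy.io import wavfile

P_REF = 20e-6  # reference pressure, Pa

#: Just-intonation frequency ratios for the chromatic scale (unison to octave).
JUST_RATIOS: dict[str, Fraction] = {
    "P1": Fraction(1, 1),
    "m2": Fraction(16, 15),
    "M2": Fraction(9, 8),
    "m3": Fraction(6, 5),
    "M3": Fraction(5, 4),
    "P4": Fraction(4, 3),
    "TT": Fraction(45, 32),
    "P5": Fraction(3, 2),
    "m6": Fraction(8, 5),
    "M6": Fraction(5, 3),
    "m7": Fraction(16, 9),
    "M7": Fraction(15, 8),
    "P8": Fraction(2, 1),
}

#: Number of equal-temperament semitones above the lower note.
SEMITONES: dict[str, int] = {
    name: i for i, name in enumerate(
        ["P1", "m2", "M2", "m3", "M3", "P4", "TT", "P5", "m6", "M6", "m7", "M7", "P8"]
    )
}

#: Helmholtz consonance classes: perfect consonant, imperfect consonant, dissonant.
CONSONANCE_CLASS: dict[str, str] = {
    "P1": "PC", "P4": "PC", "P5": "PC", "P8": "PC",
    "m3": "IC", "M3": "IC", "m6": "IC", "M6": "IC",
    "m2": "D", "M2": "D", "TT": "D", "m7": "D", "M7": "D",
}

#: The six dyads used in the MEG experiment, in descending consonance order.
EXPERIMENTAL_INTERVALS = ("P1", "P5", "M3", "TT", "m7", "m2")

#: Helmholtz consonant / dissonant sets used for the chromatic-scale analysis.
CONSONANT_SET = ("P1", "M3", "P4", "P5", "P8")
DISSONANT_SET = ("m2", "M2", "TT", "m7", "M7")


@dataclass(frozen=True)
class DyadSpec:
    """A musical interval between two simultaneous notes.

    The frequency ratio is exact (a :class:`fractions.Fraction`) under just
    intonation, or ``2^(semitones/12)`` under equal temperament.
    """

    interval: str
    tuning: str = "just"  # "just" | "equal"

    def __post_init__(self):
        if self.interval not in JUST_RATIOS:
            raise ValueError(
                f"unknown interval {self.interval!r}; valid intervals: "
                + ", ".join(JUST_RATIOS)
            )
        if self.tuning not in ("just", "equal"):
            raise ValueError(f"tuning must be 'just' or 'equal', got {self.tuning!r}")

    @property
    def ratio(self) -> float:
        if self.tuning == "just":
            return float(JUST_RATIOS[self.interval])
        return 2.0 ** (SEMITONES[self.interval] / 12.0)

    @property
    def consonance_class(self) -> str:
        return CONSONANCE_CLASS[self.interval]

    def upper_delay(self, delay_t0: float) -> float:
        """Delay of the upper note, T1 = T0 / ratio (seconds)."""
        return delay_t0 / self.ratio

    def upper_frequency(self, delay_t0: float) -> float:
        """Frequency of the upper note in Hz for a lower-note delay T0."""
        return self.ratio / delay_t0


@dataclass(frozen=True)
class StimulusSpec:
    """Synthesis parameters for one stimulus.

    Parameters mirror the delay-and-add construction: ``delay_t0`` (and
    ``delay_t1`` for dyads) in seconds, number of ``iterations``, per-iteration
    ``gain`` g_f, bandpass edges in Hz, segment ``duration`` in seconds,
    presentation ``level`` in dB SPL and the RNG ``seed`` for the noise token.
    """

    kind: str = "irn"  # irn | dyad_irn | pure_tone | harmonic_complex | click_train | noise
    delay_t0: float = 6.25e-3
    delay_t1: float | None = None
    iterations: int = 8
    gain: float = 1.0
    band_low: float = 125.0
    band_high: float = 2000.0
    duration: float = 0.75
    level: float = 80.0
    sample_rate: float = 48000.0
    seed: int = 0

    def __post_init__(self):
        if self.iterations < 1:
            raise ValueError(f"iterations must be >= 1, got {self.iterations}")
        if not (0.0 <= self.gain <= 1.0):
            raise ValueError(f"gain must lie in [0, 1], got {self.gain}")
        if not (0.0 < self.band_low < self.band_high < self.sample_rate / 2):
            raise ValueError(
                f"band ({self.band_low}, {self.band_high}) Hz must satisfy "
                f"0 < low < high < sample_rate/2 = {self.sample_rate / 2}"
            )
        if self.kind in ("irn", "dyad_irn"):
            if not (0.0 < self.delay_t0 <= self.duration):
                raise ValueError(
                    f"delay_t0 = {self.delay_t0} s must satisfy 0 < delay <= "
                    f"duration = {self.duration} s"
                )


@dataclass
class Waveform:
    """Sampled pressure waveform with named sample-index markers."""

    samples: np.ndarray
    sample_rate: float
    markers: dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("waveform samples must be finite")
        idx = list(self.markers.values())
        if any(i < 0 or i > self.samples.size for i in idx):
            raise ValueError("markers must lie within the sample range")
        if sorted(idx) != idx:
            raise ValueError("markers must be non-decreasing")

    @property
    def duration(self) -> float:
        return self.samples.size / self.sample_rate

    @property
    def rms(self) -> float:
        return float(np.sqrt(np.mean(self.samples**2)))

    def level_db_spl(self) -> float:
        return 20.0 * np.log10(self.rms / P_REF)

    def time(self) -> np.ndarray:
        return np.arange(self.samples.size) / self.sample_rate


def _bandpass(x: np.ndarray, low: float, high: float, fs: float) -> np.ndarray:
    # Zero-phase 4th-order Butterworth: filtering must not add group delay
    # that would bias downstream latency estimates.
    sos = signal.butter(4, [low, high], btype="bandpass", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, x)


def _delay_add(s0: np.ndarray, delays_samp, iterations: int, gain: float, n: int) -> np.ndarray:
    """Delay-and-add of a noise token: the segment [pad, pad+n) of the infinite
    sum, with pad chosen so every delayed copy is defined."""
    pad = (iterations - 1) * max(delays_samp)
    out = np.zeros(n)
    for d in delays_samp:
        for k in range(iterations):
            g = gain**k
            if g == 0.0 and k > 0:
                break
            start = pad - k * d
            out += g * s0[start : start + n]
    return out


def generate_irn(spec: StimulusSpec) -> Waveform:
    """Synthesize a single-pitch iterated rippled noise segment.

    The single-tone form drops the second delayed term of the dyad
    construction; with ``iterations=1`` (or zero gain) the output reduces to
    the bandpass-filtered source noise.
    """
    if spec.kind != "irn":
        raise ValueError(f"spec.kind must be 'irn', got {spec.kind!r}")
    return _generate_irn_like(spec, [spec.delay_t0])


def generate_dyad_irn(spec: StimulusSpec, dyad: DyadSpec) -> Waveform:
    """Synthesize an IRN dyad: both delayed copies drawn from the same noise.

    The upper-note delay is T1 = T0/ratio (just intonation) or
    T1 = 2^(-semitones/12) T0 (equal temperament), unless ``spec.delay_t1``
    overrides it.
    """
    t1 = spec.delay_t1 if spec.delay_t1 is not None else dyad.upper_delay(spec.delay_t0)
    return _generate_irn_like(spec, [spec.delay_t0, t1])


def _generate_irn_like(spec: StimulusSpec, delays: list[float]) -> Waveform:
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    delays_samp = [int(round(t * fs)) for t in delays]
    if any(d > n for d in delays_samp):
        raise ValueError(
            f"delay_t0/t1 {max(delays):g} s exceeds the stimulus buffer "
            f"({spec.duration:g} s)"
        )
    rng = np.random.default_rng(spec.seed)
    # zero gain reduces the sum to its n=0 term; use the same noise token
    # alignment as a single iteration so the two cases coincide exactly
    iterations = 1 if spec.gain == 0.0 else spec.iterations
    pad = (iterations - 1) * max(delays_samp)
    s0 = rng.standard_normal(n + pad)
    raw = _delay_add(s0, delays_samp, iterations, spec.gain, n)
    out = _bandpass(raw, spec.band_low, spec.band_high, fs)
    wave = Waveform(out, fs, {"onset": 0, "pitch_onset": 0, "offset": n})
    return set_level(wave, spec.level)


def generate_noise(spec: StimulusSpec) -> Waveform:
    """Bandpass-filtered Gaussian noise segment (no delay-and-add)."""
    fs = spec.sample_rate
    n = int(round(spec.duration * fs))
    rng = np.random.default_rng(spec.seed)
    out = _bandpass(rng.standard_normal(n), spec.band_low, spec.band_high, fs)
    wave = Waveform(out, fs, {"onset": 0, "offset": n})
    return set_level(wave, spec.level)


def set_level(wave: Waveform, level: float) -> Waveform:
    """Scale the waveform to the requested dB SPL (RMS re 20 uPa, 1 FS = 1 Pa)."""
    rms = wave.rms
    if rms == 0.0:
        raise ValueError("cannot calibrate a silent waveform")
    target = P_REF * 10.0 ** (level / 20.0)
    return Waveform(wave.samples * (target / rms), wave.sample_rate, dict(wave.markers))


def make_noise_pitch_sequence(
    noise_dur: float,
    pitch_wave: Waveform,
    fade: float = 0.010,
    *,
    band: tuple[float, float] | None = None,
    seed: int = 1,
    ramp: float = 0.010,
) -> Waveform:
    """Cross-fade an energy-balanced noise precursor into the pitch segment.

    The precursor is fresh Gaussian noise, bandpass-matched (``band``, default
    the pitch segment's full band is assumed already applied by the caller) and
    scaled to the pitch segment's RMS.  The cross-fade uses equal-power
    (cos/sin) ramps over ``fade`` seconds centred on the boundary, so the
    summed squared envelope stays approximately constant through the
    transition; the ``pitch_onset`` marker sits at the cross-fade midpoint.
    Raised-cosine ramps of ``ramp`` seconds shape the sequence on- and offset.
    """
    fs = pitch_wave.sample_rate
    nn = int(round(noise_dur * fs))
    nf = int(round(fade * fs))
    np_ = pitch_wave.samples.size
    if nf > min(nn, np_):
        raise ValueError(
            f"fade {fade:g} s is longer than a segment "
            f"(noise {noise_dur:g} s, pitch {np_ / fs:g} s)"
        )
    half = nf // 2
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal(nn + half)
    if band is not None:
        noise = _bandpass(noise, band[0], band[1], fs)
    # energy balance: match RMS to the pitch segment
    noise *= pitch_wave.rms / np.sqrt(np.mean(noise**2))

    total = nn - half + np_ if nf > 0 else nn + np_
    out = np.zeros(total)
    if nf > 0:
        theta = np.linspace(0.0, np.pi / 2, nf, endpoint=False)
        noise_f = noise.copy()
        noise_f[nn - half : nn + half] *= np.cos(theta)
        pitch_f = pitch_wave.samples.copy()
        pitch_f[:nf] = pitch_f[:nf] * np.sin(theta)
        out[: nn + half] += noise_f
        out[nn - half :] += pitch_f
        pitch_onset = nn
    else:
        out[:nn] = noise
        out[nn:] = pitch_wave.samples
        pitch_onset = nn
    if ramp > 0:
        nr = int(round(ramp * fs))
        env = 0.5 * (1.0 - np.cos(np.pi * np.arange(nr) / nr))
        out[:nr] *= env
        out[-nr:] *= env[::-1]
    return Waveform(
        out, fs, {"onset": 0, "pitch_onset": pitch_onset, "offset": total}
    )


def generate_auxiliary(kind: str, **params) -> Waveform:
    """Pure tones, harmonic complexes and click trains (prediction presets).

    ``harmonic_complex`` sums equal-amplitude cosine partials over an explicit
    harmonic index set (missing-fundamental stimuli simply omit index 1);
    ``click_train`` places unit impulses at the inter-click interval.
    """
    fs = float(params.get("sample_rate", 48000.0))
    dur = float(params.get("duration", 0.75))
    level = float(params.get("level", 80.0))
    n = int(round(dur * fs))
    t = np.arange(n) / fs
    if kind == "pure_tone":
        f0 = float(params["frequency"])
        x = np.sin(2 * np.pi * f0 * t)
    elif kind == "harmonic_complex":
        f0 = float(params["f0"])
        harmonics = list(params.get("harmonics", range(1, 7)))
        if not harmonics:
            raise ValueError("harmonic_complex requires a non-empty harmonic set")
        x = np.zeros(n)
        for k in harmonics:
            x += np.cos(2 * np.pi * k * f0 * t)
        band = params.get("band")
        if band is not None:
            x = _bandpass(x, band[0], band[1], fs)
    elif kind == "click_train":
        interval = float(params["interval"])
        step = int(round(interval * fs))
        x = np.zeros(n)
        x[::step] = 1.0
        band = params.get("band")
        if band is not None:
            x = _bandpass(x, band[0], band[1], fs)
    else:
        raise ValueError(f"unknown auxiliary stimulus kind {kind!r}")
    wave = Waveform(x, fs, {"onset": 0, "pitch_onset": 0, "offset": n})
    return set_level(wave, level)


def write_wav(wave: Waveform, path: str | Path, *, sidecar: dict | None = None) -> None:
    """Write 32-bit float RIFF WAV plus a JSON sidecar with markers/metadata."""
    path = Path(path)
    wavfile.write(path, int(wave.sample_rate), wave.samples.astype(np.float32))
    meta = {
        "sample_rate": wave.sample_rate,
        "markers": {k: int(v) for k, v in wave.markers.items()},
    }
    if sidecar:
        meta.update(sidecar)
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))
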