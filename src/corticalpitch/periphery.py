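"""Simplified auditory-nerve front end.

Converts a pressure waveform into per-channel instantaneous firing
probability on a fixed bank of 40 cochlear channels with centre frequencies
log-spaced between 125 Hz and 10 kHz.  The processing chain is a
phenomenological stand-in for a biophysical periphery, chosen because the
downstream summary-autocorrelation stage only needs periodicity-preserving
probability traces:

    gammatone filterbank (group-delay aligned) -> half-wave rectification ->
    power-law compression (exponent 0.3) -> Gaussian low-pass at the
    channel's phase-locking cutoff (at most 1 kHz) -> decimation to the
    internal rate -> normalisation into [0, 1].

The chain is deterministic (no spontaneous firing noise); the interface is
pluggable so a biophysical periphery producing the same ``p(t)_m`` matrix can
be swapped in via the config key ``periphery: simple``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from scipy import signal
from scipy.ndimage import gaussian_filter1d

from .stimuli import Waveform

#: Probability floor playing the role of a spontaneous-rate term; outputs
#: below this are considered silent.
P_FLOOR = 1e-6


def erb_bandwidth(cf: float) -> float:
    """Equivalent rectangular bandwidth (Glasberg & Moore) in Hz."""
    return 24.7 * (4.37 * cf / 1000.0 + 1.0)


def gammatone_filter(x: np.ndarray, cf: float, fs: float) -> np.ndarray:
    """Complex 4th-order gammatone bandpass at centre frequency ``cf``.

    Implemented as four cascaded complex one-pole resonators (pole radius
    exp(-2 pi 1.019 ERB / fs)), which is unconditionally stable at any CF and
    sample rate; gain-normalised at CF.  The real part is the band signal,
    the magnitude its Hilbert envelope.
    """
    b = 1.019 * erb_bandwidth(cf)
    r = np.exp(-2.0 * np.pi * b / fs)
    pole = r * np.exp(2j * np.pi * cf / fs)
    y = x.astype(np.complex128)
    for _ in range(4):
        y = signal.lfilter([1.0], [1.0, -pole], y)
    return ((1.0 - r) ** 4) * y


@dataclass(frozen=True)
class ChannelBank:
    """Fixed log-spaced cochlear channel bank."""

    n_channels: int = 40
    cf_low: float = 125.0
    cf_high: float = 10000.0
    internal_rate: float = 10000.0  # rate of the emitted probability traces, Hz

    @property
    def center_frequencies(self) -> np.ndarray:
        return np.geomspace(self.cf_low, self.cf_high, self.n_channels)


@dataclass
class AuditoryNerveResponse:
    """Channel x time matrix of instantaneous spiking probability in [0, 1]."""

    p: np.ndarray
    dt: float
    bank: ChannelBank = field(default_factory=ChannelBank)

    def __post_init__(self):
        if not np.all(np.isfinite(self.p)):
            raise ValueError("auditory nerve response must be finite")
        if self.p.min() < 0.0 or self.p.max() > 1.0 + 1e-12:
            raise ValueError("spiking probabilities must lie in [0, 1]")

    @property
    def duration(self) -> float:
        return self.p.shape[1] * self.dt


def auditory_nerve_probability(
    wave: Waveform, bank: ChannelBank | None = None, *, compression: float = 0.3,
    lp_cutoff: float = 1000.0, pl_rolloff: float = 1.0, pl_floor: float = 250.0,
    delay_comp: float = 0.85,
) -> AuditoryNerveResponse:
    """Run the simplified periphery on a waveform.

    Each channel is gammatone-filtered at its CF, half-wave rectified,
    compressed (``x**compression``) and smoothed by a Gaussian low-pass whose
    cutoff models the progressive loss of phase locking: it is the smaller of
    ``lp_cutoff`` and ``pl_rolloff * CF`` (never below ``pl_floor``).  Tying
    the cutoff to CF attenuates each channel's own carrier while passing its
    (slower) envelope fluctuations, so periodicity above the phase-locking
    range is carried by envelope beats rather than resolved fine structure.
    The result is decimated to ``bank.internal_rate`` and normalised by the
    global response maximum, which makes the output approximately invariant
    to overall stimulus level.
    """
    bank = bank or ChannelBank()
    x = wave.samples
    if not np.all(np.isfinite(x)):
        raise ValueError("input waveform contains non-finite samples")
    if wave.duration < 0.050:
        raise ValueError(f"waveform too short ({wave.duration:g} s < 50 ms)")
    fs = wave.sample_rate

    ratio = Fraction(bank.internal_rate / fs).limit_denominator(1000)

    rows = []
    for cf in bank.center_frequencies:
        yc = gammatone_filter(x, cf, fs)
        # partially compensate the filter's envelope group delay,
        # (n-1)/(2 pi b) for an n-th order gammatone, so channel responses are
        # approximately time-aligned and the summary autocorrelation sees a
        # sharp noise-to-pitch transition; full compensation would be
        # non-causal for the rising response flank
        d = int(round(delay_comp * 3.0 / (2.0 * np.pi * 1.019 * erb_bandwidth(cf)) * fs))
        if d > 0:
            yc = np.concatenate([yc[d:], np.zeros(d, dtype=yc.dtype)])
        y = np.maximum(yc.real, 0.0) ** compression
        # Gaussian smoother: -3 dB at the channel's phase-locking cutoff;
        # chosen over an IIR low-pass because its autocorrelation has no
        # ringing side lobes that would masquerade as periodicity.
        cutoff = min(lp_cutoff, max(pl_floor, pl_rolloff * cf))
        sigma_samp = np.sqrt(np.log(2.0) / 2.0) / (np.pi * cutoff) * fs
        y = gaussian_filter1d(y, sigma_samp)
        y = signal.resample_poly(np.maximum(y, 0.0), ratio.numerator, ratio.denominator)
        rows.append(np.maximum(y, 0.0))
    chans = np.vstack(rows)
    norm = max(chans.max(), P_FLOOR)
    p = np.clip(chans / norm, 0.0, 1.0)
    return AuditoryNerveResponse(p, 1.0 / bank.internal_rate, bank)


#: Registry of available peripheries; the contract is the plug-in interface.
PERIPHERIES = {"simple": auditory_nerve_probability}


def get_periphery(name: str):
    try:
        return PERIPHERIES[name]
    except KeyError:
        raise ValueError(
            f"unknown periphery {name!r}; available: {sorted(PERIPHERIES)}"
        ) from None
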