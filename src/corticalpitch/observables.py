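"""Measurable quantities derived from a cortical run.

The equivalent dipole moment is the column sum of the decoder's excitatory
rates, shifted by the subcortical processing delay (50 ms for single tones,
75 ms for dyads); its post-onset maximum is identified with the latency of the
pitch onset response (POR).  The decoded pitch(es) are the prominent peaks of
the time-averaged decoder-inhibitory profile within a window after the
decision has completed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks

from .cortex import SimulationResult

#: Fraction of a run's dynamic range used as decision/peak prominence floor.
PROMINENCE_FRAC = 0.10

#: Absolute decoder-inhibitory rate (Hz) separating an ignited (winner-take-
#: all completed) ensemble from sub-threshold hum; ignited winners sit at
#: 80-170 Hz, undecided columns below ~25 Hz.
ACTIVATION_FLOOR_HZ = 30.0


def dipole_moment(result: SimulationResult, delay: float | None = None) -> np.ndarray:
    """Equivalent dipole moment m(t) = sum_n H_e_n(t - delay) (arbitrary units).

    ``delay`` defaults to the run's subcortical delay; the leading ``delay``
    seconds are padded with the initial value.  Sign/axis inversion used when
    plotting evoked fields is presentation-only and not applied here.
    """
    if delay is None:
        delay = result.subcortical_delay
    m = result.H_e.sum(axis=1).astype(np.float64)
    d = int(round(delay / result.dt))
    if d == 0:
        return m
    return np.concatenate([np.full(d, m[0]), m[:-d]])


def extract_por_latency(
    m: np.ndarray,
    dt: float,
    pitch_onset: float,
    window: tuple[float, float] = (0.0, 0.350),
    prominence_frac: float = PROMINENCE_FRAC,
) -> float | None:
    """POR latency in seconds relative to pitch onset, or None if no decision.

    The latency is the argmax of the dipole moment within ``window`` (relative
    to pitch onset; the subcortical delay must already be applied to ``m``).
    Ties break to the earliest sample.  Runs whose peak does not rise above
    the pre-onset baseline by more than ``prominence_frac`` of the analysis
    window's dynamic range are flagged as "no decision" (None).
    """
    i0 = int(round((pitch_onset + window[0]) / dt))
    i1 = int(round((pitch_onset + window[1]) / dt))
    seg = m[i0:i1]
    if seg.size == 0:
        raise ValueError("analysis window lies outside the record")
    span = float(seg.max() - seg.min())
    baseline = float(m[max(i0 - 1, 0)])
    peak = int(np.argmax(seg))
    if span <= 0 or (seg[peak] - baseline) < prominence_frac * span:
        return None
    return (i0 + peak) * dt - pitch_onset


def decode_pitch(
    result: SimulationResult,
    window: tuple[float, float] = (0.250, 0.300),
    max_pitches: int = 1,
    prominence_frac: float = PROMINENCE_FRAC,
    min_rate: float = ACTIVATION_FLOOR_HZ,
) -> list[float]:
    """Decoded period(s) in seconds: prominent local maxima of the
    time-averaged decoder-inhibitory profile, top-k by height.

    ``window`` is relative to pitch onset.  Peaks must exceed ``min_rate``
    (an ignited winner, not sub-threshold hum); returns an empty list when no
    peak qualifies ("no pitch").
    """
    i0 = int(round((result.pitch_onset + window[0]) / result.dt))
    i1 = int(round((result.pitch_onset + window[1]) / result.dt))
    if i0 >= result.H_i.shape[0]:
        return []  # record ends before the decision window
    profile = result.H_i[i0:i1].mean(axis=0).astype(np.float64)
    span = float(profile.max() - profile.min())
    if span <= 0:
        return []
    idx, _ = find_peaks(profile, prominence=prominence_frac * span)
    idx = idx[profile[idx] >= min_rate]
    if idx.size == 0:
        return []
    order = np.argsort(profile[idx])[::-1][:max_pitches]
    chosen = np.sort(idx[order])
    return [float(result.grid.lags[i]) for i in chosen]


@dataclass
class RunObservables:
    """Scalar summary of one run."""

    latency: float | None          # seconds re pitch onset (incl. subcortical delay)
    decoded_periods: list[float]   # seconds
    peak_dipole: float

    def as_dict(self) -> dict:
        return {
            "latency_ms": None if self.latency is None else 1e3 * self.latency,
            "decoded_periods_ms": [1e3 * p for p in self.decoded_periods],
            "peak_dipole": self.peak_dipole,
        }


def summarize(
    result: SimulationResult,
    *,
    max_pitches: int = 1,
    latency_window: tuple[float, float] = (0.0, 0.350),
    decode_window: tuple[float, float] = (0.250, 0.300),
) -> RunObservables:
    """Dipole moment, POR latency and decoded pitch(es) for one run."""
    m = dipole_moment(result)
    lat = extract_por_latency(m, result.dt, result.pitch_onset, latency_window)
    periods = decode_pitch(result, decode_window, max_pitches)
    return RunObservables(lat, periods, float(m.max()))
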