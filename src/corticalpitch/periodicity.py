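"""Summary autocorrelation (SACF) periodicity detection.

One leaky integrator per candidate period (lag) accumulates the
channel-summed product of the auditory-nerve activity with its delayed copy::

    tau_n dA_n/dt = -A_n + sum_m p(t)_m p(t - dt_n)_m

over N = 250 lags uniformly spaced between 0.5 ms (a conservative
phase-locking limit) and 30 ms (the lower limit of melodic pitch).  The lag
integration time constants grow with lag, tau_n = max(tau_floor, c * dt_n),
calibrated once so that the lag-T detector first reaches half of its steady
response about 1.25 * T after pitch onset for reference IRNs.

The raw SACF is regularized into the cortical input in four steps: divisive
normalisation across the lag axis (removes the dependence on overall
stimulus intensity), subtraction of a local lag-axis baseline pool
(lateral-inhibition-style contrast enhancement that keeps narrow harmonic
peaks and discards broad lag-unspecific humps), subtraction of a slowly
adapting temporal baseline (emphasising changes such as the noise-to-pitch
transition), and a fixed mode-specific rescale (single tones vs dyads) with
a sensitivity taper at the short-lag grid edge.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from scipy.ndimage import uniform_filter1d

from .periphery import AuditoryNerveResponse


@dataclass(frozen=True)
class LagGrid:
    """Uniform grid of candidate periods (lags)."""

    n: int = 250
    lag_min: float = 0.5e-3
    lag_max: float = 30e-3

    @property
    def lags(self) -> np.ndarray:
        return np.linspace(self.lag_min, self.lag_max, self.n)

    @property
    def step(self) -> float:
        return (self.lag_max - self.lag_min) / (self.n - 1)

    def nearest(self, period: float) -> int:
        """Index of the column whose lag is nearest to ``period`` (seconds)."""
        return int(np.argmin(np.abs(self.lags - period)))


@dataclass(frozen=True)
class SACFParams:
    """Integration and regularization constants.

    ``tau_floor``/``tau_scale`` set the per-lag integration time constants.
    ``k_semisat`` is the semi-saturation constant of the divisive
    normalisation; ``contrast_window`` is the width (in lag-grid columns) of
    the local baseline pool subtracted along the lag axis (lateral-inhibition
    style contrast enhancement, which removes broad lag-unspecific humps while
    preserving narrow harmonic peaks); ``theta`` is a small residual threshold
    and ``rescale_single``/``rescale_dyad`` the fixed affine factors mapping
    the normalized SACF onto the current range the decoder expects.
    """

    tau_floor: float = 1.0e-3
    tau_scale: float = 0.3
    k_semisat: float = 1.0
    contrast_window: int = 31
    theta: float = 0.02
    adapt_tau: float = 0.5
    adapt_strength: float = 1.0
    edge_taper_until: float = 2.3e-3
    edge_gain_min: float = 0.1
    rescale_single: float = 4000.0
    rescale_dyad: float = 1500.0

    def tau(self, grid: LagGrid) -> np.ndarray:
        t = np.maximum(self.tau_floor, self.tau_scale * grid.lags)
        return t


@dataclass
class SACFOutput:
    """Raw (A) and, once regularized, normalized (Ahat) lag x time matrices."""

    A: np.ndarray
    dt: float
    grid: LagGrid
    Ahat: np.ndarray | None = None
    mode: str | None = None

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.A.shape[1]) * self.dt


def compute_sacf(
    an: AuditoryNerveResponse,
    grid: LagGrid | None = None,
    params: SACFParams | None = None,
    *,
    out_dt: float = 1e-3,
) -> SACFOutput:
    """Integrate the SACF over the lag grid and resample to the cortical step.

    The leaky integration uses the exact exponential update for a
    piecewise-constant drive, A[t] = e^(-dt/tau) A[t-1] + (1 - e^(-dt/tau)) x[t],
    evaluated at the periphery rate, then decimated to ``out_dt``.
    """
    grid = grid or LagGrid()
    params = params or SACFParams()
    p = an.p
    dt = an.dt
    if an.duration <= grid.lag_max:
        raise ValueError(
            f"response duration {an.duration:g} s must exceed the maximum lag "
            f"{grid.lag_max:g} s"
        )
    n_t = p.shape[1]
    taus = params.tau(grid)
    A = np.empty((grid.n, n_t), dtype=np.float64)
    for i, (lag, tau) in enumerate(zip(grid.lags, taus)):
        d = int(round(lag / dt))
        x = np.zeros(n_t)
        if d < n_t:
            x[d:] = np.einsum("ct,ct->t", p[:, d:], p[:, :-d] if d else p)
        a = np.exp(-dt / tau)
        A[i] = signal.lfilter([1.0 - a], [1.0, -a], x)
    stride = int(round(out_dt / dt))
    return SACFOutput(A[:, ::stride], dt * stride, grid)


def regularize(sacf: SACFOutput, params: SACFParams | None = None, mode: str = "single") -> SACFOutput:
    """Divisive normalisation plus local-baseline contrast enhancement.

    At every time step the raw SACF is divided by the lag-mean (with
    semi-saturation ``k``), the local lag-axis baseline (uniform pool of
    ``contrast_window`` columns, reflected at the grid edges) is subtracted,
    a slowly adapting per-lag temporal baseline (exponential average with
    time constant ``adapt_tau``) is removed, and the positive residual is
    scaled by the mode-specific factor R::

        z_n    = A_n / (k + mean_n A_n)
        res_n  = max(0, z_n - pool(z)_n - theta)
        Ahat_n = R * max(0, res_n - q * ema(res)_n)

    The adaptation term emphasises *changes* in the periodicity pattern: the
    stationary structure of a noise precursor fades before pitch onset while
    the harmonic peaks appearing at the noise-to-pitch transition pass at
    full strength.  An all-zero SACF maps to an all-zero output (no division
    blow-up); a lag-flat SACF maps to the documented baseline of 0.
    """
    params = params or SACFParams()
    if mode not in ("single", "dyad"):
        raise ValueError(f"mode must be 'single' or 'dyad', got {mode!r}")
    r = params.rescale_single if mode == "single" else params.rescale_dyad
    mean = sacf.A.mean(axis=0, keepdims=True)
    z = sacf.A / (params.k_semisat + mean)
    w = params.contrast_window
    if w > 1:
        pool = uniform_filter1d(z, size=w, axis=0, mode="reflect")
    else:
        pool = np.zeros_like(z)
    resid = np.maximum(0.0, z - pool - params.theta)
    if params.adapt_strength > 0.0 and params.adapt_tau > 0.0:
        alpha = sacf.dt / params.adapt_tau
        ema = signal.lfilter([alpha], [1.0, alpha - 1.0], resid, axis=1)
        resid = np.maximum(0.0, resid - params.adapt_strength * ema)
    # sensitivity taper at the short-lag edge: detectors close to the
    # phase-locking limit respond weakly, which also suppresses the spurious
    # band-edge periodicity of the noise precursor
    lags = sacf.grid.lags
    span = params.edge_taper_until - lags[0]
    if span > 0:
        taper = np.clip((lags - lags[0]) / span, 0.0, 1.0)
        taper = params.edge_gain_min + (1.0 - params.edge_gain_min) * taper
        resid = resid * taper[:, None]
    ahat = r * resid
    return SACFOutput(sacf.A, sacf.dt, sacf.grid, Ahat=ahat, mode=mode)


def half_rise_time(
    sacf: SACFOutput,
    period: float,
    onset: float,
    *,
    steady_window: tuple[float, float] = (0.300, 0.450),
    use_regularized: bool = True,
) -> float:
    """Time after ``onset`` at which the lag-matched channel first reaches half
    of its late-window steady value (seconds).

    ``steady_window`` is expressed relative to onset.  Used to calibrate and
    verify the 1.25*T activation time of the periodicity detectors.
    """
    mat = sacf.Ahat if (use_regularized and sacf.Ahat is not None) else sacf.A
    row = mat[sacf.grid.nearest(period)]
    i0 = int(round(onset / sacf.dt))
    s0 = int(round((onset + steady_window[0]) / sacf.dt))
    s1 = int(round((onset + steady_window[1]) / sacf.dt))
    steady = float(np.mean(row[s0:s1]))
    if steady <= 0:
        raise ValueError("steady-state response is zero; cannot measure rise time")
    post = row[i0:]
    above = np.nonzero(post >= 0.5 * steady)[0]
    if above.size == 0:
        raise ValueError("response never reaches half of its steady value")
    return float(above[0] * sacf.dt)
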