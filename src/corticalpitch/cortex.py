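"""Decoder and sustainer mean-field cortical networks.

Both networks consist of 250 columns, one per candidate period on the lag
grid; each column holds an excitatory and an inhibitory neural ensemble with
instantaneous firing rates H^e, H^i following

    tau_pop(H) dH/dt = -H + phi(I),

where phi is the Abbott–Chance transfer function

    phi(I) = (a I - b) / (1 - exp(-d (a I - b)))

and the population time constant adapts with activity,
tau_pop = tau0 * Delta_T * phi'(I) / H (clamped to a configurable range).

Synaptic gating follows Brunel's formulation: AMPA and GABA gating relax with
their decay constants and are driven by the presynaptic rate; NMDA gating
saturates via the coupling gamma.  The decoder receives the regularized SACF
through AMPA-like subcortical gating; its columns are wired so that the
inhibitory ensemble at period T collects excitation from the columns at
{T, 2T, 3T} (three harmonic inputs are required to ignite it) and projects
inhibition onto the columns encoding the lower harmonics {2T, 3T, 4T, ...},
implementing a winner-take-all decision that leaves the fundamental active.
The sustainer is a second, block-local network receiving bottom-up input from
the decoder and returning top-down NMDA drive to the decoder's inhibitory
ensembles, locking in the decoded pitch.

Integration is forward Euler at 1 ms with independent Gaussian noise (scaled
by sqrt(dt)) injected into every gating variable at every step.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace

import numpy as np

from .periodicity import LagGrid, SACFOutput


@dataclass(frozen=True)
class CorticalParams:
    """Cortical model parameters (conductivities in nA, times in seconds)."""

    # conductivities
    J_th_ampa: float = 2.7        # subcortical input -> decoder excitatory
    J_e_nmda: float = 0.45        # top-down (sustainer -> decoder inhibitory)
    Jhat_a_gaba: float = 0.45     # bottom-up (decoder inh -> sustainer inh)
    Jhat_a_ampa: float = 0.35     # bottom-up (decoder exc -> sustainer exc)
    J_ee_nmda: float = 0.14
    J_ee_ampa: float = 0.00099
    J_ei_nmda: float = 0.17
    J_ei_ampa: float = 0.000065
    J_ie_gaba: float = 0.53
    J_ii_gaba: float = 0.11
    Jhat_ee_nmda: float = 0.25
    Jhat_ee_ampa: float = 0.00099
    Jhat_ei_ampa: float = 0.00099
    Jhat_ie_gaba: float = 0.80
    c0_ie: float = 0.1            # ratio between global and specific inhibition
    gamma: float = 0.641          # NMDA gating coupling
    # transfer functions
    a_e: float = 310.0            # (V nC)^-1
    b_e: float = 125.0            # Hz
    d_e: float = 0.16             # s
    a_i: float = 615.0
    b_i: float = 177.0
    d_i: float = 0.087
    # baseline drives
    I0_e: float = 0.315
    I0_i: float = 0.15
    Ihat0_e: float = 0.26
    Ihat0_i: float = 0.18
    I0_sus: float = 0.24          # extra constant drive to both sustainer populations
    # time constants
    tau_ampa: float = 0.002
    tau_gaba: float = 0.005
    tau_nmda: float = 0.030
    tau_pop0: float = 0.010
    delta_T: float = 1.0          # mV
    sigma: float = 0.0007         # synaptic noise amplitude, nA
    dt: float = 0.001
    # numerical safeguards / architecture
    tau_pop_min: float = 0.001
    tau_pop_max: float = 0.010
    harmonic_sigma: float = 1.5     # C^ie smearing width, in grid steps
    harmonic_sigma_ei: float = 1.0  # C^ei smearing width, in grid steps
    n_harmonics_ei: int = 3         # harmonic inputs collected by each inhibitory ensemble
    ei_gain: float = 1.2            # overall C^ei synaptic weight scale
    two_harmonic_boost: float = 1.3  # extra C^ei weight when only 2 harmonics fit the grid
    one_harmonic_gain: float = 0.5  # C^ei de-weighting when a single harmonic fits the grid
    # subcortical delays applied when deriving the evoked field
    delay_single: float = 0.050
    delay_dyads: float = 0.075

    def as_dict(self) -> dict:
        return asdict(self)

    def with_updates(self, **kw) -> "CorticalParams":
        unknown = set(kw) - set(self.as_dict())
        if unknown:
            raise KeyError(f"unknown cortical parameter(s): {sorted(unknown)}")
        return replace(self, **kw)


# ---------------------------------------------------------------------------
# transfer function


def _phi(I, a, b, d):
    """phi(I) = (aI-b)/(1-exp(-d(aI-b))) with the removable singularity at
    aI = b handled by its series expansion."""
    u = a * np.asarray(I, dtype=np.float64) - b
    du = np.clip(d * u, -60.0, 60.0)
    small = np.abs(du) < 1e-6
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(small, 1.0 / d + u / 2.0, u / (-np.expm1(-du)))
    return out


def _phi_prime(I, a, b, d):
    """Analytic derivative of the transfer function (everywhere positive)."""
    u = a * np.asarray(I, dtype=np.float64) - b
    du = np.clip(d * u, -60.0, 60.0)
    small = np.abs(du) < 1e-6
    E = np.exp(-du)
    denom = -np.expm1(-du)  # 1 - e^{-du}
    with np.errstate(divide="ignore", invalid="ignore"):
        exact = a * (denom - u * d * E) / denom**2
    series = a * (0.5 + du / 6.0)
    return np.where(small, series, exact)


def transfer(I, which: str, params: CorticalParams):
    """Population transfer function phi(I) in Hz; ``which`` is 'exc' or 'inh'."""
    if which == "exc":
        return _phi(I, params.a_e, params.b_e, params.d_e)
    if which == "inh":
        return _phi(I, params.a_i, params.b_i, params.d_i)
    raise ValueError(f"which must be 'exc' or 'inh', got {which!r}")


def transfer_derivative(I, which: str, params: CorticalParams):
    """d(phi)/dI in Hz/nA."""
    if which == "exc":
        return _phi_prime(I, params.a_e, params.b_e, params.d_e)
    if which == "inh":
        return _phi_prime(I, params.a_i, params.b_i, params.d_i)
    raise ValueError(f"which must be 'exc' or 'inh', got {which!r}")


def effective_tau(H, I, which: str, params: CorticalParams):
    """Adaptive population time constant tau0 * Delta_T * phi'(I) / H.

    Diverges as H -> 0; clamped to [tau_pop_min, tau_pop_max], with H = 0
    mapped to the clamp maximum.
    """
    H = np.asarray(H, dtype=np.float64)
    dphi = transfer_derivative(I, which, params)
    with np.errstate(divide="ignore", invalid="ignore"):
        tau = params.tau_pop0 * params.delta_T * dphi / H
    tau = np.where(H <= 0.0, params.tau_pop_max, tau)
    return np.clip(tau, params.tau_pop_min, params.tau_pop_max)


# ---------------------------------------------------------------------------
# connectivity


@dataclass(frozen=True)
class ConnectivityMatrices:
    """Decoder connectivity. Row = target column, column = source column."""

    C_ee: np.ndarray
    C_ei: np.ndarray  # excitatory -> inhibitory (harmonics {T, 2T, 3T})
    C_ie: np.ndarray  # inhibitory -> excitatory (lower harmonics {2T, 3T, ...})
    C_ii: np.ndarray


def _harmonic_bumps(
    grid: LagGrid, centers: np.ndarray, sigma_steps: float, norm: str
) -> np.ndarray:
    """Sum of Gaussian profiles over grid lags, one per centre.

    ``norm='mass'`` scales each bump to unit total weight, so one harmonic
    location contributes at most one unit of drive no matter how broad the
    activation under it is; ``norm='peak'`` scales each bump to unit height.
    """
    lags = grid.lags
    sig = sigma_steps * grid.step
    # analytic mass of an untruncated bump (in columns); bumps truncated at
    # the grid edge genuinely lose the off-grid share of their weight
    full_mass = np.sqrt(2.0 * np.pi) * sigma_steps
    out = np.zeros(grid.n)
    for c in centers:
        bump = np.exp(-0.5 * ((lags - c) / sig) ** 2)
        if norm == "mass":
            bump /= full_mass
        out += bump
    return out


def build_connectivity(grid: LagGrid, params: CorticalParams) -> ConnectivityMatrices:
    """Construct the four 250x250 decoder weight matrices.

    C^ee is the identity; C^ii mixes specific and global inhibition,
    (1 - c0) * delta + c0.  The inhibitory ensemble at period T receives
    Gaussian-smeared excitatory input from the columns at {T, 2T, 3T}, each
    harmonic bump normalised to unit mass so that igniting the ensemble
    requires activity at three *distinct* harmonic locations (harmonics beyond
    the grid edge are dropped).  It projects peak-normalised inhibition onto
    the excitatory columns at the lower harmonics {2T, 3T, ...} up to the
    grid edge.
    """
    n = grid.n
    lags = grid.lags
    edge = grid.lag_max + grid.step / 2
    C_ee = np.eye(n)
    C_ii = (1.0 - params.c0_ie) * np.eye(n) + params.c0_ie * np.ones((n, n))
    C_ei = np.zeros((n, n))
    C_ie = np.zeros((n, n))
    for j in range(n):
        t = lags[j]
        ei_centers = np.array(
            [h * t for h in range(1, params.n_harmonics_ei + 1) if h * t <= edge]
        )
        if ei_centers.size:
            # columns whose 3rd harmonic falls beyond the grid keep a larger
            # per-harmonic weight (partial row renormalisation), so periods in
            # the upper half of the range remain decodable from 2 harmonics;
            # singleton rows (period > half the grid) get no boost.
            if ei_centers.size == 2:
                gain = params.ei_gain * params.two_harmonic_boost
            elif ei_centers.size == 1:
                gain = params.ei_gain * params.one_harmonic_gain
            else:
                gain = params.ei_gain
            C_ei[j] = gain * _harmonic_bumps(
                grid, ei_centers, params.harmonic_sigma_ei, "mass")
        max_h = int(np.floor(edge / t))
        ie_centers = np.array([h * t for h in range(2, max_h + 1)])
        if ie_centers.size:
            C_ie[:, j] = _harmonic_bumps(grid, ie_centers, params.harmonic_sigma,
                                         "peak")
    return ConnectivityMatrices(C_ee, C_ei, C_ie, C_ii)


# ---------------------------------------------------------------------------
# state, synapses, inputs


@dataclass
class NetworkState:
    """Rates and gating for the decoder and sustainer networks."""

    H_e: np.ndarray
    H_i: np.ndarray
    S_ampa_e: np.ndarray   # AMPA gating of the excitatory ensembles
    S_nmda_e: np.ndarray   # NMDA gating of the excitatory ensembles
    S_gaba_i: np.ndarray   # GABA gating of the inhibitory ensembles
    Hh_e: np.ndarray
    Hh_i: np.ndarray
    Sh_ampa_e: np.ndarray
    Sh_nmda_e: np.ndarray
    Sh_gaba_i: np.ndarray
    S_th: np.ndarray       # subcortical AMPA gating driving the decoder

    @classmethod
    def zeros(cls, n: int) -> "NetworkState":
        return cls(*[np.zeros(n) for _ in range(11)])


def synaptic_step(state: NetworkState, params: CorticalParams, dt: float,
                  A_t: np.ndarray, rng: np.random.Generator | None) -> None:
    """One Euler step of every gating variable (in place).

    AMPA/GABA: dS/dt = -S/tau + H + xi;  NMDA: dS/dt = -S/tau + gamma(1-S)H + xi;
    subcortical: dS/dt = -S/tau_AMPA + A_n(t) (no noise).  xi = sigma sqrt(dt) z
    independently per variable and step.  Gating is clamped to >= 0 (NMDA
    additionally <= 1) after the update.
    """
    g = params.gamma

    def noise(shape):
        if rng is None or params.sigma == 0.0:
            return 0.0
        return params.sigma * np.sqrt(dt) * rng.standard_normal(shape)

    n = state.H_e.size
    state.S_ampa_e += dt * (-state.S_ampa_e / params.tau_ampa + state.H_e) + noise(n)
    state.S_nmda_e += dt * (
        -state.S_nmda_e / params.tau_nmda + g * (1.0 - state.S_nmda_e) * state.H_e
    ) + noise(n)
    state.S_gaba_i += dt * (-state.S_gaba_i / params.tau_gaba + state.H_i) + noise(n)
    state.Sh_ampa_e += dt * (-state.Sh_ampa_e / params.tau_ampa + state.Hh_e) + noise(n)
    state.Sh_nmda_e += dt * (
        -state.Sh_nmda_e / params.tau_nmda + g * (1.0 - state.Sh_nmda_e) * state.Hh_e
    ) + noise(n)
    state.Sh_gaba_i += dt * (-state.Sh_gaba_i / params.tau_gaba + state.Hh_i) + noise(n)
    state.S_th += dt * (-state.S_th / params.tau_ampa + A_t)

    for s in (state.S_ampa_e, state.S_gaba_i, state.Sh_ampa_e, state.Sh_gaba_i,
              state.S_th):
        np.maximum(s, 0.0, out=s)
    np.clip(state.S_nmda_e, 0.0, 1.0, out=state.S_nmda_e)
    np.clip(state.Sh_nmda_e, 0.0, 1.0, out=state.Sh_nmda_e)


def compute_inputs(
    state: NetworkState, mats: ConnectivityMatrices, params: CorticalParams
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Total synaptic currents (I_e, I_i, Ihat_e, Ihat_i) per column, nA.

    Decoder: internal recurrence through the C matrices, subcortical AMPA
    drive to the excitatory ensembles, top-down sustainer NMDA drive to the
    inhibitory ensembles.  Sustainer: block-local recurrence plus bottom-up
    AMPA (from decoder excitatory) and GABA (from decoder inhibitory) inputs,
    and the extra constant sustainer drive on both populations.
    """
    exc_drive = params.J_ei_nmda * state.S_nmda_e + params.J_ei_ampa * state.S_ampa_e
    gaba = params.J_ie_gaba * state.S_gaba_i

    I_e = (
        params.I0_e
        + params.J_th_ampa * state.S_th
        + params.J_ee_nmda * state.S_nmda_e + params.J_ee_ampa * state.S_ampa_e
        - mats.C_ie @ gaba
    )
    # global + specific inhibition among inhibitory ensembles (rank-1 structure)
    s_g = state.S_gaba_i
    ii = params.J_ii_gaba * ((1.0 - params.c0_ie) * s_g + params.c0_ie * s_g.sum())
    I_i = (
        params.I0_i
        + mats.C_ei @ exc_drive
        - ii
        + params.J_e_nmda * state.Sh_nmda_e
    )
    Ihat_e = (
        params.Ihat0_e + params.I0_sus
        + params.Jhat_ee_nmda * state.Sh_nmda_e + params.Jhat_ee_ampa * state.Sh_ampa_e
        - params.Jhat_ie_gaba * state.Sh_gaba_i
        + params.Jhat_a_ampa * state.S_ampa_e
    )
    Ihat_i = (
        params.Ihat0_i + params.I0_sus
        + params.Jhat_ei_ampa * state.Sh_ampa_e
        - params.Jhat_a_gaba * state.S_gaba_i
    )
    return I_e, I_i, Ihat_e, Ihat_i


# ---------------------------------------------------------------------------
# simulation


@dataclass
class SimulationResult:
    """Trajectories of one cortical run (1 ms resolution, float32 storage)."""

    dt: float
    grid: LagGrid
    H_e: np.ndarray    # time x columns, decoder excitatory
    H_i: np.ndarray
    Hh_e: np.ndarray
    Hh_i: np.ndarray
    params: CorticalParams
    seed: int | None = None
    pitch_onset: float = 0.0
    mode: str = "single"

    @property
    def time(self) -> np.ndarray:
        return np.arange(self.H_e.shape[0]) * self.dt

    @property
    def subcortical_delay(self) -> float:
        return self.params.delay_single if self.mode == "single" else self.params.delay_dyads


def simulate(
    ahat: SACFOutput,
    params: CorticalParams | None = None,
    seed: int | None = 0,
    *,
    pitch_onset: float = 0.0,
    mats: ConnectivityMatrices | None = None,
    record_gating: bool = False,
) -> SimulationResult:
    """Forward-Euler integration of both networks driven by the regularized SACF.

    ``ahat`` must be regularized (``Ahat`` set); its time step must equal the
    cortical step.  The state starts from zero and settles to baseline during
    the (pitch-free) head of the input.  Reproducible given ``seed``; with
    ``seed=None`` the synaptic noise is disabled.
    """
    params = params or CorticalParams()
    if ahat.Ahat is None:
        raise ValueError("SACF output must be regularized before simulation")
    if abs(ahat.dt - params.dt) > 1e-12:
        raise ValueError(f"SACF step {ahat.dt} differs from cortical step {params.dt}")
    grid = ahat.grid
    A = ahat.Ahat
    n_steps = A.shape[1]
    dt = params.dt
    mats = mats or build_connectivity(grid, params)
    rng = np.random.default_rng(seed) if seed is not None else None

    state = NetworkState.zeros(grid.n)
    traj = {k: np.empty((n_steps, grid.n), dtype=np.float32)
            for k in ("H_e", "H_i", "Hh_e", "Hh_i")}
    gating_traj = {}
    if record_gating:
        gating_traj = {k: np.empty((n_steps, grid.n), dtype=np.float32)
                       for k in ("S_nmda_e", "S_gaba_i", "Sh_nmda_e", "S_th")}

    for t in range(n_steps):
        I_e, I_i, Ih_e, Ih_i = compute_inputs(state, mats, params)
        for H, I, which in (
            (state.H_e, I_e, "exc"), (state.H_i, I_i, "inh"),
            (state.Hh_e, Ih_e, "exc"), (state.Hh_i, Ih_i, "inh"),
        ):
            tau = effective_tau(H, I, which, params)
            H += dt / tau * (-H + transfer(I, which, params))
            np.maximum(H, 0.0, out=H)
        synaptic_step(state, params, dt, A[:, t], rng)
        traj["H_e"][t] = state.H_e
        traj["H_i"][t] = state.H_i
        traj["Hh_e"][t] = state.Hh_e
        traj["Hh_i"][t] = state.Hh_i
        if record_gating:
            for k in gating_traj:
                gating_traj[k][t] = getattr(state, k)
        if t % 50 == 0 and not np.isfinite(state.H_e).all():
            bad = int(np.flatnonzero(~np.isfinite(state.H_e))[0])
            raise FloatingPointError(
                f"non-finite decoder rate at step {t}, column {bad}"
            )

    result = SimulationResult(
        dt=dt, grid=grid, H_e=traj["H_e"], H_i=traj["H_i"],
        Hh_e=traj["Hh_e"], Hh_i=traj["Hh_i"], params=params, seed=seed,
        pitch_onset=pitch_onset, mode=ahat.mode or "single",
    )
    if record_gating:
        result.gating = gating_traj  # type: ignore[attr-defined]
    return result
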