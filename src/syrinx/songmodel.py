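"""Hierarchical Lorenz song model and the synthetic syrinx.

The generative model of song is two stacked Lorenz attractors.  The higher
(extrasensory) attractor is an order of magnitude slower than the lower
(sensory) one; its output map reads its first state into a descending
control signal, v = gain * x2[0] + offset.  The coupling parameter theta
scales the (softly saturated) control into the effective Rayleigh number
of the fast attractor:

    rho_eff = rayleigh_base + theta * sat(v)     (rayleigh_base = 0)

so at theta = 0 the fast attractor has Rayleigh number zero, collapses to
its origin and the bird falls silent, while at theta = 1 the slow sweep of
v carries the fast attractor through fixed-point, periodic and chaotic
regimes — amplitude bursts (chirps) every few hundred milliseconds.

Two fast states drive a synthetic syrinx: one controls instantaneous
frequency (clipped to the 2-5 kHz band), the other amplitude (silent below
a threshold).  The rendered output is a sonogram: a time x frequency-band
amplitude matrix.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .gencoords import SmoothnessSpec

__all__ = [
    "LorenzParams",
    "SyrinxMap",
    "HierarchicalModel",
    "Sonogram",
    "SimulationError",
    "lorenz_flow",
    "lorenz_jacobian",
    "rayleigh_control",
    "sat_control",
    "syrinx_output",
    "render_sonogram",
    "generate_song",
    "default_model",
    "random_attractor_state",
]


class SimulationError(RuntimeError):
    """Numerical blow-up during integration (reports the failure time)."""


@dataclass(frozen=True)
class LorenzParams:
    """Lorenz attractor constants; ``tau`` (s) scales the flow speed."""

    prandtl: float = 10.0
    rayleigh_base: float = 0.0
    beta: float = 8.0 / 3.0
    tau: float = 0.25

    def __post_init__(self) -> None:
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.beta <= 0:
            raise ValueError("beta must be positive")


@dataclass(frozen=True)
class SyrinxMap:
    """Affine state-to-sound maps with saturation.

    Frequency: ``freq_lo + freq_gain * state[freq_state_index]`` clipped to
    [freq_lo, freq_hi].  Amplitude: the vibration magnitude of the syrinx,
    ``amp_gain * (|state[amp_state_index]| - silence_threshold)`` floored at
    zero — the sign of the controlling state is vibratory phase, not
    loudness, so both lobes of the attractor are audible.
    """

    freq_lo: float = 2000.0
    freq_hi: float = 5000.0
    freq_state_index: int = 2
    amp_state_index: int = 1
    freq_gain: float = 60.0  # Hz per state unit
    amp_gain: float = 1.0
    silence_threshold: float = 4.0


# sensory log-precisions 'aud'/'prop' are placeholders here; the dyad's
# turn-taking schedule overwrites them per role
DEFAULT_LOG_PRECISIONS: dict[str, float] = {
    "aud": 2.0,   # auditory channels
    "prop": 0.0,  # proprioceptive channels
    "v": 4.0,     # level-2 cause (fixed at 4 in all roles)
    "x1": 2.0,    # fast-attractor state noise
    "x2": 4.0,    # slow-attractor state noise
}


@dataclass
class HierarchicalModel:
    """Two-level dynamic generative model of song.

    ``theta`` scales the descending control; the level-2 output map reads the
    slow attractor's first state, v = level2_gain * x2[0] + level2_offset, so
    the control sweeps a positive band and theta alone sets how strongly it
    reaches the fast attractor.
    """

    level2: LorenzParams = field(
        default_factory=lambda: LorenzParams(rayleigh_base=28.0, tau=2.5)
    )
    level1: LorenzParams = field(default_factory=LorenzParams)
    theta: float = 1.0
    level2_gain: float = 0.5
    level2_offset: float = 32.0
    log_precisions: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_LOG_PRECISIONS)
    )
    smoothness: SmoothnessSpec = field(default_factory=SmoothnessSpec)
    syrinx: SyrinxMap = field(default_factory=SyrinxMap)

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be non-negative")
        missing = set(DEFAULT_LOG_PRECISIONS) - set(self.log_precisions)
        if missing:
            raise ValueError(f"missing log-precisions: {sorted(missing)}")

    def with_theta(self, theta: float) -> "HierarchicalModel":
        return replace(self, theta=theta, log_precisions=dict(self.log_precisions))


def default_model(theta: float = 1.0) -> HierarchicalModel:
    return HierarchicalModel(theta=theta)


def random_attractor_state(
    params: LorenzParams, rng: np.random.Generator, dt: float = 1.0 / 64.0
) -> np.ndarray:
    """A random point on a Lorenz attractor (burned-in, random phase)."""
    x = np.array([1.0, 1.0, max(params.rayleigh_base - 3.0, 1.0)])
    n = 384 + int(rng.integers(0, 256))
    for _ in range(n):
        f = lorenz_flow(x, params, params.rayleigh_base)
        J = lorenz_jacobian(x, params, params.rayleigh_base)
        x = _ll_step(x, f, J, dt)
    return x


@dataclass
class Sonogram:
    """Time x frequency amplitude matrix in the 2-5 kHz band."""

    times: np.ndarray  # (T,) seconds
    freqs: np.ndarray  # (F,) Hz
    amplitude: np.ndarray  # (T, F), >= 0

    def envelope(self) -> np.ndarray:
        """Peak amplitude over frequency at each time."""
        return self.amplitude.max(axis=1)


def lorenz_flow(
    state: np.ndarray, params: LorenzParams, rayleigh_eff: float
) -> np.ndarray:
    """Lorenz velocity (1/tau) * [s(y-x); x(rho-z)-y; xy - bz]."""
    state = np.asarray(state, dtype=float)
    if not np.all(np.isfinite(state)):
        raise FloatingPointError("non-finite state passed to lorenz_flow")
    x, y, z = state
    s, b = params.prandtl, params.beta
    return (
        np.array([s * (y - x), x * (rayleigh_eff - z) - y, x * y - b * z])
        / params.tau
    )


def lorenz_jacobian(
    state: np.ndarray, params: LorenzParams, rayleigh_eff: float
) -> np.ndarray:
    x, y, z = np.asarray(state, dtype=float)
    s, b = params.prandtl, params.beta
    return (
        np.array(
            [
                [-s, s, 0.0],
                [rayleigh_eff - z, -1.0, -x],
                [y, x, -b],
            ]
        )
        / params.tau
    )


RAYLEIGH_SAT = 64.0  # soft bound on the descending control signal


def sat_control(v: float) -> float:
    """Soft saturation of the descending control, V tanh(v / V)."""
    return RAYLEIGH_SAT * np.tanh(v / RAYLEIGH_SAT)


def sat_control_d1(v: float) -> float:
    return 1.0 / np.cosh(v / RAYLEIGH_SAT) ** 2


def sat_control_d2(v: float) -> float:
    u = v / RAYLEIGH_SAT
    return -2.0 * np.tanh(u) / np.cosh(u) ** 2 / RAYLEIGH_SAT


def rayleigh_control(v: float, theta: float, params: LorenzParams) -> float:
    """Effective Rayleigh number of the fast attractor.

    Affine in theta around ``params.rayleigh_base`` with a softly saturated
    control signal (the biophysical gain of the descending pathway is
    bounded): rho = rayleigh_base + theta * sat(v).  At theta = 0 the fast
    level is disconnected from the descending control; within the slow
    attractor's operating band the saturation is mild and the control is
    close to affine in v.
    """
    return params.rayleigh_base + theta * sat_control(v)


def syrinx_output(
    fast_state: np.ndarray, syrinx: SyrinxMap
) -> tuple[float, float]:
    """Map fast-attractor states to (frequency Hz, amplitude >= 0)."""
    fast_state = np.asarray(fast_state, dtype=float)
    freq = syrinx.freq_lo + syrinx.freq_gain * fast_state[syrinx.freq_state_index]
    freq = float(np.clip(freq, syrinx.freq_lo, syrinx.freq_hi))
    amp = syrinx.amp_gain * (
        abs(fast_state[syrinx.amp_state_index]) - syrinx.silence_threshold
    )
    return freq, float(max(amp, 0.0))


def render_sonogram(
    times: np.ndarray,
    freq_hz: np.ndarray,
    amp: np.ndarray,
    n_bins: int = 64,
    freq_lo: float = 2000.0,
    freq_hi: float = 5000.0,
    ridge_width: float = 150.0,
) -> Sonogram:
    """Render instantaneous (frequency, amplitude) as a single-ridge sonogram.

    Each time column is a Gaussian bump of fixed spectral width centered on
    the instantaneous frequency and scaled by the amplitude (cosmetic —
    analysis runs on the underlying channels or the envelope).
    """
    freqs = np.linspace(freq_lo, freq_hi, n_bins)
    amp = np.maximum(np.asarray(amp, dtype=float), 0.0)
    d = freqs[None, :] - np.asarray(freq_hz, dtype=float)[:, None]
    amplitude = amp[:, None] * np.exp(-0.5 * (d / ridge_width) ** 2)
    return Sonogram(np.asarray(times, dtype=float), freqs, amplitude)


def _ll_step(x: np.ndarray, flow: np.ndarray, jac: np.ndarray, dt: float) -> np.ndarray:
    """Local-linearization (matrix-exponential) update dx = (e^{J dt}-I) J^+ f.

    Computed via the augmented exponential so singular Jacobians need no
    special casing.
    """
    from scipy.linalg import expm

    n = x.size
    aug = np.zeros((n + 1, n + 1))
    aug[:n, :n] = jac * dt
    aug[:n, n] = flow * dt
    return x + expm(aug)[:n, n]


def joint_flow_jacobian(
    x1: np.ndarray, x2: np.ndarray, model: HierarchicalModel
) -> tuple[np.ndarray, np.ndarray]:
    """Flow and Jacobian of the stacked (x1, x2) deterministic hierarchy."""
    p1, p2 = model.level1, model.level2
    v = model.level2_gain * x2[0] + model.level2_offset
    rho = rayleigh_control(v, model.theta, p1)
    f1 = lorenz_flow(x1, p1, rho)
    f2 = lorenz_flow(x2, p2, p2.rayleigh_base)
    J = np.zeros((6, 6))
    J[:3, :3] = lorenz_jacobian(x1, p1, rho)
    J[3:, 3:] = lorenz_jacobian(x2, p2, p2.rayleigh_base)
    # d f1 / d x2[0] through the descending control
    J[1, 3] = (
        x1[0] * model.theta * sat_control_d1(v) * model.level2_gain / p1.tau
    )
    return np.concatenate([f1, f2]), J


def generate_song(
    model: HierarchicalModel,
    duration: float = 2.0,
    dt: float = 1.0 / 64.0,
    seed: int = 0,
    noise: bool = True,
    noise_std: tuple[float, float] = (0.125, 0.125),
    x1_init: np.ndarray | None = None,
    x2_init: np.ndarray | None = None,
    n_bins: int = 64,
) -> tuple[dict[str, np.ndarray], Sonogram]:
    """Integrate the hierarchy forward and render the emitted sonogram.

    The slow attractor is spun up from a standard initial condition (or
    ``x2_init``); both levels advance with local-linearization steps plus
    optional additive state noise.  Bit-reproducible for a given seed.

    Returns a trace dict (t, x1, x2, v, rho, freq, amp) and the Sonogram.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    x1 = np.array([1.0, 1.0, 1.0]) if x1_init is None else np.array(x1_init, float)
    x2 = (
        np.array([1.0, 1.0, 25.0]) if x2_init is None else np.array(x2_init, float)
    )
    if x2_init is None:
        # burn the slow attractor onto its manifold (deterministic)
        for _ in range(256):
            f2 = lorenz_flow(x2, model.level2, model.level2.rayleigh_base)
            J2 = lorenz_jacobian(x2, model.level2, model.level2.rayleigh_base)
            x2 = _ll_step(x2, f2, J2, dt)

    t = np.arange(n_steps) * dt
    X1 = np.empty((n_steps, 3))
    X2 = np.empty((n_steps, 3))
    V = np.empty(n_steps)
    RHO = np.empty(n_steps)
    FREQ = np.empty(n_steps)
    AMP = np.empty(n_steps)
    state = np.concatenate([x1, x2])
    for i in range(n_steps):
        X1[i], X2[i] = state[:3], state[3:]
        V[i] = model.level2_gain * state[3] + model.level2_offset
        RHO[i] = rayleigh_control(V[i], model.theta, model.level1)
        FREQ[i], AMP[i] = syrinx_output(state[:3], model.syrinx)
        flow, J = joint_flow_jacobian(state[:3], state[3:], model)
        state = _ll_step(state, flow, J, dt)
        if noise:
            state[:3] += noise_std[0] * np.sqrt(dt) * rng.standard_normal(3)
            state[3:] += noise_std[1] * np.sqrt(dt) * rng.standard_normal(3)
        if not np.all(np.isfinite(state)):
            raise SimulationError(f"integration blew up at t = {i * dt:.3f} s")

    sono = render_sonogram(
        t,
        FREQ,
        AMP,
        n_bins=n_bins,
        freq_lo=model.syrinx.freq_lo,
        freq_hi=model.syrinx.freq_hi,
    )
    traces = {"t": t, "x1": X1, "x2": X2, "v": V, "rho": RHO, "freq": FREQ, "amp": AMP}
    return traces, sono
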