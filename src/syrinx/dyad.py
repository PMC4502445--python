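"""Coupled songbird agents: turn taking, duets, omission and learning.

Two agents, each running the generalized filter on its own copy of the
hierarchical song model, exchange the syrinx control channels.  Turn
taking is implemented purely by a precision schedule: the listener has low
proprioceptive and high auditory precision (so its reflex arc is frozen
and it attends to the other bird), the singer the converse (so it enacts
its predictions while its own audition is attenuated).  Exactly one agent
sings at a time, in anti-phase epochs.

The acoustic channel is idealized: the listener receives the singer's
emitted control signals (the signals from which the sonogram is rendered)
without delay or filtering, as a local jet — the instantaneous value (the
singer's action, realized by its reflex arc) together with the temporal
derivatives of the singer's descending predictions.  Out of earshot the
listener receives ambient silence: zero-mean observation noise well below
its assumed sensory noise floor.

Learning, when enabled, accumulates free-energy gradients with respect to
the coupling parameter theta over each epoch and applies a Laplace belief
update at every epoch boundary, re-centring the prior (precision 64) on
the new posterior mean.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .gencoords import embed_sequence
from .inference import (
    DEFAULT_ACTION_GAIN,
    ActionState,
    GeneralizedFilter,
    ParameterAccumulator,
    ParameterBelief,
    birdsong_functions,
    update_parameter_belief,
)
from .songmodel import (
    HierarchicalModel,
    SimulationError,
    Sonogram,
    default_model,
    random_attractor_state,
    render_sonogram,
)

__all__ = [
    "Role",
    "PrecisionSchedule",
    "DyadConfig",
    "AgentTraces",
    "DyadTraces",
    "SongStimulus",
    "OmissionResult",
    "run_dyad",
    "run_soliloquy",
    "run_learning",
    "run_omission",
    "run_solo",
    "channels_to_sonogram",
]


class Role(Enum):
    SING = "sing"
    LISTEN = "listen"


@dataclass(frozen=True)
class PrecisionSchedule:
    """Per-role sensory log-precisions implementing turn taking.

    Listening: proprioception strongly attenuated (-8), audition attended
    (+2).  Singing: proprioception precise (0), audition attenuated (-2).
    The level-2 (cause) log-precision stays fixed in all roles.
    """

    epoch_duration: float = 2.0
    listen_prop: float = -8.0
    listen_aud: float = 2.0
    sing_prop: float = 0.0
    sing_aud: float = -2.0
    # ambient quiet is quieter than the listener's assumed sensory noise
    # floor (+2): were it at the assumed level, the filter would over-explain
    # the jitter through the descending coupling and theta would drift up
    # instead of decaying when only silence is heard
    ambient_log_precision: float = 6.0
    # attention does not switch instantaneously: log-precisions ramp
    # linearly over this many samples at each role change, so expectations
    # decay gracefully instead of being slammed to the new evidence (an
    # instantaneous switch injects a large artifactual burst of
    # parameter-evidence of systematic sign)
    switch_ramp: int = 8

    def log_precisions(
        self,
        role: Role,
        model: HierarchicalModel,
        blend: float = 1.0,
    ) -> dict[str, float]:
        """Role log-precisions; ``blend`` < 1 interpolates from the other role."""
        lp = dict(model.log_precisions)
        if role is Role.SING:
            new = (self.sing_prop, self.sing_aud)
            old = (self.listen_prop, self.listen_aud)
        else:
            new = (self.listen_prop, self.listen_aud)
            old = (self.sing_prop, self.sing_aud)
        lp["prop"] = blend * new[0] + (1.0 - blend) * old[0]
        lp["aud"] = blend * new[1] + (1.0 - blend) * old[1]
        return lp


@dataclass
class DyadConfig:
    """Configuration of a two-agent simulation."""

    model_a: HierarchicalModel = field(default_factory=default_model)
    model_b: HierarchicalModel = field(default_factory=default_model)
    audible: bool = True
    epochs: int = 4
    epoch_duration: float = 2.0
    learning: bool = False
    seed: int = 0
    dt: float = 1.0 / 64.0
    order: int = 6
    cause_order: int = 2
    prior_precision: float = 64.0
    action_gain: float = DEFAULT_ACTION_GAIN
    init_scale: float = 1.0
    # which agent opens the exchange, and optional explicit per-agent seeds
    # (default: substreams spawned from `seed`); both exist so that swapping
    # the agent labels swaps the traces exactly
    first_singer: int = 0
    agent_seeds: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("need at least one epoch")
        if self.epoch_duration <= 0:
            raise ValueError("epoch_duration must be positive")


@dataclass
class AgentTraces:
    """Per-agent expectation, error, action and belief trajectories."""

    mu_x1: np.ndarray  # (T, 3) order-0 fast-state expectations
    mu_x2: np.ndarray  # (T, 3) order-0 slow-state expectations
    mu_x1_d1: np.ndarray  # (T, 3) first-derivative rows (per-sample units)
    mu_x2_d1: np.ndarray
    mu_v: np.ndarray  # (T,) descending-control expectation
    free_energy: np.ndarray  # (T,)
    action: np.ndarray  # (T, 2)
    role: np.ndarray  # (T,) 1 when singing
    weighted_error: dict[str, np.ndarray]  # block -> (T,) rms of weighted errors
    theta_mean: np.ndarray  # (epochs + 1,)
    theta_post_precision: np.ndarray  # (epochs + 1,)


@dataclass
class DyadTraces:
    """Joint record of a dyad run."""

    t: np.ndarray
    dt: float
    epoch_duration: float
    epochs: int
    audible: bool
    agents: tuple[AgentTraces, AgentTraces]
    heard: np.ndarray  # (T, 2) the medium: active singer's emitted channels
    singer_index: np.ndarray  # (T,)
    model: HierarchicalModel  # agent A's model (for rendering)

    def heard_sonogram(self, n_bins: int = 64) -> Sonogram:
        """Continuous sonogram of the exchanged song (alternating singers)."""
        return channels_to_sonogram(self.t, self.heard, self.model, n_bins)

    def emitted_sonogram(
        self, agent: int, epoch: int, n_bins: int = 64
    ) -> Sonogram:
        """Sonogram emitted by ``agent`` during ``epoch`` (zeros if listening)."""
        spe = int(round(self.epoch_duration / self.dt))
        sl = slice(epoch * spe, (epoch + 1) * spe)
        tr = self.agents[agent]
        chan = np.where(
            tr.role[sl, None] == 1, self.agents[agent].action[sl], 0.0
        )
        return channels_to_sonogram(self.t[sl], chan, self.model, n_bins)


def channels_to_sonogram(
    t: np.ndarray, channels: np.ndarray, model: HierarchicalModel, n_bins: int = 64
) -> Sonogram:
    """Render (frequency-state, amplitude-state) channels through the syrinx."""
    sx = model.syrinx
    freq = np.clip(sx.freq_lo + sx.freq_gain * channels[:, 0], sx.freq_lo, sx.freq_hi)
    amp = np.maximum(sx.amp_gain * (np.abs(channels[:, 1]) - sx.silence_threshold), 0.0)
    return render_sonogram(t, freq, amp, n_bins, sx.freq_lo, sx.freq_hi)


# ---------------------------------------------------------------------------
# the coupled simulation
# ---------------------------------------------------------------------------


class _Agent:
    """One bird: filter, posterior, action, theta belief and accumulator."""

    def __init__(
        self, model: HierarchicalModel, config: DyadConfig, rng: np.random.Generator
    ) -> None:
        self.model = model
        self.funcs = birdsong_functions(model)
        self.filt = GeneralizedFilter(
            self.funcs,
            order=config.order,
            cause_order=config.cause_order,
            smoothness=model.smoothness,
            theta=model.theta,
            dt=config.dt,
        )
        self.post = self.filt.init_posterior(rng, scale=config.init_scale)
        # slow-level expectations start at a random phase of the slow
        # attractor (random narrative), jittered by the init noise: starting
        # all agents at the origin would leave them climbing the same
        # origin-escape transient and delay the divergence of their songs
        x2 = random_attractor_state(model.level2, rng, config.dt)
        self.post.mu_x2[0] += x2
        self.post.mu_v[0, 0] += model.level2_gain * x2[0] + model.level2_offset
        self.action = ActionState(a=self.post.mu_x1[0][[2, 1]].copy())
        self.belief = ParameterBelief(model.theta, config.prior_precision)
        self.acc = ParameterAccumulator()

    def emitted_jet(self) -> np.ndarray:
        """Generalized emitted signal: realized action + predicted derivatives."""
        jet = self.filt.predicted_output_jet(self.post)[:, :2].copy()
        jet[0] = self.action.a
        return jet


def run_dyad(config: DyadConfig) -> DyadTraces:
    """Integrate two coupled agents under the turn-taking schedule.

    Agent A sings the even epochs, agent B the odd ones.  The singer's
    auditory input is its own emitted signal; the listener's is the
    singer's signal when audible, ambient noise otherwise.  Bit
    reproducible for a given seed.
    """
    sched = PrecisionSchedule(epoch_duration=config.epoch_duration)
    ss = np.random.SeedSequence(config.seed)
    child_a, child_b, child_world = ss.spawn(3)
    if config.agent_seeds is not None:
        child_a, child_b = (np.random.SeedSequence(x) for x in config.agent_seeds)
    rng_world = np.random.default_rng(child_world)
    agents = [
        _Agent(config.model_a, config, np.random.default_rng(child_a)),
        _Agent(config.model_b, config, np.random.default_rng(child_b)),
    ]
    spe = int(round(config.epoch_duration / config.dt))
    T = spe * config.epochs
    t = np.arange(T) * config.dt
    n = config.order

    blocks = ("s", "v", "x1", "x2")
    rec = [
        AgentTraces(
            mu_x1=np.zeros((T, 3)),
            mu_x2=np.zeros((T, 3)),
            mu_x1_d1=np.zeros((T, 3)),
            mu_x2_d1=np.zeros((T, 3)),
            mu_v=np.zeros(T),
            free_energy=np.zeros(T),
            action=np.zeros((T, 2)),
            role=np.zeros(T, dtype=int),
            weighted_error={b: np.zeros(T) for b in blocks},
            theta_mean=np.zeros(config.epochs + 1),
            theta_post_precision=np.zeros(config.epochs + 1),
        )
        for _ in range(2)
    ]
    for i in (0, 1):
        rec[i].theta_mean[0] = agents[i].belief.mean
        rec[i].theta_post_precision[0] = agents[i].belief.precision
    heard = np.zeros((T, 2))
    singer_index = np.zeros(T, dtype=int)
    sigma_amb = np.exp(-sched.ambient_log_precision / 2.0)

    for step in range(T):
        epoch = step // spe
        singer = (epoch + config.first_singer) % 2
        singer_index[step] = singer
        emit = agents[singer].emitted_jet()
        heard[step] = emit[0]
        ambient = np.zeros((n + 1, 2))
        ambient[0] = sigma_amb * rng_world.standard_normal(2)

        instep = step - epoch * spe
        blend = 1.0 if epoch == 0 else min(1.0, (instep + 1) / max(sched.switch_ramp, 1))
        new_posts = []
        for i, ag in enumerate(agents):
            role = Role.SING if i == singer else Role.LISTEN
            lp = sched.log_precisions(role, ag.model, blend=blend)
            aud = emit if (i == singer or config.audible) else ambient
            prop = ag.emitted_jet() if i == singer else np.zeros((n + 1, 2))
            if i != singer:
                prop[0] = ag.action.a
            sens = np.concatenate([aud, prop], axis=1)
            errors = ag.filt.prediction_errors(ag.post, sens, lp)
            r = rec[i]
            r.mu_x1[step] = ag.post.mu_x1[0]
            r.mu_x2[step] = ag.post.mu_x2[0]
            r.mu_x1_d1[step] = ag.post.mu_x1[1]
            r.mu_x2_d1[step] = ag.post.mu_x2[1]
            r.mu_v[step] = ag.post.mu_v[0, 0]
            r.action[step] = ag.action.a
            r.role[step] = 1 if role is Role.SING else 0
            for b in blocks:
                r.weighted_error[b][step] = float(
                    np.sqrt(np.mean(errors.weighted[b] ** 2))
                )
            if config.learning:
                w = np.exp(lp["aud"] - sched.listen_aud)
                ag.acc.add(ag.filt, ag.post, errors, lp, weight=w)
            try:
                new_post = ag.filt.filter_step(ag.post, sens, lp, errors=errors)
            except SimulationError as exc:
                raise SimulationError(
                    f"agent {'ab'[i]} failed at t = {step * config.dt:.3f} s: {exc}"
                ) from exc
            r.free_energy[step] = new_post.free_energy
            ag.action = ag.filt.action_step(
                ag.post, errors, ag.action, lp, dt=1.0, gain=config.action_gain
            )
            new_posts.append(new_post)
        for ag, np_ in zip(agents, new_posts):
            ag.post = np_

        if (step + 1) % spe == 0:
            for i, ag in enumerate(agents):
                if config.learning:
                    g, c = ag.acc.finalize()
                    prior = ParameterBelief(ag.belief.mean, config.prior_precision)
                    ag.belief = update_parameter_belief(
                        prior, g, c, prior_precision=config.prior_precision
                    )
                    ag.belief.mean = max(ag.belief.mean, 0.0)
                    ag.filt.theta = ag.belief.mean
                    ag.acc = ParameterAccumulator()
                rec[i].theta_mean[epoch + 1] = ag.belief.mean
                rec[i].theta_post_precision[epoch + 1] = ag.belief.precision

    return DyadTraces(
        t=t,
        dt=config.dt,
        epoch_duration=config.epoch_duration,
        epochs=config.epochs,
        audible=config.audible,
        agents=(rec[0], rec[1]),
        heard=heard,
        singer_index=singer_index,
        model=config.model_a,
    )


def run_soliloquy(config: DyadConfig | None = None, **kwargs) -> DyadTraces:
    """Two birds out of earshot: same schedule, no acoustic coupling."""
    from dataclasses import replace

    config = config or DyadConfig(**kwargs)
    return run_dyad(replace(config, audible=False, learning=False))


def run_learning(
    theta_a: float = 0.5,
    theta_b: float = 1.0,
    epochs: int = 32,
    epoch_duration: float = 1.0,
    audible: bool = True,
    seed: int = 0,
    **kwargs,
) -> DyadTraces:
    """The perceptual-learning experiment: unequal coupling parameters.

    Bird A starts with theta = 0.5 (impoverished prosody), bird B with
    theta = 1; beliefs are updated at every epoch boundary over ``epochs``
    one-second exchanges.
    """
    if epochs < 2:
        raise ValueError("learning needs at least two epochs")
    config = DyadConfig(
        model_a=default_model(theta_a),
        model_b=default_model(theta_b),
        audible=audible,
        epochs=epochs,
        epoch_duration=epoch_duration,
        learning=True,
        seed=seed,
        **kwargs,
    )
    return run_dyad(config)


# ---------------------------------------------------------------------------
# single-agent runs: self-song and omission
# ---------------------------------------------------------------------------


def run_solo(
    model: HierarchicalModel,
    duration: float = 1.0,
    seed: int = 0,
    dt: float = 1.0 / 64.0,
    order: int = 6,
    cause_order: int = 2,
    action_gain: float = DEFAULT_ACTION_GAIN,
    init_scale: float = 1.0,
    x2_init: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """One bird singing to itself (SING precisions throughout).

    Returns expectation, action and free-energy traces; the basis of the
    bifurcation diagram.
    """
    config = DyadConfig(
        model_a=model, model_b=model, dt=dt, order=order, cause_order=cause_order
    )
    sched = PrecisionSchedule()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    ag = _Agent(model, config, rng)
    if x2_init is not None:
        ag.post.mu_x2[0] = np.asarray(x2_init, dtype=float)
    lp = sched.log_precisions(Role.SING, model)
    T = int(round(duration / dt))
    out = {
        "t": np.arange(T) * dt,
        "mu_x1": np.zeros((T, 3)),
        "mu_x2": np.zeros((T, 3)),
        "action": np.zeros((T, 2)),
        "free_energy": np.zeros(T),
    }
    for step in range(T):
        emit = ag.emitted_jet()
        sens = np.concatenate([emit, emit], axis=1)
        errors = ag.filt.prediction_errors(ag.post, sens, lp)
        out["mu_x1"][step] = ag.post.mu_x1[0]
        out["mu_x2"][step] = ag.post.mu_x2[0]
        out["action"][step] = ag.action.a
        new_post = ag.filt.filter_step(ag.post, sens, lp, errors=errors)
        out["free_energy"][step] = new_post.free_energy
        ag.action = ag.filt.action_step(
            ag.post, errors, ag.action, lp, dt=1.0, gain=action_gain
        )
        ag.post = new_post
    return out


@dataclass
class SongStimulus:
    """A canned song: control channels, rendered sonogram and chirp onsets."""

    t: np.ndarray
    channels: np.ndarray  # (T, 2): frequency-state, amplitude-state
    sonogram: Sonogram
    chirp_onsets: np.ndarray
    chirp_offsets: np.ndarray

    @property
    def n_chirps(self) -> int:
        return len(self.chirp_onsets)


@dataclass
class OmissionResult:
    """Percept and prediction-error traces for one listening run."""

    t: np.ndarray
    stimulus: Sonogram
    percept: Sonogram
    mu_x1: np.ndarray
    mu_x2: np.ndarray
    weighted_error: dict[str, np.ndarray]
    truncate_time: float | None


def run_omission(
    model: HierarchicalModel,
    stimulus: SongStimulus,
    truncate_after: int | None = None,
    seed: int = 0,
    dt: float = 1.0 / 64.0,
    order: int = 6,
    cause_order: int = 2,
    freq_log_precision: float = 2.0,
    amp_log_precision: float = -1.0,
) -> OmissionResult:
    """Play a (possibly truncated) song to a purely listening agent.

    ``truncate_after`` (1-based chirp index) silences the stimulus after
    that chirp's offset — the omission paradigm.  The percept is the
    agent's predicted sonogram; precision-weighted errors are recorded per
    block (key ``"aud"`` holds the auditory-channel rms).

    The listening bird resolves the two auditory dimensions with different
    precision: frequency finely (log-precision +2, which keeps the percept
    locked to the stimulus) and loudness coarsely (-1).  The coarse
    loudness channel is what lets the dynamical prior transiently override
    silence when an expected chirp fails to occur — the omission response
    and its anomalous percept.  The stimulus is embedded into generalized
    coordinates with a centered window, so evidence of the truncation
    reaches the filter about half an embedding window before the nominal
    cut time.
    """
    from dataclasses import replace as _replace

    if truncate_after is not None:
        if truncate_after < 1 or truncate_after >= stimulus.n_chirps:
            raise ValueError(
                f"truncate_after must be in [1, {stimulus.n_chirps - 1}], "
                f"got {truncate_after}"
            )
    sched = PrecisionSchedule()
    lp = dict(model.log_precisions)
    lp.pop("aud", None)
    lp.update(
        {
            "prop": sched.listen_prop,
            "aud_f": freq_log_precision,
            "aud_a": amp_log_precision,
        }
    )
    sigma_amb = np.exp(-sched.ambient_log_precision / 2.0)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    chan_played = stimulus.channels.copy()
    cut_time = None
    if truncate_after is not None:
        cut_time = float(stimulus.chirp_offsets[truncate_after - 1])
        chan_played[stimulus.t > cut_time] = 0.0
    chan = chan_played + sigma_amb * rng.standard_normal(chan_played.shape)
    # embed the sampled stimulus into generalized coordinates (per-sample units)
    jets = embed_sequence(chan, order, dt=1.0)

    funcs = _replace(
        birdsong_functions(model),
        channel_groups=("aud_f", "aud_a", "prop", "prop"),
    )
    filt = GeneralizedFilter(
        funcs,
        order=order,
        cause_order=cause_order,
        smoothness=model.smoothness,
        theta=model.theta,
        dt=dt,
    )
    post = filt.init_posterior(rng)
    x2 = random_attractor_state(model.level2, rng, dt)
    post.mu_x2[0] += x2
    post.mu_v[0, 0] += model.level2_gain * x2[0] + model.level2_offset

    T = len(stimulus.t)
    out_mu1 = np.zeros((T, 3))
    out_mu2 = np.zeros((T, 3))
    werr = {b: np.zeros(T) for b in ("s", "v", "x1", "x2", "aud")}
    for step in range(T):
        sens = np.concatenate([jets[step], np.zeros((order + 1, 2))], axis=1)
        errors = filt.prediction_errors(post, sens, lp)
        out_mu1[step] = post.mu_x1[0]
        out_mu2[step] = post.mu_x2[0]
        for b in ("s", "v", "x1", "x2"):
            werr[b][step] = float(np.sqrt(np.mean(errors.weighted[b] ** 2)))
        aud_rows = errors.weighted["s"].reshape(order + 1, 4)[:, :2]
        werr["aud"][step] = float(np.sqrt(np.mean(aud_rows**2)))
        post = filt.filter_step(post, sens, lp, errors=errors)

    percept = channels_to_sonogram(stimulus.t, out_mu1[:, [2, 1]], model)
    return OmissionResult(
        t=stimulus.t,
        stimulus=channels_to_sonogram(stimulus.t, chan_played, model),
        percept=percept,
        mu_x1=out_mu1,
        mu_x2=out_mu2,
        weighted_error=werr,
        truncate_time=cut_time,
    )
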