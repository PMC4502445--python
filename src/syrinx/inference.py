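"""Predictive-coding engine: generalized filtering, action and learning.

The agent carries posterior expectations over hidden states and causes in
generalized coordinates of motion and updates them by a gradient flow on
variational free energy,

    mu_dot = D mu - dF/dmu,      F = 1/2 sum_b (eps_b' Pi_b eps_b - log|Pi_b|)

where D is the shift operator, eps are generalized prediction errors
(sensory, cause, and dynamical, per level) and Pi are their precisions:
exp(log-precision) per channel, structured over derivative orders by the
inverse of the smoothness covariance of the assumed fluctuations.  Each
step is integrated by local linearization (matrix exponential of the
flow's Jacobian), which is stable on the chaotic song model.

Action is the fulfilment of proprioceptive predictions: the action
variables enter sensation directly, and a classical-reflex loop descends
the same free energy, da/dt = -kappa (ds/da)' Pi eps.  Because sensation
equals action on the proprioceptive channels this loop is linear in a and
is integrated exactly.

Parameters (here the scalar inter-level coupling theta) do not change in
time, so their prediction errors are accumulated over an epoch and the
Gaussian (Laplace) belief is updated once at the epoch boundary — the slow
timescale of learning.

The engine is generic over a :class:`GenerativeFunctions` bundle; the
birdsong hierarchy is provided by :func:`birdsong_functions`, and tests
exercise the same engine on linear models where a Kalman-Bucy filter is an
independent oracle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np
from scipy.linalg import expm

from . import songmodel
from .gencoords import SmoothnessSpec, smoothness_precision
from .songmodel import HierarchicalModel

__all__ = [
    "GenerativeFunctions",
    "birdsong_functions",
    "linear_functions",
    "PosteriorState",
    "ErrorSet",
    "ParameterBelief",
    "ActionState",
    "GeneralizedFilter",
    "ParameterAccumulator",
    "update_parameter_belief",
    "DEFAULT_ACTION_GAIN",
]

DEFAULT_ACTION_GAIN = 0.25  # reflex rate per sample per unit precision (~30 ms lag)


# ---------------------------------------------------------------------------
# generative-model function bundles
# ---------------------------------------------------------------------------


@dataclass
class GenerativeFunctions:
    """Flows, output maps and their derivatives for a (<=2)-level model.

    Level 1 has hidden states x1 (dim ``nx1``) with flow ``f1(x1, v, theta)``
    and a linear output map ``C1`` onto ``ny`` sensory channels.  Level 2
    (optional: ``nx2 = 0`` disables it) has autonomous flow ``f2(x2)`` and a
    linear-plus-offset output map generating the cause v.  ``channel_groups``
    names the log-precision group of each sensory channel; ``prop_channels``
    lists the channels that sense the agent's own action.
    """

    nx1: int
    nx2: int
    nv: int
    ny: int
    C1: np.ndarray
    f1: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    f1_jac_x: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    f1_jac_v: Callable[[np.ndarray, np.ndarray, float], np.ndarray]
    channel_groups: tuple[str, ...]
    prop_channels: tuple[int, ...] = ()
    # derivative of (Jx xi + Jv nu) w.r.t. (x1, v): exact gradients need the
    # flow's second derivatives (constant tensors for the Lorenz flows)
    f1_hess: Callable[..., np.ndarray] | None = None
    f1_dtheta: Callable[[np.ndarray, np.ndarray], np.ndarray] | None = None
    f1_jac_dtheta: Callable[..., np.ndarray] | None = None
    f2: Callable[[np.ndarray], np.ndarray] | None = None
    f2_jac: Callable[[np.ndarray], np.ndarray] | None = None
    f2_hess: Callable[..., np.ndarray] | None = None
    G2: np.ndarray | None = None
    g2_offset: np.ndarray | None = None
    # d/d(x1_0, v_0, x1_k, v_k) of the k-th row of d f1-tilde/d theta; used
    # for the mean-field contribution to parameter learning
    f1_dtheta_hess: Callable[..., tuple] | None = None


def birdsong_functions(model: HierarchicalModel) -> GenerativeFunctions:
    """Engine bundle for the two-level Lorenz song hierarchy.

    Sensory channels are (auditory frequency-state, auditory amplitude-state,
    proprioceptive frequency-state, proprioceptive amplitude-state): the same
    two fast states are predicted exteroceptively and proprioceptively, so the
    expectations themselves are amodal.
    """
    p1, p2 = model.level1, model.level2
    fi, ai = model.syrinx.freq_state_index, model.syrinx.amp_state_index
    C1 = np.zeros((4, 3))
    C1[0, fi] = C1[2, fi] = 1.0
    C1[1, ai] = C1[3, ai] = 1.0

    def f1(x, v, theta):
        rho = songmodel.rayleigh_control(float(v[0]), theta, p1)
        return songmodel.lorenz_flow(x, p1, rho)

    def f1_jac_x(x, v, theta):
        rho = songmodel.rayleigh_control(float(v[0]), theta, p1)
        return songmodel.lorenz_jacobian(x, p1, rho)

    def f1_jac_v(x, v, theta):
        J = np.zeros((3, 1))
        J[1, 0] = theta * x[0] * songmodel.sat_control_d1(float(v[0])) / p1.tau
        return J

    def f1_hess(x, v, theta, xi, nu):
        # d(Jx xi + Jv nu)/d(x, v);  columns: x1, x2, x3, v
        s1 = songmodel.sat_control_d1(float(v[0]))
        s2 = songmodel.sat_control_d2(float(v[0]))
        H = np.zeros((3, 4))
        H[1, 0] = (-xi[2] + theta * s1 * nu[0]) / p1.tau
        H[1, 2] = -xi[0] / p1.tau
        H[1, 3] = theta * (s1 * xi[0] + x[0] * s2 * nu[0]) / p1.tau
        H[2, 0] = xi[1] / p1.tau
        H[2, 1] = xi[0] / p1.tau
        return H

    def f1_dtheta(x, v):
        return np.array(
            [0.0, x[0] * songmodel.sat_control(float(v[0])) / p1.tau, 0.0]
        )

    def f1_jac_dtheta(x, v, xi, nu):
        s0 = songmodel.sat_control(float(v[0]))
        s1 = songmodel.sat_control_d1(float(v[0]))
        return np.array([0.0, (s0 * xi[0] + x[0] * s1 * nu[0]) / p1.tau, 0.0])

    def f1_dtheta_hess(x, v, xi, nu, order0):
        """Partials of row k of d f1-tilde/d theta (the y-equation entry).

        Returns (d/dx1_0, d/dv_0, d/dxi_0, d/dnu) of that entry; for the
        order-0 row (order0=True) xi/nu do not apply.
        """
        v0 = float(v[0])
        s0 = songmodel.sat_control(v0)
        s1 = songmodel.sat_control_d1(v0)
        s2 = songmodel.sat_control_d2(v0)
        if order0:
            return (s0 / p1.tau, x[0] * s1 / p1.tau, 0.0, 0.0)
        return (
            s1 * nu[0] / p1.tau,
            (s1 * xi[0] + x[0] * s2 * nu[0]) / p1.tau,
            s0 / p1.tau,
            x[0] * s1 / p1.tau,
        )

    def f2(x):
        return songmodel.lorenz_flow(x, p2, p2.rayleigh_base)

    def f2_jac(x):
        return songmodel.lorenz_jacobian(x, p2, p2.rayleigh_base)

    def f2_hess(x, xi):
        H = np.zeros((3, 3))
        H[1, 0] = -xi[2] / p2.tau
        H[1, 2] = -xi[0] / p2.tau
        H[2, 0] = xi[1] / p2.tau
        H[2, 1] = xi[0] / p2.tau
        return H

    G2 = np.array([[model.level2_gain, 0.0, 0.0]])
    return GenerativeFunctions(
        nx1=3,
        nx2=3,
        nv=1,
        ny=4,
        C1=C1,
        f1=f1,
        f1_jac_x=f1_jac_x,
        f1_jac_v=f1_jac_v,
        channel_groups=("aud", "aud", "prop", "prop"),
        prop_channels=(2, 3),
        f1_hess=f1_hess,
        f1_dtheta=f1_dtheta,
        f1_jac_dtheta=f1_jac_dtheta,
        f1_dtheta_hess=f1_dtheta_hess,
        f2=f2,
        f2_jac=f2_jac,
        f2_hess=f2_hess,
        G2=G2,
        g2_offset=np.array([model.level2_offset]),
    )


def linear_functions(
    A: np.ndarray,
    C: np.ndarray,
    group: str = "y",
) -> GenerativeFunctions:
    """One-level linear model dx = A x dt, y = C x (Kalman-oracle fixture)."""
    A = np.asarray(A, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    nx, ny = A.shape[0], C.shape[0]
    zero_v = np.zeros((nx, 0))
    return GenerativeFunctions(
        nx1=nx,
        nx2=0,
        nv=0,
        ny=ny,
        C1=C,
        f1=lambda x, v, theta: A @ x,
        f1_jac_x=lambda x, v, theta: A,
        f1_jac_v=lambda x, v, theta: zero_v,
        channel_groups=(group,) * ny,
    )


# ---------------------------------------------------------------------------
# posterior, errors, beliefs
# ---------------------------------------------------------------------------


@dataclass
class PosteriorState:
    """Expectations over generalized hidden states and causes, per level."""

    mu_x1: np.ndarray  # (n+1, nx1)
    mu_x2: np.ndarray  # (n+1, nx2)
    mu_v: np.ndarray  # (d+1, nv)
    free_energy: float = np.nan

    def copy(self) -> "PosteriorState":
        return PosteriorState(
            self.mu_x1.copy(), self.mu_x2.copy(), self.mu_v.copy(), self.free_energy
        )


@dataclass
class ErrorSet:
    """Generalized prediction errors and their precision-weighted versions.

    ``eps['s']`` is sensation minus predicted output (one block per sensory
    channel), ``eps['v']`` the level-2 cause error, ``eps['x1']/['x2']`` the
    dynamical errors D mu - f(mu).  ``weighted[b] = Pi_b eps_b`` (flattened).
    """

    eps: dict[str, np.ndarray]
    weighted: dict[str, np.ndarray]


@dataclass
class ParameterBelief:
    """Gaussian (Laplace) belief over the coupling parameter theta."""

    mean: float
    precision: float

    def __post_init__(self) -> None:
        if self.precision <= 0:
            raise ValueError("belief precision must be positive")


@dataclass
class ActionState:
    """Action variables slaved to proprioceptive predictions."""

    a: np.ndarray
    da_dt: np.ndarray = field(default_factory=lambda: np.zeros(2))


def update_parameter_belief(
    belief: ParameterBelief,
    gradient: float,
    curvature: float,
    prior_precision: float = 64.0,
) -> ParameterBelief:
    """Laplace update of the theta belief at an epoch boundary.

    The posterior precision adds the epoch's accumulated curvature to the
    prior precision; the mean takes a Newton step down the accumulated
    free-energy gradient.  The returned belief becomes the next epoch's
    prior mean (its precision is reset to ``prior_precision`` by the caller
    at the next boundary — priors are re-centred, not sharpened).
    """
    post_precision = prior_precision + curvature
    if post_precision <= 0:
        raise FloatingPointError("non-positive posterior precision for theta")
    mean = belief.mean - gradient / post_precision
    return ParameterBelief(mean=mean, precision=post_precision)


# ---------------------------------------------------------------------------
# the generalized filter
# ---------------------------------------------------------------------------


class GeneralizedFilter:
    """Free-energy filtering for one agent's generative model.

    Parameters
    ----------
    funcs : GenerativeFunctions
    order : embedding order n for hidden states and sensations
    cause_order : embedding order d for causes
    smoothness : assumed roughness of random fluctuations
    theta : current value of the learned coupling parameter
    """

    def __init__(
        self,
        funcs: GenerativeFunctions,
        order: int = 6,
        cause_order: int = 2,
        smoothness: SmoothnessSpec | None = None,
        theta: float = 0.0,
        dt: float = 1.0 / 64.0,
    ) -> None:
        self.funcs = funcs
        self.n = order
        self.d = min(cause_order, order)
        # Internal time is measured in samples: flows are scaled by dt so a
        # filter step advances one unit.  This keeps generalized derivatives
        # of the fast chaotic flow O(1) per order instead of O((1/dt)^k).
        self.dt = dt
        self.max_step = 100.0  # trust region on the per-sample update norm
        gamma = (smoothness or SmoothnessSpec()).gamma
        self.Sinv_n = smoothness_precision(SmoothnessSpec(gamma=gamma, order=self.n))
        self.Sinv_d = smoothness_precision(SmoothnessSpec(gamma=gamma, order=self.d))
        self.theta = theta
        f = funcs
        self._sizes = {
            "s": (self.n + 1) * f.ny,
            "v": (self.d + 1) * f.nv,
            "x1": (self.n + 1) * f.nx1,
            "x2": (self.n + 1) * f.nx2,
        }
        self._mu_sizes = {
            "x1": (self.n + 1) * f.nx1,
            "x2": (self.n + 1) * f.nx2,
            "v": (self.d + 1) * f.nv,
        }
        self._prec_cache: dict[tuple, dict] = {}
        # shift operator on the flattened posterior
        blocks = []
        for name, dim, order_b in (
            ("x1", f.nx1, self.n),
            ("x2", f.nx2, self.n),
            ("v", f.nv, self.d),
        ):
            if dim:
                blocks.append(np.kron(np.eye(order_b + 1, k=1), np.eye(dim)))
        from scipy.linalg import block_diag

        self._D = block_diag(*blocks) if blocks else np.zeros((0, 0))

    # -- posterior plumbing -------------------------------------------------

    def init_posterior(
        self, rng: np.random.Generator | None = None, scale: float = 1.0
    ) -> PosteriorState:
        """Random (or zero) initial expectations: N(0, scale^2) on order 0."""
        f = self.funcs
        mu_x1 = np.zeros((self.n + 1, f.nx1))
        mu_x2 = np.zeros((self.n + 1, f.nx2))
        mu_v = np.zeros((self.d + 1, f.nv))
        if rng is not None:
            mu_x1[0] = scale * rng.standard_normal(f.nx1)
            if f.nx2:
                mu_x2[0] = scale * rng.standard_normal(f.nx2)
            if f.nv:
                mu_v[0] = scale * rng.standard_normal(f.nv)
        return PosteriorState(mu_x1, mu_x2, mu_v)

    def flatten(self, post: PosteriorState) -> np.ndarray:
        return np.concatenate(
            [post.mu_x1.ravel(), post.mu_x2.ravel(), post.mu_v.ravel()]
        )

    def unflatten(self, mu: np.ndarray, free_energy: float = np.nan) -> PosteriorState:
        f = self.funcs
        i1 = self._mu_sizes["x1"]
        i2 = i1 + self._mu_sizes["x2"]
        return PosteriorState(
            mu[:i1].reshape(self.n + 1, f.nx1),
            mu[i1:i2].reshape(self.n + 1, f.nx2),
            mu[i2:].reshape(self.d + 1, f.nv),
            free_energy,
        )

    # -- precisions ---------------------------------------------------------

    def precisions(self, log_prec: dict[str, float]) -> dict:
        """Per-block precision matrices Pi_b = Sinv (x) exp(omega) and log-dets."""
        f = self.funcs
        key = tuple(sorted(log_prec.items()))
        if key in self._prec_cache:
            return self._prec_cache[key]
        chan = np.array([np.exp(log_prec[g]) for g in f.channel_groups])
        out = {
            "Pi": {
                "s": np.kron(self.Sinv_n, np.diag(chan)),
                "v": np.kron(self.Sinv_d, np.exp(log_prec.get("v", 0.0)) * np.eye(f.nv))
                if f.nv
                else np.zeros((0, 0)),
                "x1": np.kron(self.Sinv_n, np.exp(log_prec["x1"]) * np.eye(f.nx1)),
                "x2": np.kron(self.Sinv_n, np.exp(log_prec.get("x2", 0.0)) * np.eye(f.nx2))
                if f.nx2
                else np.zeros((0, 0)),
            }
        }
        logdet = 0.0
        for P in out["Pi"].values():
            if P.size:
                sign, ld = np.linalg.slogdet(P)
                logdet += ld
        out["logdet"] = logdet
        self._prec_cache[key] = out
        return out

    # -- errors and free energy --------------------------------------------

    def generalized_flows(self, post: PosteriorState) -> tuple[np.ndarray, np.ndarray]:
        """f-tilde for both levels: row 0 = flow, rows k>=1 linearized."""
        f = self.funcs
        x0, v0 = post.mu_x1[0], post.mu_v[0] if f.nv else np.zeros(0)
        J1x = self.dt * f.f1_jac_x(x0, v0, self.theta)
        J1v = self.dt * f.f1_jac_v(x0, v0, self.theta)
        f1t = np.zeros_like(post.mu_x1)
        f1t[0] = self.dt * f.f1(x0, v0, self.theta)
        for k in range(1, self.n + 1):
            f1t[k] = J1x @ post.mu_x1[k]
            if f.nv and k <= self.d:
                f1t[k] += J1v @ post.mu_v[k]
        if f.nx2:
            y0 = post.mu_x2[0]
            J2 = self.dt * f.f2_jac(y0)
            f2t = np.zeros_like(post.mu_x2)
            f2t[0] = self.dt * f.f2(y0)
            for k in range(1, self.n + 1):
                f2t[k] = J2 @ post.mu_x2[k]
        else:
            f2t = np.zeros((self.n + 1, 0))
        return f1t, f2t

    def prediction_errors(
        self,
        post: PosteriorState,
        sensation: np.ndarray,
        log_prec: dict[str, float],
    ) -> ErrorSet:
        """Generalized sensory, cause and dynamical prediction errors.

        ``sensation`` is the generalized sensory input: shape (n+1, ny) (a
        plain (ny,) vector is promoted with zero derivatives).
        """
        f = self.funcs
        s = np.asarray(sensation, dtype=float)
        if s.ndim == 1:
            s_full = np.zeros((self.n + 1, f.ny))
            s_full[0] = s
            s = s_full
        if s.shape != (self.n + 1, f.ny):
            raise ValueError(
                f"sensation shape {s.shape} does not conform to "
                f"({self.n + 1}, {f.ny})"
            )
        eps: dict[str, np.ndarray] = {}
        eps["s"] = s - post.mu_x1 @ f.C1.T
        if f.nv:
            pred_v = post.mu_x2[: self.d + 1] @ f.G2.T
            pred_v[0] += f.g2_offset
            eps["v"] = post.mu_v - pred_v
        else:
            eps["v"] = np.zeros((self.d + 1, 0))
        f1t, f2t = self.generalized_flows(post)
        from .gencoords import shift

        eps["x1"] = shift(post.mu_x1) - f1t
        eps["x2"] = shift(post.mu_x2) - f2t if f.nx2 else np.zeros((self.n + 1, 0))
        Pi = self.precisions(log_prec)["Pi"]
        weighted = {b: Pi[b] @ eps[b].ravel() for b in eps}
        return ErrorSet(eps=eps, weighted=weighted)

    def free_energy(self, errors: ErrorSet, log_prec: dict[str, float]) -> float:
        """F = 1/2 sum_b eps_b' Pi_b eps_b - 1/2 log|Pi| (+ constants)."""
        quad = sum(
            float(errors.eps[b].ravel() @ errors.weighted[b]) for b in errors.eps
        )
        return 0.5 * (quad - self.precisions(log_prec)["logdet"])

    # -- error Jacobian -----------------------------------------------------

    def error_jacobian(self, post: PosteriorState) -> np.ndarray:
        """Exact d eps_flat / d mu_flat (includes flow second derivatives)."""
        f = self.funcs
        n, d = self.n, self.d
        sz = self._sizes
        msz = self._mu_sizes
        off_e = {
            "s": 0,
            "v": sz["s"],
            "x1": sz["s"] + sz["v"],
            "x2": sz["s"] + sz["v"] + sz["x1"],
        }
        off_m = {"x1": 0, "x2": msz["x1"], "v": msz["x1"] + msz["x2"]}
        E = np.zeros((sum(sz.values()), sum(msz.values())))

        def blk(err, k_e, mu, k_m):
            r = off_e[err] + k_e * {"s": f.ny, "v": f.nv, "x1": f.nx1, "x2": f.nx2}[err]
            c = off_m[mu] + k_m * {"x1": f.nx1, "x2": f.nx2, "v": f.nv}[mu]
            return r, c

        def add(err, k_e, mu, k_m, mat):
            r, c = blk(err, k_e, mu, k_m)
            E[r : r + mat.shape[0], c : c + mat.shape[1]] += mat

        x0 = post.mu_x1[0]
        v0 = post.mu_v[0] if f.nv else np.zeros(0)
        # sensory errors: -C1 per order
        for k in range(n + 1):
            add("s", k, "x1", k, -f.C1)
        # cause errors
        if f.nv:
            for k in range(d + 1):
                add("v", k, "v", k, np.eye(f.nv))
                add("v", k, "x2", k, -f.G2)
        # level-1 dynamical errors
        J1x = self.dt * f.f1_jac_x(x0, v0, self.theta)
        J1v = self.dt * f.f1_jac_v(x0, v0, self.theta)
        for k in range(n + 1):
            if k < n:
                add("x1", k, "x1", k + 1, np.eye(f.nx1))
            add("x1", k, "x1", k, -J1x)
            if f.nv and k <= d:
                add("x1", k, "v", k, -J1v)
            if k >= 1 and f.f1_hess is not None:
                nu = post.mu_v[k] if (f.nv and k <= d) else np.zeros(max(f.nv, 1))
                H = self.dt * f.f1_hess(x0, v0, self.theta, post.mu_x1[k], nu)
                add("x1", k, "x1", 0, -H[:, : f.nx1])
                if f.nv:
                    add("x1", k, "v", 0, -H[:, f.nx1 :])
        # level-2 dynamical errors
        if f.nx2:
            y0 = post.mu_x2[0]
            J2 = self.dt * f.f2_jac(y0)
            for k in range(n + 1):
                if k < n:
                    add("x2", k, "x2", k + 1, np.eye(f.nx2))
                add("x2", k, "x2", k, -J2)
                if k >= 1 and f.f2_hess is not None:
                    add("x2", k, "x2", 0, -self.dt * f.f2_hess(y0, post.mu_x2[k]))
        return E

    def free_energy_gradient(
        self, post: PosteriorState, errors: ErrorSet, log_prec: dict[str, float]
    ) -> np.ndarray:
        """Exact dF/dmu (flattened)."""
        E = self.error_jacobian(post)
        w = np.concatenate([errors.weighted[b] for b in ("s", "v", "x1", "x2")])
        return E.T @ w

    # -- filtering ----------------------------------------------------------

    def filter_step(
        self,
        post: PosteriorState,
        sensation: np.ndarray,
        log_prec: dict[str, float],
        dt: float = 1.0,
        errors: ErrorSet | None = None,
    ) -> PosteriorState:
        """One local-linearization update of mu_dot = D mu - dF/dmu.

        ``dt`` is in internal (sample) units: 1.0 advances one sample.  With
        zero errors the update reduces to the pure temporal translation D mu
        (prediction); prediction errors bend the trajectory toward the
        free-energy minimum.
        """
        if dt <= 0:
            raise ValueError("dt must be positive")
        if errors is None:
            errors = self.prediction_errors(post, sensation, log_prec)
        E = self.error_jacobian(post)
        Pi = self.precisions(log_prec)["Pi"]
        w = np.concatenate([errors.weighted[b] for b in ("s", "v", "x1", "x2")])
        mu = self.flatten(post)
        mu_dot = self._D @ mu - E.T @ w
        # Gauss-Newton curvature of F
        PiE = np.concatenate(
            [Pi[b] @ E[self._block_rows(b)] for b in ("s", "v", "x1", "x2")]
        )
        J = self._D - E.T @ PiE
        if not np.all(np.isfinite(J)):
            raise songmodel.SimulationError("non-finite Jacobian in filter step")
        # Joint local linearization with the sensory jet advancing under its
        # own shift operator: in the error-free case the update is then the
        # exact temporal translation of the expectations.
        f = self.funcs
        ns = (self.n + 1) * f.ny
        m = mu.size
        s_flat = np.asarray(sensation, dtype=float).reshape(self.n + 1, f.ny).ravel()
        Ds = np.kron(np.eye(self.n + 1, k=1), np.eye(f.ny))
        dmu_ds = E[self._block_rows("s")].T @ Pi["s"]  # = -d(mu_dot)/d(s)
        aug = np.zeros((ns + m + 1, ns + m + 1))
        aug[:ns, :ns] = Ds * dt
        aug[ns : ns + m, :ns] = -dmu_ds * dt
        aug[ns : ns + m, ns : ns + m] = J * dt
        aug[:ns, -1] = (Ds @ s_flat) * dt
        aug[ns : ns + m, -1] = mu_dot * dt
        delta = expm(aug)[ns : ns + m, -1]
        # trust region: never binds in healthy runs, prevents runaway steps
        step_norm = np.linalg.norm(delta)
        if step_norm > self.max_step:
            delta *= self.max_step / step_norm
        mu_new = mu + delta
        if not np.all(np.isfinite(mu_new)):
            raise songmodel.SimulationError("filter update produced non-finite state")
        new = self.unflatten(mu_new)
        new.free_energy = self.free_energy(errors, log_prec)
        return new

    def _block_rows(self, b: str) -> slice:
        order = ("s", "v", "x1", "x2")
        start = sum(self._sizes[x] for x in order[: order.index(b)])
        return slice(start, start + self._sizes[b])

    def consistent_posterior(
        self, x1: np.ndarray, x2: np.ndarray
    ) -> PosteriorState:
        """Self-consistent generalized expectations at a hierarchy point.

        Jets follow the filter's own generalized flow (linearized recursion,
        causes truncated at order d), so every dynamical and cause error
        vanishes identically — the noiseless 'clamped states' construction
        used for teacher-student parameter recovery.
        """
        f = self.funcs
        mu_x2 = np.zeros((self.n + 1, f.nx2))
        mu_v = np.zeros((self.d + 1, f.nv))
        if f.nx2:
            mu_x2[0] = np.asarray(x2, dtype=float)
            mu_x2[1] = self.dt * f.f2(mu_x2[0])
            J2 = self.dt * f.f2_jac(mu_x2[0])
            for k in range(1, self.n):
                mu_x2[k + 1] = J2 @ mu_x2[k]
            mu_v[: self.d + 1] = mu_x2[: self.d + 1] @ f.G2.T
            mu_v[0] += f.g2_offset
        mu_x1 = np.zeros((self.n + 1, f.nx1))
        mu_x1[0] = np.asarray(x1, dtype=float)
        v0 = mu_v[0] if f.nv else np.zeros(0)
        mu_x1[1] = self.dt * f.f1(mu_x1[0], v0, self.theta)
        J1x = self.dt * f.f1_jac_x(mu_x1[0], v0, self.theta)
        J1v = self.dt * f.f1_jac_v(mu_x1[0], v0, self.theta)
        for k in range(1, self.n):
            mu_x1[k + 1] = J1x @ mu_x1[k]
            if f.nv and k <= self.d:
                mu_x1[k + 1] += J1v @ mu_v[k]
        return PosteriorState(mu_x1, mu_x2, mu_v)

    # -- action -------------------------------------------------------------

    def predicted_output_jet(self, post: PosteriorState) -> np.ndarray:
        """Generalized predicted sensory output g1(mu) (n+1, ny)."""
        return post.mu_x1 @ self.funcs.C1.T

    def action_step(
        self,
        post: PosteriorState,
        errors: ErrorSet,
        action: ActionState,
        log_prec: dict[str, float],
        dt: float,
        gain: float = DEFAULT_ACTION_GAIN,
    ) -> ActionState:
        """Reflex-arc action update da/dt = -gain (ds/da)' Pi_s eps_s.

        Action enters sensation only on the proprioceptive channels (order
        0), so the loop is linear in a and is integrated exactly over dt.
        Listening (strongly attenuated proprioceptive precision) freezes the
        action; singing slaves it to the descending predictions.
        """
        f = self.funcs
        if not f.prop_channels:
            return action
        Pi_s = self.precisions(log_prec)["Pi"]["s"]
        na = len(f.prop_channels)
        M = np.zeros(((self.n + 1) * f.ny, na))
        for j, ch in enumerate(f.prop_channels):
            M[ch, j] = 1.0  # order-0 rows only
        grad = gain * (M.T @ errors.weighted["s"])
        H = gain * (M.T @ Pi_s @ M)
        # exact integration of the linear loop a' = -(H a + c)
        m = na
        aug = np.zeros((m + 1, m + 1))
        aug[:m, :m] = -H * dt
        aug[:m, m] = -grad * dt
        delta = expm(aug)[:m, m]
        return ActionState(a=action.a + delta, da_dt=-grad)


# ---------------------------------------------------------------------------
# slow timescale: accumulating evidence about theta
# ---------------------------------------------------------------------------


class ParameterAccumulator:
    """Epoch-level accumulation of dF/dtheta and its Gauss-Newton curvature.

    Because theta does not change in time, its prediction errors are summed
    over every filter step of an epoch; the Laplace belief update happens
    once at the epoch boundary.
    """

    def __init__(self) -> None:
        self.gradient = 0.0
        self.curvature = 0.0
        self.n_steps = 0

    def add(
        self,
        filt: GeneralizedFilter,
        post: PosteriorState,
        errors: ErrorSet,
        log_prec: dict[str, float],
        weight: float = 1.0,
        mean_field: bool = True,
    ) -> None:
        """Add one filter step's contribution, d eps_x1 / d theta products.

        ``weight`` scales the evidence: the dyad weights each step by the
        scheduled auditory precision ratio, so learning is driven almost
        entirely by heard (not self-generated) song — evidence produced by
        the agent's own predictions is circular and carries little
        information about the coupling.
        """
        f = filt.funcs
        if f.f1_dtheta is None:
            return
        dflat = theta_error_derivative(filt, post).ravel()
        Pi_x1 = filt.precisions(log_prec)["Pi"]["x1"]
        g = float(dflat @ errors.weighted["x1"])
        c = float(dflat @ Pi_x1 @ dflat)
        if mean_field:
            # Laplace mean-field contribution: expectation of the gradient
            # under the conditional (Gauss-Newton) uncertainty of the
            # states.  This is what lets sustained silence testify against
            # the coupling: exactly-zero expectations are flow-consistent
            # at any theta, but quiet *fluctuations* are unlikely under an
            # unstable (high-theta) attractor.
            E = filt.error_jacobian(post)
            Pi = filt.precisions(log_prec)["Pi"]
            PiE = np.concatenate(
                [Pi[b] @ E[filt._block_rows(b)] for b in ("s", "v", "x1", "x2")]
            )
            H = E.T @ PiE
            H[np.diag_indices_from(H)] += 1e-6
            Sigma = np.linalg.inv(H)
            Jd = theta_error_derivative_jacobian(filt, post)
            E_x1 = E[filt._block_rows("x1")]
            g += float(np.sum((Jd.T @ Pi_x1 @ E_x1) * Sigma.T))
            c += float(np.sum((Jd.T @ Pi_x1 @ Jd) * Sigma.T))
        self.gradient += weight * g
        self.curvature += weight * c
        self.n_steps += 1

    def finalize(self) -> tuple[float, float]:
        if self.n_steps == 0:
            raise ValueError("empty epoch: no accumulated parameter statistics")
        return self.gradient, self.curvature


def theta_error_derivative_jacobian(
    filt: GeneralizedFilter, post: PosteriorState
) -> np.ndarray:
    """d/dmu of the flattened d eps_x1 / d theta, shape ((n+1) nx1, n_mu)."""
    f = filt.funcs
    n, d = filt.n, filt.d
    nmu = (n + 1) * (f.nx1 + f.nx2) + (d + 1) * f.nv
    J = np.zeros(((n + 1) * f.nx1, nmu))
    if f.f1_dtheta_hess is None:
        return J
    off_v = (n + 1) * (f.nx1 + f.nx2)
    x0 = post.mu_x1[0]
    v0 = post.mu_v[0]
    for k in range(n + 1):
        r = k * f.nx1 + 1  # only the y-equation row carries theta
        if k == 0:
            hx, hv, _, _ = f.f1_dtheta_hess(x0, v0, None, None, True)
            J[r, 0] = -filt.dt * hx
            J[r, off_v] = -filt.dt * hv
        else:
            nu = post.mu_v[k] if (f.nv and k <= d) else np.zeros(max(f.nv, 1))
            hx, hv, hxi, hnu = f.f1_dtheta_hess(x0, v0, post.mu_x1[k], nu, False)
            J[r, 0] = -filt.dt * hx
            J[r, off_v] = -filt.dt * hv
            J[r, k * f.nx1] = -filt.dt * hxi
            if f.nv and k <= d:
                J[r, off_v + k * f.nv] = -filt.dt * hnu
    return J


def theta_error_derivative(
    filt: GeneralizedFilter, post: PosteriorState
) -> np.ndarray:
    """d eps_x1 / d theta at fixed expectations, shape (n+1, nx1)."""
    f = filt.funcs
    x0 = post.mu_x1[0]
    v0 = post.mu_v[0] if f.nv else np.zeros(1)
    deps = np.zeros((filt.n + 1, f.nx1))
    deps[0] = -filt.dt * f.f1_dtheta(x0, v0)
    for k in range(1, filt.n + 1):
        nu = post.mu_v[k] if (f.nv and k <= filt.d) else np.zeros(max(f.nv, 1))
        deps[k] = -filt.dt * f.f1_jac_dtheta(x0, v0, post.mu_x1[k], nu)
    return deps
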