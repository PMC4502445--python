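"""Quantitative analysis: bifurcations, synchronization, chirps, divergence.

These are the measurement tools behind the package's experiments: the
bifurcation diagram of the song model over the coupling parameter theta,
the linear synchronization-manifold fit between two agents' slow-level
expectations, amplitude-threshold chirp detection on sonograms, and
epoch-wise divergence metrics contrasting coupled and uncoupled dyads.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dyad import AgentTraces, run_solo
from .songmodel import HierarchicalModel, SimulationError, Sonogram

__all__ = [
    "BifurcationResult",
    "SyncFit",
    "ChirpSet",
    "bifurcation_diagram",
    "sync_fit",
    "detect_chirps",
    "divergence_metric",
]


@dataclass
class BifurcationResult:
    """Extrema of the auditory expectation trace per coupling value."""

    theta_grid: np.ndarray
    extrema: list[np.ndarray]  # per theta: local max/min values (may be empty)
    failed: np.ndarray  # bool mask: simulation failed at that theta

    def n_distinct(self, tol: float = 0.5) -> np.ndarray:
        """Distinct extremum count per theta (values closer than tol merge)."""
        out = np.zeros(len(self.theta_grid), dtype=int)
        for i, ex in enumerate(self.extrema):
            if len(ex) == 0:
                continue
            vals = np.sort(ex)
            out[i] = 1 + int(np.sum(np.diff(vals) > tol))
        return out


@dataclass
class SyncFit:
    """Least-squares linear map onto the synchronization manifold."""

    weights: np.ndarray  # (n_features + 1, n_targets), last row = intercept
    r_squared: float  # NaN when the fit is degenerate
    residual: np.ndarray  # (T, n_targets)
    fitted: np.ndarray  # (T, n_targets)


@dataclass
class ChirpSet:
    """Detected chirps: non-overlapping, time ordered."""

    onsets: np.ndarray
    offsets: np.ndarray
    peak_amplitude: np.ndarray
    peak_frequency: np.ndarray

    def __len__(self) -> int:
        return len(self.onsets)


def bifurcation_diagram(
    model: HierarchicalModel,
    n_theta: int = 128,
    duration: float = 1.0,
    seed: int = 0,
    state_index: int = 1,
    burn_frac: float = 0.2,
    theta_max: float = 1.0,
) -> BifurcationResult:
    """Extrema of self-song auditory expectations over a theta grid.

    For each of ``n_theta`` coupling values spanning [0, theta_max]
    inclusive, one bird sings to itself for ``duration`` seconds and the
    local maxima and minima of its amplitude-state expectation (after
    burn-in discard) are collected.  A simulation failure at some theta is
    recorded as missing rather than fatal.  Bit-reproducible given seed.
    """
    if n_theta < 2:
        raise ValueError("need at least two theta values")
    grid = np.linspace(0.0, theta_max, n_theta)
    extrema: list[np.ndarray] = []
    failed = np.zeros(n_theta, dtype=bool)
    for i, theta in enumerate(grid):
        try:
            out = run_solo(model.with_theta(float(theta)), duration=duration, seed=seed)
            trace = out["mu_x1"][:, state_index]
            burn = int(len(trace) * burn_frac)
            extrema.append(_local_extrema(trace[burn:]))
        except SimulationError:
            failed[i] = True
            extrema.append(np.empty(0))
    return BifurcationResult(theta_grid=grid, extrema=extrema, failed=failed)


def _local_extrema(x: np.ndarray) -> np.ndarray:
    """Values at sign changes of the first difference."""
    d = np.sign(np.diff(x))
    # carry forward zero slopes so plateaus do not spawn spurious extrema
    for i in range(1, len(d)):
        if d[i] == 0:
            d[i] = d[i - 1]
    idx = np.where(np.diff(d) != 0)[0] + 1
    return x[idx]


def sync_fit(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    derivatives_b: np.ndarray | None = None,
    include_derivatives: bool = True,
) -> SyncFit:
    """Fit a linear mixture of one bird's expectations onto the other's.

    Regresses agent A's slow-level expectations on agent B's expectations
    (and, optionally, their temporal derivatives, taken directly from the
    generalized-coordinate rows) by ordinary least squares with an
    intercept.  An identity relationship (identical synchronization) gives
    r_squared = 1 with identity weights on the non-derivative block.

    Degenerate (constant) traces give ``r_squared = nan``.
    """
    Y = np.atleast_2d(np.asarray(traces_a, dtype=float))
    Xb = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if Y.shape[0] != Xb.shape[0]:
        raise ValueError("traces must be time aligned (equal length)")
    feats = [Xb]
    if include_derivatives and derivatives_b is not None:
        feats.append(np.atleast_2d(np.asarray(derivatives_b, dtype=float)))
    X = np.column_stack(feats + [np.ones(len(Y))])
    sst = float(np.sum((Y - Y.mean(axis=0)) ** 2))
    if sst < 1e-12 or np.all(X[:, :-1].std(axis=0) < 1e-12):
        return SyncFit(
            weights=np.full((X.shape[1], Y.shape[1]), np.nan),
            r_squared=float("nan"),
            residual=np.zeros_like(Y),
            fitted=Y.copy(),
        )
    W, *_ = np.linalg.lstsq(X, Y, rcond=None)
    fitted = X @ W
    resid = Y - fitted
    r2 = 1.0 - float(np.sum(resid**2)) / sst
    return SyncFit(weights=W, r_squared=max(0.0, r2), residual=resid, fitted=fitted)


def sync_fit_epoch(
    agent_a: AgentTraces,
    agent_b: AgentTraces,
    epoch: int,
    samples_per_epoch: int,
    include_derivatives: bool = True,
) -> SyncFit:
    """Convenience: slow-level sync fit restricted to one epoch."""
    sl = slice(epoch * samples_per_epoch, (epoch + 1) * samples_per_epoch)
    return sync_fit(
        agent_a.mu_x2[sl],
        agent_b.mu_x2[sl],
        derivatives_b=agent_b.mu_x2_d1[sl],
        include_derivatives=include_derivatives,
    )


def detect_chirps(
    sonogram: Sonogram,
    amp_threshold: float | None = None,
    min_gap: float = 0.05,
) -> ChirpSet:
    """Amplitude-threshold chirp segmentation.

    The default threshold is 10% of the sonogram's peak amplitude; segments
    separated by less than ``min_gap`` seconds merge.  Deterministic; an
    all-zero sonogram yields an empty set.
    """
    env = sonogram.envelope()
    if amp_threshold is None:
        amp_threshold = 0.1 * float(env.max())
    if env.max() <= 0 or amp_threshold <= 0:
        empty = np.empty(0)
        return ChirpSet(empty, empty, empty, empty)
    above = env > amp_threshold
    d = np.diff(above.astype(int))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if above[0]:
        starts.insert(0, 0)
    if above[-1]:
        ends.append(len(env))
    # merge segments separated by less than min_gap
    t = sonogram.times
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        if merged and t[s] - t[merged[-1][1] - 1] < min_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    onsets, offsets, peak_a, peak_f = [], [], [], []
    for s, e in merged:
        onsets.append(t[s])
        offsets.append(t[e - 1])
        seg = sonogram.amplitude[s:e]
        peak_a.append(float(seg.max()))
        ti, fi = np.unravel_index(np.argmax(seg), seg.shape)
        peak_f.append(float(sonogram.freqs[fi]))
    return ChirpSet(
        np.array(onsets), np.array(offsets), np.array(peak_a), np.array(peak_f)
    )


def divergence_metric(
    traces_a: np.ndarray,
    traces_b: np.ndarray,
    samples_per_epoch: int,
) -> dict[str, np.ndarray]:
    """Per-epoch RMS distance and mean per-state Pearson correlation.

    Operates on aligned (T, d) slow-level expectation traces; quantifies
    the contrast between coupled (synchronizing) and uncoupled (diverging)
    dyads.
    """
    A = np.atleast_2d(np.asarray(traces_a, dtype=float))
    B = np.atleast_2d(np.asarray(traces_b, dtype=float))
    if A.shape != B.shape:
        raise ValueError("traces must be aligned with equal shapes")
    n_epochs = A.shape[0] // samples_per_epoch
    rms = np.zeros(n_epochs)
    corr = np.zeros(n_epochs)
    for ep in range(n_epochs):
        sl = slice(ep * samples_per_epoch, (ep + 1) * samples_per_epoch)
        rms[ep] = float(np.sqrt(np.mean((A[sl] - B[sl]) ** 2)))
        rs = []
        for j in range(A.shape[1]):
            sa, sb = A[sl, j], B[sl, j]
            if sa.std() < 1e-12 or sb.std() < 1e-12:
                rs.append(1.0 if np.allclose(sa, sb) else 0.0)
            else:
                rs.append(float(np.corrcoef(sa, sb)[0, 1]))
        corr[ep] = float(np.mean(rs))
    return {"rms": rms, "correlation": corr}
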