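"""Continuous-time dynamics of connectivity snapshots: encode -> graph-ODE -> decode.

The state X(t) is the full m x m connectivity matrix; each node's feature
vector is its correlation profile.  A linear + tanh encoder maps X(t) to a
hidden representation X_h(t), whose evolution follows a graph-convolutional
vector field

    dX_h/dt = act( A_op @ X_h @ W_h + b_h ),

where A_op = D^{-1/2} (A + I) D^{-1/2} is the normalized diffusion operator of
a static coupling graph A summarizing the observed connectivity.  A linear
decoder maps the hidden trajectory back to connectivity space.  Training
minimizes the running loss — the mean discrepancy between the decoded
trajectory at the observed snapshot times and the observed matrices — by
integrating the vector field with a fixed-step solver and differentiating
through the unrolled steps (discretize-then-optimize), with Adam updates.
A terminal semantic-label loss hook exists in the configuration but is
disabled: no node labels are used; classification happens downstream on
snapshot features.

Once fitted, the model predicts the instantaneous network at any time:
*in-snapshots* by interpolation inside the acquisition window, and
*out-snapshots* by extrapolating the initial-value problem beyond it.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .snapshots import Snapshot, SnapshotSequence

logger = logging.getLogger("dynbrain")

__all__ = [
    "CouplingGraph",
    "NdcnConfig",
    "NdcnModel",
    "build_coupling_graph",
    "dynamics_rhs",
    "integrate",
    "fit",
    "predict_in_snapshots",
    "predict_out_snapshots",
    "save_model",
    "load_model",
]

_CHECKPOINT_SCHEMA = 1


# ---------------------------------------------------------------------------
# containers

@dataclass
class CouplingGraph:
    """Static coupling graph: non-negative symmetric adjacency and its
    normalized diffusion operator D^{-1/2}(A+I)D^{-1/2} (spectral norm <= 1)."""

    adjacency: np.ndarray
    operator: np.ndarray


@dataclass
class NdcnConfig:
    """Hyper-parameters of the snapshot dynamics model.

    ``hidden_dim=None`` resolves to ``min(m, 32)`` at fit time.  Fixed-step
    solvers (euler, rk4) support both training and prediction; the adaptive
    solver (scipy RK45) supports prediction only, since gradients are taken
    through the unrolled fixed-step trajectory.
    """

    hidden_dim: int | None = None
    ode_solver: str = "rk4"          # euler | rk4 | adaptive
    step_size: float = 0.2           # volume units, fixed-step solvers
    rtol: float = 1e-6
    atol: float = 1e-8
    epochs: int = 300
    learning_rate: float = 0.02
    weight_decay: float = 0.0
    seed: int = 0
    terminal_loss_enabled: bool = False   # label hook; always off here
    loss_norm: str = "l1"            # l1 | l2
    activation: str = "tanh"         # dynamics nonlinearity: tanh | linear
    encoder_activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.ode_solver not in ("euler", "rk4", "adaptive"):
            raise ValueError(f"unknown solver {self.ode_solver!r}")
        if self.loss_norm not in ("l1", "l2"):
            raise ValueError(f"loss_norm must be l1 or l2, got {self.loss_norm!r}")
        if self.activation not in ("tanh", "linear"):
            raise ValueError(f"activation must be tanh or linear")
        if self.step_size <= 0 or self.learning_rate <= 0 or self.epochs < 1:
            raise ValueError("step_size, learning_rate, epochs must be positive")
        if self.terminal_loss_enabled:
            raise NotImplementedError(
                "terminal label loss is a disabled hook: no node labels are used"
            )


@dataclass
class NdcnModel:
    """Fitted weights, coupling graph and solver settings.

    ``params`` holds W_e, b_e (encoder), W_h, b_h (hidden dynamics),
    W_d, b_d (decoder).  ``t_anchor`` is the absolute time (volume axis) of
    the initial state used for integration; ``span`` is the trained time
    interval on the same axis, within which requests count as interpolation.
    """

    params: dict[str, np.ndarray]
    coupling: CouplingGraph
    config: NdcnConfig
    t_anchor: float = 0.0
    span: tuple[float, float] = (0.0, 0.0)
    x0: np.ndarray | None = None
    final_loss: float = float("nan")
    loss_history: list[float] = field(default_factory=list)


# ---------------------------------------------------------------------------
# coupling graph

def build_coupling_graph(sequence: SnapshotSequence, density: float = 0.15) -> CouplingGraph:
    """Static coupling summary: mean |correlation| over observed snapshots,
    proportionally thresholded to the strongest ``density`` fraction of
    off-diagonal weights, symmetrized, with self-loop normalisation."""
    if len(sequence) == 0:
        raise ValueError("empty snapshot sequence")
    if not 0.0 < density <= 1.0:
        raise ValueError("density must lie in (0, 1]")
    mean_abs = np.mean(np.abs(sequence.matrices), axis=0)
    m = mean_abs.shape[0]
    iu = np.triu_indices(m, k=1)
    w = mean_abs[iu]
    k = int(round(density * w.size))
    if k < 1:
        raise ValueError(f"density {density} keeps no edges for m={m}")
    # deterministic tie-break: sort by (-weight, i, j)
    order = np.lexsort((iu[1], iu[0], -w))
    keep = order[:k]
    A = np.zeros((m, m))
    A[iu[0][keep], iu[1][keep]] = w[keep]
    A = A + A.T
    return CouplingGraph(adjacency=A, operator=_normalized_operator(A))


def _normalized_operator(A: np.ndarray) -> np.ndarray:
    A_hat = A + np.eye(A.shape[0])
    d = A_hat.sum(axis=1)
    inv_sqrt = 1.0 / np.sqrt(d)
    return A_hat * inv_sqrt[:, None] * inv_sqrt[None, :]


# ---------------------------------------------------------------------------
# network primitives

def _act(z: np.ndarray, kind: str) -> np.ndarray:
    return np.tanh(z) if kind == "tanh" else z


def _act_grad_from_out(out: np.ndarray, kind: str) -> np.ndarray:
    return 1.0 - out * out if kind == "tanh" else np.ones_like(out)


def _encode(model: NdcnModel, x: np.ndarray) -> np.ndarray:
    p = model.params
    return _act(x @ p["W_e"] + p["b_e"], model.config.encoder_activation)


def _decode(model: NdcnModel, h: np.ndarray) -> np.ndarray:
    p = model.params
    return h @ p["W_d"] + p["b_d"]


def dynamics_rhs(model: NdcnModel, hidden_state: np.ndarray) -> np.ndarray:
    """Hidden-space vector field dX_h/dt = act(A_op @ X_h @ W_h + b_h)."""
    p = model.params
    if hidden_state.shape != (model.coupling.operator.shape[0], p["W_h"].shape[0]):
        raise ValueError(
            f"hidden state shape {hidden_state.shape} does not match "
            f"(m={model.coupling.operator.shape[0]}, d={p['W_h'].shape[0]})"
        )
    z = model.coupling.operator @ hidden_state @ p["W_h"] + p["b_h"]
    return _act(z, model.config.activation)


def _rhs(op, W_h, b_h, kind, H):
    return _act(op @ H @ W_h + b_h, kind)


def _rhs_vjp(op, W_h, b_h, kind, H, g):
    """VJP of the vector field at H for cotangent g: returns (gH, gW_h, gb_h)."""
    out = _rhs(op, W_h, b_h, kind, H)
    gz = g * _act_grad_from_out(out, kind)
    AH = op @ H
    gH = op.T @ (gz @ W_h.T)
    gW = AH.T @ gz
    gb = gz.sum(axis=0)
    return gH, gW, gb


def _step_forward(op, W_h, b_h, kind, H, dt, solver):
    if solver == "euler":
        return H + dt * _rhs(op, W_h, b_h, kind, H)
    k1 = _rhs(op, W_h, b_h, kind, H)
    k2 = _rhs(op, W_h, b_h, kind, H + 0.5 * dt * k1)
    k3 = _rhs(op, W_h, b_h, kind, H + 0.5 * dt * k2)
    k4 = _rhs(op, W_h, b_h, kind, H + dt * k3)
    return H + dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)


def _step_vjp(op, W_h, b_h, kind, H, dt, solver, g):
    """Backprop one solver step: cotangent of the step output -> cotangents of
    the step input and the dynamics parameters.  Stages are recomputed."""
    gW = np.zeros_like(W_h)
    gb = np.zeros_like(b_h)
    if solver == "euler":
        gH_f, gW_f, gb_f = _rhs_vjp(op, W_h, b_h, kind, H, dt * g)
        return g + gH_f, gW + gW_f, gb + gb_f
    k1 = _rhs(op, W_h, b_h, kind, H)
    H2 = H + 0.5 * dt * k1
    k2 = _rhs(op, W_h, b_h, kind, H2)
    H3 = H + 0.5 * dt * k2
    k3 = _rhs(op, W_h, b_h, kind, H3)
    H4 = H + dt * k3
    g_k1 = dt / 6.0 * g
    g_k2 = dt / 3.0 * g
    g_k3 = dt / 3.0 * g
    g_k4 = dt / 6.0 * g
    gH = g.copy()
    gH4, gWs, gbs = _rhs_vjp(op, W_h, b_h, kind, H4, g_k4)
    gW += gWs; gb += gbs
    gH += gH4
    g_k3 = g_k3 + dt * gH4
    gH3, gWs, gbs = _rhs_vjp(op, W_h, b_h, kind, H3, g_k3)
    gW += gWs; gb += gbs
    gH += gH3
    g_k2 = g_k2 + 0.5 * dt * gH3
    gH2, gWs, gbs = _rhs_vjp(op, W_h, b_h, kind, H2, g_k2)
    gW += gWs; gb += gbs
    gH += gH2
    g_k1 = g_k1 + 0.5 * dt * gH2
    gH1, gWs, gbs = _rhs_vjp(op, W_h, b_h, kind, H, g_k1)
    gW += gWs; gb += gbs
    gH += gH1
    return gH, gW, gb


def _integrate_grid(model: NdcnModel, H0: np.ndarray, n_steps: int, dt: float) -> list[np.ndarray]:
    """Hidden states at grid points 0..n_steps with signed step dt."""
    p = model.params
    op = model.coupling.operator
    kind = model.config.activation
    solver = model.config.ode_solver
    states = [H0]
    H = H0
    for _ in range(n_steps):
        H = _step_forward(op, p["W_h"], p["b_h"], kind, H, dt, solver)
        states.append(H)
    return states


# ---------------------------------------------------------------------------
# integration (public)

def integrate(model: NdcnModel, x0: np.ndarray, times: np.ndarray) -> list[np.ndarray]:
    """Encode x0, integrate the hidden dynamics from time 0 through ``times``,
    decode each requested state.  ``times`` must be non-negative increasing."""
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return []
    if np.any(np.diff(times) <= 0) or times[0] < 0:
        raise ValueError("times must be non-negative and strictly increasing")
    if not np.all(np.isfinite(x0)):
        raise ValueError("x0 must be finite")
    H0 = _encode(model, np.asarray(x0, dtype=float))
    if model.config.ode_solver == "adaptive":
        return [_decode(model, h) for h in _integrate_adaptive(model, H0, times)]
    dt = model.config.step_size
    n_steps = int(np.ceil(times[-1] / dt - 1e-12))
    states = _integrate_grid(model, H0, n_steps, dt)
    return [_decode(model, _interp_state(states, t, dt)) for t in times]


def _interp_state(states: list[np.ndarray], t: float, dt: float) -> np.ndarray:
    """Linear interpolation between bracketing fixed-step grid states."""
    pos = t / dt
    lo = int(np.floor(pos + 1e-12))
    lo = min(max(lo, 0), len(states) - 1)
    hi = min(lo + 1, len(states) - 1)
    frac = pos - lo
    if hi == lo or frac <= 1e-12:
        return states[lo]
    return (1.0 - frac) * states[lo] + frac * states[hi]


def _integrate_adaptive(model: NdcnModel, H0: np.ndarray, times: np.ndarray) -> list[np.ndarray]:
    from scipy.integrate import solve_ivp

    p = model.params
    op = model.coupling.operator
    kind = model.config.activation
    shape = H0.shape

    def rhs_flat(_t, y):
        return _rhs(op, p["W_h"], p["b_h"], kind, y.reshape(shape)).ravel()

    t_eval = times if times[0] > 0 else times
    sol = solve_ivp(
        rhs_flat, (0.0, float(times[-1]) if times[-1] > 0 else 1e-12), H0.ravel(),
        t_eval=t_eval, rtol=model.config.rtol, atol=model.config.atol, method="RK45",
    )
    if not sol.success:
        reached = sol.t[-1] if sol.t.size else 0.0
        raise RuntimeError(f"adaptive solver failed near t={reached}: {sol.message}")
    return [sol.y[:, i].reshape(shape) for i in range(sol.y.shape[1])]


# ---------------------------------------------------------------------------
# training

def _init_params(m: int, d: int, rng: np.random.Generator) -> dict[str, np.ndarray]:
    # Glorot-scale codec; near-zero dynamics so the initial trajectory is
    # almost constant (stable start for stiff-free training).
    return {
        "W_e": rng.normal(0.0, np.sqrt(2.0 / (m + d)), size=(m, d)),
        "b_e": np.zeros(d),
        "W_h": rng.normal(0.0, 0.01, size=(d, d)),
        "b_h": np.zeros(d),
        "W_d": rng.normal(0.0, np.sqrt(2.0 / (m + d)), size=(d, m)),
        "b_d": np.zeros(m),
    }


def _loss_and_grads(model: NdcnModel, x0, rel_times, obs_mats):
    """Running loss at the observed snapshot times and its parameter gradients.

    Forward: encode x0, march the fixed-step solver across the grid, decode at
    the grid indices of the observation times.  Backward: decoder cotangents
    are injected at those indices and swept back through the unrolled steps.
    """
    p = model.params
    cfg = model.config
    op = model.coupling.operator
    kind = cfg.activation
    dt = cfg.step_size

    idx_f = rel_times / dt
    idx = np.round(idx_f).astype(int)
    if np.max(np.abs(idx_f - idx)) > 1e-6:
        raise ValueError(
            "snapshot times must fall on the integration grid: choose a "
            "step_size dividing the snapshot spacing"
        )
    n_steps = int(idx[-1])

    pre_e = x0 @ p["W_e"] + p["b_e"]
    H0 = _act(pre_e, cfg.encoder_activation)
    states = _integrate_grid(model, H0, n_steps, dt)

    n_obs = len(obs_mats)
    scale = 1.0 / (n_obs * x0.size)
    loss = 0.0
    g_local = {}          # grid index -> hidden cotangent from the decoder
    gW_d = np.zeros_like(p["W_d"])
    gb_d = np.zeros_like(p["b_d"])
    for t_i, X_i in zip(idx, obs_mats):
        H = states[t_i]
        Xhat = H @ p["W_d"] + p["b_d"]
        diff = Xhat - X_i
        if cfg.loss_norm == "l1":
            loss += np.abs(diff).sum() * scale
            gX = np.sign(diff) * scale
        else:
            loss += 0.5 * (diff * diff).sum() * scale
            gX = diff * scale
        gW_d += H.T @ gX
        gb_d += gX.sum(axis=0)
        gH = gX @ p["W_d"].T
        g_local[t_i] = g_local.get(t_i, 0.0) + gH

    gW_h = np.zeros_like(p["W_h"])
    gb_h = np.zeros_like(p["b_h"])
    g = np.asarray(g_local.get(n_steps, np.zeros_like(H0)))
    for k in range(n_steps - 1, -1, -1):
        g, gWs, gbs = _step_vjp(op, p["W_h"], p["b_h"], kind, states[k], dt,
                                cfg.ode_solver, g)
        gW_h += gWs
        gb_h += gbs
        if k in g_local:
            g = g + g_local[k]

    g_pre = g * _act_grad_from_out(H0, cfg.encoder_activation)
    grads = {
        "W_e": x0.T @ g_pre,
        "b_e": g_pre.sum(axis=0),
        "W_h": gW_h,
        "b_h": gb_h,
        "W_d": gW_d,
        "b_d": gb_d,
    }
    if cfg.weight_decay > 0:
        for name in ("W_e", "W_h", "W_d"):
            grads[name] = grads[name] + cfg.weight_decay * p[name]
    return loss, grads


def fit(
    sequence: SnapshotSequence,
    coupling: CouplingGraph,
    config: NdcnConfig | None = None,
    t_max: float | None = None,
) -> NdcnModel:
    """Train the dynamics model on a sequence of observed snapshots.

    Parameters
    ----------
    sequence : SnapshotSequence
        At least 3 observed snapshots; their time indices (volume axis) are
        used as the training times, anchored at the first snapshot.
    coupling : CouplingGraph
        Static graph whose normalized operator drives the hidden dynamics.
    config : NdcnConfig, optional
        Hyper-parameters; defaults are desk-scale single-CPU settings.
    t_max : float, optional
        Upper end of the interpolation span on the volume axis (e.g. T - 1
        when the acquisition has T volumes).  Defaults to the last snapshot
        time.  Interpolation requests are valid on [0, t_max].
    """
    config = config or NdcnConfig()
    if config.ode_solver == "adaptive":
        raise ValueError(
            "fit requires a fixed-step solver (euler or rk4); the adaptive "
            "solver is available for prediction"
        )
    if len(sequence) < 3:
        raise ValueError("need at least 3 observed snapshots to fit dynamics")
    times = sequence.times
    spacing = np.diff(times)
    if config.step_size >= spacing.min():
        raise ValueError(
            f"step_size {config.step_size} must be smaller than the minimum "
            f"snapshot spacing {spacing.min()}"
        )
    t0 = float(times[0])
    rel_times = times - t0
    x0 = sequence[0].matrix
    m = x0.shape[0]
    d = config.hidden_dim or min(m, 32)

    rng = np.random.default_rng(config.seed)
    model = NdcnModel(
        params=_init_params(m, d, rng),
        coupling=coupling,
        config=config,
        t_anchor=t0,
        span=(0.0, float(t_max) if t_max is not None else float(times[-1])),
        x0=x0.copy(),
    )
    obs_mats = [s.matrix for s in sequence]

    # Adam
    lr = config.learning_rate
    b1, b2, eps = 0.9, 0.999, 1e-8
    mom = {k: np.zeros_like(v) for k, v in model.params.items()}
    vel = {k: np.zeros_like(v) for k, v in model.params.items()}
    best_loss, best_params = np.inf, None
    history = []
    for epoch in range(1, config.epochs + 1):
        loss, grads = _loss_and_grads(model, x0, rel_times, obs_mats)
        if not np.isfinite(loss):
            raise RuntimeError(
                "training loss diverged (non-finite); reduce learning_rate "
                "or step_size"
            )
        history.append(float(loss))
        if loss < best_loss:
            best_loss = loss
            best_params = {k: v.copy() for k, v in model.params.items()}
        for k in model.params:
            g = grads[k]
            mom[k] = b1 * mom[k] + (1 - b1) * g
            vel[k] = b2 * vel[k] + (1 - b2) * g * g
            mhat = mom[k] / (1 - b1**epoch)
            vhat = vel[k] / (1 - b2**epoch)
            model.params[k] = model.params[k] - lr * mhat / (np.sqrt(vhat) + eps)

    model.params = best_params
    model.final_loss = float(best_loss)
    model.loss_history = history
    logger.info(
        "fit %s: %d snapshots, hidden_dim=%d, final loss %.5f",
        sequence.subject_id, len(sequence), d, best_loss,
    )
    return model


def training_loss(model: NdcnModel, sequence: SnapshotSequence) -> float:
    """Recompute the running loss of a fitted model on a snapshot sequence
    (same computational path as fit)."""
    rel_times = sequence.times - model.t_anchor
    loss, _ = _loss_and_grads(model, sequence[0].matrix, rel_times,
                              [s.matrix for s in sequence])
    return float(loss)


# ---------------------------------------------------------------------------
# prediction

def _decode_at_times(model: NdcnModel, abs_times: np.ndarray) -> list[np.ndarray]:
    """Decoded states at absolute (volume-axis) times; integrates forward from
    the anchor and, if needed, backward below it."""
    if model.x0 is None:
        raise ValueError("model has no initial state; fit it first")
    H0 = _encode(model, model.x0)
    dt = model.config.step_size
    solver = model.config.ode_solver
    if solver == "adaptive":
        # split around the anchor; adaptive path reuses scipy in each direction
        out = {}
        fwd = abs_times[abs_times >= model.t_anchor] - model.t_anchor
        bwd = model.t_anchor - abs_times[abs_times < model.t_anchor]
        if fwd.size:
            hs = _integrate_adaptive(model, H0, np.maximum(np.sort(fwd), 1e-12))
            for t, h in zip(np.sort(fwd) + model.t_anchor, hs):
                out[float(t)] = h
        if bwd.size:
            # backward leg: integrate d/ds H(t0 - s) = -f(H)
            op = model.coupling.operator
            from scipy.integrate import solve_ivp
            shape = H0.shape

            def neg_rhs(_t, y):
                return -_rhs(op, model.params["W_h"], model.params["b_h"],
                             model.config.activation, y.reshape(shape)).ravel()

            s_eval = np.sort(bwd)
            sol = solve_ivp(neg_rhs, (0.0, float(s_eval[-1])), H0.ravel(),
                            t_eval=s_eval, rtol=model.config.rtol,
                            atol=model.config.atol, method="RK45")
            if not sol.success:
                raise RuntimeError(f"adaptive solver failed: {sol.message}")
            for s, i in zip(s_eval, range(sol.y.shape[1])):
                out[float(model.t_anchor - s)] = sol.y[:, i].reshape(shape)
        return [_decode(model, out[float(t)]) for t in abs_times]

    t_lo = min(float(abs_times.min()), model.t_anchor)
    t_hi = max(float(abs_times.max()), model.t_anchor)
    n_fwd = int(np.ceil((t_hi - model.t_anchor) / dt - 1e-12))
    n_bwd = int(np.ceil((model.t_anchor - t_lo) / dt - 1e-12))
    fwd_states = _integrate_grid(model, H0, n_fwd, dt)
    bwd_states = _integrate_grid(model, H0, n_bwd, -dt)
    # single grid indexed from the lowest backward point
    states = bwd_states[::-1] + fwd_states[1:]
    grid_origin = model.t_anchor - n_bwd * dt
    return [
        _decode(model, _interp_state(states, t - grid_origin, dt)) for t in abs_times
    ]


def predict_in_snapshots(
    model: NdcnModel, times: np.ndarray | None = None
) -> SnapshotSequence:
    """Interpolated snapshots inside the trained span.

    ``times=None`` requests one snapshot per integer volume index covered by
    the signal (0 .. span end), the convention under which a 140-volume
    acquisition yields 140 in-snapshots.  Matrices are symmetrized as
    (M + M')/2 and tagged with provenance ``in``.
    """
    lo, hi = model.span
    if times is None:
        times = np.arange(int(np.floor(lo)), int(np.floor(hi)) + 1, dtype=float)
    times = np.asarray(times, dtype=float)
    if times.size == 0:
        return SnapshotSequence(subject_id="", snapshots=[])
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    if times[0] < lo - 1e-9 or times[-1] > hi + 1e-9:
        raise ValueError(
            f"requested times outside trained span [{lo}, {hi}]; use "
            "predict_out_snapshots for extrapolation"
        )
    mats = _decode_at_times(model, times)
    snaps = [
        Snapshot(time_index=float(t), matrix=(M + M.T) / 2.0, provenance="in")
        for t, M in zip(times, mats)
    ]
    return SnapshotSequence(subject_id="", snapshots=snaps)


def predict_out_snapshots(model: NdcnModel, horizon: int) -> SnapshotSequence:
    """Extrapolated snapshots at the ``horizon`` unit time steps past the
    trained span; symmetrized and clamped to [-1, 1], tagged ``out``."""
    if horizon < 0:
        raise ValueError("horizon must be non-negative")
    if horizon == 0:
        return SnapshotSequence(subject_id="", snapshots=[])
    _, hi = model.span
    base = np.floor(hi)
    times = base + np.arange(1, horizon + 1, dtype=float)
    mats = _decode_at_times(model, times)
    snaps = [
        Snapshot(
            time_index=float(t),
            matrix=np.clip((M + M.T) / 2.0, -1.0, 1.0),
            provenance="out",
        )
        for t, M in zip(times, mats)
    ]
    return SnapshotSequence(subject_id="", snapshots=snaps)


# ---------------------------------------------------------------------------
# checkpoints

def save_model(model: NdcnModel, path: str | Path) -> Path:
    """Save weights + config + coupling graph as a versioned .npz archive."""
    path = Path(path)
    meta = {"schema": _CHECKPOINT_SCHEMA, "config": asdict(model.config),
            "t_anchor": model.t_anchor, "span": list(model.span),
            "final_loss": model.final_loss}
    arrays = {f"param_{k}": v for k, v in model.params.items()}
    arrays["adjacency"] = model.coupling.adjacency
    arrays["operator"] = model.coupling.operator
    if model.x0 is not None:
        arrays["x0"] = model.x0
    np.savez(path, meta=json.dumps(meta), **arrays)
    return path


def load_model(path: str | Path) -> NdcnModel:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta["schema"] != _CHECKPOINT_SCHEMA:
            raise ValueError(
                f"checkpoint schema {meta['schema']} != supported {_CHECKPOINT_SCHEMA}"
            )
        params = {k[6:]: z[k] for k in z.files if k.startswith("param_")}
        model = NdcnModel(
            params=params,
            coupling=CouplingGraph(adjacency=z["adjacency"], operator=z["operator"]),
            config=NdcnConfig(**meta["config"]),
            t_anchor=meta["t_anchor"],
            span=tuple(meta["span"]),
            x0=z["x0"] if "x0" in z.files else None,
            final_loss=meta["final_loss"],
        )
    return model
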