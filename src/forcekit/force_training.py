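"""FORCE trainers built on recursive least squares (RLS).

FORCE (First-Order, Reduced and Controlled Error) learning trains a
chaotic recurrent network online: at every update step the inverse
regularized correlation matrix of the network rates,

    P(t) = (alpha*I + sum_s r(s) r(s)^T)^(-1),

is maintained by a Sherman-Morrison rank-one recursion, the a-priori
readout error e_-(t) = z(t) - f_out(t) is computed with the pre-update
weights, and the readout weights move along the pseudogradient
``-P(t) r(t) e_-(t)^T``.  Because the update happens every (or every
k-th) step, the output error stays clamped near zero during training and
the network's own fed-back output is a good stand-in for the target.

Four trainers share this machinery:

``force_fit``
    classic FORCE on a rate layer: trains the readout (and optionally the
    recurrent weights through per-neuron inverse-correlation matrices
    ``A^i`` restricted to each neuron's presynaptic set ``B(i)``).
``full_force_fit``
    trains a no-feedback rate network's *full* recurrent matrix so that
    its recurrent current matches that of a separate, fixed
    target-generating network which is driven by the target (and hint);
    a single shared P makes this O(N^2) per step instead of the O(N^3)
    of classic recurrent FORCE.
``spiking_fit``
    FORCE on the decoders of a spiking layer, with the filtered spike
    trains as the regression features.
``bio_force_fit``
    per-neuron FORCE fitting of a connectome-constrained rate network to
    recorded activity traces, yielding an effective weight matrix.
"""

from __future__ import annotations

import dataclasses
import time
import warnings
from typing import Callable, Optional

import numpy as np

from .rate_layers import (
    RateNetworkParams,
    RateNetworkState,
    _copy_params,
    init_rate_network,
    run_network,
    step_rate,
)
from .spiking_layers import (
    SpikingNetworkParams,
    SpikingState,
    step_spiking,
)
from .synthetic_tasks import TaskData

__all__ = [
    "RLSState",
    "RecurrentRLSFamily",
    "TrainingConfig",
    "TrainingHistory",
    "BioFitResult",
    "init_P",
    "rls_update_P",
    "compute_error",
    "update_output_weights",
    "init_recurrent_rls",
    "update_recurrent_weights",
    "force_fit",
    "full_force_fit",
    "spiking_fit",
    "bio_force_fit",
    "predict",
]


# ---------------------------------------------------------------------------
# RLS primitives


@dataclasses.dataclass
class RLSState:
    """Shared inverse-correlation matrix P with regularizer alpha."""

    P: np.ndarray
    alpha: float


@dataclasses.dataclass
class RecurrentRLSFamily:
    """Per-neuron inverse-correlation matrices A^i on index sets B(i).

    ``indices[i]`` holds the presynaptic set B(i) (row indices into the
    rate vector); ``A[i]`` is the |B(i)| x |B(i)| matrix, initialized to
    alpha^-1 * I.  Neurons with empty B(i) carry an empty matrix and are
    never updated.
    """

    indices: list[np.ndarray]
    A: list[np.ndarray]
    alpha: float


def init_P(alpha: float, n: int) -> np.ndarray:
    """P(0) = alpha^-1 * I."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    return np.eye(n) / alpha


def rls_update_P(P: np.ndarray, r: np.ndarray) -> np.ndarray:
    """Sherman-Morrison rank-one update: P' = (P^-1 + r r^T)^-1.

    Computed as P - (P r)(P r)^T / (1 + r^T P r); the result is
    re-symmetrized to keep accumulated round-off from breaking symmetry.
    """
    r = np.asarray(r, dtype=float)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError("non-finite rate vector in RLS update")
    pr = P @ r
    denom = 1.0 + r @ pr
    P_new = P - np.outer(pr, pr) / denom
    return 0.5 * (P_new + P_new.T)


def compute_error(z: np.ndarray, f_out_t: np.ndarray) -> np.ndarray:
    """A-priori error e_-(t) = z(t) - f_out(t), per output dimension."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    f_out_t = np.atleast_1d(np.asarray(f_out_t, dtype=float))
    if z.shape != f_out_t.shape:
        raise ValueError(
            f"readout shape {z.shape} does not match target {f_out_t.shape}"
        )
    return z - f_out_t


def update_output_weights(
    w_out: np.ndarray,
    e_minus: np.ndarray,
    P: np.ndarray,
    r: np.ndarray,
) -> np.ndarray:
    """Delta-rule readout update w_out' = w_out - (P r) e_-^T.

    P must already contain this step's rate vector (the P update precedes
    the weight update); a single P is shared across output dimensions.
    """
    e_minus = np.atleast_1d(np.asarray(e_minus, dtype=float))
    if w_out.shape[1] != e_minus.shape[0]:
        raise ValueError("error dimension does not match w_out columns")
    return w_out - np.outer(P @ r, e_minus)


def init_recurrent_rls(mask: np.ndarray, alpha: float) -> RecurrentRLSFamily:
    """One A^i = alpha^-1 I per neuron, sized to its presynaptic set."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    indices = [np.flatnonzero(mask[:, i]) for i in range(mask.shape[1])]
    A = [np.eye(len(idx)) / alpha for idx in indices]
    return RecurrentRLSFamily(indices=indices, A=A, alpha=alpha)


def _family_rls_step(
    family: RecurrentRLSFamily, r: np.ndarray
) -> list[np.ndarray]:
    """Update every A^i in place; return the post-update vectors A^i r|B(i).

    Uses A_new r = (A_old r) / (1 + r^T A_old r), the rank-one identity
    that also underlies ``rls_update_P``.
    """
    us = []
    for idx, A in zip(family.indices, family.A):
        if len(idx) == 0:
            us.append(np.empty(0))
            continue
        rb = r[idx]
        u = A @ rb
        denom = 1.0 + rb @ u
        A -= np.outer(u, u) / denom
        us.append(u / denom)
    return us


def update_recurrent_weights(
    w_R: np.ndarray,
    family: RecurrentRLSFamily,
    e_minus: float,
    r: np.ndarray,
    mask: np.ndarray,
) -> tuple[np.ndarray, RecurrentRLSFamily]:
    """Classic recurrent FORCE update for a scalar output.

    Each neuron i's incoming weights move by
    ``w_R[j, i] -= e_- * sum_k A^i[j, k] r[k]`` over j, k in B(i); entries
    outside the mask are untouched.  The A^i recursion itself does not
    depend on the error and runs regardless of e_-.
    """
    e_arr = np.atleast_1d(np.asarray(e_minus, dtype=float))
    if e_arr.size != 1:
        raise ValueError(
            "recurrent FORCE training supports scalar outputs only"
        )
    if len(family.indices) != mask.shape[1]:
        raise ValueError("A-family inconsistent with mask")
    e = float(e_arr[0])
    us = _family_rls_step(family, r)
    w_R = w_R.copy()
    for i, (idx, u) in enumerate(zip(family.indices, us)):
        if len(idx):
            w_R[idx, i] -= e * u
    return w_R, family


# ---------------------------------------------------------------------------
# training configuration and bookkeeping


@dataclasses.dataclass
class EarlyStopping:
    patience: int = 3
    min_delta: float = 0.0


@dataclasses.dataclass
class TrainingConfig:
    """Knobs shared by every trainer.

    ``update_interval`` k gates RLS: after ``warmup_steps`` settling steps
    (forward pass only), updates fire on every k-th step, i.e. at in-epoch
    step numbers warmup+k, warmup+2k, ... giving floor((T-warmup)/k)
    updates per epoch.
    """

    alpha: float = 1.0
    epochs: int = 1
    update_interval: int = 1
    train_output: bool = True
    train_recurrent: bool = False
    warmup_steps: int = 0
    early_stopping: Optional[EarlyStopping] = None
    seed: int = 0

    def validate(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        if self.update_interval < 1:
            raise ValueError("update_interval must be >= 1")
        if self.warmup_steps < 0:
            raise ValueError("warmup_steps must be >= 0")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


@dataclasses.dataclass
class TrainingHistory:
    """Per-epoch log: training MAE (a-priori errors), validation MAE,
    RLS update count, wall time."""

    train_mae: list[float] = dataclasses.field(default_factory=list)
    val_mae: list[float] = dataclasses.field(default_factory=list)
    n_updates: list[int] = dataclasses.field(default_factory=list)
    wall_time_s: list[float] = dataclasses.field(default_factory=list)

    @property
    def epochs_completed(self) -> int:
        return len(self.val_mae)

    def to_csv(self, path: str) -> None:
        # repr() round-trips float64 exactly, keeping reruns byte-identical
        with open(path, "w", encoding="utf-8") as f:
            f.write("epoch,train_mae,val_mae,n_updates\n")
            for i, (tr, va, nu) in enumerate(
                zip(self.train_mae, self.val_mae, self.n_updates)
            ):
                f.write(f"{i},{tr!r},{va!r},{nu}\n")


def _zero_rate_state(params: RateNetworkParams) -> RateNetworkState:
    h = params.activation_fn()
    x0 = np.zeros(params.n_neurons)
    r0 = h(x0)
    return RateNetworkState(x=x0, r=r0, z=params.w_out.T @ r0, step_index=0)


def _task_input(task: TaskData, m_in: Optional[int] = None) -> np.ndarray:
    """Input series matching a layer's input width.

    Classic FORCE treats hint channels as extra input dimensions, so the
    default is f_in with the hint appended; a layer expecting only the
    bare input (full-FORCE task networks) gets f_in alone.
    """
    full = task.f_in
    if task.hint is not None and task.hint.shape[1] > 0:
        full = np.hstack([task.f_in, task.hint])
    if m_in is None or full.shape[1] == m_in:
        return full
    if task.f_in.shape[1] == m_in:
        return task.f_in
    raise ValueError(
        f"task supplies {task.f_in.shape[1]} input channels "
        f"({full.shape[1]} with hint) but layer expects {m_in}"
    )


def _scheduled(step_no: int, warmup: int, k: int) -> bool:
    return step_no > warmup and (step_no - warmup) % k == 0


def _stop_early(
    val: float, best: float, stall: int, es: EarlyStopping
) -> tuple[float, int, bool]:
    if val < best - es.min_delta:
        return val, 0, False
    stall += 1
    return best, stall, stall >= es.patience


# ---------------------------------------------------------------------------
# trainers


def force_fit(
    params: RateNetworkParams,
    task: TaskData,
    config: TrainingConfig,
    state0: Optional[RateNetworkState] = None,
    step_callback: Optional[Callable[[int, int, RateNetworkParams], None]] = None,
) -> tuple[RateNetworkParams, TrainingHistory]:
    """Classic FORCE training of a rate layer (Algorithm-1 loop).

    Per scheduled step: forward pass -> P update -> a-priori error ->
    pseudogradient -> weight update; the readout is then refreshed so any
    feedback carries the clamped output.  Validation at each epoch end is
    a closed-loop forward pass on the same input/target with no updates.
    P (and the A^i family when ``train_recurrent``) persist across epochs.

    ``step_callback(epoch, step_no, params)``, if given, runs after every
    step (used to observe update gating).
    """
    config.validate()
    if params.layer_kind not in ("feedback_esn", "nofeedback_esn"):
        raise ValueError(
            f"force_fit expects a feedback/nofeedback rate layer, got "
            f"{params.layer_kind!r}"
        )
    params = _copy_params(params)
    if state0 is None:
        state0 = _zero_rate_state(params)
    inputs = _task_input(task, params.m_in)
    f_out = task.f_out
    t_steps = task.n_steps
    k = config.update_interval
    family = None
    if config.train_recurrent:
        if params.m_out != 1:
            raise ValueError(
                "recurrent FORCE training requires a scalar output"
            )
        family = init_recurrent_rls(params.connectivity_mask, config.alpha)
    P = init_P(config.alpha, params.n_neurons)
    history = TrainingHistory()

    for epoch in range(config.epochs):
        tic = time.perf_counter()
        state = state0.copy()
        abs_err = 0.0
        n_upd = 0
        for t in range(t_steps):
            state = step_rate(params, state, inputs[t])
            e_pre = compute_error(state.z, f_out[t])
            abs_err += float(np.mean(np.abs(e_pre)))
            step_no = t + 1
            if _scheduled(step_no, config.warmup_steps, k):
                P = rls_update_P(P, state.r)
                if config.train_output:
                    params.w_out = update_output_weights(
                        params.w_out, e_pre, P, state.r
                    )
                if config.train_recurrent:
                    params.w_R, family = update_recurrent_weights(
                        params.w_R, family, float(e_pre[0]), state.r,
                        params.connectivity_mask,
                    )
                state.z = params.w_out.T @ state.r
                n_upd += 1
            if step_callback is not None:
                step_callback(epoch, step_no, params)
        _, val_mae = predict(params, task, state0=state0)
        history.train_mae.append(abs_err / t_steps)
        history.val_mae.append(val_mae)
        history.n_updates.append(n_upd)
        history.wall_time_s.append(time.perf_counter() - tic)
        if config.early_stopping is not None:
            if epoch == 0:
                best, stall = val_mae, 0
            else:
                best, stall, stop = _stop_early(
                    val_mae, best, stall, config.early_stopping
                )
                if stop:
                    break
    return params, history


def full_force_fit(
    params: RateNetworkParams,
    task: TaskData,
    config: TrainingConfig,
    state0: Optional[RateNetworkState] = None,
    target_seed: Optional[int] = None,
) -> tuple[RateNetworkParams, TrainingHistory]:
    """full-FORCE training of a no-feedback rate layer.

    A separate target-generating network with the same architecture and
    fixed random weights is driven by the task input, the hint and the
    target itself (through random target/hint encoders).  The task
    network's recurrent weights are trained with a shared-P RLS so that
    its recurrent current matches the target network's recurrent current
    plus the target- and hint-drive terms; the readout is trained on the
    output error with the same P.  Cost is O(N^2) per update step.
    """
    config.validate()
    if params.layer_kind != "nofeedback_esn":
        raise ValueError(
            f"full_force_fit requires a nofeedback_esn layer, got "
            f"{params.layer_kind!r}"
        )
    params = _copy_params(params)
    if state0 is None:
        state0 = _zero_rate_state(params)
    inputs = _task_input(task, params.m_in)
    f_out = task.f_out
    m_out = f_out.shape[1]
    if m_out != params.m_out:
        raise ValueError("target dimension does not match layer M_out")
    t_steps = task.n_steps
    k = config.update_interval
    n = params.n_neurons
    mask = params.connectivity_mask

    # Target-generating network: same size/gain, fixed random recurrent
    # weights, receiving the task input through the SAME input weights as
    # the task network (so their currents can actually agree) plus the
    # hint and the target through its own random encoders.  Hint channels
    # not already consumed by the task network drive only the target
    # network, which is their training-crutch role.
    m_hint = 0 if task.hint is None else task.hint.shape[1]
    hint_in_task = inputs.shape[1] > task.f_in.shape[1]
    aux_series = [f_out]
    if m_hint and not hint_in_task:
        aux_series.insert(0, task.hint)
    aux = np.hstack(aux_series)
    if target_seed is None:
        target_seed = int(
            np.random.default_rng(config.seed).integers(0, 2**31 - 1)
        )
    d_params, d_state0 = init_rate_network(
        n,
        "nofeedback_esn",
        sparsity=params.sparsity,
        gain=params.gain,
        dims=(inputs.shape[1] + aux.shape[1], m_out),
        seed=target_seed,
        tau=params.tau,
        dt=params.dt,
        activation=params.activation,
    )
    d_params.w_in[: inputs.shape[1]] = params.w_in
    d_inputs = np.hstack([inputs, aux])
    # encoder rows whose drive enters the current-matching target
    u_drive = d_params.w_in[inputs.shape[1]:, :]
    drive_series = aux

    P = init_P(config.alpha, n)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        tic = time.perf_counter()
        state = state0.copy()
        d_state = d_state0.copy()
        abs_err = 0.0
        n_upd = 0
        for t in range(t_steps):
            state = step_rate(params, state, inputs[t])
            d_state = step_rate(d_params, d_state, d_inputs[t])
            e_out = compute_error(state.z, f_out[t])
            abs_err += float(np.mean(np.abs(e_out)))
            step_no = t + 1
            if _scheduled(step_no, config.warmup_steps, k):
                P = rls_update_P(P, state.r)
                pr = P @ state.r
                # the driven network combines r_D(t) with the NEXT step's
                # target/hint drive, so the matching target does too
                t_next = min(t + 1, t_steps - 1)
                target_current = (
                    d_params.w_R.T @ d_state.r
                    + u_drive.T @ drive_series[t_next]
                )
                e_j = params.w_R.T @ state.r - target_current
                dw = np.outer(pr, e_j)
                dw[~mask] = 0.0
                params.w_R = params.w_R - dw
                if config.train_output:
                    params.w_out = update_output_weights(
                        params.w_out, e_out, P, state.r
                    )
                state.z = params.w_out.T @ state.r
                n_upd += 1
        _, val_mae = predict(params, task, state0=state0)
        history.train_mae.append(abs_err / t_steps)
        history.val_mae.append(val_mae)
        history.n_updates.append(n_upd)
        history.wall_time_s.append(time.perf_counter() - tic)
        if config.early_stopping is not None:
            if epoch == 0:
                best, stall = val_mae, 0
            else:
                best, stall, stop = _stop_early(
                    val_mae, best, stall, config.early_stopping
                )
                if stop:
                    break
    return params, history


def spiking_fit(
    params: SpikingNetworkParams,
    state0: SpikingState,
    task: TaskData,
    config: TrainingConfig,
) -> tuple[SpikingNetworkParams, TrainingHistory]:
    """FORCE training of a spiking layer's decoders.

    The filtered spike trains ``syn_r`` are the regression features; the
    decoders ``phi`` are updated by RLS every k-th step after the warm-up
    (forward-pass-only) period.  The decoded output feeds back through the
    encoders ``eta`` during both training and inference.
    """
    config.validate()
    params = dataclasses.replace(
        params,
        omega0=params.omega0.copy(),
        eta=params.eta.copy(),
        phi=params.phi.copy(),
        w_in=params.w_in.copy(),
    )
    f_out = task.f_out
    if f_out.shape[1] != params.m_out:
        raise ValueError("target dimension does not match decoder M_out")
    inputs = task.f_in if params.m_in else None
    t_steps = task.n_steps
    k = config.update_interval
    P = init_P(config.alpha, params.n_neurons)
    history = TrainingHistory()
    for epoch in range(config.epochs):
        tic = time.perf_counter()
        state = state0.copy()
        abs_err = 0.0
        n_upd = 0
        for t in range(t_steps):
            f_in_t = inputs[t] if inputs is not None else None
            state = step_spiking(params, state, f_in_t)
            e_pre = compute_error(state.z, f_out[t])
            abs_err += float(np.mean(np.abs(e_pre)))
            step_no = t + 1
            if _scheduled(step_no, config.warmup_steps, k):
                P = rls_update_P(P, state.syn_r)
                params.phi = update_output_weights(
                    params.phi, e_pre, P, state.syn_r
                )
                state.z = params.phi.T @ state.syn_r
                n_upd += 1
        _, val_mae = predict(params, task, state0=state0)
        history.train_mae.append(abs_err / t_steps)
        history.val_mae.append(val_mae)
        history.n_updates.append(n_upd)
        history.wall_time_s.append(time.perf_counter() - tic)
        if config.early_stopping is not None:
            if epoch == 0:
                best, stall = val_mae, 0
            else:
                best, stall, stop = _stop_early(
                    val_mae, best, stall, config.early_stopping
                )
                if stop:
                    break
    return params, history


# ---------------------------------------------------------------------------
# bio-constrained fitting


@dataclasses.dataclass
class BioFitResult:
    """Outcome of fitting a constrained network to recorded traces."""

    params: RateNetworkParams          # trained layer
    effective_weights: np.ndarray      # learned w_R, the effective connectivity
    history: TrainingHistory
    outputs: np.ndarray                # (T, N) rates from the final no-update pass
    scaled_traces: np.ndarray          # (T, N) traces after rescaling


def rescale_traces(
    traces: np.ndarray, activation: str = "tanh", margin: float = 0.95
) -> np.ndarray:
    """Scale traces into the activation's invertible range if they exceed it.

    For tanh the traces must lie strictly inside (-1, 1); if any sample
    falls outside ``margin`` times that range the whole array is scaled
    down uniformly (no offset, so zero stays zero and relative amplitudes
    are preserved).  Traces already in range are returned unchanged.
    """
    if activation != "tanh":
        return np.asarray(traces, dtype=float).copy()
    peak = float(np.max(np.abs(traces))) if traces.size else 0.0
    if peak <= margin:
        return np.asarray(traces, dtype=float).copy()
    return np.asarray(traces, dtype=float) * (margin / peak)


def _invert_rates(y: np.ndarray, activation: str) -> np.ndarray:
    """Map rates back to currents (x = H^-1(r)); clips tanh near +/-1."""
    if activation == "tanh":
        return np.arctanh(np.clip(y, -0.999, 0.999))
    return np.asarray(y, dtype=float).copy()


def state_from_traces(
    params: RateNetworkParams, trace_sample: np.ndarray
) -> RateNetworkState:
    """Network state whose rates match one (rescaled) trace sample."""
    x0 = _invert_rates(np.asarray(trace_sample, dtype=float), params.activation)
    h = params.activation_fn()
    r0 = h(x0)
    return RateNetworkState(x=x0, r=r0, z=params.w_out.T @ r0, step_index=0)


def bio_force_fit(
    params: RateNetworkParams,
    traces: np.ndarray,
    config: TrainingConfig,
    f_in: Optional[np.ndarray] = None,
    match: str = "currents",
) -> BioFitResult:
    """Fit a connectome-constrained rate network to recorded traces.

    Each model neuron is paired one-to-one with a recorded neuron; the
    network starts from the state implied by the first trace sample.
    Training is teacher-forced: the recorded rates (and the recorded
    input, when given) are the regressors at every step, which is the
    FORCE error clamp applied exactly — the model's presynaptic activity
    is pinned to the data it is being fitted to.  At every scheduled step
    each neuron i's incoming weights (recurrent weights restricted to its
    presynaptic set B(i), self-loops excluded, plus its input weights)
    are updated by per-neuron RLS.

    Two error conventions are available.  ``match='currents'`` (default)
    regresses the trace-implied current increment
    ``(x(t) - (1-dt/tau) x(t-1)) / (dt/tau)`` on the presynaptic rates —
    an exactly linear problem, so each per-neuron RLS converges to its
    ridge solution in a single pass.  ``match='rates'`` propagates the
    teacher-forced currents and applies the delta rule to the rate error
    ``H(x_i) - trace_i``; the update direction is the same but its
    magnitude is attenuated by the leak and activation slope, so more
    epochs are needed.

    Validation at each epoch end is a closed-loop pass (model's own rates,
    no updates) scored against the traces; early stopping per the config.
    After training one final closed-loop pass produces the reported
    outputs, and the learned ``w_R`` is returned as the effective weight
    matrix.
    """
    config.validate()
    if params.layer_kind != "constrained_esn":
        raise ValueError(
            f"bio_force_fit requires a constrained_esn layer, got "
            f"{params.layer_kind!r}"
        )
    if match not in ("currents", "rates"):
        raise ValueError("match must be 'currents' or 'rates'")
    traces = np.asarray(traces, dtype=float)
    if traces.ndim != 2 or traces.shape[1] != params.n_neurons:
        raise ValueError(
            f"traces must be T x N with N={params.n_neurons}, got "
            f"{traces.shape}"
        )
    params = _copy_params(params)
    n = params.n_neurons
    t_steps = traces.shape[0]
    if f_in is None:
        f_in = np.zeros((t_steps, params.m_in))
    f_in = np.asarray(f_in, dtype=float)
    if f_in.shape != (t_steps, params.m_in):
        raise ValueError(
            f"f_in must be ({t_steps}, {params.m_in}), got {f_in.shape}"
        )
    mask = params.connectivity_mask
    isolated = np.flatnonzero(~mask.any(axis=0))
    if len(isolated):
        warnings.warn(
            f"neurons {isolated.tolist()} have no presynaptic partners and "
            "are left untrained",
            stacklevel=2,
        )
    y = rescale_traces(traces, params.activation)
    xh = _invert_rates(y, params.activation)
    lam = params.dt / params.tau
    h = params.activation_fn()
    state0 = state_from_traces(params, y[0])
    m_in = params.m_in
    # per-neuron regressor = [presynaptic rates in B(i); input channels];
    # neurons with an empty B(i) are left entirely untrained
    ext_mask = np.vstack([mask, np.ones((m_in, n), dtype=bool)])
    ext_mask[:, isolated] = False
    family = init_recurrent_rls(ext_mask, config.alpha)
    k = config.update_interval
    history = TrainingHistory()

    def _closed_loop_pass() -> tuple[np.ndarray, float]:
        out = np.empty_like(y)
        out[0] = state0.r
        state = state0.copy()
        for t in range(1, t_steps):
            state = step_rate(params, state, f_in[t])
            out[t] = state.r
        return out, float(np.mean(np.abs(out[1:] - y[1:])))

    for epoch in range(config.epochs):
        tic = time.perf_counter()
        abs_err = 0.0
        n_upd = 0
        x_tf = xh[0].copy()  # teacher-forced currents ('rates' mode)
        for t in range(1, t_steps):
            reg = np.concatenate([y[t - 1], f_in[t]])
            drive = params.w_R.T @ y[t - 1] + params.w_in.T @ f_in[t]
            if match == "currents":
                target = (xh[t] - (1.0 - lam) * xh[t - 1]) / lam
                e_vec = drive - target
                abs_err += float(
                    np.mean(np.abs(h((1 - lam) * xh[t - 1] + lam * drive) - y[t]))
                )
            else:
                x_tf = (1.0 - lam) * x_tf + lam * drive
                e_vec = h(x_tf) - y[t]
                abs_err += float(np.mean(np.abs(e_vec)))
            if _scheduled(t, config.warmup_steps, k):
                us = _family_rls_step(family, reg)
                for i, (idx, u) in enumerate(zip(family.indices, us)):
                    if len(idx) == 0:
                        continue
                    step_vec = e_vec[i] * u
                    rec = idx < n
                    params.w_R[idx[rec], i] -= step_vec[rec]
                    params.w_in[idx[~rec] - n, i] -= step_vec[~rec]
                n_upd += 1
        _, val_mae = _closed_loop_pass()
        history.train_mae.append(abs_err / max(t_steps - 1, 1))
        history.val_mae.append(val_mae)
        history.n_updates.append(n_upd)
        history.wall_time_s.append(time.perf_counter() - tic)
        if config.early_stopping is not None:
            if epoch == 0:
                best, stall = val_mae, 0
            else:
                best, stall, stop = _stop_early(
                    val_mae, best, stall, config.early_stopping
                )
                if stop:
                    break
    outputs, _ = _closed_loop_pass()
    return BioFitResult(
        params=params,
        effective_weights=params.w_R.copy(),
        history=history,
        outputs=outputs,
        scaled_traces=y,
    )


# ---------------------------------------------------------------------------
# inference


def predict(
    params,
    task: TaskData,
    state0=None,
) -> tuple[np.ndarray, float]:
    """Forward pass with no updates; returns outputs and MAE vs. target.

    Accepts either a rate layer's params (with an optional initial rate
    state) or a spiking layer's params (initial state required).  The MAE
    is the mean absolute readout error over all steps and output
    dimensions.
    """
    f_out = task.f_out
    if isinstance(params, SpikingNetworkParams):
        if state0 is None:
            raise ValueError("spiking predict requires an initial state")
        state = state0.copy()
        zs = np.empty((task.n_steps, params.m_out))
        inputs = task.f_in if params.m_in else None
        for t in range(task.n_steps):
            f_in_t = inputs[t] if inputs is not None else None
            state = step_spiking(params, state, f_in_t)
            zs[t] = state.z
    else:
        if state0 is None:
            state0 = _zero_rate_state(params)
        inputs = _task_input(task, params.m_in)
        traj, _ = run_network(params, state0.copy(), inputs)
        zs = traj.z
    mae = float(np.mean(np.abs(zs - f_out)))
    return zs, mae
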