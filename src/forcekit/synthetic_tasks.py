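"""Synthetic task and recording generators.

Everything a FORCE trainer consumes can be generated here: a periodic
sum-of-sines target with a brief constant input cue, Lorenz-attractor
trajectories for autonomous spiking dynamics, delayed-response boxcar
input/target pairs, random structural connectomes, and teacher-network
"neural recordings" that emulate calcium-imaging-style population traces
(smooth, correlated rate time series from a recurrently connected brain
area, recorded on a coarse time grid with observation noise).

All generators are pure functions of their arguments including the seed.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Optional

import numpy as np

from .rate_layers import RateNetworkState, init_rate_network, run_network

__all__ = [
    "TaskData",
    "gen_sum_of_sines",
    "gen_lorenz",
    "gen_delayed_response",
    "gen_connectome",
    "gen_synthetic_recording",
    "save_task_csv",
    "load_task_csv",
]


@dataclasses.dataclass
class TaskData:
    """Input/target series on a shared time grid.

    ``f_in`` is (T, M_in), ``f_out`` (T, M_out), ``hint`` (T, M_hint) or
    None.  ``metadata`` records the generator name, seed and parameters.
    """

    f_in: np.ndarray
    f_out: np.ndarray
    dt: float
    hint: Optional[np.ndarray] = None
    metadata: dict = dataclasses.field(default_factory=dict)

    @property
    def n_steps(self) -> int:
        return self.f_out.shape[0]

    def validate(self) -> None:
        if self.f_in.shape[0] != self.f_out.shape[0]:
            raise ValueError("f_in and f_out must share T")
        if self.hint is not None and self.hint.shape[0] != self.n_steps:
            raise ValueError("hint must share T")
        for name in ("f_in", "f_out", "hint"):
            arr = getattr(self, name)
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")


def gen_sum_of_sines(
    n_steps: int = 801,
    n_input_on: int = 20,
    amplitude: float = 1.0,
    frequencies: Optional[list[float]] = None,
    seed: int = 0,
) -> TaskData:
    """Periodic sum-of-sines target with a constant input cue.

    The scalar input is constant (1.0) on the first ``n_input_on`` steps
    and zero thereafter; the network must then generate the target
    autonomously.  The default four components are harmonics 1, 2, 3, 5 of
    a 400-step base period (two base periods span the default 801-step
    window), with the sum normalized to peak amplitude ``amplitude``.  A
    dummy hint channel of zeros is included.
    """
    if frequencies is None:
        frequencies = [1.0 / 400, 2.0 / 400, 3.0 / 400, 5.0 / 400]
    if len(frequencies) == 0:
        raise ValueError("frequency list must be non-empty")
    if n_input_on > n_steps:
        raise ValueError("n_input_on cannot exceed n_steps")
    t = np.arange(n_steps, dtype=float)
    raw = np.zeros(n_steps)
    for f in frequencies:
        raw += np.sin(2.0 * np.pi * f * t)
    peak = np.max(np.abs(raw))
    f_out = (amplitude * raw / peak)[:, None] if peak > 0 else raw[:, None]
    f_in = np.zeros((n_steps, 1))
    f_in[:n_input_on, 0] = 1.0
    hint = np.zeros((n_steps, 1))
    task = TaskData(
        f_in=f_in,
        f_out=f_out,
        dt=1.0,
        hint=hint,
        metadata=dict(
            name="sum_of_sines",
            seed=seed,
            n_steps=n_steps,
            n_input_on=n_input_on,
            amplitude=amplitude,
            frequencies=list(frequencies),
        ),
    )
    task.validate()
    return task


def _lorenz_deriv(
    state: np.ndarray, sigma: float, rho: float, beta: float
) -> np.ndarray:
    x, y, z = state
    return np.array(
        [sigma * (y - x), x * (rho - z) - y, x * y - beta * z]
    )


def gen_lorenz(
    duration_s: float = 5.0,
    dt: float = 1e-4,
    sigma: float = 10.0,
    rho: float = 28.0,
    beta: float = 8.0 / 3.0,
    init: Optional[np.ndarray] = None,
    seed: int = 0,
    scale: float = 0.1,
) -> TaskData:
    """Integrate the Lorenz system with RK4 and return it as a 3-D target.

    The classical chaotic parameters are the defaults; the trajectory is
    rescaled by ``scale`` (default 1/10) so a tanh-range readout can match
    it.  The task is autonomous: ``f_in`` has zero input channels.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    n_steps = int(round(duration_s / dt))
    if init is None:
        rng = np.random.default_rng(seed)
        init = rng.uniform(-10.0, 10.0, size=3) + np.array([0.0, 0.0, 25.0])
    state = np.asarray(init, dtype=float).copy()
    traj = np.empty((n_steps, 3))
    for i in range(n_steps):
        k1 = _lorenz_deriv(state, sigma, rho, beta)
        k2 = _lorenz_deriv(state + 0.5 * dt * k1, sigma, rho, beta)
        k3 = _lorenz_deriv(state + 0.5 * dt * k2, sigma, rho, beta)
        k4 = _lorenz_deriv(state + dt * k3, sigma, rho, beta)
        state = state + (dt / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
        if not np.all(np.isfinite(state)):
            raise FloatingPointError(f"Lorenz integration blew up at step {i}")
        traj[i] = state
    task = TaskData(
        f_in=np.zeros((n_steps, 0)),
        f_out=scale * traj,
        dt=dt,
        metadata=dict(
            name="lorenz", seed=seed, duration_s=duration_s, dt=dt,
            sigma=sigma, rho=rho, beta=beta, scale=scale,
            init=list(np.asarray(init, dtype=float)),
        ),
    )
    task.validate()
    return task


def gen_delayed_response(
    duration_s: float = 5.0,
    dt: float = 1e-4,
    pulse_width_s: float = 0.5,
    delay_s: float = 0.05,
    seed: int = 0,
    amplitude: float = 1.0,
) -> TaskData:
    """Boxcar delayed-response pair: echo the input pulse after a delay.

    The input is a boxcar of ``pulse_width_s`` at a seeded random onset;
    the target is an identical boxcar starting ``delay_s`` after the input
    turns off.  Defaults: 5 s duration, 0.1 ms step, 0.5 s pulse, 50 ms
    delay (so the input is high for exactly 5000 samples and the target
    onset lags the input offset by 500 samples).
    """
    n_steps = int(round(duration_s / dt))
    pulse = int(round(pulse_width_s / dt))
    delay = int(round(delay_s / dt))
    latest_onset = n_steps - (2 * pulse + delay)
    if latest_onset < 0:
        raise ValueError(
            "input pulse, delay and response pulse do not fit in duration"
        )
    rng = np.random.default_rng(seed)
    onset = int(rng.integers(0, latest_onset + 1))
    f_in = np.zeros((n_steps, 1))
    f_in[onset : onset + pulse, 0] = amplitude
    f_out = np.zeros((n_steps, 1))
    target_onset = onset + pulse + delay
    f_out[target_onset : target_onset + pulse, 0] = amplitude
    task = TaskData(
        f_in=f_in,
        f_out=f_out,
        dt=dt,
        metadata=dict(
            name="delayed_response", seed=seed, duration_s=duration_s, dt=dt,
            pulse_width_s=pulse_width_s, delay_s=delay_s,
            onset_index=onset, target_onset_index=target_onset,
        ),
    )
    task.validate()
    return task


def gen_connectome(n_neurons: int, density: float = 1.0, seed: int = 0) -> np.ndarray:
    """Bernoulli(density) off-diagonal boolean mask with no self-loops."""
    if not 0.0 < density <= 1.0:
        raise ValueError("density must be in (0, 1]")
    rng = np.random.default_rng(seed)
    mask = rng.random((n_neurons, n_neurons)) < density
    np.fill_diagonal(mask, False)
    return mask


def gen_synthetic_recording(
    n_neurons: int = 365,
    n_steps: int = 2500,
    dt: float = 0.25,
    connectome_density: float = 1.0,
    teacher_gain: float = 1.2,
    noise_sd: float = 0.02,
    seed: int = 0,
    tau: Optional[float] = None,
    n_latents: int = 3,
    input_scale: float = 0.5,
    latent_tau: Optional[float] = None,
) -> tuple[TaskData, np.ndarray, np.ndarray]:
    """Simulate a known teacher network and return noisy rate traces.

    Emulates a single-brain-area population recording: by default 365
    neurons for 2500 steps at dt = 0.25 s, mirroring a larval-zebrafish
    subpallium dataset's dimensions.  A connectome-constrained rate
    network (teacher) with known weights is driven by a few slow latent
    inputs (Ornstein-Uhlenbeck processes with a ~50*dt timescale,
    standing in for sensory/state drive shared across the population);
    its rates plus additive Gaussian observation noise are the recorded
    traces.  The slow shared drive makes the traces smooth and correlated
    (lag-1 autocorrelation well above 0.5), as in calcium-indicator data,
    while keeping rates away from the activation's saturated range where
    observation noise would be unrecoverable.

    If the teacher settles into a fixed point (temporally degenerate
    traces), it is re-drawn with a new internal seed, at most 5 times.

    Returns ``(task, ground_truth_weights, mask)``: the traces are the
    task target, the latent drive is the task input.
    """
    if tau is None:
        tau = 2.0 * dt
    if latent_tau is None:
        latent_tau = 50.0 * dt
    mask = gen_connectome(n_neurons, connectome_density, seed)
    for attempt in range(5):
        teacher_seed = seed + 1000 * attempt
        params, _ = init_rate_network(
            n_neurons,
            "constrained_esn",
            sparsity=connectome_density,
            gain=teacher_gain,
            dims=(n_latents, 1),
            seed=teacher_seed,
            tau=tau,
            dt=dt,
            mask=mask,
            input_scale=input_scale,
        )
        rng = np.random.default_rng(teacher_seed + 1)
        latents = np.empty((n_steps, n_latents))
        lat = rng.normal(0.0, 1.0, size=n_latents)
        decay = 1.0 - dt / latent_tau
        kick = np.sqrt(2.0 * dt / latent_tau)
        for t in range(n_steps):
            lat = decay * lat + kick * rng.normal(0.0, 1.0, size=n_latents)
            latents[t] = lat
        x0 = rng.normal(0.0, 1.0, size=n_neurons)
        h = params.activation_fn()
        state = RateNetworkState(
            x=x0, r=h(x0), z=params.w_out.T @ h(x0), step_index=0
        )
        traj, _ = run_network(params, state, latents)
        late = traj.r[n_steps // 2 :]
        if float(np.mean(np.std(late, axis=0))) > 0.02:
            break
    else:
        raise RuntimeError(
            "teacher dynamics degenerate (fixed-point rates) after 5 attempts"
        )
    noise = (
        np.random.default_rng(teacher_seed + 2).normal(
            0.0, noise_sd, size=traj.r.shape
        )
        if noise_sd > 0
        else 0.0
    )
    traces = traj.r + noise
    task = TaskData(
        f_in=latents,
        f_out=traces,
        dt=dt,
        metadata=dict(
            name="synthetic_recording", seed=seed, n_neurons=n_neurons,
            n_steps=n_steps, dt=dt, connectome_density=connectome_density,
            teacher_gain=teacher_gain, noise_sd=noise_sd, tau=tau,
            n_latents=n_latents, input_scale=input_scale,
            latent_tau=latent_tau, teacher_seed=teacher_seed,
        ),
    )
    task.validate()
    return task, params.w_R, mask


# ---------------------------------------------------------------------------
# CSV round trip with a JSON sidecar for dt/seed/parameters


def save_task_csv(task: TaskData, path: str) -> None:
    """Write a TaskData as CSV plus a ``<path>.json`` metadata sidecar."""
    blocks = [("f_in", task.f_in), ("f_out", task.f_out)]
    if task.hint is not None:
        blocks.append(("hint", task.hint))
    header = ["time"]
    cols = [np.arange(task.n_steps) * task.dt]
    for name, arr in blocks:
        for j in range(arr.shape[1]):
            header.append(f"{name}_{j}")
            cols.append(arr[:, j])
    data = np.column_stack(cols) if cols else np.empty((0, 1))
    with open(path, "w", encoding="utf-8") as f:
        f.write(",".join(header) + "\n")
        for row in data:
            f.write(",".join(repr(float(v)) for v in row) + "\n")
    sidecar = dict(
        dt=task.dt,
        metadata=task.metadata,
        n_cols={name: int(arr.shape[1]) for name, arr in blocks},
    )
    with open(path + ".json", "w", encoding="utf-8") as f:
        json.dump(sidecar, f, indent=2, sort_keys=True)


def load_task_csv(path: str) -> TaskData:
    """Read a TaskData written by :func:`save_task_csv`."""
    with open(path + ".json", "r", encoding="utf-8") as f:
        sidecar = json.load(f)
    raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    n_cols = sidecar["n_cols"]
    offset = 1  # skip time column
    parts = {}
    for name in ("f_in", "f_out", "hint"):
        k = n_cols.get(name, 0)
        parts[name] = raw[:, offset : offset + k] if k else None
        offset += k
    task = TaskData(
        f_in=parts["f_in"] if parts["f_in"] is not None else np.zeros((raw.shape[0], 0)),
        f_out=parts["f_out"],
        dt=float(sidecar["dt"]),
        hint=parts["hint"],
        metadata=sidecar["metadata"],
    )
    task.validate()
    return task
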