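"""Spiking chaotic network layers: LIF, Izhikevich and theta neurons.

Each layer simulates ``N`` spiking neurons driven by a static random
recurrent weight matrix ``omega0`` (scaled by a gain ``G``), feedback of the
decoded readout ``z`` through fixed random encoders ``eta`` (scaled by
``Q``), an optional external input, and a constant bias current.  Spikes
are passed through a double-exponential synaptic filter; the filtered spike
trains ``syn_r`` play the role of the rate vector in FORCE training, and
the readout is ``z = phi^T syn_r`` with learned decoders ``phi``.

Voltage models (one Euler step per ``dt``):

LIF
    ``tau_m dv/dt = -(v - v_rest) + R*I``; spike and reset to ``v_reset``
    when ``v`` crosses ``v_thresh``, then absolute refractory ``t_ref``.
Izhikevich
    classic two-variable form ``dv/dt = 0.04 v^2 + 5v + 140 - u + I``,
    ``du/dt = a(bv - u)`` with time in milliseconds; spike at ``v_peak``,
    reset ``v <- c``, ``u <- u + d``.
Theta
    phase model ``dtheta/dt = (1 - cos theta) + (1 + cos theta) * I``; a
    spike is the phase crossing pi (the phase then wraps by -2*pi).  Under
    constant drive I > 0 the firing period is pi / sqrt(I).

The synaptic filter is the coupled pair

    dh/dt = -h / tau_r + s(t) / (tau_r * tau_d)
    dr/dt = -r / tau_d + h

integrated *exactly* (exponential integration) between spikes, so a single
spike produces the impulse response
``(exp(-t/tau_d) - exp(-t/tau_r)) / (tau_d - tau_r)`` to machine precision
on the step grid.
"""

from __future__ import annotations

import dataclasses
from typing import Optional

import numpy as np

__all__ = [
    "SPIKING_KINDS",
    "SpikingNetworkParams",
    "SpikingState",
    "SpikingTrajectory",
    "init_spiking_network",
    "initialize_voltage",
    "update_voltage",
    "step_spiking",
    "run_spiking_network",
    "spikes_to_csv",
]

SPIKING_KINDS = ("lif", "izhikevich", "theta")

# Per-kind default constants.  They place a few-hundred-neuron network in an
# asynchronous, spontaneously spiking regime at the default dt, which is the
# working point FORCE training needs (the chaotic reservoir must be active
# before decoders are learned).
_DEFAULTS = {
    "lif": dict(
        dt=5e-5, tau_m=0.01, v_rest=-65.0, v_thresh=-40.0, v_reset=-65.0,
        r_m=1.0, i_bias=30.0, t_ref=0.002,
    ),
    "izhikevich": dict(
        dt=1e-4, a=0.02, b=0.2, c=-65.0, d=8.0, v_peak=30.0,
        i_bias=10.0, t_ref=0.0,
    ),
    "theta": dict(
        dt=1e-4, i_bias=100.0, t_ref=0.0,
    ),
}


@dataclasses.dataclass
class SpikingNetworkParams:
    """Constants and weights of a spiking network.

    ``omega0`` is (N, N) with the ``(j, i)`` = j->i convention of the rate
    layers; ``eta`` is (M_out, N), ``phi`` (N, M_out), ``w_in`` (M_in, N).
    The total current each step is
    ``I = G * omega0^T syn_r + Q * eta^T z + w_in^T f_in + i_bias``.
    """

    model_kind: str
    n_neurons: int
    dt: float
    tau_r: float
    tau_d: float
    omega0: np.ndarray
    eta: np.ndarray
    phi: np.ndarray
    w_in: np.ndarray
    sparsity: float
    gain: float
    feedback_scale: float
    i_bias: float
    t_ref: float
    seed: int
    # LIF constants
    tau_m: float = 0.01
    v_rest: float = -65.0
    v_thresh: float = -40.0
    v_reset: float = -65.0
    r_m: float = 1.0
    # Izhikevich constants
    a: float = 0.02
    b: float = 0.2
    c: float = -65.0
    d: float = 8.0
    v_peak: float = 30.0

    @property
    def m_in(self) -> int:
        return self.w_in.shape[0]

    @property
    def m_out(self) -> int:
        return self.eta.shape[0]

    def validate(self) -> None:
        if self.model_kind not in SPIKING_KINDS:
            raise ValueError(f"unknown spiking model {self.model_kind!r}")
        if not (self.tau_d > self.tau_r > 0):
            raise ValueError("need tau_d > tau_r > 0")
        if self.dt <= 0 or self.dt > self.tau_r:
            raise ValueError("need 0 < dt <= tau_r for the synaptic filter")
        n = self.n_neurons
        if self.omega0.shape != (n, n):
            raise ValueError("omega0 must be N x N")
        if self.phi.shape != (n, self.m_out):
            raise ValueError("phi must be N x M_out")


@dataclasses.dataclass
class SpikingState:
    """Voltages/phases, refractory clocks, filter states and readout."""

    v: np.ndarray
    aux: np.ndarray
    refractory_until: np.ndarray  # step index until which each neuron is silent
    syn_r: np.ndarray
    syn_h: np.ndarray
    spiked: np.ndarray
    z: np.ndarray
    step_index: int = 0

    def copy(self) -> "SpikingState":
        return SpikingState(
            self.v.copy(), self.aux.copy(), self.refractory_until.copy(),
            self.syn_r.copy(), self.syn_h.copy(), self.spiked.copy(),
            self.z.copy(), self.step_index,
        )


@dataclasses.dataclass
class SpikingTrajectory:
    v: np.ndarray        # (T, N)
    syn_r: np.ndarray    # (T, N)
    z: np.ndarray        # (T, M_out)
    spikes: np.ndarray   # (n_spikes, 2): time_s, neuron_index


def init_spiking_network(
    n_neurons: int,
    model_kind: str,
    dims: tuple[int, int] = (0, 1),
    sparsity: float = 1.0,
    gain: float = 15.0,
    feedback_scale: float = 1.0,
    seed: int = 0,
    *,
    tau_r: float = 0.002,
    tau_d: float = 0.02,
    input_scale: float = 1.0,
    **overrides,
) -> tuple[SpikingNetworkParams, SpikingState]:
    """Build a seeded random spiking network with zero decoders.

    ``omega0`` entries are Bernoulli(``sparsity``) nonzero, drawn
    N(0, 1/(sparsity*N)); the gain ``G`` multiplies the recurrent current at
    run time.  Encoders ``eta`` are uniform in [-1, 1]; decoders ``phi``
    start at zero (they are what FORCE learns).  Keyword ``overrides``
    replace any per-kind membrane constant (``tau_m``, ``v_thresh``,
    ``i_bias``, ``a``/``b``/``c``/``d``, ``dt``, ``t_ref``, ...).
    """
    if model_kind not in SPIKING_KINDS:
        raise ValueError(
            f"unknown spiking model {model_kind!r}; expected one of "
            f"{SPIKING_KINDS}"
        )
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must be in (0, 1]")
    m_in, m_out = dims
    n = n_neurons
    consts = dict(_DEFAULTS[model_kind])
    unknown = set(overrides) - {
        "dt", "tau_m", "v_rest", "v_thresh", "v_reset", "r_m", "i_bias",
        "t_ref", "a", "b", "c", "d", "v_peak",
    }
    if unknown:
        raise TypeError(f"unknown spiking parameter(s): {sorted(unknown)}")
    consts.update(overrides)

    rng = np.random.default_rng(seed)
    pattern = rng.random((n, n)) < sparsity
    omega0 = np.where(
        pattern, rng.normal(0.0, 1.0 / np.sqrt(sparsity * n), size=(n, n)), 0.0
    )
    eta = rng.uniform(-1.0, 1.0, size=(m_out, n))
    w_in = input_scale * rng.uniform(-1.0, 1.0, size=(m_in, n))
    params = SpikingNetworkParams(
        model_kind=model_kind,
        n_neurons=n,
        tau_r=tau_r,
        tau_d=tau_d,
        omega0=omega0,
        eta=eta,
        phi=np.zeros((n, m_out)),
        w_in=w_in,
        sparsity=sparsity,
        gain=gain,
        feedback_scale=feedback_scale,
        seed=seed,
        **consts,
    )
    params.validate()
    v0 = initialize_voltage(params, seed)
    state = SpikingState(
        v=v0,
        aux=(params.b * v0 if model_kind == "izhikevich" else np.zeros(n)),
        refractory_until=np.zeros(n, dtype=np.int64),
        syn_r=np.zeros(n),
        syn_h=np.zeros(n),
        spiked=np.zeros(n, dtype=bool),
        z=np.zeros(m_out),
        step_index=0,
    )
    return params, state


def initialize_voltage(params: SpikingNetworkParams, seed: int) -> np.ndarray:
    """Seeded uniform initial voltages between reset and threshold.

    Theta neurons get phases uniform in (-pi, pi).
    """
    rng = np.random.default_rng(seed)
    n = params.n_neurons
    if params.model_kind == "theta":
        return rng.uniform(-np.pi, np.pi, size=n)
    if params.model_kind == "izhikevich":
        return rng.uniform(params.c, params.v_peak, size=n)
    return rng.uniform(params.v_reset, params.v_thresh, size=n)


def update_voltage(
    params: SpikingNetworkParams,
    current: np.ndarray,
    state: SpikingState,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """One Euler step of the voltage equation with spike detection/reset.

    Returns ``(v_new, spiked, aux_new)``.  Refractory neurons hold their
    voltage (LIF/Izhikevich: at reset; theta: phase hold) and cannot spike.
    """
    kind = params.model_kind
    dt = params.dt
    v = state.v
    refractory = state.refractory_until > state.step_index

    if kind == "lif":
        dv = (-(v - params.v_rest) + params.r_m * current) / params.tau_m
        v_new = v + dt * dv
        aux_new = state.aux
        spiked = (v_new >= params.v_thresh) & ~refractory
        v_new = np.where(spiked, params.v_reset, v_new)
        v_new = np.where(refractory, params.v_reset, v_new)
    elif kind == "izhikevich":
        dt_ms = dt * 1e3
        u = state.aux
        v_new = v + dt_ms * (0.04 * v * v + 5.0 * v + 140.0 - u + current)
        aux_new = u + dt_ms * params.a * (params.b * v - u)
        spiked = (v_new >= params.v_peak) & ~refractory
        v_new = np.where(spiked, params.c, v_new)
        aux_new = np.where(spiked, aux_new + params.d, aux_new)
        v_new = np.where(refractory, params.c, v_new)
    else:  # theta
        dtheta = (1.0 - np.cos(v)) + (1.0 + np.cos(v)) * current
        v_new = np.where(refractory, v, v + dt * dtheta)
        aux_new = state.aux
        spiked = (v_new >= np.pi) & ~refractory
        v_new = np.where(spiked, v_new - 2.0 * np.pi, v_new)

    if not np.all(np.isfinite(v_new)):
        raise FloatingPointError(
            f"non-finite voltage at step {state.step_index + 1}"
        )
    return v_new, spiked, aux_new


def _filter_decay(params: SpikingNetworkParams) -> tuple[float, float, float]:
    """Exact one-step propagator of the double-exponential filter."""
    ed = np.exp(-params.dt / params.tau_d)
    er = np.exp(-params.dt / params.tau_r)
    # r(t+dt) = ed*r + coupling*h ; h(t+dt) = er*h
    coupling = (ed - er) * params.tau_r * params.tau_d / (
        params.tau_d - params.tau_r
    )
    return ed, er, coupling


def step_spiking(
    params: SpikingNetworkParams,
    state: SpikingState,
    f_in_t: Optional[np.ndarray] = None,
) -> SpikingState:
    """Advance the spiking network one step.

    Current assembly uses the previous step's filtered rates and readout;
    the new spikes are injected into the synaptic filter (``syn_h`` jumps
    by ``1/(tau_r*tau_d)`` per spike) after the exact exponential decay
    over ``dt``, and the readout is refreshed as ``z = phi^T syn_r``.
    """
    current = params.gain * (params.omega0.T @ state.syn_r) + params.i_bias
    if params.m_out:
        current = current + params.feedback_scale * (params.eta.T @ state.z)
    if params.m_in:
        if f_in_t is None:
            raise ValueError("network expects an input but none was given")
        f_in_t = np.atleast_1d(np.asarray(f_in_t, dtype=float))
        if f_in_t.shape[0] != params.m_in:
            raise ValueError(
                f"input has length {f_in_t.shape[0]}, expected {params.m_in}"
            )
        current = current + params.w_in.T @ f_in_t

    v_new, spiked, aux_new = update_voltage(params, current, state)
    ref_steps = int(round(params.t_ref / params.dt))
    refractory_until = np.where(
        spiked, state.step_index + 1 + ref_steps, state.refractory_until
    )

    ed, er, coupling = _filter_decay(params)
    syn_r = ed * state.syn_r + coupling * state.syn_h
    syn_h = er * state.syn_h + spiked / (params.tau_r * params.tau_d)
    z = params.phi.T @ syn_r

    return SpikingState(
        v=v_new,
        aux=aux_new,
        refractory_until=refractory_until,
        syn_r=syn_r,
        syn_h=syn_h,
        spiked=spiked,
        z=z,
        step_index=state.step_index + 1,
    )


def run_spiking_network(
    params: SpikingNetworkParams,
    state: SpikingState,
    n_steps: int,
    input_series: Optional[np.ndarray] = None,
    record: bool = True,
) -> tuple[Optional[SpikingTrajectory], SpikingState]:
    """Forward-simulate ``n_steps`` with no training."""
    if input_series is not None:
        input_series = np.asarray(input_series, dtype=float)
        if input_series.shape[0] < n_steps:
            raise ValueError("input series shorter than n_steps")
    if record:
        vs = np.empty((n_steps, params.n_neurons))
        rs = np.empty((n_steps, params.n_neurons))
        zs = np.empty((n_steps, params.m_out))
        spike_times: list[tuple[float, int]] = []
    for t in range(n_steps):
        f_in_t = input_series[t] if input_series is not None else None
        state = step_spiking(params, state, f_in_t)
        if record:
            vs[t] = state.v
            rs[t] = state.syn_r
            zs[t] = state.z
            for idx in np.flatnonzero(state.spiked):
                spike_times.append((state.step_index * params.dt, int(idx)))
    if not record:
        return None, state
    spikes = (
        np.array(spike_times, dtype=float)
        if spike_times
        else np.empty((0, 2))
    )
    return SpikingTrajectory(vs, rs, zs, spikes), state


def spikes_to_csv(spikes: np.ndarray, path: str) -> None:
    """Write a spike raster as two-column CSV (time_s, neuron_index)."""
    with open(path, "w", encoding="utf-8") as f:
        f.write("time_s,neuron_index\n")
        for t, i in spikes:
            f.write(f"{t!r},{int(i)}\n")
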