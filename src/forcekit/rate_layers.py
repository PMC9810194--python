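"""Rate-based chaotic recurrent network layers.

A rate layer is a dynamical system of ``N`` neurons with currents ``x(t)``
and rates ``r(t) = H(x(t))`` driven by an input series, its own recurrent
activity and (optionally) feedback of its linear readout
``z(t) = w_out^T r(t)``.  The discrete forward pass is a forward-Euler step
of the standard leaky reservoir equation

    x(t) = x(t-dt) + (dt/tau) * ( -x(t-dt) + w_in^T f_in(t)
                                  + w_R^T r(t-dt) + w_F^T z(t-dt) )

Three variants are provided:

``feedback_esn``
    classic echo-state architecture with readout feedback through ``w_F``.
``nofeedback_esn``
    same dynamics with ``w_F = 0``; the reservoir evolves independently of
    the readout, which makes it the natural substrate for full-FORCE
    training.
``constrained_esn``
    a no-feedback network whose recurrent weights are restricted to a
    structural connectivity mask with an empty diagonal (no self-loops),
    used to fit recorded neural activity.

Forward dynamics are deliberately independent of any training rule; the
trainers in :mod:`forcekit.force_training` consume these layers.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Optional

import h5py
import numpy as np
import scipy.io
import scipy.sparse

__all__ = [
    "ACTIVATIONS",
    "LAYER_KINDS",
    "RateNetworkParams",
    "RateNetworkState",
    "Trajectory",
    "init_rate_network",
    "step_rate",
    "run_network",
    "save_rate_network",
    "load_rate_network",
    "load_mask_mtx",
    "save_mask_mtx",
]

#: Named activation functions H.  Pluggable: registries map a config string
#: to an elementwise callable.
ACTIVATIONS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "tanh": np.tanh,
    "identity": lambda x: np.asarray(x, dtype=float),
    "relu": lambda x: np.maximum(x, 0.0),
}

LAYER_KINDS = ("feedback_esn", "nofeedback_esn", "constrained_esn")


@dataclasses.dataclass
class RateNetworkParams:
    """Weights and constants of a rate network.

    Weight shape conventions (all dense float64 arrays):

    - ``w_in``  : (M_in, N)  input weights
    - ``w_R``   : (N, N)     recurrent weights; entry ``(j, i)`` is the
      weight of the connection from neuron ``j`` onto neuron ``i``, so the
      recurrent current into the network is ``w_R.T @ r``
    - ``w_out`` : (N, M_out) readout weights
    - ``w_F``   : (M_out, N) feedback weights

    ``connectivity_mask[j, i]`` is True iff ``j`` is presynaptic to ``i``;
    ``w_R`` is exactly zero wherever the mask is False.
    """

    n_neurons: int
    tau: float
    dt: float
    activation: str
    w_in: np.ndarray
    w_R: np.ndarray
    w_out: np.ndarray
    w_F: np.ndarray
    connectivity_mask: np.ndarray
    sparsity: float
    gain: float
    layer_kind: str
    seed: int

    @property
    def m_in(self) -> int:
        return self.w_in.shape[0]

    @property
    def m_out(self) -> int:
        return self.w_out.shape[1]

    def activation_fn(self) -> Callable[[np.ndarray], np.ndarray]:
        return ACTIVATIONS[self.activation]

    def validate(self) -> None:
        n = self.n_neurons
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.tau < self.dt:
            raise ValueError("tau must be >= dt for a stable Euler step")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")
        if self.w_R.shape != (n, n):
            raise ValueError("w_R must be N x N")
        if self.connectivity_mask.shape != (n, n):
            raise ValueError("connectivity_mask shape mismatch")
        if self.w_in.shape[1] != n or self.w_F.shape[1] != n:
            raise ValueError("w_in / w_F must have N columns")
        if self.w_out.shape[0] != n:
            raise ValueError("w_out must have N rows")
        if self.w_out.shape[1] != self.w_F.shape[0]:
            raise ValueError("w_out and w_F disagree on output dimension")
        if np.any(self.w_R[~self.connectivity_mask] != 0.0):
            raise ValueError("w_R has nonzero entries outside the mask")
        if self.layer_kind == "constrained_esn" and np.any(
            np.diag(self.connectivity_mask)
        ):
            raise ValueError("constrained layer mask must exclude self-loops")


@dataclasses.dataclass
class RateNetworkState:
    """Instantaneous state: currents ``x``, rates ``r``, readout ``z``."""

    x: np.ndarray
    r: np.ndarray
    z: np.ndarray
    step_index: int = 0

    def copy(self) -> "RateNetworkState":
        return RateNetworkState(
            self.x.copy(), self.r.copy(), self.z.copy(), self.step_index
        )


@dataclasses.dataclass
class Trajectory:
    """Recorded (T, ...) arrays of a simulated run."""

    x: np.ndarray
    r: np.ndarray
    z: np.ndarray


def _copy_params(params: RateNetworkParams) -> RateNetworkParams:
    return dataclasses.replace(
        params,
        w_in=params.w_in.copy(),
        w_R=params.w_R.copy(),
        w_out=params.w_out.copy(),
        w_F=params.w_F.copy(),
        connectivity_mask=params.connectivity_mask.copy(),
    )


def init_rate_network(
    n_neurons: int,
    layer_kind: str,
    sparsity: float = 1.0,
    gain: float = 1.5,
    dims: tuple[int, int] = (1, 1),
    seed: int = 0,
    *,
    tau: float = 10.0,
    dt: float = 1.0,
    activation: str = "tanh",
    mask: Optional[np.ndarray] = None,
    input_scale: float = 1.0,
    feedback_scale: float = 1.0,
    w_out_init: str = "uniform",
) -> tuple[RateNetworkParams, RateNetworkState]:
    """Draw a seeded random rate network and its zero initial state.

    Recurrent weights are nonzero with probability ``sparsity`` and drawn
    zero-mean normal with standard deviation ``gain / sqrt(sparsity * N)``
    (for gain > 1 the network is in the chaotic regime).  ``w_in`` and
    ``w_F`` are uniform in [-1, 1] times their scale factors.  ``w_out`` is
    either small uniform (``'uniform'``, scaled by 1/sqrt(N)) or exactly
    zero (``'zeros'``).

    Parameters
    ----------
    dims
        ``(M_in, M_out)`` input and output dimensions.
    mask
        Boolean (N, N) connectivity mask.  Required semantics for
        ``constrained_esn``: False diagonal.  If omitted for the
        constrained kind, a dense off-diagonal mask is used; for the other
        kinds the mask is the drawn Bernoulli sparsity pattern.
    """
    if layer_kind not in LAYER_KINDS:
        raise ValueError(
            f"unknown layer kind {layer_kind!r}; expected one of {LAYER_KINDS}"
        )
    if not 0.0 < sparsity <= 1.0:
        raise ValueError("sparsity must be in (0, 1]")
    if w_out_init not in ("uniform", "zeros"):
        raise ValueError("w_out_init must be 'uniform' or 'zeros'")
    m_in, m_out = dims
    n = n_neurons
    rng = np.random.default_rng(seed)

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (n, n):
            raise ValueError(
                f"mask shape {mask.shape} does not match N={n}"
            )
    if layer_kind == "constrained_esn":
        if mask is None:
            mask = ~np.eye(n, dtype=bool)
        if np.any(np.diag(mask)):
            raise ValueError("constrained mask must have a False diagonal")
        conn = mask
    else:
        pattern = rng.random((n, n)) < sparsity
        conn = pattern if mask is None else (pattern & mask)

    sd = gain / np.sqrt(sparsity * n)
    w_R = np.where(conn, rng.normal(0.0, sd, size=(n, n)), 0.0)
    w_in = input_scale * rng.uniform(-1.0, 1.0, size=(m_in, n))
    w_F = feedback_scale * rng.uniform(-1.0, 1.0, size=(m_out, n))
    if layer_kind in ("nofeedback_esn", "constrained_esn"):
        w_F = np.zeros_like(w_F)
    if w_out_init == "zeros":
        w_out = np.zeros((n, m_out))
    else:
        w_out = rng.uniform(-1.0, 1.0, size=(n, m_out)) / np.sqrt(n)

    params = RateNetworkParams(
        n_neurons=n,
        tau=tau,
        dt=dt,
        activation=activation,
        w_in=w_in,
        w_R=w_R,
        w_out=w_out,
        w_F=w_F,
        connectivity_mask=conn,
        sparsity=sparsity,
        gain=gain,
        layer_kind=layer_kind,
        seed=seed,
    )
    params.validate()
    h = params.activation_fn()
    x0 = np.zeros(n)
    r0 = h(x0)
    state = RateNetworkState(x=x0, r=r0, z=w_out.T @ r0, step_index=0)
    return params, state


def step_rate(
    params: RateNetworkParams,
    state: RateNetworkState,
    f_in_t: np.ndarray,
) -> RateNetworkState:
    """Advance the network one Euler step.

    Feedback uses the readout from the *previous* step (``state.z``); the
    returned state satisfies ``r = H(x)`` and ``z = w_out^T r``.
    """
    f_in_t = np.atleast_1d(np.asarray(f_in_t, dtype=float))
    if f_in_t.shape[0] != params.m_in:
        raise ValueError(
            f"input has length {f_in_t.shape[0]}, expected M_in={params.m_in}"
        )
    leak = params.dt / params.tau
    drive = (
        params.w_in.T @ f_in_t
        + params.w_R.T @ state.r
        + params.w_F.T @ state.z
    )
    x = state.x + leak * (-state.x + drive)
    if not np.all(np.isfinite(x)):
        raise FloatingPointError(
            f"non-finite currents at step {state.step_index + 1}: "
            "network dynamics blew up"
        )
    r = params.activation_fn()(x)
    z = params.w_out.T @ r
    return RateNetworkState(x=x, r=r, z=z, step_index=state.step_index + 1)


def run_network(
    params: RateNetworkParams,
    state: RateNetworkState,
    input_series: np.ndarray,
    record: bool = True,
) -> tuple[Optional[Trajectory], RateNetworkState]:
    """Run the forward pass over a (T, M_in) input series; no training.

    Returns the recorded trajectory (or None if ``record`` is False) and
    the final state.  An empty series is the identity.
    """
    input_series = np.asarray(input_series, dtype=float)
    if input_series.ndim == 1:
        input_series = input_series[:, None]
    t_steps = input_series.shape[0]
    if record:
        xs = np.empty((t_steps, params.n_neurons))
        rs = np.empty((t_steps, params.n_neurons))
        zs = np.empty((t_steps, params.m_out))
    for t in range(t_steps):
        state = step_rate(params, state, input_series[t])
        if record:
            xs[t] = state.x
            rs[t] = state.r
            zs[t] = state.z
    if not record:
        return None, state
    if t_steps == 0:
        return Trajectory(
            np.empty((0, params.n_neurons)),
            np.empty((0, params.n_neurons)),
            np.empty((0, params.m_out)),
        ), state
    return Trajectory(xs, rs, zs), state


# ---------------------------------------------------------------------------
# serialization


def save_rate_network(params: RateNetworkParams, path: str) -> None:
    """Write the weight matrices and mask to an HDF5 container."""
    with h5py.File(path, "w") as f:
        # track_times=False keeps identical reruns byte-identical
        f.create_dataset("w_in", data=params.w_in, track_times=False)
        f.create_dataset("w_R", data=params.w_R, track_times=False)
        f.create_dataset("w_out", data=params.w_out, track_times=False)
        f.create_dataset("w_F", data=params.w_F, track_times=False)
        f.create_dataset(
            "mask",
            data=params.connectivity_mask.astype(np.uint8),
            track_times=False,
        )
        for key in ("n_neurons", "tau", "dt", "sparsity", "gain", "seed"):
            f.attrs[key] = getattr(params, key)
        f.attrs["activation"] = params.activation
        f.attrs["layer_kind"] = params.layer_kind


def load_rate_network(path: str) -> tuple[RateNetworkParams, RateNetworkState]:
    """Load a network saved by :func:`save_rate_network`."""
    with h5py.File(path, "r") as f:
        params = RateNetworkParams(
            n_neurons=int(f.attrs["n_neurons"]),
            tau=float(f.attrs["tau"]),
            dt=float(f.attrs["dt"]),
            activation=str(f.attrs["activation"]),
            w_in=f["w_in"][...],
            w_R=f["w_R"][...],
            w_out=f["w_out"][...],
            w_F=f["w_F"][...],
            connectivity_mask=f["mask"][...].astype(bool),
            sparsity=float(f.attrs["sparsity"]),
            gain=float(f.attrs["gain"]),
            layer_kind=str(f.attrs["layer_kind"]),
            seed=int(f.attrs["seed"]),
        )
    params.validate()
    h = params.activation_fn()
    x0 = np.zeros(params.n_neurons)
    state = RateNetworkState(
        x=x0, r=h(x0), z=params.w_out.T @ h(x0), step_index=0
    )
    return params, state


def load_mask_mtx(path: str) -> np.ndarray:
    """Read a boolean connectivity mask from a Matrix Market file."""
    m = scipy.io.mmread(path)
    if scipy.sparse.issparse(m):
        m = m.toarray()
    return np.asarray(m) != 0


def save_mask_mtx(mask: np.ndarray, path: str) -> None:
    """Write a boolean mask as a sparse Matrix Market file (1-based)."""
    scipy.io.mmwrite(path, scipy.sparse.coo_matrix(mask.astype(np.int8)))
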