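"""Conduction model: Thiran all-pass filters between neighbor voxels.

The current density of a voxel is predicted from the delayed, gain-mixed
current densities of its neighbors plus a control drive:

    j_v(n) = sum_o C_{v,o} y_{v,o}(n) + b_v u(n)

Each directed connection (source voxel o -> target voxel v) carries a
first-order Thiran all-pass filter realizing a group delay of tau samples,
split into an integer part ``k`` and a fractional part encoded by the
all-pass coefficient ``a = (1 - frac) / (1 + frac)``.  The filter has unit
magnitude response everywhere and approximately constant group delay below
fs/10, so an impulse travelling through a chain of connections arrives with
the accumulated conduction delay but unchanged shape.

The nine gains of a connection share one coefficient ``a``, and the three
distinct filter input signals are the source voxel's three current-density
components; a connection therefore tracks three filter output channels.

Two recursion conventions are available:

``group_delay`` (default)
    ``y(n) = a * (x(n-k) - y(n-1)) + x(n-k-1)``, i.e.
    ``H(z) = z^-k (a + z^-1) / (1 + a z^-1)`` with DC group delay
    ``k + (1-a)/(1+a) = tau``.
``printed``
    The same recursion with inputs shifted one sample further
    (``x(n-k-1)``/``x(n-k-2)``), realizing ``tau + 1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import scipy.sparse as sp


def thiran_coefficients(tau: float) -> tuple[int, float]:
    """Split a group delay ``tau`` (samples, >= 1) into (integer delay, coefficient).

    ``a = (1 - frac(tau)) / (1 + frac(tau))``; the round trip
    ``k + (1 - a)/(1 + a)`` recovers ``tau`` exactly.
    """
    if tau < 1.0:
        raise ValueError(f"Thiran group delay must be >= 1 sample, got {tau}")
    k = int(np.floor(tau))
    frac = tau - k
    a = (1.0 - frac) / (1.0 + frac)
    return k, float(a)


def realized_delay(k: int, a: float) -> float:
    """DC group delay of a first-order Thiran section, ``k + (1-a)/(1+a)``."""
    return k + (1.0 - a) / (1.0 + a)


@dataclass(frozen=True)
class APTemplateParams:
    """Phenomenological action-potential template (all times in ms).

    A smoothstep depolarization rise, a flat plateau, and an exponential
    repolarization tail.  Only the normalization of its derivative matters to
    the estimation algorithm.  The default rise time is the *voxel-aggregate*
    upstroke: the cellular upstroke (~1-2 ms) convolved with the ~2.3 ms the
    wavefront needs to traverse a 2.5 mm voxel at 1.1 m/s.
    """

    onset_ms: float = 10.0
    rise_ms: float = 5.0
    plateau_ms: float = 200.0
    repol_ms: float = 100.0


@dataclass(frozen=True)
class ControlFunction:
    """Discrete control drive ``u(n)``: the normalized derivative of the
    action-potential template, peak value 1 (normalized current-density unit,
    nominally A/mm²)."""

    waveform: np.ndarray
    fs: float
    params: APTemplateParams

    @property
    def n_samples(self) -> int:
        return self.waveform.shape[0]


def ap_template(t_ms: np.ndarray, params: APTemplateParams) -> np.ndarray:
    """Evaluate the action-potential template (arbitrary amplitude) at ``t_ms``."""
    t = np.asarray(t_ms, dtype=float)
    s = np.clip((t - params.onset_ms) / params.rise_ms, 0.0, 1.0)
    rise = s * s * (3.0 - 2.0 * s)  # C1 smoothstep
    t_fall = params.onset_ms + params.rise_ms + params.plateau_ms
    envelope = np.where(t <= t_fall, 1.0, np.exp(-(t - t_fall) / params.repol_ms))
    return rise * envelope


def make_control_function(params: APTemplateParams, Nm: int, fs: float) -> ControlFunction:
    """Differentiate the AP template and scale the result to a peak of 1."""
    if min(params.rise_ms, params.plateau_ms, params.repol_ms) <= 0 or params.onset_ms < 0:
        raise ValueError(f"degenerate AP template durations: {params}")
    duration_ms = Nm / fs * 1e3
    if params.onset_ms + params.rise_ms + params.plateau_ms >= duration_ms:
        raise ValueError(
            f"AP template ({params.onset_ms}+{params.rise_ms}+{params.plateau_ms} ms) "
            f"does not fit in {duration_ms} ms"
        )
    t = np.arange(Nm + 1) / fs * 1e3  # ms
    v = ap_template(t, params)
    u = np.diff(v) * fs  # derivative, evaluated at sample n from (v(n) - v(n-1))
    u = np.concatenate([[0.0], u[:-1]])
    peak = np.max(u)
    if peak <= 0:
        raise ValueError("AP template produced a non-positive derivative peak")
    return ControlFunction(waveform=u / peak, fs=float(fs), params=params)


@dataclass
class StateSpaceModel:
    """Complete conduction model over a voxel grid.

    Connections are stored struct-of-arrays: entry ``c`` is the directed link
    ``conn_source[c] -> conn_target[c]`` with integer delay ``conn_delay[c]``,
    all-pass coefficient ``conn_a[c]`` and 3x3 gain block ``conn_gain[c]``
    (rows: target component, columns: source component).  A self-slot
    (source == target) exists for every voxel so refinement can populate it.

    ``control_vector`` is the length-``3*Nv`` drive vector ``b`` (a single 1
    at the x-component of the sinoatrial origin), ``control`` the shared
    drive waveform ``u``.
    """

    n_voxels: int
    fs: float
    conn_target: np.ndarray
    conn_source: np.ndarray
    conn_delay: np.ndarray
    conn_a: np.ndarray
    conn_gain: np.ndarray
    control_vector: np.ndarray
    control: ControlFunction
    convention: str = "group_delay"

    def __post_init__(self):
        if self.convention not in ("group_delay", "printed"):
            raise ValueError(f"unknown all-pass convention {self.convention!r}")

    @property
    def n_connections(self) -> int:
        return self.conn_target.shape[0]

    @property
    def n_states(self) -> int:
        return 3 * self.n_voxels

    def copy(self) -> "StateSpaceModel":
        return replace(
            self,
            conn_delay=self.conn_delay.copy(),
            conn_a=self.conn_a.copy(),
            conn_gain=self.conn_gain.copy(),
            control_vector=self.control_vector.copy(),
        )

    def output_matrix(self) -> sp.csr_matrix:
        """Sparse map from stacked all-pass outputs (3 per connection) to the
        3*Nv state vector: entry ((3*target + j), (3*c + k)) = gain[c, j, k]."""
        nc = self.n_connections
        rows = (3 * self.conn_target[:, None, None] + np.arange(3)[None, :, None]) * np.ones(
            (1, 1, 3), dtype=np.int64
        )
        cols = (3 * np.arange(nc)[:, None, None] + np.arange(3)[None, None, :]) * np.ones(
            (1, 3, 1), dtype=np.int64
        )
        mat = sp.coo_matrix(
            (self.conn_gain.ravel(), (rows.ravel(), cols.ravel())),
            shape=(self.n_states, 3 * nc),
        ).tocsr()
        mat.eliminate_zeros()
        return mat

    def gain_matrix(self) -> sp.csr_matrix:
        """Sparse 3*Nv x 3*Nv matrix of gains: entry (3i+j, 3o+k) = c_{j,k} of
        the connection o -> i.  Used as the one-step transition in the
        covariance recursion."""
        nc = self.n_connections
        rows = np.repeat(3 * self.conn_target, 9) + np.tile(np.repeat(np.arange(3), 3), nc)
        cols = np.repeat(3 * self.conn_source, 9) + np.tile(np.tile(np.arange(3), 3), nc)
        mat = sp.coo_matrix(
            (self.conn_gain.ravel(), (rows, cols)), shape=(self.n_states, self.n_states)
        ).tocsr()
        mat.eliminate_zeros()
        return mat


class AllpassBank:
    """Runtime state of all connection filters of a model.

    ``step(n, history)`` consumes the trajectory history (rows < n must be
    filled with whatever signal feeds the delay lines: open-loop predictions
    during simulation, corrected estimates inside the Kalman filter) and
    returns the (Nc, 3) all-pass outputs y(n).
    """

    def __init__(self, model: StateSpaceModel):
        self.model = model
        nc = model.n_connections
        self.y_prev = np.zeros((nc, 3))
        self.src_cols = 3 * model.conn_source[:, None] + np.arange(3)[None, :]
        shift = 0 if model.convention == "group_delay" else 1
        self.lag1 = model.conn_delay + shift  # x(n - k [-1])
        self.lag2 = self.lag1 + 1

    def reset(self):
        self.y_prev[:] = 0.0

    def _gather(self, n: int, lag: np.ndarray, history: np.ndarray) -> np.ndarray:
        idx = n - lag
        valid = idx >= 0
        x = history[np.clip(idx, 0, None)[:, None], self.src_cols]
        x[~valid] = 0.0
        return x

    #: magnitudes below this are flushed to zero: the recursion decays
    #: geometrically on silent inputs and subnormal arithmetic is slow
    _FLUSH = 1e-30

    def step(self, n: int, history: np.ndarray) -> np.ndarray:
        x1 = self._gather(n, self.lag1, history)
        x2 = self._gather(n, self.lag2, history)
        y = self.model.conn_a[:, None] * (x1 - self.y_prev) + x2
        y[np.abs(y) < self._FLUSH] = 0.0
        self.y_prev = y
        return y

    def step_with_sensitivity(
        self, n: int, history: np.ndarray, dy_prev: np.ndarray
    ) -> tuple[np.ndarray, np.ndarray]:
        """One step plus the recursion for dy/da (shared per connection).

        dy/da(n) = (x(n-k) - y(n-1)) - a * dy/da(n-1), the analytic
        derivative of the recursion with the input signal held fixed.
        """
        x1 = self._gather(n, self.lag1, history)
        x2 = self._gather(n, self.lag2, history)
        a = self.model.conn_a[:, None]
        dy = (x1 - self.y_prev) - a * dy_prev
        y = a * (x1 - self.y_prev) + x2
        y[np.abs(y) < self._FLUSH] = 0.0
        dy[np.abs(dy) < self._FLUSH] = 0.0
        self.y_prev = y
        return y, dy


def allpass_apply(x: np.ndarray, tau: float, convention: str = "group_delay") -> np.ndarray:
    """Filter a 1-D signal through a single Thiran section of group delay ``tau``.

    Reference implementation used for filter-level tests; zero initial state.
    """
    k, a = thiran_coefficients(tau)
    x = np.asarray(x, dtype=float)
    shift = 0 if convention == "group_delay" else 1
    y = np.zeros_like(x)
    y_prev = 0.0
    for n in range(x.shape[0]):
        i1 = n - k - shift
        i2 = i1 - 1
        x1 = x[i1] if i1 >= 0 else 0.0
        x2 = x[i2] if i2 >= 0 else 0.0
        y[n] = a * (x1 - y_prev) + x2
        y_prev = y[n]
    return y


class Rollout:
    """Incremental forward evaluation of a model.

    Maintains the all-pass bank and the trajectory history; ``predict(n)``
    returns j(n) from the history rows < n, after which the caller stores
    either the prediction itself (open loop) or a corrected estimate via
    ``commit``.
    """

    def __init__(self, model: StateSpaceModel, Nm: int):
        self.model = model
        self.Nm = Nm
        self.bank = AllpassBank(model)
        self.history = np.zeros((max(Nm, 1), model.n_states))
        self.G_y = model.output_matrix()
        u = model.control.waveform
        if Nm > u.shape[0]:
            u = np.concatenate([u, np.zeros(Nm - u.shape[0])])
        self.u = u
        self.last_y: np.ndarray | None = None

    def predict(self, n: int) -> np.ndarray:
        y = self.bank.step(n, self.history)
        self.last_y = y
        return self.G_y @ y.reshape(-1) + self.model.control_vector * self.u[n]

    def commit(self, n: int, j: np.ndarray) -> None:
        self.history[n] = j


def simulate(model: StateSpaceModel, Nm: int) -> np.ndarray:
    """Open-loop rollout of the model for ``Nm`` steps; returns ``(Nm, 3*Nv)``."""
    if Nm == 0:
        return np.zeros((0, model.n_states))
    roll = Rollout(model, Nm)
    for n in range(Nm):
        roll.commit(n, roll.predict(n))
    return roll.history
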