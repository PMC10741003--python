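"""Gradient-descent refinement of the conduction model.

One refinement epoch re-runs the model forward with the delay lines fed by
the Kalman-filtered trajectory, compares the predicted measurements against
the measured ones, and descends the loss

    L(n) = Lm(n) + gamma * Lv(n)
    Lm(n) = 1/Ns sum_k (z_k - z_hat_k)^2
    Lv(n) = sum_v max(0, ||j_v||_1 - threshold)^2

with respect to every connection gain c and every all-pass coefficient a.
The gain gradient is closed-form (the forward pass is linear in c given the
filter outputs); the coefficient gradient needs the recursive sensitivity
dy/da of the all-pass output, accumulated alongside the forward pass.  The
constraint term contributes to the gain gradient only.

Updates are full-batch: gradients are summed over all Nm samples and applied
once per epoch with step eta / Nm.  Out-of-range coefficients are wrapped by
trading a unit of fractional delay against the integer delay (a < 0 becomes
a + 1 with k + 1; a > 1 becomes a - 1 with k - 1 while k >= 1, else a = 1),
which keeps the realized group delay continuous at the boundary.

Unit convention: measurement residuals are expressed in units of 1e-10 T
(``measurement_unit_scale`` = 1e10 from tesla), i.e. normalized to the order
of the R-peak amplitude.  This is the scale on which the reference learning
rate eta = 200 is meaningful: a full optimization (eta * epochs ~ 4e5 sample
updates) moves gains by O(1), and a ~1 pT residual corresponds to a
measurement loss of ~5e-5.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .forward import MeasurementMatrix, MeasurementSeries
from .propagation import AllpassBank, StateSpaceModel, simulate


@dataclass
class RefinementConfig:
    eta: float = 200.0
    gamma: float = 1.0
    epochs: int = 2000
    threshold: float = 1.01
    measurement_unit_scale: float = 1e10  # residuals in units of 1e-10 T
    input: str = "filtered"  # feed delay lines with "filtered" or "open_loop"

    def __post_init__(self):
        if self.eta <= 0:
            raise ValueError("learning rate must be positive")
        if self.gamma < 0:
            raise ValueError("regularization strength must be nonnegative")
        if self.input not in ("filtered", "open_loop"):
            raise ValueError(f"unknown refinement input mode {self.input!r}")


@dataclass
class LossBreakdown:
    """Per-epoch loss summary; the series are per time step."""

    Lm: float
    Lv: float
    gamma: float
    Lm_series: np.ndarray
    Lv_series: np.ndarray
    #: forward-pass measurement predictions in the working (1e-10 T) unit
    predicted_measurements: np.ndarray | None = None

    @property
    def total(self) -> float:
        return self.Lm + self.gamma * self.Lv


@dataclass
class GradientSet:
    """Accumulated (summed over time) loss gradients, shaped like the model's
    parameters."""

    d_gains: np.ndarray  # (Nc, 3, 3)
    d_allpass: np.ndarray  # (Nc,)


def measurement_loss(z: np.ndarray, z_hat: np.ndarray) -> float:
    """Mean squared residual over sensors, ``1/Ns sum (z_k - z_hat_k)^2``."""
    z = np.asarray(z, dtype=float)
    z_hat = np.asarray(z_hat, dtype=float)
    if z.shape != z_hat.shape:
        raise ValueError("measurement vectors must have equal length")
    return float(np.mean((z - z_hat) ** 2))


def constraint_loss(j_hat: np.ndarray, threshold: float = 1.01) -> float:
    """Sum over voxels of the squared positive excess of the L1 norm over the
    physiological ceiling."""
    l1 = np.sum(np.abs(np.asarray(j_hat, dtype=float).reshape(-1, 3)), axis=1)
    excess = np.maximum(0.0, l1 - threshold)
    return float(np.sum(excess**2))


def gradient_gain_entry(
    y: float,
    h: np.ndarray,
    residual: np.ndarray,
    j_component: float,
    l1_voxel: float,
    gamma: float,
    threshold: float = 1.01,
) -> float:
    """Loss gradient for a single gain entry at one time step.

    ``y``: the all-pass output multiplied by this gain; ``h``: the H column of
    the influenced state; ``residual``: z_hat - z; ``j_component`` /
    ``l1_voxel``: the influenced current-density component and its voxel's L1
    norm (for the constraint term).  Reference scalar form of the vectorized
    epoch accumulation.
    """
    ns = residual.shape[0]
    g = y * (2.0 / ns) * float(h @ residual)
    g += gamma * 2.0 * y * np.sign(j_component) * max(0.0, l1_voxel - threshold)
    return float(g)


def refinement_forward(
    model: StateSpaceModel,
    H: MeasurementMatrix,
    Z: MeasurementSeries,
    J_input: np.ndarray,
    config: RefinementConfig,
) -> tuple[LossBreakdown, GradientSet]:
    """Forward pass over all samples: losses plus accumulated gradients.

    ``J_input`` is the trajectory feeding the all-pass delay lines (the
    filtered estimates during nested optimization).  Gradients are exact
    derivatives of the accumulated loss under fixed ``J_input``.
    """
    Nm = Z.n_samples
    nc = model.n_connections
    scale_u = config.measurement_unit_scale
    Hs = H.entries * scale_u
    Zs = Z.values * scale_u
    ns = Hs.shape[0]

    bank = AllpassBank(model)
    dy_prev = np.zeros((nc, 3))
    G_y = model.output_matrix()
    b = model.control_vector
    u = model.control.waveform
    if Nm > u.shape[0]:
        u = np.concatenate([u, np.zeros(Nm - u.shape[0])])
    tstates = 3 * model.conn_target[:, None] + np.arange(3)[None, :]  # (Nc, 3)

    d_gains = np.zeros((nc, 3, 3))
    d_allpass = np.zeros(nc)
    Lm_series = np.zeros(Nm)
    Lv_series = np.zeros(Nm)
    z_hats = np.zeros((Nm, ns))

    for n in range(Nm):
        y, dy = bank.step_with_sensitivity(n, J_input, dy_prev)
        dy_prev = dy
        j_pred = G_y @ y.reshape(-1) + b * u[n]
        z_hat = Hs @ j_pred
        z_hats[n] = z_hat
        r = z_hat - Zs[n]
        Lm_series[n] = np.mean(r**2)
        htr = Hs.T @ r
        g_m = (2.0 / ns) * htr[tstates]  # (Nc, 3): dLm/d(j_target_component)
        d_gains += np.einsum("cj,ck->cjk", g_m, y)
        d_allpass += np.einsum("cjk,cj,ck->c", model.conn_gain, g_m, dy)

        jv = j_pred.reshape(-1, 3)
        l1 = np.sum(np.abs(jv), axis=1)
        excess = np.maximum(0.0, l1 - config.threshold)
        Lv_series[n] = np.sum(excess**2)
        if config.gamma > 0 and np.any(excess > 0):
            gl = 2.0 * excess[:, None] * np.sign(jv)  # (Nv, 3)
            d_gains += config.gamma * np.einsum(
                "cj,ck->cjk", gl[model.conn_target], y
            )

    loss = LossBreakdown(
        Lm=float(np.mean(Lm_series)),
        Lv=float(np.mean(Lv_series)),
        gamma=config.gamma,
        Lm_series=Lm_series,
        Lv_series=Lv_series,
        predicted_measurements=z_hats,
    )
    return loss, GradientSet(d_gains=d_gains, d_allpass=d_allpass)


def wrap_allpass(a: float, k: int) -> tuple[float, int]:
    """Fold an out-of-range all-pass coefficient back into [0, 1].

    a < 0: borrow from the fractional side (a + 1, k + 1); a > 1: carry into
    the integer side while possible (a - 1, k - 1), else clamp to 1.
    """
    if a < 0.0:
        n = int(np.ceil(-a))
        a += n
        k += n
    if a > 1.0 and k >= 1:
        m = min(int(np.ceil(a - 1.0)), k)
        a -= m
        k -= m
    if a > 1.0:
        a = 1.0
    return a, k


def update_parameters(
    model: StateSpaceModel, grads: GradientSet, eta: float, Nm: int
) -> StateSpaceModel:
    """Apply the full-batch gradient step and the coefficient wrap rules.

    Returns a new model; gains c and coefficients a move by
    ``-eta / Nm * sum_n gradient(n)``.  Integer delays change only through
    wrapping; the drive vector b is never updated.
    """
    if not (np.all(np.isfinite(grads.d_gains)) and np.all(np.isfinite(grads.d_allpass))):
        bad = np.flatnonzero(
            ~np.isfinite(grads.d_gains.reshape(model.n_connections, -1)).all(axis=1)
            | ~np.isfinite(grads.d_allpass)
        )
        raise FloatingPointError(f"non-finite gradient for connection(s) {bad[:10].tolist()}")
    step = eta / Nm
    new = model.copy()
    # trust region: the wrap rules are defined for order-one excursions, so a
    # single epoch may move any parameter by at most one unit
    new.conn_gain = model.conn_gain - np.clip(step * grads.d_gains, -1.0, 1.0)
    a_new = model.conn_a - np.clip(step * grads.d_allpass, -1.0, 1.0)
    k_new = model.conn_delay.copy()
    for c in range(model.n_connections):
        a_c, k_c = wrap_allpass(float(a_new[c]), int(k_new[c]))
        a_new[c] = a_c
        k_new[c] = k_c
    new.conn_a = a_new
    new.conn_delay = k_new
    return new


def refine_epoch(
    model: StateSpaceModel,
    H: MeasurementMatrix,
    Z: MeasurementSeries,
    estimates,
    config: RefinementConfig,
) -> tuple[StateSpaceModel, LossBreakdown]:
    """One epoch: forward pass on the estimated trajectory, then one update.

    ``estimates`` is the state-estimation result (its ``filtered`` trajectory
    feeds the delay lines) or ``None`` with ``config.input='open_loop'``.
    """
    if config.input == "filtered":
        J_input = estimates.filtered
    else:
        J_input = simulate(model, Z.n_samples)
    loss, grads = refinement_forward(model, H, Z, J_input, config)
    new_model = update_parameters(model, grads, config.eta, Z.n_samples)
    return new_model, loss
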