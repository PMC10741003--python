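"""Neighbor-sparse Kalman filter over the 3*Nv current-density states.

The state covariance P is only tracked on the neighbor support: entries
(i, o) whose voxels are 26-neighbors or identical.  All covariance algebra
(C P C^T + Q, (I - K H) P) is evaluated exactly and then projected back onto
that support, which is what keeps the filter linear in the number of voxels
instead of quadratic.  The innovation covariance S is a small dense Ns x Ns
matrix and is factorized densely.

Because the support pattern is fixed for a given grid, P is stored as a flat
data vector aligned with a precomputed CSR template; projection,
symmetrization and diagonal flooring are then plain array operations.

The one-step covariance transition uses the gain matrix C of the conduction
model directly; uncertainty inside the all-pass delay lines is not
propagated.  Process and measurement noise are isotropic diagonals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from ._kernels import sampled_row_dots
from .forward import MeasurementMatrix, MeasurementSeries
from .geometry import VoxelGrid, neighbor_pairs
from .propagation import Rollout, StateSpaceModel


class SingularInnovationError(np.linalg.LinAlgError):
    pass


def support_mask(grid: VoxelGrid) -> sp.csr_matrix:
    """Sparsity pattern of the covariance: all state pairs whose voxels are
    neighbors or identical, as a canonical csr matrix of ones."""
    pairs = neighbor_pairs(grid)
    nv = grid.n_voxels
    vi = np.concatenate([pairs[:, 0], np.arange(nv)])
    vo = np.concatenate([pairs[:, 1], np.arange(nv)])
    rows = (3 * vi[:, None, None] + np.arange(3)[None, :, None] + np.zeros((1, 1, 3), dtype=np.int64)).ravel()
    cols = (3 * vo[:, None, None] + np.zeros((1, 3, 1), dtype=np.int64) + np.arange(3)[None, None, :]).ravel()
    mask = sp.coo_matrix((np.ones(rows.shape[0]), (rows, cols)), shape=(3 * nv, 3 * nv)).tocsr()
    mask.sum_duplicates()
    mask.sort_indices()
    mask.data[:] = 1.0
    return mask


class CovarianceSupport:
    """Fixed sparsity template plus the index machinery for fast projection."""

    def __init__(self, grid: VoxelGrid):
        self.mask = support_mask(grid)
        self.n = self.mask.shape[0]
        coo = self.mask.tocoo()
        self.rows = coo.row.astype(np.int64)
        self.cols = coo.col.astype(np.int64)
        self.nnz = self.rows.shape[0]
        # permutation mapping each entry to its transposed partner
        t = sp.csr_matrix(
            (np.arange(self.nnz, dtype=np.int64), self.mask.indices, self.mask.indptr),
            shape=self.mask.shape,
        ).T.tocsr()
        t.sort_indices()
        self.transpose_perm = t.data
        self.diag_positions = np.flatnonzero(self.rows == self.cols)
        # strictly increasing flat keys (csr order) for entry lookup
        self._keys = self.rows * self.n + self.cols

    def extract_dense(self, M: np.ndarray) -> np.ndarray:
        """Aligned data vector of a dense matrix restricted to the support."""
        return np.asarray(M)[self.rows, self.cols]

    def extract(self, M: sp.spmatrix) -> np.ndarray:
        """Project an arbitrary sparse matrix onto the template, returning the
        aligned data vector."""
        proj = M.multiply(self.mask).tocoo()
        data = np.zeros(self.nnz)
        keys = proj.row.astype(np.int64) * self.n + proj.col
        data[np.searchsorted(self._keys, keys)] = proj.data
        return data


@dataclass
class SparseCovariance:
    """Covariance restricted to the neighbor support (aligned data vector)."""

    data: np.ndarray
    support: CovarianceSupport = field(repr=False)

    @classmethod
    def diagonal(cls, value: float, support: CovarianceSupport) -> "SparseCovariance":
        data = np.zeros(support.nnz)
        data[support.diag_positions] = value
        return cls(data=data, support=support)

    def to_csr(self) -> sp.csr_matrix:
        m = self.support.mask
        return sp.csr_matrix((self.data, m.indices, m.indptr), shape=m.shape)

    def to_dense(self) -> np.ndarray:
        return self.to_csr().toarray()

    def symmetrized(self) -> "SparseCovariance":
        return SparseCovariance(
            data=0.5 * (self.data + self.data[self.support.transpose_perm]),
            support=self.support,
        )

    def floor_diagonal(self) -> "SparseCovariance":
        data = self.data.copy()
        dp = self.support.diag_positions
        data[dp] = np.maximum(data[dp], 0.0)
        return SparseCovariance(data=data, support=self.support)


@dataclass
class KalmanConfig:
    """Noise and initialization parameters (never stated by the reference
    setup; exposed as configuration).

    q_diag: process-noise variance, (normalized current unit)^2.
    r_diag: measurement-noise variance, T^2; default is the variance of the
        study's 40 fT/sqrt(Hz) sensor noise sampled at 2 kHz.
    p0_diag: initial state variance.
    feed: which estimate is written into the all-pass delay lines --
        "corrected" (measurement information propagates into future
        predictions, default) or "predicted" (pure open-loop memory).
    """

    q_diag: float = 1e-4
    r_diag: float = (1.2649110640673518e-12) ** 2
    p0_diag: float = 1e-2
    feed: str = "corrected"

    def __post_init__(self):
        if min(self.q_diag, self.r_diag, self.p0_diag) < 0:
            raise ValueError("noise variances must be nonnegative")
        if self.feed not in ("corrected", "predicted"):
            raise ValueError(f"unknown feed mode {self.feed!r}")


@dataclass
class FilterResult:
    filtered: np.ndarray
    predicted: np.ndarray
    innovations: np.ndarray
    predicted_measurements: np.ndarray
    covariance_trace: np.ndarray | None = None  # diag(P) per step (debug)


def predict_covariance(
    P: SparseCovariance, q_diag: float, G: sp.csr_matrix
) -> SparseCovariance:
    """P(n|n-1) = proj(C P C^T) + Q, re-symmetrized."""
    M = (G @ P.to_csr()) @ G.T
    data = P.support.extract(M)
    data[P.support.diag_positions] += q_diag
    return SparseCovariance(data=data, support=P.support).symmetrized()


def gain_and_innovation(
    P: SparseCovariance, H: np.ndarray, r_diag: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Kalman gain K = P H^T S^-1 and innovation covariance S = H P H^T + R.

    Returns ``(K, S, PHt)``; ``PHt`` is reused by the covariance correction.
    Raises :class:`SingularInnovationError` (naming the smallest eigenvalue)
    if S cannot be factorized.
    """
    PHt = P.to_csr() @ H.T  # (3Nv, Ns) dense
    S = H @ PHt
    S = 0.5 * (S + S.T)
    S[np.diag_indices_from(S)] += r_diag
    try:
        cho = scipy.linalg.cho_factor(S, lower=True)
    except np.linalg.LinAlgError as exc:
        # The support projection of P is not PSD-preserving, so H P H^T can
        # carry negative eigenvalues.  Floor the spectrum at the measurement
        # noise level (standard covariance conditioning); S stays an honest
        # uncertainty in every direction the projection corrupted.
        if not np.all(np.isfinite(S)):
            raise SingularInnovationError(
                "innovation covariance contains non-finite entries"
            ) from exc
        w, V = np.linalg.eigh(S)
        w_max = max(float(w[-1]), 0.0)
        floor = max(r_diag, 1e-12 * w_max)
        if floor <= 0:
            raise SingularInnovationError(
                f"innovation covariance singular (smallest eigenvalue {float(w[0]):.3e})"
            ) from exc
        S = (V * np.maximum(w, floor)) @ V.T
        S = 0.5 * (S + S.T)
        S[np.diag_indices_from(S)] += 1e-9 * w_max
        cho = scipy.linalg.cho_factor(S, lower=True)
    K = np.ascontiguousarray(scipy.linalg.cho_solve(cho, PHt.T).T)
    return K, S, PHt


def correct_state(
    j_pred: np.ndarray, K: np.ndarray, z: np.ndarray, z_pred: np.ndarray
) -> np.ndarray:
    """j(n|n) = j(n|n-1) + K (z - z_hat)."""
    return j_pred + K @ (z - z_pred)


def correct_covariance(
    P: SparseCovariance, K: np.ndarray, PHt: np.ndarray
) -> SparseCovariance:
    """P(n|n) = proj((I - K H) P), evaluated as P - proj(K (H P)).

    ``H P = PHt^T`` for symmetric P, so the correction entries on the support
    are dot products K[i, :] . (H P)[:, o]; off-support terms are discarded.
    Re-symmetrized, diagonal floored at zero.
    """
    sup = P.support
    vals = sampled_row_dots(sup.rows, sup.cols, K, PHt)
    out = SparseCovariance(data=P.data - vals, support=sup)
    return out.symmetrized().floor_diagonal()


def run_filter(
    model: StateSpaceModel,
    H: MeasurementMatrix,
    Z: MeasurementSeries,
    config: KalmanConfig,
    grid: VoxelGrid,
    support: CovarianceSupport | None = None,
    save_covariance_trace: bool = False,
) -> FilterResult:
    """Run the sparse Kalman filter over all samples of ``Z``.

    Per step: predict the state through the conduction model, predict the
    covariance on the neighbor support, compute gain and innovation, correct
    state and covariance, and feed the delay lines with the corrected (or,
    optionally, predicted) estimate.  A prebuilt ``support`` can be passed to
    amortize the template across epochs.
    """
    Nm = Z.n_samples
    ns = model.n_states
    sup = support if support is not None else CovarianceSupport(grid)
    G = model.gain_matrix()
    Hd = H.entries
    P = SparseCovariance.diagonal(config.p0_diag, sup)
    roll = Rollout(model, Nm)

    filtered = np.zeros((Nm, ns))
    predicted = np.zeros((Nm, ns))
    innovations = np.zeros((Nm, Z.n_channels))
    z_hats = np.zeros((Nm, Z.n_channels))
    cov_trace = np.zeros((Nm, ns)) if save_covariance_trace else None

    for n in range(Nm):
        j_pred = roll.predict(n)
        P = predict_covariance(P, config.q_diag, G)
        K, _, PHt = gain_and_innovation(P, Hd, config.r_diag)
        z_hat = Hd @ j_pred
        j_corr = correct_state(j_pred, K, Z.values[n], z_hat)
        P = correct_covariance(P, K, PHt)
        predicted[n] = j_pred
        filtered[n] = j_corr
        innovations[n] = Z.values[n] - z_hat
        z_hats[n] = z_hat
        if cov_trace is not None:
            cov_trace[n] = P.data[sup.diag_positions]
        roll.commit(n, j_corr if config.feed == "corrected" else j_pred)

    return FilterResult(
        filtered=filtered,
        predicted=predicted,
        innovations=innovations,
        predicted_measurements=z_hats,
        covariance_trace=cov_trace,
    )
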