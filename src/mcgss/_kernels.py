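"""Numerical hot-loop kernels, numba-accelerated when available."""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    @njit(cache=True, fastmath=False)
    def _sddmm_nb(rows, cols, A, B, out):
        for i in range(rows.shape[0]):
            r = rows[i]
            c = cols[i]
            acc = 0.0
            for j in range(A.shape[1]):
                acc += A[r, j] * B[c, j]
            out[i] = acc

    def sampled_row_dots(rows, cols, A, B):
        """out[i] = A[rows[i], :] . B[cols[i], :] (sampled dense-dense product)."""
        out = np.empty(rows.shape[0])
        _sddmm_nb(rows, cols, np.ascontiguousarray(A), np.ascontiguousarray(B), out)
        return out

except ImportError:  # pragma: no cover

    def sampled_row_dots(rows, cols, A, B):
        return np.einsum("ij,ij->i", A[rows], B[cols])
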