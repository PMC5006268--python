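"""Inner simulation loop, with an optional numba-compiled fast path.

Both implementations advance a block of time slices and must produce
bit-identical spike matrices given the same pre-drawn uniform block: the
pure-numpy version is the reference, the numba version the accelerator,
and the test suite cross-checks them against each other.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    HAVE_NUMBA = False

    def njit(*args, **kwargs):  # type: ignore
        def wrap(f):
            return f

        return wrap


@njit(cache=False)
def _step_block_nb(uniforms, prev, c, indptr, indices, data, dt_eff, f):
    T, n = uniforms.shape
    spikes = np.zeros((T, n), dtype=np.uint8)
    lam = np.empty(n, dtype=np.float64)
    for t in range(T):
        for i in range(n):
            lam[i] = c[i]
        for j in range(n):
            if prev[j]:
                for k in range(indptr[j], indptr[j + 1]):
                    lam[indices[k]] += data[k]
        for i in range(n):
            rate = lam[i]
            if rate < 0.0:
                rate = 0.0
            x = rate * dt_eff
            p = np.exp(-x) * x
            u = uniforms[t, i]
            if prev[i]:
                u = f * u
            if u < p:
                spikes[t, i] = 1
        for i in range(n):
            prev[i] = spikes[t, i]
    return spikes


def _step_block_py(uniforms, prev, c, indptr, indices, data, dt_eff, f):
    T, n = uniforms.shape
    spikes = np.zeros((T, n), dtype=np.uint8)
    for t in range(T):
        lam = c.copy()
        for j in np.nonzero(prev)[0]:
            sl = slice(indptr[j], indptr[j + 1])
            lam[indices[sl]] += data[sl]
        np.maximum(lam, 0.0, out=lam)
        x = lam * dt_eff
        p = np.exp(-x) * x
        u = uniforms[t].copy()
        u[prev.astype(bool)] *= f
        row = (u < p).astype(np.uint8)
        spikes[t] = row
        prev[:] = row
    return spikes


def step_block(uniforms, prev, c, indptr, indices, data, dt_eff, f,
               use_numba=True):
    """Advance ``uniforms.shape[0]`` slices; mutates ``prev`` in place."""
    fn = _step_block_nb if (use_numba and HAVE_NUMBA) else _step_block_py
    return fn(
        np.ascontiguousarray(uniforms),
        prev,
        np.ascontiguousarray(c, dtype=np.float64),
        indptr,
        indices,
        np.ascontiguousarray(data, dtype=np.float64),
        float(dt_eff),
        float(f),
    )
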