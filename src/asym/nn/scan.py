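"""Linear recurrence kernels: h_t = a_t * h_{t-1} + b_t (diagonal state).

The forward and reverse-mode sweeps are plain sequential loops; they are
jit-compiled with numba when available and fall back to the identical
pure-Python implementation otherwise.
"""

from __future__ import annotations

import numpy as np

try:  # pragma: no cover - exercised implicitly
    from numba import njit

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover
    _HAVE_NUMBA = False

    def njit(*args, **kwargs):
        if args and callable(args[0]):
            return args[0]

        def wrap(fn):
            return fn

        return wrap


@njit(cache=True, fastmath=True)
def _recurrence_fwd(a, b, h):
    """a, b, h: (B, T, D, N); fills h in place."""
    B, T, D, N = a.shape
    for bi in range(B):
        for d in range(D):
            for n in range(N):
                acc = 0.0
                for t in range(T):
                    acc = a[bi, t, d, n] * acc + b[bi, t, d, n]
                    h[bi, t, d, n] = acc
    return h


@njit(cache=True, fastmath=True)
def _recurrence_bwd(a, h, gh, ga, gb):
    """Reverse sweep: g_t = gh_t + a_{t+1} g_{t+1}; ga_t = g_t h_{t-1}."""
    B, T, D, N = a.shape
    for bi in range(B):
        for d in range(D):
            for n in range(N):
                g = 0.0
                for t in range(T - 1, -1, -1):
                    g = gh[bi, t, d, n] + (a[bi, t + 1, d, n] * g if t + 1 < T else 0.0)
                    gb[bi, t, d, n] = g
                    ga[bi, t, d, n] = g * (h[bi, t - 1, d, n] if t > 0 else 0.0)
    return ga, gb


def recurrence_forward(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    h = np.empty_like(b)
    return _recurrence_fwd(np.ascontiguousarray(a), np.ascontiguousarray(b), h)


def recurrence_backward(a, h, gh):
    ga = np.empty_like(a)
    gb = np.empty_like(a)
    return _recurrence_bwd(np.ascontiguousarray(a), h,
                           np.ascontiguousarray(gh), ga, gb)
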