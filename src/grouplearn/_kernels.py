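"""Hot numerical loops, JIT-compiled when numba is available.

The Rescorla-Wagner forward recursion and the exponentially discounted
prediction-error sums are evaluated thousands of times inside the
multi-start optimizers, so they are isolated here as plain array-in /
array-out functions.  The NumPy fallbacks are the reference semantics; the
numba path must agree with them bit-for-bit on the same inputs (both are
straight-line float64 code).
"""

from __future__ import annotations

import numpy as np


def _rw_forward_py(
    is_ingroup: np.ndarray,
    outcomes: np.ndarray,
    v0_in: float,
    v0_out: float,
    a_in_pos: float,
    a_in_neg: float,
    a_out_pos: float,
    a_out_neg: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial pre-update value of the active group and its prediction error.

    V for a group is carried across the other group's trials unchanged;
    the learning rate applied on each update is selected by the sign of the
    prediction error (ties, delta == 0, route to the positive cell — the
    update is a no-op either way).
    """
    n = outcomes.shape[0]
    values = np.empty(n)
    deltas = np.empty(n)
    v_in = v0_in
    v_out = v0_out
    for t in range(n):
        if is_ingroup[t]:
            v = v_in
            d = outcomes[t] - v
            a = a_in_pos if d >= 0.0 else a_in_neg
            v_in = v + a * d
        else:
            v = v_out
            d = outcomes[t] - v
            a = a_out_pos if d >= 0.0 else a_out_neg
            v_out = v + a * d
        values[t] = v
        deltas[t] = d
    return values, deltas


def _discounted_sums_py(pe: np.ndarray, gamma: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Running discounted sums S(t) = sum_{j<=t} gamma^(t-j) pe_v(j).

    Returns (all, positive-part, negative-part) sums; the clock runs in
    absolute trial time, so zeros in ``pe`` (inactive-group trials) still
    discount the existing sums.
    """
    n = pe.shape[0]
    s_all = np.empty(n)
    s_pos = np.empty(n)
    s_neg = np.empty(n)
    a = p = q = 0.0
    for t in range(n):
        x = pe[t]
        xp = x if x > 0.0 else 0.0
        xn = x if x < 0.0 else 0.0
        a = gamma * a + x
        p = gamma * p + xp
        q = gamma * q + xn
        s_all[t] = a
        s_pos[t] = p
        s_neg[t] = q
    return s_all, s_pos, s_neg


try:  # pragma: no cover - exercised implicitly when numba is installed
    from numba import njit

    rw_forward = njit(cache=True)(_rw_forward_py)
    discounted_sums = njit(cache=True)(_discounted_sums_py)
    HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    rw_forward = _rw_forward_py
    discounted_sums = _discounted_sums_py
    HAVE_NUMBA = False
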