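"""Sequential negative log-likelihood kernel for the Q-learning choice models.

The forward pass is inherently sequential (each trial's choice probability
depends on the Q values left by all earlier feedback), so it is written as a
scalar loop and JIT-compiled with numba when available.  The pure-Python
definition below is the reference; the compiled version is bit-identical.
"""

from __future__ import annotations

import math

import numpy as np

_PCLIP = 1e-12


def _nll_forward(context, choice, reward, coherence,
                 beta0, beta1, alpha, q0, context_dependent):
    """NLL of observed choices under the logit choice rule + delta-rule update.

    ``q0`` is a (2, 2) array of initial values indexed [context, direction];
    the context-free model reads and writes row 0 only.  Choices coded
    1 = up, 0 = down; a trial with choice -1 contributes no likelihood term
    and no update.  Probabilities are clipped to [1e-12, 1 - 1e-12].
    """
    q = q0.copy()
    nll = 0.0
    n = choice.shape[0]
    for t in range(n):
        c = context[t] if context_dependent else 0
        x = beta0 * (q[c, 1] - q[c, 0]) + beta1 * coherence[t]
        if x >= 0.0:
            p_up = 1.0 / (1.0 + math.exp(-x))
        else:
            e = math.exp(x)
            p_up = e / (1.0 + e)
        m = choice[t]
        if m >= 0:
            p = p_up if m == 1 else 1.0 - p_up
            if p < _PCLIP:
                p = _PCLIP
            elif p > 1.0 - _PCLIP:
                p = 1.0 - _PCLIP
            nll -= math.log(p)
            q[c, m] += alpha * (reward[t] - q[c, m])
    return nll


nll_forward_py = _nll_forward

try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    nll_forward = njit(cache=False)(_nll_forward)
except ImportError:  # pragma: no cover
    nll_forward = _nll_forward


def prepare_arrays(data):
    """Extract contiguous typed arrays from a trial table for the kernel."""
    context = np.ascontiguousarray(
        data["context"].to_numpy() if "context" in data else
        np.zeros(len(data)), dtype=np.int64)
    choice = np.ascontiguousarray(data["choice"].to_numpy(), dtype=np.int64)
    reward = np.ascontiguousarray(data["reward"].to_numpy(), dtype=np.float64)
    coherence = np.ascontiguousarray(data["coherence"].to_numpy(),
                                     dtype=np.float64)
    return context, choice, reward, coherence
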