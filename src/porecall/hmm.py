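"""Log-space Forward-Backward and Viterbi over the sparse k-mer chain.

Both algorithms run on the truncated <=21-neighbour transition structure.
All recursions are carried in natural-log space; the per-step sums use a
max-shift so the sparse kernel can be applied in probability space without
underflow.  The initial state distribution is uniform over the 4**K states.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .transitions import TransitionModel

__all__ = ["PosteriorSet", "DecodedPath", "forward_backward", "viterbi"]


class UnderflowError(FloatingPointError):
    """All states became impossible at some event."""


@dataclass
class PosteriorSet:
    """Forward-Backward output: per-event state posteriors (rows sum to 1),
    expected transition mass per shift class (stay/step/one-skip), and the
    total log-likelihood in nats."""

    posteriors: np.ndarray
    shift_masses: np.ndarray
    log_likelihood: float


@dataclass
class DecodedPath:
    """Viterbi output: one state per event and the joint log-probability of
    the best path and the observations."""

    states: np.ndarray
    log_joint: float


def _check_column(v: np.ndarray, t: int) -> None:
    if not np.any(v > -np.inf):
        raise UnderflowError(f"all states impossible at event {t}")


def forward_backward(log_emissions: np.ndarray, trans: TransitionModel) -> PosteriorSet:
    """Posterior state probabilities and shift-class transition masses.

    ``log_emissions`` is the (n_events, 4**K) matrix of log emission
    densities.  Expected shift-class masses sum to n_events - 1.
    """
    n, S = log_emissions.shape
    if n == 0:
        raise ValueError("need at least one event")
    if S != trans.n_states:
        raise ValueError("emission matrix does not match state space")
    log_init = -np.log(S)
    w0, w1, w2 = trans.w_stay, trans.w_step, trans.w_skip

    # the regular successor structure turns the sparse kernel into
    # contiguous reshape-reductions: predecessors of k2 under a step are
    # {a*4^(K-1) + (k2>>2)}, so their sum is a fold over the leading base;
    # successors of k1 are {(k1 mod 4^(K-1))*4 + b}, a fold over the
    # trailing base.  Summing unmerged contributions equals applying the
    # merged kernel.
    alpha = np.empty((n, S))
    alpha[0] = log_init + log_emissions[0]
    _check_column(alpha[0], 0)
    with np.errstate(divide="ignore"):
        for t in range(1, n):
            m = alpha[t - 1].max()
            a = np.exp(alpha[t - 1] - m)
            g = np.repeat(a.reshape(4, -1).sum(0), 4)
            h = np.repeat(a.reshape(16, -1).sum(0), 16)
            alpha[t] = np.log(w0 * a + w1 * g + w2 * h) + m + log_emissions[t]
            _check_column(alpha[t], t)

        last = alpha[n - 1]
        m = last.max()
        loglik = float(np.log(np.exp(last - m).sum()) + m)

        beta = np.empty((n, S))
        beta[n - 1] = 0.0
        masses = np.zeros(3)
        for t in range(n - 2, -1, -1):
            nxt = beta[t + 1] + log_emissions[t + 1]
            m2 = nxt.max()
            b = np.exp(nxt - m2)
            b_step = np.tile(b.reshape(-1, 4).sum(1), 4)
            b_skip = np.tile(b.reshape(-1, 16).sum(1), 16)
            beta[t] = np.log(w0 * b + w1 * b_step + w2 * b_skip) + m2
            _check_column(beta[t], t)
            # expected transition mass by shift class across this step
            ma = alpha[t].max()
            a = np.exp(alpha[t] - ma)
            scale = np.exp(ma + m2 - loglik)
            masses[0] += w0 * float(a @ b) * scale
            masses[1] += w1 * float(a @ b_step) * scale
            masses[2] += w2 * float(a @ b_skip) * scale

    # exponentiate in row blocks (large one-shot transcendentals are slow)
    post = alpha
    post += beta
    post -= loglik
    for i in range(0, n, 512):
        np.exp(post[i : i + 512], out=post[i : i + 512])
    return PosteriorSet(posteriors=post, shift_masses=masses, log_likelihood=loglik)


def viterbi(log_emissions: np.ndarray, trans: TransitionModel) -> DecodedPath:
    """Most likely state path under the truncated transition structure.

    Ties in the max-product recursion resolve toward the numerically
    smallest predecessor state; the final state is the smallest argmax of
    the last column.
    """
    n, S = log_emissions.shape
    if n == 0:
        raise ValueError("need at least one event")
    if S != trans.n_states:
        raise ValueError("emission matrix does not match state space")
    pred_idx, pred_logp = trans.pred_idx, trans.pred_logp

    delta = -np.log(S) + log_emissions[0]
    _check_column(delta, 0)
    backptr = np.empty((n, S), dtype=np.int64)
    rows = np.arange(S)
    for t in range(1, n):
        scores = delta[pred_idx] + pred_logp
        best = scores.argmax(axis=1)  # first max = smallest predecessor
        delta = scores[rows, best] + log_emissions[t]
        backptr[t] = pred_idx[rows, best]
        _check_column(delta, t)

    states = np.empty(n, dtype=np.int64)
    states[n - 1] = int(delta.argmax())
    log_joint = float(delta[states[n - 1]])
    for t in range(n - 1, 0, -1):
        states[t - 1] = backptr[t, states[t]]
    return DecodedPath(states=states, log_joint=log_joint)
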