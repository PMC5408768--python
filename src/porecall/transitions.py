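"""Prior state-transition probabilities of the k-mer HMM.

Consecutive segmented events are emitted from k-mer states that advance
along the DNA sequence by a variable shift: 0 (a "stay", the segmenter
over-split one event), 1 (the normal step) or >=2 (a "skip", one or more
events were lost).  Because extra skips can reconnect any pair of states,
the full transition probability between two k-mers sums contributions over
every shift amount; for decoding, shifts beyond 2 are disregarded, leaving
each state at most 21 successors (itself, 4 step successors, 16 skip
successors), and rows are renormalized.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

__all__ = [
    "TransitionModel",
    "transition_prob_full",
    "min_skips",
    "build_neighbour_table",
    "update_transition_params",
]

DEFAULT_P_STAY = 0.1
DEFAULT_P_SKIP = 0.3

# Baum-Welch estimates are kept away from the boundary of the parameter
# space to avoid degenerate fixed points.
_P_MIN = 1e-4
_P_MAX = 0.49


def transition_prob_full(k1: int, k2: int, p_stay: float, p_skip: float, K: int) -> float:
    """Untruncated prior transition probability between k-mer states.

    Sums the stay term, the single-step term (weight p_step/4), every
    multi-skip overlap term (weight p_skip1**(i-1) / 4**i for a shift of i
    when the length-(K-i) suffix of k1 equals the prefix of k2), and the
    closed-form tail over shifts >= K, which applies to every successor.
    Rows of this kernel sum to exactly 1.
    """
    p_step = 1.0 - p_stay - p_skip
    ps1 = p_skip / (1.0 + p_skip)
    p = 0.0
    if k1 == k2:
        p += p_stay
    for i in range(1, K):
        if k1 % 4 ** (K - i) == k2 // 4**i:
            p += p_step / 4.0 if i == 1 else ps1 ** (i - 1) / 4.0**i
    # shifts of K or more: no sequence overlap required
    p += ps1 ** (K - 1) / (1.0 - ps1) / 4.0**K
    return p


def min_skips(k1: int, k2: int, K: int) -> int:
    """Smallest number of skips in a single k1 -> k2 transition.

    A pure step returns 0; a shift of i corresponds to i-1 skips.  A shift
    of K (complete state replacement) always connects, so the result is at
    most K-1.  The stay (k1 == k2 at shift 0) is not counted as a move.
    """
    for i in range(1, K):
        if k1 % 4 ** (K - i) == k2 // 4**i:
            return i - 1
    return K - 1


class TransitionModel:
    """Truncated sparse transition structure for the 4**K-state chain.

    Each state's successors are itself, the 4 one-step extensions and the
    16 two-step extensions; coinciding successors (low-complexity k-mers)
    have their contributions summed.  Rows are renormalized so the
    truncated kernel is a proper transition matrix.
    """

    def __init__(self, p_stay: float = DEFAULT_P_STAY, p_skip: float = DEFAULT_P_SKIP, K: int = 6):
        if not (p_stay >= 0 and p_skip >= 0 and p_stay + p_skip < 1):
            raise ValueError("require p_stay, p_skip >= 0 and p_stay + p_skip < 1")
        if K < 2:
            raise ValueError("K must be at least 2")
        self.p_stay = float(p_stay)
        self.p_skip = float(p_skip)
        self.K = int(K)
        self._build()

    @property
    def p_step(self) -> float:
        return 1.0 - self.p_stay - self.p_skip

    @property
    def p_skip1(self) -> float:
        return self.p_skip / (1.0 + self.p_skip)

    @property
    def n_states(self) -> int:
        return 4**self.K

    def _build(self) -> None:
        S = self.n_states
        K = self.K
        k1 = np.arange(S, dtype=np.int64)
        # truncation keeps the stay/step/one-skip contributions only;
        # their total mass is constant across rows
        Z = self.p_stay + self.p_step + self.p_skip1

        rows, cols, vals = [k1], [k1], [np.full(S, self.p_stay)]
        step_base = (k1 % 4 ** (K - 1)) * 4
        for b in range(4):
            rows.append(k1)
            cols.append(step_base + b)
            vals.append(np.full(S, self.p_step / 4.0))
        skip_base = (k1 % 4 ** (K - 2)) * 16
        for c in range(16):
            rows.append(k1)
            cols.append(skip_base + c)
            vals.append(np.full(S, self.p_skip1 / 16.0))

        # merged kernel: duplicate (row, col) contributions are summed
        T = sparse.coo_matrix(
            (np.concatenate(vals) / Z, (np.concatenate(rows), np.concatenate(cols))),
            shape=(S, S),
        ).tocsr()
        T.sum_duplicates()
        self.trans_csr = T

        # gather tables for the DP inner loops: step/skip successor and
        # predecessor state indices, applied with the per-contribution
        # weights below (summing unmerged contributions equals applying the
        # merged kernel)
        self.w_stay = self.p_stay / Z
        self.w_step = self.p_step / 4.0 / Z
        self.w_skip = self.p_skip1 / 16.0 / Z
        self.step_succ = step_base[:, None] + np.arange(4)[None, :]
        self.skip_succ = skip_base[:, None] + np.arange(16)[None, :]
        k2 = np.arange(S, dtype=np.int64)
        self.step_pred = (np.arange(4)[None, :] * 4 ** (K - 1)) + (k2 >> 2)[:, None]
        self.skip_pred = (np.arange(16)[None, :] * 4 ** (K - 2)) + (k2 >> 4)[:, None]

        # padded predecessor table for Viterbi: for each destination state,
        # predecessor indices in ascending order (ties resolve to the
        # numerically smallest predecessor) and merged log probabilities
        C = T.tocsc()
        width = int(np.diff(C.indptr).max())
        self.pred_idx = np.zeros((S, width), dtype=np.int64)
        self.pred_logp = np.full((S, width), -np.inf)
        for j in range(S):
            lo, hi = C.indptr[j], C.indptr[j + 1]
            self.pred_idx[j, : hi - lo] = C.indices[lo:hi]
            self.pred_logp[j, : hi - lo] = np.log(C.data[lo:hi])

    def neighbours(self, k1: int) -> list[tuple[int, float]]:
        """Merged, renormalized successor list of one state."""
        lo, hi = self.trans_csr.indptr[k1], self.trans_csr.indptr[k1 + 1]
        return list(zip(self.trans_csr.indices[lo:hi].tolist(), self.trans_csr.data[lo:hi].tolist()))

    def with_params(self, p_stay: float, p_skip: float) -> "TransitionModel":
        return TransitionModel(p_stay, p_skip, self.K)

    def __repr__(self) -> str:  # pragma: no cover
        return f"TransitionModel(p_stay={self.p_stay:.4g}, p_skip={self.p_skip:.4g}, K={self.K})"


def build_neighbour_table(p_stay: float, p_skip: float, K: int) -> TransitionModel:
    """Construct the truncated, renormalized sparse transition structure."""
    return TransitionModel(p_stay, p_skip, K)


def update_transition_params(
    masses, current: tuple[float, float] | None = None
) -> tuple[float, float]:
    """Baum-Welch M-step for (p_stay, p_skip) from shift-class masses.

    ``masses`` holds the total posterior transition mass assigned by
    Forward-Backward to the stay (shift 0), step (shift 1) and one-skip
    (shift 2) classes.  The update is the maximum-likelihood inversion of
    the truncated kernel's class weights: the truncated model assigns the
    classes relative mass (p_stay, p_step, p_skip1) / Z with
    Z = p_stay + p_step + p_skip1, so given observed class fractions
    (a, b, c) we solve

        p_stay = a * Z,   p_skip1 = c * Z,   p_skip = p_skip1 / (1 - p_skip1),
        Z = 1 - p_skip + p_skip1

    for Z by bisection.  Estimates are clamped to [1e-4, 0.49]; all-zero
    masses leave the current parameters unchanged.
    """
    m0, m1, m2 = (float(m) for m in masses)
    if min(m0, m1, m2) < 0:
        raise ValueError("shift-class masses must be nonnegative")
    total = m0 + m1 + m2
    if total == 0:
        if current is None:
            raise ValueError("all-zero masses and no current parameters")
        return current
    a, c = m0 / total, m2 / total

    def gap(z: float) -> float:
        # Z consistency: Z - 1 + p_skip - p_skip1 must vanish, with
        # p_skip1 = c*Z and p_skip = c*Z / (1 - c*Z)
        ps1 = c * z
        return z - 1.0 + ps1 / (1.0 - ps1) - ps1

    if c == 0:
        z = 1.0
    else:
        lo, hi = 1e-9, (1.0 - 1e-9) / c
        # gap is increasing in z; gap(lo) < 0
        for _ in range(200):
            mid = 0.5 * (lo + hi)
            if gap(mid) <= 0:
                lo = mid
            else:
                hi = mid
        z = 0.5 * (lo + hi)
    ps1 = c * z
    p_stay = min(max(a * z, _P_MIN), _P_MAX)
    p_skip = min(max(ps1 / (1.0 - ps1), _P_MIN), _P_MAX)
    return p_stay, p_skip
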