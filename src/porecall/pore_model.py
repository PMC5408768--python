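"""Pore models, per-read scaling parameters, and emission densities.

A pore model describes, for every DNA k-mer that can occupy the nanopore,
the distribution of the segmented event statistics it produces: the event
mean current follows a Gaussian with parameters (level_mean, level_stdv)
and the event standard deviation follows an Inverse Gaussian with
parameters (sd_mean, sd_stdv).  Individual reads see an affine-distorted
version of the model, described by six per-read/per-strand scaling
parameters (shift, scale, drift, var, scale_sd, var_sd).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "BASES",
    "PoreModel",
    "ScalingParams",
    "EventSequence",
    "kmer_index",
    "index_to_kmer",
    "scaled_params",
    "log_emission",
    "log_emission_matrix",
    "read_model_table",
    "write_model_table",
]

BASES = "ACGT"
_BASE_CODE = {b: i for i, b in enumerate(BASES)}

# IG densities are undefined at 0; segmented events occasionally report a
# zero standard deviation, which is clamped to this floor (pA).
STDV_FLOOR = 1e-3


def kmer_index(kmer: str) -> int:
    """Encode a k-mer as its rank in A<C<G<T lexicographic order.

    The leftmost base is the most significant base-4 digit, so for K=6
    "AAAAAA" -> 0 and "TTTTTT" -> 4095.
    """
    idx = 0
    for ch in kmer:
        try:
            idx = idx * 4 + _BASE_CODE[ch]
        except KeyError:
            raise ValueError(f"invalid base {ch!r} in kmer {kmer!r}") from None
    return idx


def index_to_kmer(idx: int, K: int) -> str:
    """Inverse of :func:`kmer_index` for a given k-mer length."""
    if not 0 <= idx < 4**K:
        raise ValueError(f"state index {idx} out of range for K={K}")
    out = []
    for _ in range(K):
        out.append(BASES[idx & 3])
        idx >>= 2
    return "".join(reversed(out))


@dataclass(frozen=True)
class ScalingParams:
    """Per-read/per-strand distortion of the pore model.

    For an event at time t emitted from k-mer state k:

        mean ~ N(scale * level_mean[k] + shift + drift * t,
                 (var * level_stdv[k])**2)
        stdv ~ IG(scale_sd * sd_mean[k], var_sd * sd_stdv[k])

    The neutral element (no distortion) is shift=0, scale=1, drift=0,
    var=1, scale_sd=1, var_sd=1.
    """

    shift: float = 0.0
    scale: float = 1.0
    drift: float = 0.0
    var: float = 1.0
    scale_sd: float = 1.0
    var_sd: float = 1.0

    def __post_init__(self) -> None:
        if not (self.scale > 0 and self.var > 0 and self.scale_sd > 0 and self.var_sd > 0):
            raise ValueError("scale, var, scale_sd, var_sd must be strictly positive")

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shift, self.scale, self.drift, self.var, self.scale_sd, self.var_sd]
        )


class PoreModel:
    """Per-kmer emission parameters for one strand model.

    Parameters are stored as dense arrays of length 4**K indexed by the
    canonical k-mer encoding of :func:`kmer_index`.
    """

    def __init__(
        self,
        name: str,
        K: int,
        level_mean: np.ndarray,
        level_stdv: np.ndarray,
        sd_mean: np.ndarray,
        sd_stdv: np.ndarray,
    ):
        n_states = 4**K
        arrays = {}
        for label, arr in (
            ("level_mean", level_mean),
            ("level_stdv", level_stdv),
            ("sd_mean", sd_mean),
            ("sd_stdv", sd_stdv),
        ):
            arr = np.asarray(arr, dtype=float)
            if arr.shape != (n_states,):
                raise ValueError(
                    f"{label} must have exactly {n_states} entries for K={K}, got {arr.shape}"
                )
            arrays[label] = arr
        for label in ("level_stdv", "sd_mean", "sd_stdv"):
            if not np.all(arrays[label] > 0):
                raise ValueError(f"{label} must be strictly positive for every kmer")
        self.name = name
        self.K = int(K)
        self.level_mean = arrays["level_mean"]
        self.level_stdv = arrays["level_stdv"]
        self.sd_mean = arrays["sd_mean"]
        self.sd_stdv = arrays["sd_stdv"]

    @property
    def n_states(self) -> int:
        return 4**self.K

    def __repr__(self) -> str:  # pragma: no cover
        return f"PoreModel(name={self.name!r}, K={self.K})"


@dataclass
class EventSequence:
    """Ordered segmented events: start (s), length (s), mean (pA), stdv (pA)."""

    start: np.ndarray
    length: np.ndarray
    mean: np.ndarray
    stdv: np.ndarray
    read_id: str = "read"

    def __post_init__(self) -> None:
        self.start = np.asarray(self.start, dtype=float)
        self.length = np.asarray(self.length, dtype=float)
        self.mean = np.asarray(self.mean, dtype=float)
        self.stdv = np.asarray(self.stdv, dtype=float)
        n = len(self.start)
        if not (len(self.length) == len(self.mean) == len(self.stdv) == n):
            raise ValueError("event columns must have equal length")
        if n and np.any(np.diff(self.start) < 0):
            raise ValueError("event start times must be nondecreasing")

    def __len__(self) -> int:
        return len(self.start)

    def slice(self, lo: int, hi: int) -> "EventSequence":
        return EventSequence(
            self.start[lo:hi],
            self.length[lo:hi],
            self.mean[lo:hi],
            self.stdv[lo:hi],
            self.read_id,
        )

    def take(self, idx: np.ndarray) -> "EventSequence":
        return EventSequence(
            self.start[idx], self.length[idx], self.mean[idx], self.stdv[idx], self.read_id
        )

    def rezeroed(self) -> "EventSequence":
        """Shift start times so the first event starts at t=0 (drift conditioning)."""
        if len(self) == 0:
            return self
        return EventSequence(
            self.start - self.start[0], self.length, self.mean, self.stdv, self.read_id
        )


def scaled_params(
    model: PoreModel, k: int, s: ScalingParams, t: float
) -> tuple[float, float, float, float]:
    """Distorted emission parameters for state k at event start time t.

    Returns (gaussian mean, gaussian sd, inverse-gaussian mean,
    inverse-gaussian shape).
    """
    m = s.scale * model.level_mean[k] + s.shift + s.drift * t
    sd = s.var * model.level_stdv[k]
    ig_mean = s.scale_sd * model.sd_mean[k]
    ig_shape = s.var_sd * model.sd_stdv[k]
    return float(m), float(sd), float(ig_mean), float(ig_shape)


def _log_normal_pdf(x, m, sd):
    return -0.5 * math.log(2 * math.pi) - np.log(sd) - 0.5 * ((x - m) / sd) ** 2


def _log_invgauss_pdf(x, mean, shape):
    # f(x; m, lambda) = sqrt(lambda / (2 pi x^3)) exp(-lambda (x-m)^2 / (2 m^2 x))
    return 0.5 * (np.log(shape) - math.log(2 * math.pi) - 3.0 * np.log(x)) - shape * (
        x - mean
    ) ** 2 / (2.0 * mean**2 * x)


def log_emission(
    mean: float, stdv: float, t: float, k: int, model: PoreModel, s: ScalingParams
) -> float:
    """Log emission density (nats) of one event under state k.

    The density is the product of the Gaussian for the event mean and the
    Inverse Gaussian for the event standard deviation, both under the
    scaled model.
    """
    if not (math.isfinite(mean) and math.isfinite(stdv)):
        raise ValueError("event mean/stdv must be finite")
    m, sd, ig_mean, ig_shape = scaled_params(model, k, s, t)
    x = max(stdv, STDV_FLOOR)
    return float(_log_normal_pdf(mean, m, sd) + _log_invgauss_pdf(x, ig_mean, ig_shape))


def log_emission_matrix(
    events: EventSequence, model: PoreModel, s: ScalingParams
) -> np.ndarray:
    """Dense (n_events, 4**K) matrix of log emission densities.

    Assembled from per-state and per-event precomputed logs plus pure
    arithmetic per cell, so cost stays linear in n_events * 4**K with no
    per-cell transcendentals.
    """
    if len(events) == 0:
        return np.zeros((0, model.n_states))
    if not (np.all(np.isfinite(events.mean)) and np.all(np.isfinite(events.stdv))):
        raise ValueError("event mean/stdv must be finite")
    sd = s.var * model.level_stdv
    ig_mean = s.scale_sd * model.sd_mean
    ig_shape = s.var_sd * model.sd_stdv
    level = s.scale * model.level_mean + s.shift
    state_const = -math.log(2 * math.pi) - np.log(sd) + 0.5 * np.log(ig_shape)
    x = np.maximum(events.stdv, STDV_FLOOR)
    event_const = -1.5 * np.log(x)
    # mean channel: z^2 with z = (mean_i - drift*t_i - level_k)/sd_k
    y = events.mean - s.drift * events.start
    z = (y[:, None] - level[None, :]) / sd[None, :]
    np.multiply(z, z, out=z)
    z *= -0.5
    # stdv channel exponent: shape_k (x_i - igm_k)^2 / (2 igm_k^2 x_i)
    w = x[:, None] - ig_mean[None, :]
    np.multiply(w, w, out=w)
    w *= (ig_shape / (2.0 * ig_mean**2))[None, :]
    w /= x[:, None]
    z -= w
    z += state_const[None, :]
    z += event_const[:, None]
    return z


_MODEL_COLUMNS = ("kmer", "level_mean", "level_stdv", "sd_mean", "sd_stdv")


def read_model_table(path, name: str | None = None) -> PoreModel:
    """Load a pore model from a 5-column TSV (kmer, level_mean, level_stdv,
    sd_mean, sd_stdv).  K is inferred from the kmer column; the table must
    contain all 4**K kmers exactly once.  Extra columns are ignored.
    """
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        col = {}
        for c in _MODEL_COLUMNS:
            if c not in header:
                raise ValueError(f"model table {path}: missing column {c!r}")
            col[c] = header.index(c)
        rows = {}
        K = None
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            kmer = parts[col["kmer"]]
            if K is None:
                K = len(kmer)
            elif len(kmer) != K:
                raise ValueError(
                    f"model table {path}:{lineno}: inconsistent kmer length"
                )
            idx = kmer_index(kmer)
            if idx in rows:
                raise ValueError(f"model table {path}:{lineno}: duplicate kmer {kmer}")
            try:
                rows[idx] = tuple(
                    float(parts[col[c]]) for c in _MODEL_COLUMNS[1:]
                )
            except (ValueError, IndexError):
                raise ValueError(
                    f"model table {path}:{lineno}: malformed numeric field"
                ) from None
    if K is None:
        raise ValueError(f"model table {path}: no data rows")
    n_states = 4**K
    if len(rows) != n_states:
        raise ValueError(
            f"model table {path}: expected {n_states} kmers for K={K}, got {len(rows)}"
        )
    arr = np.array([rows[i] for i in range(n_states)])
    if name is None:
        import os

        name = os.path.splitext(os.path.basename(str(path)))[0]
    return PoreModel(name, K, arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3])


def write_model_table(model: PoreModel, path) -> None:
    """Write a pore model as the 5-column TSV read by :func:`read_model_table`."""
    with open(path, "w") as fh:
        fh.write("\t".join(_MODEL_COLUMNS) + "\n")
        for i in range(model.n_states):
            fh.write(
                f"{index_to_kmer(i, model.K)}\t{float(model.level_mean[i])!r}\t"
                f"{float(model.level_stdv[i])!r}\t{float(model.sd_mean[i])!r}\t"
                f"{float(model.sd_stdv[i])!r}\n"
            )
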