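"""Synthetic event-data generator and truth-based identity metric.

The generator reproduces the assumed generative process of the basecaller:
a k-mer path walks along a DNA sequence with stays (probability p_stay),
steps and geometric multi-skips; each visited state emits an event whose
mean is Gaussian around the scaled pore-model level (with per-read shift,
scale and drift) and whose standard deviation is Inverse-Gaussian.  A full
two-strand read is template events, an abasic hairpin island (means near
110 pA, well above the 50-90 pA range of regular DNA), then complement
events drawn from the reverse-complement sequence under a second model.

``alignment_identity`` scores a basecall against the known truth the same
way mapped nanopore reads are scored: match columns divided by read bases
aligned plus reference bases deleted, under a global alignment with free
end gaps on the called sequence (match +1, mismatch -1, gap -1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pore_model import BASES, EventSequence, PoreModel, ScalingParams, kmer_index
from .scaling import ModelSet

__all__ = [
    "SimConfig",
    "ReadTruth",
    "simulate_pore_model",
    "simulate_sequence",
    "simulate_events",
    "simulate_read",
    "alignment_identity",
    "write_truth_table",
    "read_truth_table",
    "reverse_complement",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated read; the seed fixes all
    randomness end-to-end.

    noise_inflation multiplies the Gaussian level_stdv and deflates
    (divides) the Inverse-Gaussian shape, so values < 1 mean cleaner
    events and 0 means noise-free.  hairpin_pos is the approximate
    fraction of events placed before the hairpin.  homopolymer_len plants
    one single-base run of that length in the template sequence, which the
    minimal-overlap decoder is expected to cap at K bases.
    """

    seed: int = 0
    K: int = 6
    length: int = 500
    p_stay: float = 0.1
    p_skip: float = 0.3
    params: ScalingParams = ScalingParams()
    noise_inflation: float = 1.0
    abasic_level: float = 110.0
    island_len: int = 10
    hairpin_pos: float = 0.5
    mean_event_length: float = 0.03
    homopolymer_len: int = 10
    model_seed: int = 7


@dataclass
class ReadTruth:
    """Ground truth of a simulated read."""

    read_id: str
    template_seq: str
    complement_seq: str
    island: tuple[int, int]
    params: ScalingParams
    p_stay: float
    p_skip: float
    template_states: np.ndarray
    complement_states: np.ndarray
    models: ModelSet
    config: SimConfig


def simulate_pore_model(seed: int, K: int = 6, name: str = "template") -> PoreModel:
    """Random pore model: level means without collision in the 50-90 pA
    band of regular DNA; level_stdv in [0.5, 2], sd_mean in [1, 3],
    sd_stdv in [3, 10].  Deterministic per seed."""
    if K < 1:
        raise ValueError("K must be >= 1")
    rng = np.random.default_rng(seed)
    S = 4**K
    levels = rng.uniform(50.0, 90.0, S)
    while np.unique(levels).size < S:  # pragma: no cover - a.s. never taken
        levels = rng.uniform(50.0, 90.0, S)
    return PoreModel(
        name,
        K,
        level_mean=levels,
        level_stdv=rng.uniform(0.5, 2.0, S),
        sd_mean=rng.uniform(1.0, 3.0, S),
        sd_stdv=rng.uniform(3.0, 10.0, S),
    )


def simulate_sequence(rng: np.random.Generator, length: int, homopolymer_len: int = 0) -> str:
    """Uniform random DNA, optionally with one planted homopolymer run."""
    seq = rng.choice(list(BASES), size=length).tolist()
    if 0 < homopolymer_len <= length:
        pos = int(rng.integers(0, length - homopolymer_len + 1))
        base = BASES[int(rng.integers(4))]
        seq[pos : pos + homopolymer_len] = [base] * homopolymer_len
    return "".join(seq)


def _draw_shift(rng: np.random.Generator, p_stay: float, p_skip: float) -> int:
    """Shift between consecutive events: 0 w.p. p_stay, 1 w.p. p_step, and
    1+j with j skips w.p. p_skip1**j, matching the transition prior."""
    u = rng.random()
    if u < p_stay:
        return 0
    if u < p_stay + (1.0 - p_stay - p_skip):
        return 1
    ps1 = p_skip / (1.0 + p_skip)
    return 1 + int(rng.geometric(1.0 - ps1))


def simulate_events(
    sequence: str,
    model: PoreModel,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    t_start: float = 0.0,
):
    """Walk the sequence's k-mer chain and emit events.

    Returns (EventSequence, true state path, true shift sequence).  The
    shift sequence has one entry per transition (length n_events - 1).
    """
    K = model.K
    if len(sequence) < K:
        raise ValueError(f"sequence shorter than K={K}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    p = config.params
    infl = config.noise_inflation

    kmers = [kmer_index(sequence[i : i + K]) for i in range(len(sequence) - K + 1)]
    states, shifts = [0], []
    pos = 0
    while True:
        s = _draw_shift(rng, config.p_stay, config.p_skip)
        if pos + s > len(kmers) - 1:
            break
        pos += s
        shifts.append(s)
        states.append(pos)
    state_path = np.array([kmers[i] for i in states], dtype=np.int64)

    n = len(state_path)
    lengths = rng.exponential(config.mean_event_length, n)
    starts = t_start + np.concatenate([[0.0], np.cumsum(lengths[:-1])])
    mu = model.level_mean[state_path]
    loc = p.scale * mu + p.shift + p.drift * starts
    sd = p.var * model.level_stdv[state_path] * infl
    means = rng.normal(loc, sd) if infl > 0 else loc
    ig_mean = p.scale_sd * model.sd_mean[state_path]
    if infl > 0:
        ig_shape = p.var_sd * model.sd_stdv[state_path] / infl
        stdvs = rng.wald(ig_mean, ig_shape)
    else:
        stdvs = ig_mean
    events = EventSequence(starts, lengths, means, stdvs)
    return events, state_path, np.array(shifts, dtype=np.int64)


def _island_events(rng, config: SimConfig, t_start: float) -> EventSequence:
    n = config.island_len
    lengths = rng.exponential(config.mean_event_length, n)
    starts = t_start + np.concatenate([[0.0], np.cumsum(lengths[:-1])])
    means = rng.normal(config.abasic_level, 1.0, n)
    stdvs = rng.wald(2.0, 20.0, n)
    return EventSequence(starts, lengths, means, stdvs)


def _concat(parts: list[EventSequence], read_id: str) -> EventSequence:
    return EventSequence(
        np.concatenate([p.start for p in parts]),
        np.concatenate([p.length for p in parts]),
        np.concatenate([p.mean for p in parts]),
        np.concatenate([p.stdv for p in parts]),
        read_id,
    )


def simulate_read(
    config: SimConfig,
    template_model: PoreModel | None = None,
    complement_model: PoreModel | None = None,
) -> tuple[EventSequence, ReadTruth]:
    """Full two-strand read: template + abasic hairpin island + complement.

    Both strands share the read's scaling parameters; the complement
    sequence is the reverse complement of the template (truncated when
    hairpin_pos != 0.5 so the island lands at the requested fraction of
    the read).  Island events are drawn around the abasic level (default
    110 pA), with at least island_len of them.
    """
    rng = np.random.default_rng(config.seed)
    if template_model is None:
        template_model = simulate_pore_model(config.model_seed, config.K, "template")
    if complement_model is None:
        complement_model = simulate_pore_model(config.model_seed + 1, config.K, "complement_1")

    fragment = simulate_sequence(rng, config.length, config.homopolymer_len)
    frac = min(max(config.hairpin_pos, 0.05), 0.95)
    # place the hairpin at the requested fraction of the read by shortening
    # the strand on the appropriate side (a pore can lose either end)
    if frac >= 0.5:
        tpl_seq = fragment
        comp_len = max(int(round(config.length * (1.0 - frac) / frac)), config.K)
        comp_seq = reverse_complement(fragment)[:comp_len]
    else:
        comp_seq = reverse_complement(fragment)
        tpl_len = max(int(round(config.length * frac / (1.0 - frac))), config.K)
        tpl_seq = fragment[-tpl_len:]

    tpl_events, tpl_states, _ = simulate_events(tpl_seq, template_model, config, rng, 0.0)
    t = tpl_events.start[-1] + tpl_events.length[-1]
    island = _island_events(rng, config, t)
    t = island.start[-1] + island.length[-1]
    comp_events, comp_states, _ = simulate_events(comp_seq, complement_model, config, rng, t)

    read_id = f"sim_{config.seed}"
    events = _concat([tpl_events, island, comp_events], read_id)
    truth = ReadTruth(
        read_id=read_id,
        template_seq=tpl_seq,
        complement_seq=comp_seq,
        island=(len(tpl_events), len(tpl_events) + len(island)),
        params=config.params,
        p_stay=config.p_stay,
        p_skip=config.p_skip,
        template_states=tpl_states,
        complement_states=comp_states,
        models=ModelSet(template=template_model, complements=[complement_model]),
        config=config,
    )
    return events, truth


def alignment_identity(called: str, truth: str) -> float:
    """Identity of a basecall against its known true sequence.

    Global alignment with match +1, mismatch -1, gap -1 and free end gaps
    on the called sequence; identity = match columns / (called bases
    aligned + truth bases deleted).
    """
    if not called or not truth:
        raise ValueError("sequences must be nonempty")
    n, m = len(called), len(truth)
    a = np.frombuffer(called.encode(), dtype=np.uint8)
    b = np.frombuffer(truth.encode(), dtype=np.uint8)

    H = np.zeros((n + 1, m + 1), dtype=np.int32)
    ptr = np.zeros((n + 1, m + 1), dtype=np.int8)  # 0 diag, 1 up, 2 left
    H[0, :] = -np.arange(m + 1)  # truth end gaps are charged
    ptr[0, :] = 2
    js = np.arange(1, m + 1)
    for i in range(1, n + 1):
        sub = np.where(b == a[i - 1], 1, -1)
        diag = H[i - 1, :-1] + sub
        up = H[i - 1, 1:] - 1
        M = np.maximum(diag, up)
        # left-gap chain in closed form: H[i,j] = max_{j'<=j} M[j'] - (j-j'),
        # seeded by the free start H[i,0] = 0
        run = np.maximum.accumulate(np.concatenate(([0], M + js)))[1:]
        row = run - js
        H[i, 1:] = row
        # on ties prefer consuming a called base over opening a truth gap
        ptr[i, 1:] = np.where(row > M, 2, np.where(diag >= up, 0, 1)).astype(np.int8)

    i = int(np.argmax(H[:, m]))
    j = m
    matches = aligned = deleted = 0
    while j > 0:
        move = ptr[i, j]
        if move == 0 and i > 0:
            matches += int(a[i - 1] == b[j - 1])
            aligned += 1
            i -= 1
            j -= 1
        elif move == 1 and i > 0:
            aligned += 1
            i -= 1
        else:
            deleted += 1
            j -= 1
    denom = aligned + deleted
    return matches / denom if denom else 0.0


_TRUTH_COLUMNS = (
    "read_id",
    "template_seq",
    "complement_seq",
    "island_start",
    "island_end",
    "shift",
    "scale",
    "drift",
    "var",
    "scale_sd",
    "var_sd",
    "p_stay",
    "p_skip",
)


def write_truth_table(truths: list[ReadTruth], path) -> None:
    """Sidecar TSV with the per-read ground truth (sequences, island
    coordinates, scaling and transition parameters)."""
    with open(path, "w") as fh:
        fh.write("\t".join(_TRUTH_COLUMNS) + "\n")
        for t in truths:
            p = t.params
            row = (
                t.read_id,
                t.template_seq,
                t.complement_seq,
                str(t.island[0]),
                str(t.island[1]),
                repr(float(p.shift)),
                repr(float(p.scale)),
                repr(float(p.drift)),
                repr(float(p.var)),
                repr(float(p.scale_sd)),
                repr(float(p.var_sd)),
                repr(float(t.p_stay)),
                repr(float(t.p_skip)),
            )
            fh.write("\t".join(row) + "\n")


def read_truth_table(path) -> list[dict]:
    """Parse the sidecar truth TSV back into per-read dictionaries."""
    out = []
    with open(path) as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if tuple(header) != _TRUTH_COLUMNS:
            raise ValueError(f"unexpected truth table header in {path}")
        for line in fh:
            if not line.strip():
                continue
            vals = line.rstrip("\n").split("\t")
            rec = dict(zip(header, vals))
            rec["island_start"] = int(rec["island_start"])
            rec["island_end"] = int(rec["island_end"])
            for k in ("shift", "scale", "drift", "var", "scale_sd", "var_sd", "p_stay", "p_skip"):
                rec[k] = float(rec[k])
            out.append(rec)
    return out
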