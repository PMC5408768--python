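"""Per-read basecalling pipeline: split, train, decode, assemble sequence.

The decoded Viterbi state path is converted to DNA by starting from the
first state's k-mer and appending, for each consecutive state pair, the
minimum number of bases needed to explain the transition (the smallest
shift whose suffix/prefix overlap matches).  A consequence of this
minimal-overlap rule is that no output sequence can contain a homopolymer
run longer than the k-mer size: the state does not change while a
homopolymer threads through the pore.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hmm import DecodedPath, viterbi
from .pore_model import EventSequence, index_to_kmer, log_emission_matrix
from .scaling import ModelSet, StrandFit, TrainingConfig, train_read
from .strand_split import SplitResult, split_read
from .transitions import TransitionModel

__all__ = ["StrandCall", "BasecallResult", "states_to_sequence", "select_model", "basecall_read"]


@dataclass
class StrandCall:
    """Decoded output of one strand."""

    sequence: str
    model_name: str
    log_joint: float
    n_events: int


@dataclass
class BasecallResult:
    read_id: str
    strands: dict = field(default_factory=dict)  # strand name -> StrandCall
    split: SplitResult | None = None


def states_to_sequence(path: DecodedPath | np.ndarray, K: int) -> str:
    """DNA sequence from a state path by minimal-overlap concatenation.

    For consecutive states (prev, next), the smallest shift s in 0..K with
    suffix(prev, K-s) == prefix(next, K-s) is used and the last s bases of
    next are appended; stays (s = 0) therefore add nothing.
    """
    states = path.states if isinstance(path, DecodedPath) else np.asarray(path)
    if len(states) == 0:
        raise ValueError("empty state path")
    out = [index_to_kmer(int(states[0]), K)]
    prev = int(states[0])
    for nxt in states[1:]:
        nxt = int(nxt)
        for s in range(K + 1):
            # overlap of length K-s: suffix of prev == prefix of next
            if prev % 4 ** (K - s) == nxt // 4**s:
                break
        if s:
            out.append(index_to_kmer(nxt, K)[K - s :])
        prev = nxt
    return "".join(out)


def select_model(
    candidates: list[tuple[str, DecodedPath]], training_selected: str | None = None
) -> int:
    """Index of the model whose Viterbi decode is used for output.

    A model already selected during training (the e**20 likelihood rule)
    takes precedence; otherwise the candidate with the highest joint path
    log-probability wins, ties resolving to load order.
    """
    if not candidates:
        raise ValueError("no candidate decodes")
    if training_selected is not None:
        for i, (name, _) in enumerate(candidates):
            if name == training_selected:
                return i
    best = 0
    for i, (_, d) in enumerate(candidates[1:], start=1):
        if d.log_joint > candidates[best][1].log_joint:
            best = i
    return best


def _decode_strand(events: EventSequence, fits: list[StrandFit], training_selected: str | None):
    decoded = []
    for fit in fits:
        logem = log_emission_matrix(events, fit.model, fit.params)
        decoded.append((fit.model.name, viterbi(logem, fit.transitions)))
    chosen = select_model(decoded, training_selected)
    name, path = decoded[chosen]
    K = fits[chosen].model.K
    return StrandCall(
        sequence=states_to_sequence(path, K),
        model_name=name,
        log_joint=path.log_joint,
        n_events=len(events),
    )


def basecall_read(
    events: EventSequence,
    models: ModelSet,
    config: TrainingConfig | None = None,
    base_transitions: TransitionModel | None = None,
    read_id: str | None = None,
) -> BasecallResult:
    """Basecall one read: hairpin split, per-strand training, Viterbi.

    Reads in which no acceptable hairpin island is found are basecalled
    entirely as a template strand.  A numerical failure in one strand does
    not abort the other.
    """
    if config is None:
        config = TrainingConfig()
    if base_transitions is None:
        base_transitions = TransitionModel(K=models.template.K)
    if read_id is None:
        read_id = events.read_id

    # one clock per read: drift is fit on times re-zeroed at the read start
    events = events.rezeroed()
    split = split_read(events)
    strands: dict[str, EventSequence] = {}
    t0, t1 = split.template_range
    if t1 > t0:
        strands["template"] = events.slice(t0, t1)
    if split.complement_range is not None:
        c0, c1 = split.complement_range
        if c1 > c0 and models.complements:
            strands["complement"] = events.slice(c0, c1)
        elif c1 <= c0:
            warnings.warn(f"read {read_id}: empty complement segment after split", stacklevel=2)

    result = BasecallResult(read_id=read_id, split=split)
    if not strands:
        warnings.warn(f"read {read_id}: no events to basecall", stacklevel=2)
        return result

    train = train_read(strands, models, config, base_transitions)
    selected_name = None
    if train.selected_complement is not None:
        selected_name = models.complements[train.selected_complement].name

    for strand, ev in strands.items():
        fits = train.fits.get(strand)
        if not fits:
            continue
        try:
            result.strands[strand] = _decode_strand(
                ev, fits, selected_name if strand == "complement" else None
            )
        except FloatingPointError as exc:
            warnings.warn(f"read {read_id} {strand}: decoding failed ({exc})", stacklevel=2)
    return result
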