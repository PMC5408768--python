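"""Per-read estimation of the six pore-model scaling parameters.

Estimation proceeds in two stages.  A Method-of-Moments initializer
matches the first two moments of the event means to the moments of the
pore-model k-mer levels, giving shift and scale (the remaining four
parameters start neutral).  Optional EM rounds then refine all six: the
E-step runs Forward-Backward on small subsets taken from the start and end
of each strand to obtain state posteriors, and the M-step maximizes the
expected complete-data log emission likelihood - a weighted least-squares
fit of event means on (level_mean, 1, start_time) for (scale, shift,
drift), a weighted residual variance for var, and closed-form solutions of
the Inverse-Gaussian first-order conditions for (scale_sd, var_sd).

In double-strand mode the two strands of a read share one ScalingParams
and the M-step pools their weighted statistics (each strand keeps its own
pore model); in single-strand mode each strand trains independently.
Transition parameters can be re-estimated per strand each round by
Baum-Welch from the same E-step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .hmm import forward_backward
from .pore_model import (
    STDV_FLOOR,
    EventSequence,
    PoreModel,
    ScalingParams,
    log_emission_matrix,
)
from .strand_split import abasic_threshold
from .transitions import TransitionModel, update_transition_params

__all__ = [
    "TrainingConfig",
    "ModelSet",
    "StrandFit",
    "TrainResult",
    "mom_init",
    "em_round",
    "train_read",
]

# likelihood margin (nats) at which one complement model is selected over
# the others during training: a multiplicative factor of e**20
MODEL_SELECT_MARGIN = 20.0

_CLAMP_LO, _CLAMP_HI = 1e-3, 1e3


@dataclass(frozen=True)
class TrainingConfig:
    """Knobs of the per-read training loop.

    num_events: events taken from each end of each strand (the E-step runs
    on two such subsets per strand).  max_rounds defaults to 10 in
    single-strand mode and 20 in double-strand mode when left unset.
    min_progress is the log-likelihood gain (nats) below which training
    stops; the default of 1.0 corresponds to a multiplicative factor of e.
    """

    num_events: int = 100
    max_rounds: int | None = None
    min_progress: float = 1.0
    train_transitions: bool = True
    mode: str = "double_strand"
    no_train: bool = False

    def __post_init__(self) -> None:
        if self.num_events < 1:
            raise ValueError("num_events must be >= 1")
        if self.max_rounds is not None and self.max_rounds < 0:
            raise ValueError("max_rounds must be >= 0")
        if self.min_progress < 0:
            raise ValueError("min_progress must be >= 0")
        if self.mode not in ("single_strand", "double_strand"):
            raise ValueError(f"unknown scaling mode {self.mode!r}")

    @property
    def effective_max_rounds(self) -> int:
        if self.max_rounds is not None:
            return self.max_rounds
        return 20 if self.mode == "double_strand" else 10


@dataclass
class ModelSet:
    """The pore models applicable to one run: one template model and up to
    two alternative complement models."""

    template: PoreModel
    complements: list[PoreModel] = field(default_factory=list)

    def for_strand(self, strand: str) -> list[PoreModel]:
        if strand == "template":
            return [self.template]
        if strand == "complement":
            return list(self.complements)
        raise ValueError(f"unknown strand {strand!r}")


@dataclass
class StrandFit:
    """Training outcome of one strand under one pore model."""

    model: PoreModel
    params: ScalingParams
    transitions: TransitionModel
    log_likelihood: float | None = None


@dataclass
class TrainResult:
    fits: dict  # strand name -> list[StrandFit], one per candidate model
    selected_complement: int | None = None
    rounds: int = 0


def mom_init(events: EventSequence, model: PoreModel) -> ScalingParams:
    """Method-of-Moments shift/scale from the event-mean distribution.

    Matches mean and standard deviation of the observed event means to
    those of the pore-model levels, assuming states are visited roughly
    uniformly.  Events above the read's abasic threshold are excluded.
    The other four parameters are left neutral.
    """
    if len(events) == 0:
        raise ValueError("cannot initialize scaling from an empty strand")
    means = events.mean[events.mean <= abasic_threshold(events)]
    if means.size == 0:
        means = events.mean
    ev_mean, ev_sd = float(np.mean(means)), float(np.std(means))
    lv_mean, lv_sd = float(np.mean(model.level_mean)), float(np.std(model.level_mean))
    if ev_sd == 0.0 or lv_sd == 0.0:
        return ScalingParams(shift=ev_mean - lv_mean, scale=1.0)
    scale = ev_sd / lv_sd
    return ScalingParams(shift=ev_mean - scale * lv_mean, scale=scale)


@dataclass
class _SuffStats:
    """Linear sufficient statistics of the M-step, additive across chains
    and strands (this additivity is what pools double-strand training)."""

    A: np.ndarray  # 3x3 normal-equation matrix over x = (level_mean, 1, t)
    b: np.ndarray
    Syy: float
    n: float  # total posterior weight = number of events
    Sa: float  # sum w * sd_stdv * stdv / sd_mean^2
    Sb: float  # sum w * sd_stdv / sd_mean
    Sc: float  # sum w * sd_stdv / stdv

    def __iadd__(self, other: "_SuffStats") -> "_SuffStats":
        self.A += other.A
        self.b += other.b
        self.Syy += other.Syy
        self.n += other.n
        self.Sa += other.Sa
        self.Sb += other.Sb
        self.Sc += other.Sc
        return self


def _suff_stats(events: EventSequence, model: PoreModel, W: np.ndarray) -> _SuffStats:
    inv_var = 1.0 / model.level_stdv**2
    Wn = W * inv_var[None, :]
    r = Wn.sum(axis=1)
    m = Wn @ model.level_mean
    q = Wn @ (model.level_mean**2)
    t, y = events.start, events.mean
    A = np.array(
        [
            [q.sum(), m.sum(), (t * m).sum()],
            [m.sum(), r.sum(), (t * r).sum()],
            [(t * m).sum(), (t * r).sum(), (t * t * r).sum()],
        ]
    )
    b = np.array([(y * m).sum(), (y * r).sum(), (t * y * r).sum()])
    Syy = float((y * y * r).sum())
    x = np.maximum(events.stdv, STDV_FLOOR)
    g_over_e2 = model.sd_stdv / model.sd_mean**2
    g_over_e = model.sd_stdv / model.sd_mean
    Sa = float((x * (W @ g_over_e2)).sum())
    Sb = float((W @ g_over_e).sum())
    Sc = float(((W @ model.sd_stdv) / x).sum())
    return _SuffStats(A=A, b=b, Syy=Syy, n=float(W.sum()), Sa=Sa, Sb=Sb, Sc=Sc)


def _clamp(v: float) -> float:
    return float(min(max(v, _CLAMP_LO), _CLAMP_HI))


def _m_step(stats: _SuffStats) -> ScalingParams:
    """Maximize the expected complete-data log emission likelihood."""
    beta = None
    try:
        cand = np.linalg.solve(stats.A, stats.b)
        if np.all(np.isfinite(cand)) and cand[0] > 0:
            beta = cand
    except np.linalg.LinAlgError:
        pass
    if beta is None:
        # degenerate time design (e.g. constant start times): fix drift = 0
        A2, b2 = stats.A[:2, :2], stats.b[:2]
        cand = np.linalg.lstsq(A2, b2, rcond=None)[0]
        beta = np.array([cand[0], cand[1], 0.0])
        if not np.all(np.isfinite(beta)) or beta[0] <= 0:
            raise FloatingPointError("M-step regression failed")
    scale, shift, drift = (float(v) for v in beta)
    rss = stats.Syy - 2.0 * float(beta @ stats.b) + float(beta @ stats.A @ beta)
    var = _clamp(np.sqrt(max(rss, 0.0) / stats.n))

    scale_sd = _clamp(stats.Sa / stats.Sb)
    denom = stats.Sc - stats.Sb**2 / stats.Sa
    var_sd = _clamp(stats.n / denom) if denom > 0 else _CLAMP_HI
    return ScalingParams(
        shift=shift, scale=scale, drift=drift, var=var, scale_sd=scale_sd, var_sd=var_sd
    )


def training_chains(events: EventSequence, num_events: int) -> list[EventSequence]:
    """Subsets used by the E-step: num_events from the start and num_events
    from the end of the strand, as two independent chains (one chain if the
    strand is short).  Start times are assumed already re-zeroed per strand."""
    n = len(events)
    if n <= 2 * num_events:
        return [events]
    return [events.slice(0, num_events), events.slice(n - num_events, n)]


def em_round(
    chains: EventSequence | list[EventSequence],
    model: PoreModel,
    trans: TransitionModel,
    params: ScalingParams,
) -> tuple[ScalingParams, float, np.ndarray]:
    """One EM round on one strand.

    Returns the updated ScalingParams, the E-step log-likelihood under the
    *incoming* parameters, and the pooled shift-class transition masses
    (for Baum-Welch).  Raises FloatingPointError on a non-finite
    likelihood; callers keep the previous parameters in that case.
    """
    if isinstance(chains, EventSequence):
        chains = [chains]
    stats = None
    loglik = 0.0
    masses = np.zeros(3)
    for chain in chains:
        logem = log_emission_matrix(chain, model, params)
        fb = forward_backward(logem, trans)
        if not np.isfinite(fb.log_likelihood):
            raise FloatingPointError("non-finite likelihood in E-step")
        loglik += fb.log_likelihood
        masses += fb.shift_masses
        s = _suff_stats(chain, model, fb.posteriors)
        if stats is None:
            stats = s
        else:
            stats += s
    return _m_step(stats), loglik, masses


@dataclass
class _Session:
    """One training session: the strands it couples, one candidate model
    per strand, shared or per-strand parameters, per-strand transitions."""

    strands: list[str]
    chains: dict
    models: dict
    params: dict
    transitions: dict
    complement_index: int | None
    loglik: float = -np.inf
    strand_logliks: dict = field(default_factory=dict)


def _strand_loglik_and_stats(sess, strand):
    model = sess.models[strand]
    params = sess.params[strand]
    trans = sess.transitions[strand]
    stats = None
    loglik = 0.0
    masses = np.zeros(3)
    for chain in sess.chains[strand]:
        logem = log_emission_matrix(chain, model, params)
        fb = forward_backward(logem, trans)
        loglik += fb.log_likelihood
        masses += fb.shift_masses
        s = _suff_stats(chain, model, fb.posteriors)
        stats = s if stats is None else (stats.__iadd__(s))
    return loglik, stats, masses


def train_read(
    strands: dict,
    models: ModelSet,
    config: TrainingConfig,
    base_transitions: TransitionModel | None = None,
) -> TrainResult:
    """Estimate scaling (and optionally transition) parameters per strand.

    ``strands`` maps "template"/"complement" to that strand's events (the
    hairpin island excluded).  Every strand/candidate-model pair starts
    from Method of Moments; unless no_train is set, EM rounds follow until
    the round budget is exhausted or the likelihood gain drops below
    min_progress.  With two complement candidates, a candidate whose
    likelihood beats every other by more than 20 nats is selected
    immediately; otherwise selection is left to Viterbi.
    """
    K = models.template.K
    if base_transitions is None:
        base_transitions = TransitionModel(K=K)

    # start times are expected to be re-zeroed once per read (not per
    # strand): double-strand shared scaling is only self-consistent when
    # both strands fit drift on a common clock
    live: dict[str, EventSequence] = {}
    for name, ev in strands.items():
        if ev is None or len(ev) == 0:
            warnings.warn(f"strand {name!r} is empty; skipping", stacklevel=2)
            continue
        live[name] = ev

    def fits_from(sessions, selected, rounds):
        fits: dict[str, list[StrandFit]] = {}
        for sess in sessions:
            for strand in sess.strands:
                fits.setdefault(strand, []).append(
                    StrandFit(
                        model=sess.models[strand],
                        params=sess.params[strand],
                        transitions=sess.transitions[strand],
                        log_likelihood=sess.strand_logliks.get(strand),
                    )
                )
        return TrainResult(fits=fits, selected_complement=selected, rounds=rounds)

    # build sessions: double-strand couples template with each complement
    # candidate; single-strand (or a template-only read) trains each
    # strand/candidate on its own
    sessions: list[_Session] = []
    double = config.mode == "double_strand" and "complement" in live
    if double:
        for ci, cmodel in enumerate(models.for_strand("complement")):
            sessions.append(
                _Session(
                    strands=["template", "complement"],
                    chains={},
                    models={"template": models.template, "complement": cmodel},
                    params={},
                    transitions={},
                    complement_index=ci,
                )
            )
    else:
        for strand in live:
            cands = models.for_strand(strand)
            for ci, m in enumerate(cands):
                sessions.append(
                    _Session(
                        strands=[strand],
                        chains={},
                        models={strand: m},
                        params={},
                        transitions={},
                        complement_index=ci if strand == "complement" else None,
                    )
                )

    for sess in sessions:
        mom = {}
        for strand in sess.strands:
            ev = live[strand]
            sess.chains[strand] = training_chains(ev, config.num_events)
            mom[strand] = mom_init(ev, sess.models[strand])
            sess.transitions[strand] = base_transitions
        if len(sess.strands) > 1:
            # shared parameters: event-count-weighted average of the
            # per-strand moment estimates
            w = np.array([len(live[s]) for s in sess.strands], dtype=float)
            w /= w.sum()
            shift = float(sum(wi * mom[s].shift for wi, s in zip(w, sess.strands)))
            scale = float(sum(wi * mom[s].scale for wi, s in zip(w, sess.strands)))
            shared = ScalingParams(shift=shift, scale=scale)
            sess.params = {s: shared for s in sess.strands}
        else:
            sess.params = mom

    if config.no_train or config.effective_max_rounds == 0 or not live:
        return fits_from(sessions, None, 0)

    selected: int | None = None
    if len([s for s in sessions if s.complement_index is not None]) <= 1:
        selected = None
    rounds_done = 0
    for rnd in range(config.effective_max_rounds):
        for sess in sessions:
            total = 0.0
            pooled = None
            strand_masses = {}
            try:
                for strand in sess.strands:
                    ll, stats, masses = _strand_loglik_and_stats(sess, strand)
                    sess.strand_logliks[strand] = ll
                    total += ll
                    strand_masses[strand] = masses
                    if len(sess.strands) > 1:
                        pooled = stats if pooled is None else pooled.__iadd__(stats)
                    else:
                        sess.params[strand] = _m_step(stats)
                if pooled is not None:
                    shared = _m_step(pooled)
                    sess.params = {s: shared for s in sess.strands}
                if config.train_transitions:
                    for strand in sess.strands:
                        p_stay, p_skip = update_transition_params(
                            strand_masses[strand],
                            (sess.transitions[strand].p_stay, sess.transitions[strand].p_skip),
                        )
                        sess.transitions[strand] = sess.transitions[strand].with_params(
                            p_stay, p_skip
                        )
            except FloatingPointError:
                warnings.warn(
                    f"EM round {rnd + 1} aborted for strands {sess.strands}; "
                    "keeping previous parameters",
                    stacklevel=2,
                )
                total = sess.loglik
            sess.new_loglik = total
        rounds_done = rnd + 1

        # complement model selection by the e**20 likelihood margin
        comp_sessions = [s for s in sessions if s.complement_index is not None]
        if selected is None and len(comp_sessions) > 1:
            lls = [s.strand_logliks.get("complement", -np.inf) for s in comp_sessions]
            order = np.argsort(lls)[::-1]
            if lls[order[0]] - lls[order[1]] > MODEL_SELECT_MARGIN:
                selected = comp_sessions[order[0]].complement_index
                sessions = [
                    s
                    for s in sessions
                    if s.complement_index in (None, selected)
                ]

        progress = max(sess.new_loglik - sess.loglik for sess in sessions)
        for sess in sessions:
            sess.loglik = sess.new_loglik
        if progress < config.min_progress:
            break

    return fits_from(sessions, selected, rounds_done)
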