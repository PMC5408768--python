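# Methods

## The model

`porecall` basecalls segmented nanopore current data. Its input is a list
of *events* — blocks of raw current samples summarized by a start time
(s), a length (s), a mean (pA) and a standard deviation (pA) — as produced
by the device-side segmenter. The hidden state behind event *i* is the
K-base DNA context occupying the pore (K = 6 by default, giving 4096
states), and decoding is maximum a posteriori path inference in a hidden
Markov model.

**Emissions.** A pore model assigns each k-mer *k* four parameters: the
event mean is Gaussian with mean mu_k and sd sigma_k, and the event
standard deviation is Inverse Gaussian with mean eta_k and shape gamma_k.
Per read (and optionally per strand), six scaling parameters distort the
model:

    mean_i ~ N(scale * mu_k + shift + drift * start_i, (var * sigma_k)^2)
    stdv_i ~ IG(scale_sd * eta_k, var_sd * gamma_k)

The emission density of an event is the product of the two densities.
Events reporting stdv = 0 (possible when a segment spans a single sample)
are clamped to 1e-3 pA before evaluating the IG density, which is
undefined at 0. The IG parameterization is taken literally: the first
argument is the mean and the second the shape; how a shape parameter
*should* co-transform with a scaled mean under a change of units is
ambiguous, and the literal reading is used consistently in the simulator
and the estimator, so the two cannot disagree.

**Transitions.** Consecutive events advance the context by a variable
shift: 0 (a "stay": the segmenter split one physical event), 1 (a normal
step), or >= 2 (skips: events were lost). With stay probability p_stay and
skip probability p_skip (defaults .1 and .3), and p_skip1 =
p_skip/(1+p_skip) the probability of exactly one skip, the full transition
kernel sums, over every shift amount i, the probability of the suffix of
k1 of length K-i matching the prefix of k2, weighted p_skip1^(i-1)/4^i
(with the stay term p_stay, the step term p_step/4 where p_step =
1-p_stay-p_skip, and a closed-form tail for shifts >= K that applies to
every target). Rows of this kernel sum to exactly 1.

For decoding, shifts beyond 2 are disregarded: each state keeps at most 21
successors (itself, 4 step successors, 16 skip successors; fewer for
low-complexity k-mers whose successor sets coincide — coinciding entries
have their probabilities summed). Truncated rows are renormalized — the
kept mass is the constant Z = p_stay + p_step + p_skip1 for every row —
so likelihoods remain comparable across models, which matters for
complement-model selection.

## Estimation

**Strand separation.** The hairpin adapter joining the template and
complement strands contains abasic DNA whose current (>100 pA) sits well
above the 50–90 pA band of regular DNA. Because shift/scale are unknown at
this stage, the abasic threshold is estimated per read as the
nearest-rank 99th percentile of event means plus 5 pA. Runs of >= 5
consecutive above-threshold events are islands; islands closer than 50
events are merged (edge gap, transitively); the island nearest the middle
of the read splits it, provided its midpoint lies in the middle third
[floor(n/3), floor(2n/3)) of event indices. Ties between equidistant
islands go to the earlier one. Island events belong to neither strand.
Reads without an acceptable island are basecalled whole as template.

*Limitation*: the 99%-quantile rule assumes the hairpin occupies < 1% of
the read's events. Real reads carry ~10^4 events, so a 10–50 event island
is far below 1%; on synthetic reads shorter than ~800 events with the
default 10-event island the percentile lands inside the island itself and
no split is found (the read is then called as template, as designed).

**Method of Moments.** shift and scale are initialized by matching the
mean and standard deviation of the observed event means (events above the
abasic threshold excluded) to those of the pore-model levels; drift, var,
scale_sd, var_sd start neutral. In double-strand mode the shared
initializer is the event-count-weighted average of the per-strand
estimates.

**EM refinement.** Each round runs Forward–Backward on two subsets of each
strand — `num_events` (default 100) from the start and from the end — as
two independent chains, then maximizes the expected complete-data log
emission likelihood in closed form:

- (scale, shift, drift) solve the 3x3 weighted least-squares normal
  equations regressing event means on (mu_k, 1, start_i) with weights
  w_ik / sigma_k^2 (w_ik the state posteriors);
- var^2 = sum w_ik (mean_i - fit_ik)^2 / sigma_k^2 / sum w_ik;
- scale_sd = sum(w gamma x / eta^2) / sum(w gamma / eta), the root of the
  IG first-order condition (x = event stdv);
- var_sd = sum w / sum(w gamma (x - scale_sd*eta)^2 / (scale_sd^2 eta^2 x)).

All statistics are additive, so double-strand mode (the default) pools
them across both strands — each strand under its own pore model — to fit
one shared ScalingParams per read; single-strand mode fits each strand
independently. Training stops after `max_rounds` (10 single-strand, 20
double-strand) or when the likelihood gain drops below `min_progress`
(default 1.0 nat, a multiplicative factor of e). If the regression design
is singular (e.g. constant start times), drift is fixed at 0 and the 2x2
system solved instead; var, scale_sd, var_sd are clamped to [1e-3, 1e3].

Event start times are re-zeroed once per read (not per strand): with
double-strand shared scaling and drift != 0, per-strand clocks would make
the shared shift misspecified by drift times the complement's start
offset.

**Transition training.** When enabled (default), each round also
re-estimates (p_stay, p_skip) per strand from the expected posterior
transition mass in the three shift classes (Baum–Welch). The M-step is the
maximum-likelihood inversion of the truncated kernel's class weights:
observed class fractions (a, b, c) are matched to
(p_stay, p_step, p_skip1)/Z by solving (1-c)Z + cZ/(1-cZ) = 1 for Z by
bisection, then p_stay = aZ and p_skip = cZ/(1-cZ). (The naive ratio
estimate p_skip1_hat = c/(b+c) inverts the *untruncated* geometric-skip
weights and overestimates p_skip by ~0.1 at the defaults when applied to
truncated-model posteriors.) Estimates are clamped to [1e-4, 0.49].
Repeated rounds drift p_skip upward slowly as multi-skip mass is folded
into the one-skip class; the clamp and the scaling-EM stopping rule bound
this in practice.

**Complement model selection.** Up to two complement pore models may
apply. After every training round, a candidate whose strand likelihood
beats every other's by more than 20 nats (a factor of e^20) is selected
and the others dropped. If training ends undecided, the strand is decoded
with all candidates and the Viterbi joint log-probability (the last cell
of the Viterbi matrix) picks the winner; a training-time selection takes
precedence over a later Viterbi comparison.

## Decoding and output

Viterbi runs in natural-log space over the truncated neighbour structure,
with a uniform initial distribution; score ties resolve toward the
numerically smallest predecessor state, making decodes bit-reproducible.
The DNA sequence is built by minimal overlap: starting from the first
state's k-mer, each consecutive state pair appends the fewest bases (the
smallest shift s with suffix(prev, K-s) = prefix(next, K-s)) consistent
with the transition. Consequences: stays add nothing, output never
contains a single-base run longer than K, and size-1 repeats longer than K
are systematically collapsed. Output is FASTA (no per-base quality is
estimated — per-base error is too high for qualities to be informative),
one record per decoded strand, headers `read_id:strand model=NAME`.

## Numerical engineering

Forward–Backward and Viterbi carry log-space recursions; the per-step
sums apply the sparse kernel in probability space after a max-shift.
Because step/skip successor sets have the regular form
(k mod 4^(K-1))*4 + b and (k mod 4^(K-2))*16 + c, applying the kernel
reduces to contiguous reshape-folds over the leading/trailing bases —
no sparse matrix products in the inner loop. Emission matrices are
assembled with per-state and per-event precomputed logarithms and pure
arithmetic per cell. Forward–Backward also accumulates the expected
transition mass per shift class (they sum to n_events - 1), feeding the
Baum–Welch update.

## The simulator and what passing tests mean

`simulate` draws a random pore model (4^K level means uniform, without
collision, on the 50–90 pA band; sigma in [0.5, 2], eta in [1, 3], gamma
in [3, 10]), walks a random sequence's k-mer chain with stays (prob
p_stay), steps (prob p_step) and j-skip jumps (prob p_skip1^j, the same
law as the transition kernel), and emits event means/stdvs from the
scaled Gaussian/IG model, with exponential event lengths (mean 0.03 s)
accumulating into start times. A two-strand read is template events, an
abasic island (>= 5 events, default 10, means N(110, 1) pA), then
complement events from the reverse-complement sequence under a second
model. A `noise_inflation` factor multiplies sigma_k and deflates gamma_k
(0 = noise-free). Templates carry one planted 10-base homopolymer by
default, exercising the decoder's run cap. Default read length is 500
bases (~750 events with the default transition rates).

Basecalls are scored against the known truth with the identity used for
mapped nanopore reads: match columns divided by (read bases aligned +
reference bases deleted), under a global alignment (match +1, mismatch -1,
gap -1) whose end gaps are free on the called sequence only. This aligner
is implemented here because the metric requires match/mismatch scoring
and asymmetric free ends, not plain edit distance.

The simulator reproduces the generative assumptions of the decoder
exactly. Real data violate them in ways the synthetic tests therefore do
not probe: level means are not uniformly spread (they cluster by k-mer
composition), event noise is heavier-tailed and autocorrelated, the
segmenter's stay/skip process is not memoryless, and raw-signal artifacts
(pore blocks, open-pore current) have no synthetic counterpart. Passing
tests demonstrate correctness of the inference machinery under its own
model, not field accuracy on real flowcell data. Conversely, the uniform
level spread is *adversarial* for scaling estimation: with 4096 levels
packed ~0.01 pA apart, a global offset of the read is nearly absorbable
by reassigning states, so shift is weakly identified (its error tracks
the shift/scale ridge, err_shift ~ -mean(mu) * err_scale) and a drift
offset larger than the event noise is absorbed entirely. scale and var
recover to a few percent at 2x100 training events; shift recovers to
~0.5–1 pA and drift only when drift * read_duration stays comparable to
the noise scale. Structured real-world level densities pin these
parameters much harder than this worst case.

## Parameter reference

| parameter | default | units | meaning |
|---|---|---|---|
| K | 6 | bases | k-mer/context length (state space 4^K) |
| p_stay | 0.1 | prob | prior stay probability |
| p_skip | 0.3 | prob | prior skip probability |
| num_events | 100 | events | training subset size per strand end |
| max_rounds | 10 / 20 | rounds | EM budget (single / double strand) |
| min_progress | 1.0 | nats | stop when likelihood gain falls below |
| mode | double_strand | — | share scaling across strands or not |
| no_train | off | — | Method-of-Moments only (fastest) |
| abasic level (sim) | 110 | pA | planted hairpin current |
| island_len (sim) | 10 | events | planted hairpin length |
| noise_inflation (sim) | 1.0 | — | scales sigma_k, deflates gamma_k |
| mean_event_length (sim) | 0.03 | s | exponential event duration |

Problem sizes used by the test suite and the acceptance script — 500 to
1000-base templates, 20–200 reads per property, 2600-base strands for
recovery studies, one ~7000-event fixture for transition training — were
chosen so every property is measured on the scale at which its estimator
operates (training always sees 2x100 events regardless of read length)
while the whole suite stays desk-scale.
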