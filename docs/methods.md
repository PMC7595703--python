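# Methods

## Model family

All twelve models are discrete-time linear state-space learners over the
channel-trial force-compensation scale (1 = perfect compensation of the
field; the physical field constant never enters). Each contextual cue
j ∈ {1, 2} owns a memory composed of up to four processes
p ∈ {fast, slow, ultraslow, hyperslow}; a model structure is the triple

* `n_timescales ∈ {2, 3, 4}` — dual-, triple- or quadruple-rate,
* `fast_mode ∈ {one_fast, two_fast}` — one shared fast process versus one
  per memory,
* `switch_mode ∈ {binary, weighted}` — gate `(g_cue, g_other) = (1, 0)` or
  `(c, 1−c)`.

On every trial the model first emits its output using the current trial's
cue (the gate and the prediction are computed before the update):

    one_fast : x = x_f + Σ_j g_j (x_s,j + x_us,j + x_hs,j)
    two_fast : x = Σ_j g_j Σ_p x_p,j

then experiences the error `e = f − x` (field trials; `e = 0` on channel
trials, which mechanically clamp lateral error) and updates every state

    x_p,j ← A_p x_p,j + B_p e g_j

with the shared fast state of one_fast models learning ungated
(`x_f ← A_f x_f + B_f e`). Retention applies on *every* trial; learning is
gated. States of timescales absent from a structure are represented as
zero-fixed entries of an 8-slot state vector, so a single stepping kernel
serves all twelve structures. Channel trials therefore produce pure
retention decay, `x_p ← A_p x_p` — the same law as the reference decay
curves `x_m = A^m x_0` used in the decay analysis.

Consequences worth knowing: a two_fast binary model driven by a single cue
reduces exactly to the classic two-state model; a weighted model with
`c = 1` is exactly its binary counterpart; on an alternating schedule with
opposing fields the binary two_fast dynamics are exactly antisymmetric
between cues. These identities are enforced by tests against independent
re-implementations.

## Paradigm generator

Both experiment variants are built from 16-trial blocks, 8 trials per cue,
each cue contributing 7 field trials and 1 channel trial in standard
blocks; order within a block is a seeded uniform shuffle (the design's
pseudo-randomisation states no further constraints). Phases:

| phase | exp 1 | exp 2 |
|---|---|---|
| pre-exposure (null field) | 10 blocks (160 trials) | 10 blocks |
| adaptation (cue 1 → +1, cue 2 → −1) | 47 blocks (752) | 60 blocks (960) |
| memory-decay region within adaptation | blocks 26–45 | blocks 41–50 |
| de-adaptation (mapping reversed) | 4–25 blocks (64–400) | 4–20 blocks (64–320) |
| error-clamp (all channel) | 20 blocks (320) | 10 blocks (160) |

A decay block opens with an exposure trial of its cue followed by a run of
consecutive same-cue channel trials (5 in exp 1, 3 in exp 2); in exp 1 the
run is immediately followed by an exposure trial of the opposite cue and
decay blocks alternate cues with a standard block interspersed; in exp 2
the ten decay blocks are consecutive, alternating cues (the source design
does not state the within-block interleaving for exp 2; alternation as in
exp 1 is this package's documented choice). Remaining trials fill each
decay block with the standard per-cue composition (including the opposite
cue's single channel trial) — the full decay-block contents beyond the
motif are likewise a documented choice.

The de-adaptation phase is closed-loop: blocks are generated one at a time
while the participant model is simulated with observation noise, and after
each block (from the 4-block minimum onward) the means of the last three
*noisy* channel observations per cue — raw, not centered, exactly the
statistic available online during the experiment — are tested: exp 1 stops
when the cue difference turns negative, exp 2 when cue 1's mean is below
zero *and* cue 2's above. Hitting the block cap terminates the phase and is
recorded (`termination="cap"`), not an error.

Counterbalancing is a sign flag: group-B participants are generated on the
canonical convention (cue 1 adapts positive) and have all field signs and
observations negated at the end; cohorts alternate A/B.

For the headline one-fast/two-fast spontaneous-recovery contrast,
`build_spontaneous_recovery_schedule` instead truncates de-adaptation at
the exact trial where the reference one-fast-two-slow model's slow-state
difference first returns to zero (for that model the shared fast state
cancels out of the cue difference). The block-quantised, lagging
last-3-trials criterion deliberately over-runs this point, which is why the
demonstration uses the trial-resolved rule.

## Noise model

Channel observations are the model output plus independent uniform noise on
[−w, +w], with w = 0.0831 (exp 1) and w = 0.0715 (exp 2) — the pre-exposure
force-compensation variability of the two cohorts. Noise is pure
observation noise: it does not enter the state update (field-trial errors
are noise-free), the simplest model consistent with estimating the level
from pre-exposure measurement variability. The noisy values do drive the
online termination, so de-adaptation lengths vary across seeds. What this
generator does **not** emulate: kinematic errors and raw force profiles,
trial-to-trial motor noise inside the learning loop, slow drifts or
fatigue, and participant exclusion. Passing tests therefore show that the
pipeline is correct and identifiable under the stated statistical
assumptions, not that those assumptions exhaust real data.

## Preprocessing

Fitting operates on the counterbalance-flipped, blockwise-centered channel
series: within each block the mean of the two cues' per-cue channel means
is subtracted from every channel value. Per-cue means are weighted equally
regardless of trial count (relevant in decay and clamp blocks, where the
two cues contribute unequally; the weighting is this package's documented
choice). The operator is linear and idempotent, and the equal-weighted
grand mean over per-cue block means is exactly zero afterwards. Model
predictions pass through the *identical* operator before the SSE — required
for one_fast models, whose shared fast state contributes common-mode output
that centering removed from the data. Section averaging for display splits
a series into contiguous near-equal sections, longer sections first.

## Fitting

Least squares over all channel trials of the whole experiment, parameters
constrained to

    0.5 < A_f < 0.95 < A_s, A_us < A_hs < 1
    0.1 < B_f < 0.35
    0 < B_hs, B_us < 0.02 < B_s < 0.35
    B_s < B_f
    0.5 < c < 1

(the boxes pin each process to its intended timescale so that, e.g., a slow
process cannot impersonate a fast one; `A_s < A_us` is deliberately *not*
enforced, matching the printed constraints). Optimisation is Nelder-Mead
inside the boxes via the sin² transform `x = lo + (hi−lo)·sin²θ`
(fminsearchbnd-style), with open bounds realised as closed intervals 1e−6
inside; the ordering constraints are enforced by a large finite penalty
(1e6 scaled by the violation) so the simplex can recover, never by an
exception. Note the objective itself evaluates any parameters in [0, 1]
without box-penalty: several median generating values sit exactly on
printed bounds and must evaluate cleanly. Each fit draws `n_restarts`
random feasible starts (restart seeds derived deterministically as
`[seed, restart]`) and keeps the smallest SSE; convergence tolerances are
xatol 1e−6 (θ-space), fatol 1e−10, with a 600·k evaluation cap. Because the
generating values lie on box corners that the transform only approaches
asymptotically, a refit on noise-free data reaches SSE ≈ 1e−10 rather than
exactly 0.

## Model comparison

`BIC = n ln(SSE/n) + k ln n` (Gaussian least-squares form; the source does
not print its formula, and since all comparisons are differences at fixed
n any additive constant cancels). `k` counts structural parameters only —
the observation variance is common to all models and cancels in ΔBIC. An
SSE of exactly 0 is floored at 1e−12 before the logarithm. BIC differences
map to evidence categories at 2 / 6 / 10 (none / positive / strong / very
strong); models within 2 BIC of a participant's best are flagged as tied.
Ranks break exact ties by fewer parameters, then canonical model order
(referent `1f_2s_bin` first).

## Model recovery and decay

Recovery runs in fixed-schedule mode: participant designs are realised once
(closed loop under the default ground-truth model, the two-fast weighted
triple-rate at its median parameters) and all generating models share those
trial sequences; per-dataset noise and per-fit restart seeds derive from
the run seed. The full setting is 8 replicates × 10 designs = 80 datasets
per generating model per experiment with 10 restarts per fit; the
always-on test suite and the acceptance script use the scaled-down setting
(2 replicates × 3 designs, four generating models spanning both fast modes
and switch types, 3 restarts), which already reproduces the qualitative
recovery pattern: fast-process count and switch type recovered essentially
perfectly, timescale misses skewed toward fewer timescales. The full run
remains available through `run_model_recovery` / `dualadapt recover`.

The decay comparison extracts (a) the decay-run channel series averaged
over blocks, cue-signed, and (b) the clamp-phase cue-signed series averaged
in threes, and simulates `x_m = A^m x_0` for
A ∈ {0.5, 0.8, 0.9, 0.95, 0.98, 0.993, 0.997, 0.999, 1}. The default `x_0`
is the generating model's clamp-entry output (the source's starting value
is not printed; this is the package's documented default, falling back to
the first observed clamp point when no generating model is attached).

## Numerical notes

The trial loop is a numba-jitted kernel over an 8-slot state vector (~5 µs
per simulated experiment), with a pure-Python fallback on the same code
path; the readable `step_trial`/`MemoryState` API is tested to agree with
the kernel to machine precision. Simulations raise `FloatingPointError` on
non-finite outputs (parameter blow-up) rather than returning garbage.
Degenerate inputs — empty schedules, blocks with no channel observations,
series shorter than the section count, negative noise halfwidths — raise
`ValueError` with specific messages.

## Known limitations

* The fit is a local multi-start optimum, not a certified global one; on
  noisy data occasional restarts settle in a distinct basin (visible as a
  heavy tail in trajectory-recovery error), which more restarts mitigate.
* BIC assumes i.i.d. Gaussian residuals; the generator's residuals are
  uniform (lighter-tailed), which is conservative for these comparisons
  but worth remembering when applying the pipeline to real data.
* The binary/weighted distinction becomes unidentifiable as c → 1; several
  one-fast weighted medians sit exactly at c = 1 and will tie with their
  binary counterparts up to the k-penalty.
* Only two cues/memories are modelled; the architecture is not a
  general-N mixture-of-experts.
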