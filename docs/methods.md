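# Methods

## The problem being modelled

In Pavlovian magazine-approach conditioning, rats learn that discrete
10-s visual/auditory cues predict a sucrose reward, and anticipatory
head entries into the reward magazine (goal-tracking, measured here in
the last 5 s of the cue) index the cue's acquired associative strength.
Under *massed* training — inter-trial intervals around 10 s — cue
competition degrades: a pretrained predictor fails to block a redundant
added cue. Giving an animal *agency* over trial onset (it nose-pokes to
start each trial; a yoked partner passively receives the identical
event stream) restores competition. The computational hypothesis the
package implements is that agency induces a **positivity bias in
prediction-error weighting**: learning from better-than-expected
outcomes is amplified relative to learning from worse-than-expected
ones, while passive exposure weights both equally.

## Designs

Four built-in designs (`cuecomp.designs`) specify per-session trial
types with exact reinforced/nonreinforced counts:

| id | pretraining | compound / training | sessions |
|---|---|---|---|
| `exp1_blocking` | 48 A(1), 48 B(0) | 36 A(1), 36 B(0), 12 AX(1), 12 BY(1), + 2 X(0) and 2 Y(0) probes from session 9 | 14 + 20 |
| `exp2_competition` | 24 each of A(1), B(0), X(0.75), Y(0.25) | 10 A(1), 10 B(0), 30 AX(1), 10 X(0), 30 BY(0), 10 Y(1) | 10 + 20 |
| `exp3_no_configural` | 48 A(1), 48 B(0) | 24 A(1), 24 B(0), 24 AX(0.75), 24 BY(0.25), + 2 X(0) and 2 Y(0) probes from session 13 | 8 + 32 |
| `exp4_patterning` | — | 16 each of A(1), X(1), AX(0), B(0), Y(0), BY(1) | 42 |

Session totals are 96 trials, or 100 where probes or the exp2 compound
table apply. Fractional reward probabilities are realized as **exact
per-session counts** (e.g. AX(0.75) = 18 reinforced + 6 nonreinforced),
not Bernoulli draws, so every generated session reproduces the design
odds exactly; reinforced positions are shuffled within type.

Trial order is pseudorandom under the constraint that no trial type
runs more than three in succession. The order is drawn sequentially —
each position sampled among types with remaining trials, in proportion
to remaining counts, excluding a type that has just run three times —
with a restart on the rare dead end (budget 10,000 restarts). This is
deterministic per seed and fast even for the two-type 48/48 sessions,
where rejection-sampling whole shuffles would succeed only ~1 time in
1,200. The sampled distribution is not uniform over admissible orders;
no claim in the package depends on uniformity, only on the constraint
and the exact counts. Only the run-length constraint is enforced; no
additional sub-block balancing is assumed.

Yoking (`yoke`, `run_yoked_groups`) gives both members of a pair the
identical event sequence — same types, same order, same reinforcement —
differing only in the agency annotation and learning parameters.
Session-level RNG streams derive from `(seed, pair, phase, session)` so
any session is reproducible in isolation. Counterbalancing of physical
stimuli is not modelled (the learning rule is symmetric in cue
identity), and real-time structure (ITIs, trial-availability windows,
session timeouts) is out of scope; an optional per-trial omission
probability, applied identically within a pair, stands in for forgone
trial offers.

## Learning rule

State is a vector of associative strengths V over stimulus *units*. A
trial with cue set S activates its elemental units; optionally one
configural unit per compound (needed for patterning, where no linear
elemental solution exists) and an always-on context unit. With outcome
r ∈ {0, 1}:

    δ = λ·r − Σ_{i ∈ active} V_i
    V_i ← V_i + α_i · β · w(δ) · δ        for every active unit i

with w(δ) = `w_pos` if δ > 0, `w_neg` if δ < 0; δ = 0 is a no-op.
Strengths may go negative (conditioned inhibition). Validation enforces
α, β ∈ (0, 1], w ≥ 0 and α·β·max(w_pos, w_neg) ≤ 1, which guarantees
bounded, non-oscillating single-cue acquisition; with continuous
reinforcement that acquisition has the closed form
V_t = λ(1 − (1 − αβw_pos)^t), used as an analytic oracle in the tests.
With w_pos = w_neg the rule *is* plain Rescorla–Wagner (verified
against an independently coded oracle to 1e-12 over all four designs).
Attaching the weight to δ or to the learning rate is algebraically
identical here; the package exposes it as a weight on the learning
term.

"Responding" at the simulation level is the pre-update aggregate
prediction for the trial's cue set — learning and performance are kept
separate, with the mapping to counts confined to `cuecomp.behavior`.
Probe trials update strengths as ordinary nonreinforced trials (that is
what the animal experiences); they are flagged so analyses can isolate
them.

## Parameter defaults and how they were set

Defaults (all overridable per call or via config):

| parameter | default | meaning |
|---|---|---|
| λ | 1.0 | asymptote of conditioning (unitless) |
| α | 0.003 | elemental salience; β = 1 is folded in |
| agency w_pos, w_neg | 1.0, 0.25 | positivity bias |
| passive w | 0.45 | symmetric weighting |
| configural salience scale | 3.0 | configural α relative to elemental (exp4 only) |
| context unit | off | summation with background; available as a switch |

Three considerations fix this region, and they were settled in one
exploration pass before any downstream test was written:

1. **Pretraining must be preasymptotic at the default α.** Exp 1's
   group difference exists only if the blocking cue A is still below
   asymptote after 14 × 48 reinforced trials; complete pretraining
   produces complete blocking in *both* groups. That requires
   αβw ~ 1/672, hence the small α. Setting `alpha=0.3` recovers the
   asymptotic regime (complete blocking everywhere), which the package
   treats as a check, not a default.
2. **The groups must differ in positive-PE learning.** A(1)/B(0)
   pretraining generates only positive or zero PEs, so a bias expressed
   purely as discounting of negative PEs (equal w_pos across groups)
   cannot speed agency pretraining and cannot produce the blocking
   difference. The agency condition therefore *amplifies* positive-PE
   learning relative to passive (1.0 vs 0.45) and *discounts*
   negative-PE learning (0.25 vs 0.45) — both mechanisms reported for
   self-determined learning in the choice literature.
3. **Patterning must be solvable, and harder for the biased learner.**
   Negative patterning (A+, X+, AX−) needs the configural unit to
   acquire inhibition from negative PEs; the agency condition's
   discounted w_neg slows exactly that, while its amplified w_pos
   inflates the summed compound response. A configural salience three
   times the elemental value makes both problems solvable within 42
   sessions at the small elemental α without erasing the
   agency/passive ordering.

At these defaults the simulated direction pattern across all four
designs matches the target phenomenology: blocking present under
agency and strongly attenuated under passive (and complete in both at
asymptote); terminal Y > X under agency but X > Y under passive in the
exp 2 monitoring trials; probe Y > X under agency only in exp 3;
negative patterning solved by both but more weakly under agency;
positive patterning solved comparably by both. This pattern is stable
across schedule seeds because each index averages hundreds of trials.

**The bias family.** For parameter sweeps and recovery the bias is a
single ratio ρ = w_neg/w_pos moved along a line of constant total
weight: w_pos = T/(1+ρ), w_neg = ρ·w_pos with T = 1.25, so the agency
default sits at ρ = 0.25 and ρ = 1 is the unbiased rule at matched
overall rate (`model.bias_params`). This formalization matters: if ρ is
instead lowered by shrinking w_neg at fixed w_pos, the blocked cue X is
also protected from probe extinction and the terminal Y−X contrast is
*not* monotone in the bias. Reallocating a fixed learning budget
between the PE signs isolates the asymmetry from overall speed, and
along that family the competition indices of exps 1–3 increase
monotonically as ρ falls while the negative-patterning score decreases
— the signature the bias account predicts.

## Synthetic behavior

`generate_dataset` maps each trial's aggregate prediction V to an
expected head-entry count, rate = min(ceiling, baseline + gain·max(V, 0))
(baseline 0.5, gain 5, ceiling 6 entries per 5-s window — the range
seen in goal-tracking counts), draws a Poisson (optionally
negative-binomial) count per trial, and averages within
subject × session × trial type: one response value per subject, per
cue, per session, for two gender-balanced groups of 8 yoked pairs. The
floor at baseline means inhibition is invisible in behavior, and the
ceiling emulates the saturation of count measures. A group-specific
gain can reproduce a higher passive response asymptote as a pure
performance effect; it is off by default.

What the generator does *not* emulate: trial-level autocorrelation,
sign-tracking and first-half-of-cue behavior, latencies,
session-duration bookkeeping, and any animal-specific dispersion (the
real counts' variance is unknowable from published SEM plots, so the
noise model is a modelling choice, and calibration targets are
internal). Passing pipeline tests on these data therefore shows the
pipeline is correct and well-calibrated for this generative structure —
not that real rats satisfy it. One known divergence: at the default
parameters the passive group retains a partial blocking signal
(terminal Y−X ≈ 0.17 in strength, detectable in counts with 8
subjects), whereas real passive rats showed none; the package reports
this honestly rather than inflating noise to hide it.

## Analysis stage

`session_cue_means` reduces any conforming table to one value per
subject × session × cue (weighted by trial counts when present;
missing sessions are logged, never imputed). `cue_contrast` computes
the within-subject window mean difference between two cues, Cohen's
d_z on the paired differences, and a two-sided sign-flip permutation p.
`group_by_cue_interaction` tests (agency mean [a−b]) − (passive mean
[a−b]) by swapping group labels within yoked pairs — the
exchangeability the yoked design guarantees when agency has no effect.
Both tests enumerate all 2^n sign patterns exactly whenever that is no
more work than the requested Monte-Carlo count (always true at n = 8
pairs with ≥ 256 permutations); Monte-Carlo p-values use the add-one
estimator (1 + hits)/(1 + n_perm), so p is never zero. Degenerate
zero-variance contrasts are flagged with d = NaN rather than infinite.
Bonferroni correction is provided for families of planned contrasts.
These permutation tests deliberately replace the mixed ANOVA used for
the original subjects: they preserve the inferential contrast structure
without re-implementing a mixed-model stack, and the aggregated table
can always be exported for external ANOVA software.

Analysis windows default to where the probe analyses belong: exp 1 the
last four probe sessions (global 31–34), exp 2 the final two session
blocks of the X(0)/Y(1) monitoring trials (27–30), exp 3 every probe
session (21–40), exp 4 the last four 3-session blocks (31–42).

`fit_bias_ratio` recovers ρ from a dataset by brute-force grid search:
for each candidate it simulates noiseless mean response curves along
the bias family (schedule realizations shared across candidates, so
the objective differs only through the parameter), and scores squared
error against the agency group's observed session-block × cue means.
With 8 pairs and the exp 2 design the generating ratio 0.5 is recovered
within ±0.2 in essentially every replicate, and unbiased (ρ = 1) data
land at the top of the grid; recovery error shrinks as pairs are added.

## Problem sizes and numerical choices

Simulations use the full printed designs (96–100 trials per session,
8 yoked pairs, 34–42 sessions) — a subject simulates in tens of
milliseconds, so nothing is scaled down. The test suite's calibration
property uses 500 null datasets with the exact 256-pattern interaction
null; the acceptance script uses 200 datasets and 10 recovery
replicates and runs in about two minutes. Floating-point equivalences
(plain-RW reduction, closed form) are asserted at 1e-12; monotonicity
tolerances at 1e-9. All randomness flows through numpy `SeedSequence`
keys, so every pair, session, and dataset is independently
reproducible.

## Known limitations

- The model family is deliberately minimal: no attention
  (Mackintosh/Pearce–Hall), no comparator-at-retrieval, no real-time or
  eligibility-trace dynamics, no representation of the trial-initiation
  act itself. Massed training is not mechanistically modelled; its
  empirical consequence (shallow effective learning across a session)
  enters through the small default salience.
- Simulated magnitudes are not calibrated to any animal's curves — only
  direction patterns and orderings are meaningful.
- The passive group's residual competition signal (above) is the main
  qualitative divergence from the target phenomenology at defaults.
- The configural representation is the simplest possible (one added
  unit per compound); it cannot express partial generalization between
  a compound and its elements.
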