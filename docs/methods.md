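# Methods

## Compressibility of category sets

A stimulus space is defined by D binary feature dimensions (default D = 3:
shape, color, size), giving 2^D objects. A category set S is any subset of
those objects. Its *verbatim description* lists every feature of every
member and has length D·|S|. Its *complexity* is the minimal number of
feature literals in an and/or/not expression tree whose extension is exactly
S; negation costs nothing and may apply to subformulas. Complexity measures
compressibility: the gap between verbatim and minimal description lengths is
the amount of structure a learner could exploit to recode the set.

The search must cover factored formulas, not just disjunctive normal forms:
the three-object set {small white square, large black square, small black
triangle} has a 9-literal verbatim DNF but a minimal cost of 8, achievable
only by factoring. The exhaustive oracle is a dynamic program over formula
*extensions*: any formula with k ≥ 2 literals is, once negations are pushed
aside, a conjunction or disjunction of subformulas whose literal counts sum
to k. Iterating k upward from 1 and combining all previously reached
extensions under AND/OR — closing each level under complementation, since
NOT is free — reaches every extension at its minimal literal count. For
D = 3 all 256 extensions resolve in well under a second and the catalog is
cached. Parity (complexity(S) = complexity(¬S)) holds by construction and
is verified exhaustively over all 254 proper nonempty subsets in the tests.

Witnesses: each extension stores one minimal formula. Ties within a level
are broken by the lexicographically smallest canonical serialization, with
commutative children kept in sorted order; the choice is greedy bottom-up
(children are themselves canonical minimal witnesses), which guarantees
determinism without searching the full tie set. Degenerate inputs — the
empty set and the full space — get complexity 0 with FALSE/TRUE witnesses;
they never occur as real trials.

Heuristic mode is the same level-wise dynamic program with the per-level
frontier capped (beam, default 1024 extensions). At D = 3 the cap never
binds, so heuristic and exhaustive mode agree on every subset; at larger D
the cap trades optimality for tractability, and any extension the capped
search misses falls back to the verbatim DNF, preserving the invariant
complexity ≤ verbatim length. A recursive Shannon-expansion heuristic was
prototyped and rejected: it misses the majority-type four-object sets
(returning 6 where the minimum is 5).

Serial order is deliberately *not* part of the complexity metric; it enters
the recall model as one extra feature unit (below) and the list designer as
ordering constraints.

## Stimulus lists

Abstract structures are ordered lists of distinct bit patterns. For each
length L ∈ 1..8:

- **Chunkable** templates are the minimum-complexity size-L subsets. Serial
  order is hierarchical: dimensions are ranked by diagnosticity (how
  unbalanced the feature is within the set, constant features first) and
  members sorted lexicographically under that ranking, so the list arrives
  grouped by its most diagnostic varying feature with a consistent value
  order within groups — the regularity is discoverable from the order.
- **Non-chunkable** templates are drawn from the subsets admitting an
  ordering in which consecutive objects differ on at least two features,
  restricted to the two highest complexity values present and tagged
  most/less incompressible. The ordering used is the admissible permutation
  maximizing total inter-item distance (ties broken lexicographically). In
  blocks the four trials of a length alternate most, less, most, less.

At D = 3 this yields the complexity profile (chunkable | nonchunkable
most/less): L2 2|6/5, L3 3|8/5, L4 1|10/6, L5 3|8/5, L6 2|6/5. The
most-incompressible length-3 and length-4 classes are the 8-literal
three-object set and the 10-literal odd-parity set. **Boundary:** every
7-subset costs exactly 3 literals (its complement is a singleton; parity)
and the full 8-object space costs 0, so at lengths 7 and 8 the two
conditions necessarily use equally complex (at L = 8, identical) member
sets and differ only in serial order. Strict complexity separation between
conditions is therefore asserted for lengths 2–6; it cannot exist at 7–8 in
an 8-object design. A related consequence: effective load is not monotone
in length at the very top, since near-full sets are maximally compressible.

Concrete trials instantiate a template by drawing two of eight shapes and
two of eight colors (sizes fixed at 140/280 px, recorded as metadata only,
never rendered) and applying a random bijection of abstract dimensions onto
concrete roles with random polarity — a relabeling, under which complexity
and all pairwise distances are invariant (verified property). The response
screen contains the k memoranda and the 8−k complement lures in random
positions; by parity the lure set is exactly as complex as the memoranda.
Consecutive trials never reuse a dimension assignment, which makes the
probability of repeating a stimulus space across adjacent trials zero. With
eight shapes and eight colors the vocabulary generates C(8,2)² = 784
distinct unordered spaces, or 1568 if one dimension's value pair is treated
as ordered; both counts are exposed and neither convention is forced.

## Task administration

Blocks present three practice trials (lengths 1, 1, 2), then lengths
ascending 1→8 with four trials per length. A trial is correct only if the
entire list is reproduced in exact order. Administration stops permanently
once all four scored trials of one length are failed; practice errors do
not count ("four errors within a given list length" is read as four failed
scored trials, the only reading consistent with four trials per length).
Complex-span blocks interleave one equation (operands 1–9, stated sum true
with probability .5, false sums offset by ±1 or ±2 — the offsets are this
package's choice, unspecified in the procedure) before each memorandum,
with a 3 s judgment deadline recorded as metadata. Timing constants (1 s
per item, 500 ms ISI in simple span) are logged but never waited on — there
is no reaction-time model. The four task x condition blocks are ordered by
one of the 24 permutations, cycled across participants (perfectly balanced
at n = 96; at n = 94, 22 orders occur four times and 2 three times).

## Synthetic cohort model

Per participant, recall of a whole list succeeds with probability

    P = logistic((capacity_eff − load) / tau)
    load = eta·C + (1 − eta)·D·L + 1[L ≥ 2]
    capacity_eff = kappa (simple span) or gamma·kappa (complex span)

with C the list's minimal complexity, D·L its verbatim length, and one
feature unit for serial order whenever the minimal (unordered) description
underdetermines it. Equation judgments are Bernoulli(p_eq). The logistic
link and the feature-unit currency are modeling choices of this package —
the compressibility metric itself makes no behavioral commitment — and are
isolated in `effective_load` / `recall_probability` so alternatives can be
swapped. Trials are conditionally independent given parameters (no
fatigue or learning), consistent with the absence of a length-accuracy
trend in the equation task.

Population parameters are truncated normals. Defaults (means ± between-
participant sd): kappa 8.2 ± 1.0 feature units, gamma 0.70 ± 0.08,
eta 0.55 ± 0.12, tau 1.4 ± 0.15, p_eq 0.87 ± 0.06, n = 94. The means were
calibrated once (analysis/02_calibrate_cohort.py): a grid over the analytic
expected cell spans targeting the reference human cell means
(2.49 / 4.05 / 1.45 / 2.2), verified on simulated heterogeneous cohorts;
the frozen defaults land each simulated cell within 0.3 span units of its
target. The sds are a-priori realism choices: capacity varies on the order
of one feature-chunk across people, and the latent equation-accuracy sd is
set slightly below the observed .08 because observed proportions add
binomial noise. Calibration inputs are reference values for realism; the
package makes no claim that human cell means are derivable from the model.
With a single eta shared across tasks the model embodies a multiplicative
(ratio-preserving) compression benefit; eta could be made task-specific,
but the default deliberately is not, leaving the shared-eta null as the
generative assumption.

## Parameter recovery

`fit_params` maximizes the marginal Bernoulli likelihood of per-trial
correctness with normal random effects on kappa and eta, integrated by
9-point Gauss–Hermite quadrature per dimension (81 nodes), profiling gamma,
tau and the two random-effect sds; L-BFGS-B within bounds. A pooled
(homogeneous) variant exists and is unbiased on homogeneous cohorts, but on
heterogeneous cohorts the unmodeled variance attenuates into the
temperature and biases eta upward by roughly 10–20%, which is why the
marginal estimator is the default. Standard errors, when requested, come
from the central-difference Hessian at the optimum. Recovery at the default
conditions (n = 94) returns the population means of kappa, gamma and eta
with under ~6% error per replicate and under ~1% averaged over replicates
(analysis/06_parameter_recovery.py); the acceptance suite requires 15% over
20 replicates. Degenerate logs (all correct or all incorrect) are rejected
as non-identifiable. The stop rule is ignorable for this likelihood: the
decision to stop depends only on already-observed outcomes.

## Scoring and analysis

Spans accrue 0.25 per perfectly recalled scored trial (so four correct
trials at one length contribute one unit). Length-1 trials count: although
the procedure calls them warmup, the worked scoring arithmetic includes
them, and the printed arithmetic is treated as authoritative. The cell
table reports per-cell mean, sd and se (= sd/√n). Chunking scores come in
two deliberately distinct forms: the *global* score of a task is the ratio
of its chunkable to nonchunkable cell means; *individual* scores are
per-participant ratios (participants with a zero nonchunkable span are
excluded from the individual path and counted in the report — the source
table is silent on this; exclusion avoids infinities and the count makes
the choice auditable). The multiplicative record, relative to the
nonchunkable-complex baseline b: task_ratio = simple-nonchunkable/b,
chunk_ratio = complex-chunkable/b, expected_combined = their product,
expected_span = b x expected_combined, observed_ratio =
simple-chunkable/b. Ratios are displayed at two decimals; full precision is
retained internally. Omnibus statistics (repeated-measures ANOVA, Bayes
factors, power analysis) are outside the bespoke surface and left to
standard tools.

## What the synthetic data do and do not show

The generator reproduces the study's structural conditions — 94
participants, counterbalanced 2x2 within-subject blocks, the exact trial
schedule and stop rule, compressibility-controlled lists, ~87% concurrent
accuracy — and its defaults produce cell means near the human pattern
because they were calibrated to. Passing tests therefore demonstrate that
the pipeline's machinery (design, administration, scoring, ratio algebra,
estimation) is correct and internally consistent, not that the cognitive
model is true of people: serial-position effects, output interference,
learning and fatigue, response-time structure, and strategy shifts are all
absent from the generative model. Analyses of the deposited human data can
be run through the same scoring path via `load_deposited` with a
user-edited column mapping.

## Numerical and degenerate-input choices

- Complexity catalogs are cached per (D, beam); exhaustive mode is limited
  to D ≤ 4 (the D = 3 catalog is instant; heuristic mode serves beyond).
- Formula serialization: literals `dim=value`, `&` over `|` precedence,
  `!(...)` for negated subformulas; TRUE/FALSE for the degenerate sets.
- All simulation randomness flows from a single integer seed through
  `numpy.random.SeedSequence` spawning (per participant, per block), so
  cohorts are bit-stable and CSV outputs byte-identical across runs.
- Trial-log CSV: UTF-8, comma-separated, "." decimals, a `# seed=...`
  comment header; JSON artifacts use sorted keys.
- The most/less alternation starts with "most" (the alternation's starting
  rank is not otherwise determined).
- Analysis drivers default to the study-scale cohort (n = 94) and a
  5-replicate recovery run; the full 20-replicate study is a flag away and
  is what the acceptance suite executes.
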