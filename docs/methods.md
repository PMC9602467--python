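# Methods

## Problem and pipeline

`cogtext` implements a text-augmentation pipeline for screening mild
cognitive impairment (MCI) from transcribed free speech of older
adults.  The study design it operationalises: each subject performs 12
short speaking tasks (10 episodic-recall prompts EP1a–EP8a, one picture
description, one animation description with four canonical events),
speaking freely for one to two minutes per task; transcripts are
labeled from the subject's MMSE score (≥ 28 healthy control, 23–27 MCI,
< 23 excluded as potential dementia).  Cohorts of this kind are heavily
imbalanced — here 45 healthy vs 15 MCI subjects, i.e. 540 vs 180
transcripts — so a classifier trained naively collapses toward the
majority class.  The pipeline counteracts this with class-balanced
Easy Data Augmentation (EDA): every MCI transcript is expanded 30× and
every healthy transcript 10× (multiplier = total copies, original
included), giving exactly 5,400 samples per class, 10,800 in total.

Stages: generate (or load) → cleanse → augment → split → train →
report, each with persisted artifacts and per-stage sample counts in a
log so the count chain is auditable end to end.

## Cleansing

`clean_transcript` removes recording-protocol marker strings (a
configurable set; real corpora define their own, synthetic corpora use
none), strips line breaks, and truncates to at most 512 tokenizer units
keeping the prefix.  Truncation is applied after tokenization because
the downstream encoder limit is token-based; the prefix rule is the
deterministic, order-preserving reading of "systematic truncation".
The function is idempotent, so repeated cleansing is harmless.

## EDA operators

Four token-level operators, each perturbing n = max(1, round(α·L))
tokens of an L-token sentence (α defaults to 0.05 — the conservative
rate recommended for small datasets; larger α degrades accuracy):

* **SR** replaces non-stopword tokens that have synonyms by a uniformly
  chosen synonym (positions sampled without replacement);
* **RI** inserts n tokens at uniform gap positions; the default
  `duplicate` mode inserts a copy of a chosen non-stopword token, while
  `synonym` mode (the original EDA formulation) inserts a synonym;
* **RS** applies n sequential swaps of two uniformly chosen positions;
* **RD** deletes each token independently with probability p
  (defaulting to α, the original EDA convention), returning one
  surviving token rather than an empty output if all are deleted.

Stopwords are never replaced and never inserted.  This matters
clinically: pronoun overuse is itself a marker of cognitive decline, so
the stopword list must be curated (pronouns/directives excluded from a
general-purpose list) rather than taken off the shelf; `load_stopwords`
exposes exactly that exclusion mechanism, and the list is a runtime
input with a synthetic fixture generator, never a hard-coded constant.

Per original, `augment_sentence` emits the original plus n_out − 1
copies, one operator per copy.  The operator choice per copy is not
uniquely determined by the study description; the default `cycle`
policy (SR, RI, RS, RD, repeating) gives deterministic, balanced
operator coverage, with `uniform_random` and `fixed:<op>` available.
All copies conserve label, task, subject and origin identifiers.

## Splitting and leakage

The evaluation protocol splits the augmented pool into 70% train, 10%
validation, 20% test, repeated 10 times as independent stratified
random splits (the repeated-split reading reproduces both the "10
parts" repeat count and the 20/10 fractions simultaneously; classic
k-fold cannot).  Stratification is by label via largest-remainder
apportionment of the round(fraction·N) targets.

Granularities: `sample` assigns every sample independently (the
replication protocol); `origin` keeps all augmented copies of one
original on one side; `subject` keeps all samples of one subject on one
side.  `leakage_audit` reports the fraction of test samples whose
origin/subject also appears in training: ~1.0 at sample level on the
default pool (with ≥ 10 copies per origin and a 20% test slice,
essentially every origin straddles the split — verified against direct
hypergeometric enumeration on a small toy dataset), exactly 0.0 at the
other two levels.  Sample-level scores are therefore optimistic;
subject-level is the scientifically safe default for any claim about
unseen speakers, and the directional comparisons below use it.

At group granularity the per-class size targets are met as closely as
whole groups allow (shortfall goes to train; e.g. subject-level
validation targets need not be reachable when one subject contributes
360 samples).  A single group larger than the per-class test target is
reported as an explicit infeasibility error.

## Classifier harness

The harness is backend-agnostic behind a fit/predict contract and
guarantees the backend never receives test samples.  The grid mirrors
the transformer fine-tuning search — batch sizes (1, 2, 4, 8, 16, 32) ×
learning rates (5e-5, 3e-5, 2e-5), 18 settings, epochs capped at 4 —
with validation-based early stopping (default objective: validation
log-loss, patience 1, evaluated per epoch; the objective and patience
are configuration, as no single canonical choice exists).

The shipped backend is a deterministic desk-scale baseline: L2-
normalised bag-of-words counts (vocabulary fitted on training text
only) with a logistic-regression decision rule, trained in warm-started
lbfgs increments of 40 iterations per "epoch" so early stopping applies
uniformly across backends.  Batch size and learning rate have no lbfgs
analogue; they are recorded in run metadata but inert, keeping grid
bookkeeping identical across backends.  A transformer fine-tuning
backend plugs in behind the same contract; it is deliberately not
bundled — the pipeline under test is the augmentation machinery, not
the encoder.

## Evaluation

Per-class F1, support-weighted F1 (the headline metric under
imbalance), and a per-task report: for each of the 12 tasks the
correct-prediction rate, the test count, and the within-task weighted
F1 — rate and F1 are reported side by side because the two are easily
conflated; the summary row is the unweighted mean over populated tasks
(so a 2,160-sample test set spread over 12 tasks averages n = 180.0,
and the unaugmented 144-sample test set averages 12.0).

## Synthetic corpus generator

The real corpus is private, so the generator emulates its statistical
structure.  Cohorts: MMSE drawn per group from N(29.3, 0.7²) (HC) and
N(25.9, 1.0²) (MCI), rounded and clamped to the label-consistent band —
the reported group moments are conditional on group membership, so
out-of-band draws would contradict the subject's label; ages from
N(73.7, 4.1²); sexes alternating within group (23M/22F, 8M/7F).

Transcripts are token streams over a whitespace-joinable vocabulary
(per-task topic words plus a shared pool), not grammatical language:
every pipeline stage operates on token sequences, so statistical
structure, not linguistic realism, is the design goal.  Group effects
enter through three mechanisms with support in the clinical-linguistics
literature (pronoun overuse, reduced lexical diversity, and incomplete
event description in impaired speakers):

| knob | HC default | MCI default | mechanism |
|---|---|---|---|
| pronoun rate | 0.05 | 0.18 | each content draw is replaced by a pronoun with this probability |
| TTR target | 0.75 | 0.45 | content words drawn from a round(ttr·pool)-word effective vocabulary |
| event coverage | 0.95 | 0.55 | round(coverage·4) key events embedded in template order (picture/animation only) |

plus length N(60, 12²) tokens (floored at 1, matching one-to-two-minute
utterances at conversational pace) and a 6% filler rate.  No
quantitative effect sizes exist for the emulated cohort, so these
defaults were chosen once as moderate, plausible values and are knobs,
not estimates.  Episodic templates carry no key events (free personal
recall has no canonical content).  A `no_group_difference` constructor
gives the null generator, and `disjoint_group_vocab` the
maximum-separation one; held-out accuracy moves from chance-level to
near-perfect across that range, which brackets what the generator can
and cannot show: passing tests demonstrate that the pipeline's
machinery is correct and that augmentation helps under injected lexical
signal — they say nothing about effect sizes in real clinical speech.

Fixture lexicons map each vocabulary word to k derived pseudo-synonyms
(`word~a`, …; synthetic stand-ins for a WordNet-style resource), and
fixture stopword lists are deterministic vocabulary subsets.

## Determinism and numerics

Every stochastic step takes a seed or `numpy` Generator; the pipeline
fans one global seed out as seed + stage-index so stages are
independently reproducible, and repeated runs produce byte-identical
artifacts.  Split repeats draw independent child streams via
`SeedSequence.spawn`.  Synonym candidates are sorted before sampling so
set iteration order cannot leak into results.  Degenerate inputs are
defined explicitly: empty transcripts are legal after cleansing
(flagged in logs), RD never empties a nonempty sentence, RS is the
identity below length 2, RI with no eligible source returns its input.

## Problem sizes

The default test and acceptance runs use the full emulated study
(60 subjects, 720 → 10,800 samples) for all count arithmetic, and
5-seed repeats of the full pipeline for the stochastic
with/without-augmentation comparison — chosen as the smallest design
that exercises every stage at the study's true scale while keeping the
suite fast on a single CPU.

## Known limitations

* Synthetic text has no syntax, no discourse structure, and no
  acoustic/disfluency timing; results on it do not transfer to real
  transcripts quantitatively.
* The headline F1 values reported for the private corpus are not
  reproducible here by construction; the package instead verifies the
  pipeline's exact count chain and the directional benefit of balanced
  augmentation.
* The baseline backend ignores word order entirely; sequence-sensitive
  effects (e.g. event ordering) reach it only through bag-of-words
  traces.
* Stopword normalization (case/width folding) is off by default;
  corpora must normalise upstream if they need it.
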