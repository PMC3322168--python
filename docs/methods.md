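# Methods

## Speech graphs

A transcript is an ordered sequence of canonical grammatical elements
(lexemes), each tagged `anchor` or `deviation` depending on whether the
speaker was on the anchor topic. The speech graph is the directed
multigraph with one node per distinct lexeme and one edge per
consecutive element pair, numbered 1..E in utterance order; a k-element
transcript therefore has exactly k−1 edges, and self-loops and parallel
edges are preserved. The adjacency matrix A carries integer
multiplicities and is indexed in first-appearance order, which makes
every downstream quantity deterministic for a given transcript.

Two views derive from the multigraph: the directed simple view
(self-loops dropped, multiplicities collapsed), used for the largest
strongly connected component, and the undirected simple view
(reciprocal pairs merged), used for connected components, diameter and
average shortest path.

### Measure conventions

- **ATD** is computed as the mean of in+out degree with multiplicities,
  which equals 2E/N identically (handshake lemma); the identity is used
  as a property test, not as the implementation's shortcut target.
- **PE** counts *excess* multiplicity per ordered node pair (direction
  matters), excluding self-loops, which belong to L1. With these
  conventions E′ = E − L1 − PE equals the edge count of the directed
  simple view, so density D = E′/N² lies in [0, 1].
- **L1–L3** are traces of A, A², A³ on the multiplicity matrix: closed
  walks, with parallel edges multiplying walk counts. A binary-adjacency
  reading exists in parts of the network literature; the multiplicity
  reading is implemented because the trace formula on the multigraph's
  natural matrix is the literal definition. Users wanting binary
  behaviour can simplify first.
- **Edge deviation flag**: an edge counts as deviation speech if either
  endpoint element is tagged `deviation` (default). The transition that
  *leaves* the anchor topic is itself the flight-of-thought event, so
  boundary edges count. `source`/`target`-only conventions are available
  via `build_graph(..., deviation_convention=...)` for sensitivity
  analyses.
- **DI/ASP on disconnected graphs**: averaged over finite-distance
  pairs only (pairs in different components are excluded, not set to 0
  or ∞); a largest-component-only scope is available. Undefined values
  (single node, no non-loop edges) are NaN and propagate as missing —
  they are excluded pairwise from statistics, never imputed.
- **Normalization** divides each measure by the raw word count of the
  report, which is metadata (the original recording's token count) when
  supplied and the markup-stripped token count of the transcript file
  otherwise. Elements and words differ on real data: elements are
  parsed lexemes.

## Statistics

All group tests are rank-based and hence invariant under monotone
transformations. Kruskal–Wallis (tie-corrected, χ² p-value) gates each
measure at family α = 0.05; pairwise Wilcoxon rank-sum tests are then
flagged at the Bonferroni-corrected α = 0.05/(number of pairs), with the
three-group value displayed as 0.0166 (truncated, not rounded, to four
decimals — the conventional display for this design). Rank-sum p-values
use the exact permutation null when both groups have ≤ 10 observations
and no ties (at 8 subjects per group the normal approximation is
noticeably off), otherwise the normal approximation with tie and
continuity corrections. The degenerate all-identical case is defined as
H = 0, p = 1. Spearman correlations against BPRS/PANSS totals use
pairwise deletion and require n ≥ 3 and nonzero variance. Computation
is delegated to scipy.stats; the exact tie-handling of the original
analyses is unknowable, so p-values should be compared qualitatively
(significant at the stated α or not) rather than digit for digit.

## Classification

The native classifier is Gaussian naive Bayes: class priors from
training frequencies, one Gaussian per class and feature, standard
deviations floored at 1e-6 × the global feature SD (or 1 if that is
zero) so constant features cannot degenerate, posteriors in log space.
The default features per comparison are the word-normalized subsets
that separate the groups on grammatical structure alone — N, E, ATD for
schizophrenic vs manic; N, L1, L2 for schizophrenic vs control; L1, L2,
L3 for manic vs control. Topic-deviation measures (WN, WE) are excluded
by design: they need semantic annotation.

Evaluation is leave-one-out cross-validation by default (small cohorts:
every subject serves in both roles), with a stratified k-fold
alternative under a recorded seed. Reported metrics: ROC by threshold
sweep with tied scores grouped into single steps, AUC by the trapezoid
rule (identical to the Mann–Whitney pairwise-win fraction, used as an
oracle test), sensitivity/specificity at posterior 0.5 (no operating
point is canonical; 0.5 is the symmetric choice), and Cohen's κ between
predicted and clinical labels, with κ defined as 1 when both label
vectors are constant and identical.

### Balanced training folds

Plain leave-one-out on a balanced two-class cohort is pessimistically
biased: every training fold under-represents the held-out subject's own
class by one (19 vs 20 at 20 per group), so both the frequency priors
and the class-conditional estimates systematically disfavour the true
class — on uninformative features the mean cross-validated AUC drops to
≈ 0.42 rather than 0.5 (stratification bias). `cross_validate`
therefore trims every training fold to equal class counts by rotating
one (or more) opposite-class subjects out, deterministically in the
fold index. This restores symmetry without touching the classifier
contract; the measured null AUC is ≈ 0.47, the small remaining deficit
being the cross-fold coupling inherent to leave-one-out AUC estimation
(removable only by leave-pair-out schemes, which trade away the
prescribed per-subject scores). The behaviour is a default, switchable
via `balance_training=False`.

## Synthetic cohorts

The generator is deliberately not a language model. It is a random walk
over a growing lexicon that controls exactly the graph-level quantities
the measures read out: `p_new` (fresh lexeme → divergence, drives
N/word), `p_retrace` (repeat an already-traversed outgoing transition →
parallel edges and short loops), the complementary jump to a known
lexeme (re-mention without edge repetition), and `p_deviate` /
`deviation_run` (geometric bursts of deviation-tagged speech → WN/WE).
Report length is negative-binomial (mean `mean_words`, dispersion k).
In synthetic mode one element is one word; the element/word distinction
only matters on real transcripts, so normalized measures stay
comparable.

Default profiles (chosen once; directionality verifiable with
`scripts/profile_directionality.py`):

| parameter | schizophrenic-like | manic-like | control-like |
|---|---|---|---|
| mean_words | 45 | 120 | 84 |
| dispersion | 15 | 15 | 6 |
| p_new | 0.75 | 0.30 | 0.50 |
| p_retrace | 0.02 | 0.38 | 0.15 |
| p_deviate | 0.01 | 0.08 | 0.03 |
| deviation_run | 2 | 4 | 3 |
| subject_cv | 0.08 | 0.08 | 0.35 |

Rationale: mean report lengths bracket the ~84-words-per-report scale
of anchored dream reports, with schizophrenic-like reports much shorter
than manic-like ones and the cohort mean ≈ 83. High `p_new` with
near-zero recurrence gives the schizophrenic-like profile its high
nodes-per-word and ATD-per-word (topics addressed once, no branching
back); high `p_retrace`/`p_deviate` gives the manic-like profile its
parallel edges, loops and waking edges per word even after verbosity
normalization. Controls sit between the patient groups on every mean
but carry a much larger between-subject coefficient of variation
(lognormal jitter on mean_words, p_new, p_retrace, p_deviate),
reproducing the wide, high-variance spread of non-pathological
speakers. `subject_cv` jitter is clipped so profile invariants
(p_new + p_retrace ≤ 1, probabilities in [0, 1]) always hold.

What the generator does **not** emulate: morphology and semantics,
dependence between element count and raw word count, interviewer
effects, and the absolute measure values of any real cohort. Passing
tests on synthetic cohorts therefore demonstrate that the pipeline
recovers group structure *of the kind* clinical speech exhibits, not
that any specific clinical effect size is reproduced.

## Problem sizes and determinism

The test suite and the acceptance script run on cohorts of 8–20
subjects per group and transcripts of tens to low hundreds of elements
— the scale the method targets clinically — with 50–200 seeded
replicates where distributions are being checked; at these sizes the
whole suite completes in well under a minute. All randomness flows
through `numpy.random.Generator` seeded from a single integer
(`SeedSequence.spawn` for replicate streams), so every table, report
and JSON is bit-reproducible given the seed, and every CLI run writes
its resolved configuration, package version and config hash to
`run_config.json` beside its outputs (JSON reports embed them inline).

## Known limitations

- Lexemization is table-driven (lowercasing plus a user lemma table);
  no algorithmic lemmatizer is bundled, so node identity is only as
  canonical as the supplied table.
- The transcript format assumes non-nested deviation spans; truly
  nested digressions must be flattened by the annotator.
- Exact rank-sum enumeration is only engaged for tie-free samples of
  ≤ 10 per group; heavily tied small samples fall back to the corrected
  normal approximation.
- Classification metrics at 8–20 subjects per group have wide
  confidence bands; single-cohort sensitivity/specificity values should
  be read as demonstrations, not estimates.
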