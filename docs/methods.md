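# Methods

This note documents the models implemented in `parsability`, the parameter
choices that matter, what the synthetic-data generators do and do not
emulate, and the numerical decisions a user should know about.

## Annotation model

Tokens carry part-of-speech, dependency label, morphological features,
verb argument valence, and (for nouns) an orthographic onset class.
Annotation is *lexicon-driven*: a surface form maps deterministically to
one annotation bundle. This is a simplification — in natural corpora the
dependency label depends on syntactic position — but it makes every
generator reproducible offline, and it is sufficient for the
feature-matched replacement that nonsense-sentence generation requires.
The content-word set is {noun, proper noun, verb, adjective, adverb};
onset class is read from the first letter (a/e/i/o/u → vowel), an
orthographic proxy for phonology. Valence classes are coarse
({intransitive, transitive, ditransitive, copular}); finer verb
distributional signatures are out of scope, mirroring the hand-checking
step such pipelines need in practice.

When a replacement key has no candidates, matching is relaxed in a fixed
order — drop the dependency label, then the onset class, then the
morphological features (keeping POS and valence) — and fails only when no
same-POS candidate exists. This replaces manual curation with a
deterministic, logged fallback. Self-replacement is allowed.

## Stimulus conditions

- `Scrambled{k}`: k word positions sampled without replacement; each
  chosen word (tracked as it moves) swaps with a uniformly chosen
  immediate neighbour, applied in sampled order on the evolving string.
  Swap sequences can cancel, so the output occasionally equals the input;
  this is permitted and recorded in provenance. One consequence: the
  *effective* displacement of a k-swap stimulus varies around k, so
  accuracy differences between adjacent k levels can invert in small
  samples even though they are monotone in expectation.
- `Scrambled_LowPMI`: the construction goal is separating originally
  proximal content words. The objective minimised is the number of
  content-word pairs within distance 3 in *both* the original and the
  permuted string. Length ≤ 8 is solved exhaustively; longer strings use
  seeded random-restart hill-climbing (8 restarts × 400 pairwise-swap
  steps) over whole-string permutations — function words move too, a
  documented choice where the construction is underdetermined. The
  returned permutation's objective never exceeds the identity's. PPMI
  itself is corpus-dependent and is reported as a diagnostic, not used as
  the optimisation target.
- `Backward`: exact reversal; an involution.
- `Jabberwocky` nonwords preserve length, consonant/vowel skeleton, and a
  detected inflectional suffix (-s, -ed, -ing, -er, -est), and are
  rejected against a real-word blocklist. Syllable-transition frequency
  matching, as done by full pseudoword generators, is deliberately not
  reproduced: skeleton + suffix preservation is sufficient for the
  structural role nonwords play here.
- Word/nonword lists: pooled tokens are redistributed by a seeded
  permutation (sampling without replacement), so the output token multiset
  equals the input multiset exactly.

All stochastic generators consume an explicit integer seed or generator;
there is no global random state, and a fixed seed gives bit-identical
output.

## Combinability (PPMI)

Probabilities are Laplace-smoothed with α = 0.1:
P̂(w) = (c(w)+α)/(N₁+αV) and P̂(wᵢ,wⱼ) = (c({wᵢ,wⱼ})+α)/(N₂+αV²), where V
is vocabulary size and the pair event space is the V² ordered (or
unordered, the default) combinations. The event-space denominators are
this package's choice and are configurable; only α is inherited from
standard practice. Pairs are unordered by default; an ordered-pair mode
supports directional analyses.

The per-string score averages the clipped pair scores. Two normalisations
are provided: dividing by the actual window pair count (3n−6 for n ≥ 4,
the default, matching "average across all pairs") and dividing by the
constant 3n−2 sometimes printed for this statistic; the two differ by a
fixed per-length factor and never change rankings. Summation uses
compensated `fsum`, so permuting the addends (e.g. by reversal) yields a
bit-identical mean — reversal invariance holds exactly, not just to
tolerance.

## Surprisal

Prefix probabilities are computed from a CKY-style inside chart plus, at
each start position i, a linear system over nonterminals:

    pre[A,i] = lex[A,i] + Σ_{A→BC} p (Σ_{k≤l} inside[B,i,k]·pre[C,k] − inside[B,i,l]) + Σ_{A→B…} p·pre[B,i]

solved in closed form via (I − L)⁻¹, where L collects unit rules and
binary rules whose first child spills past the prefix end. This treats
unit chains and left-recursive rules exactly (validated against geometric
closed forms). The computation assumes a *consistent* grammar (each
nonterminal's total string mass is 1); rule probabilities are validated to
sum to 1 per left-hand side within 1e-9, and ε-rules are not supported.
Grammars are binarized internally; the exhaustive-derivation enumerator
(`enumerate_language`) is an independent oracle used in tests for
finite-language grammars.

Surprisal is natural-log by default with a base-2 option. A crisp grammar
assigns zero probability to permuted word orders, so the scorer offers
unigram interpolation: P(w|prefix) = (1−λ)·P_g(w|prefix) + λ·P_uni(w).
Once a prefix has zero grammar probability the grammar component stays at
zero for the rest of the string (no re-entry); ungrammatical continuations
therefore cost ≈ −log(λ·P_uni), a high but finite ceiling. Reconstruction
analyses use λ = 0.05 — large enough to keep arbitrary orders finite,
small enough to leave grammatical strings' scores essentially unchanged.
Broad-coverage parsers are implicitly smoothed in the same spirit; within
this package surprisal comparisons are only made within one backend and
one log base. Externally computed per-word surprisals enter through a TSV
backend that validates token alignment and nothing else.

## Reordering paradigm and analyses

The trial state machine enforces that the display is always a permutation
of the revealed prefix (duplicates disambiguated by reveal index) and that
each newly revealed word is appended to the last submitted order. Analyses
consume only final submitted orders plus pass/fail bookkeeping;
intermediate submissions are stored but not analysed. Permissible-order
sets are item data supplied by the experimenter; no grammaticality oracle
is inferred. Participant inclusion requires ≥ 4 of 7 attention checks and
≥ 6 of 12 remaining fillers; rating-study inclusion requires use of the
full 1–5 scale, mean sentence grammaticality ≥ 3, and mean word-list
grammaticality ≤ 3.

## Synthetic worlds

A `SyntheticWorld` derives every artifact from one seed through named,
independent child streams (crc32-keyed `SeedSequence` spawns), so
consuming one stream never perturbs another.

- **Grammar/lexicon**: ~40 words over a small phrase-structure grammar,
  recursive through prepositional phrases; 12-token sentences are obtained
  by rejection sampling (bounded, default 2,000 attempts per sentence).
- **N-gram table**: tallied from freely sampled grammar sentences
  (default 2,000–3,000 for stable pair estimates; split-sample agreement
  is tested).
- **Participants**: the repair model is deliberately minimal. After each
  reveal the simulated participant walks the visible words in their
  original relative order; each displaced word is moved to its target slot
  with per-condition probability `skill`, and a word whose attempt fails
  is given up for the rest of the trial (the participant commits to the
  misparse). Defaults: 1.0 for intact, 0.85 for all locally scrambled
  conditions, 0.25 for the low-combinability and backward conditions —
  one fixed setting expressing that local scrambles are repairable in real
  time and severe reorderings are not. Verbatim accuracy then decays with
  the number of displaced words, and reconstructed orders of scrambled
  stimuli approach the intact originals. Working-memory limits, bonus
  mechanics, and reaction times are not modelled. Attention-check and
  filler outcomes are plain Bernoulli bookkeeping (0.95/0.85).
- **Voxels**: a `signal_fraction` (default 10%) of voxels carry a
  localizer effect (default 4.0 statistic units) and per-condition
  percent-signal-change effects (defaults 1.5 / 1.45 / 0.9 / 0.7 / 0.7 /
  0.4 for structured, feature-matched-implausible, reversed, word-list,
  jabberwocky, and nonword-list stimuli — a sign pattern, not an estimate
  of any empirical magnitude); all voxels receive independent Gaussian
  noise (default SD 1.0). No spatial autocorrelation, hemodynamics, or
  run structure is simulated, so passing recovery tests demonstrates the
  correctness of the selection/extraction arithmetic, not robustness to
  realistic fMRI noise.

What passing tests on these worlds shows: the pipeline's bookkeeping,
invariants, and parameter-recovery behaviour are correct under the
generating assumptions. What it does not show: performance on natural
lexical statistics, human repair strategies (which find *alternative*
grammatical orders, not only the original), or scanner noise.

## fROI computations

Voxel selection takes the top ⌈fraction × mask size⌉ voxels by localizer
statistic (default fraction 0.10); ties are broken by voxel id, making
selection deterministic. Lateralization uses counts of voxels exceeding a
configurable uncorrected statistic threshold; the index is
(LH−RH)/(LH+RH), antisymmetric by construction, with ≤ −0.25 classified
right-lateralized. The condition-effect model is specified as a
long-format table with treatment (dummy) coding against a reference
condition; mixed-model fitting is delegated to statsmodels' `MixedLM`
(random intercepts for participants) or any external solver, while an OLS
fixed-effects estimator is provided for parameter-recovery checks, where
it is unbiased under the generator's independent-noise assumptions.

## Problem sizes and seeds

Tests and the acceptance script run the behavioral simulation at the
study-scale 35 items × 7 conditions × 72 participants, the design
arithmetic at full scale (192 items, 8 runs), PPMI reversal invariance
over 1,000 sampled sentences, and voxel-contrast recovery over 100
replicates of 200-voxel maps — sizes chosen so each analysis exercises its
full code path while a complete run stays in the tens of seconds. Grammar
scoring memoizes per token-tuple, which makes scoring thousands of
simulated reconstructions cheap (most finals coincide with the originals).

## Known limitations

- Lexicon-fixed dependency labels understate annotation ambiguity.
- The toy grammar has no determiner–onset agreement ("a idea" can occur),
  no number agreement, and uniform lexical probabilities within a class.
- The repair model cannot produce alternative grammatical orders, so
  simulated verbatim accuracy is a lower bound on simulated "grammatical
  reconstruction" only by construction.
- The smoothed scorer's no-re-entry rule makes one early violation
  dominate a string's tail; this is conservative for mostly-grammatical
  strings.
- Numeric replication of published mixed-model estimates is not claimed;
  solver configuration is the user's.
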