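# Methods

This note documents the models, conventions and numerical choices behind
`echograph`, the parameters that matter, and what the synthetic study
conditions do and do not establish about real data.

## Conversation graph

Vertices are case-normalized usernames; an edge carries `w_t`, the total
number of mentions between the unordered pair.  Mentions in both directions
are summed into one undirected count: the graph is declared undirected and
weighted, and a single symmetric count is the natural weight for that
declaration.  A mention token is `@` followed by 1–15 word characters
(`[A-Za-z0-9_]`), with the `@` at the start of the text or preceded by a
non-word character — this excludes e-mail-like `a@b` substrings.  Duplicate
mentions within one tweet each count.  Self-mentions are dropped, edges with
`w_t` below the threshold (default 3) are dropped, and vertices left without
any surviving edge are dropped, since every downstream measure assumes each
node participates in at least one conversation.  Raising the threshold can
only remove edges (monotone filtering).

## Sentiment model

Tweet sentiment is a *compound* score in `[-1, +1]` from a pluggable scorer.
The bundled default is a compact rule-based lexicon scorer for short
social-media text: word valences on the usual `[-4, +4]` intensity scale are
adjusted by booster/dampener words within three preceding tokens (scaled
±0.293, decaying 5% per token of distance), negations within three tokens
(multiply by −0.74), and all-caps emphasis (±0.733 when the rest of the text
is not all-caps), then summed and squashed by `x / sqrt(x² + 15)`.  Texts
with no lexicon word score exactly 0; the scorer is deterministic.

Compound scores are rescaled to the discrete interval `[-α, +α]`, α = 30,
by the linear map `(x − oldMin)·newRange/oldRange + newMin`.  The source
interval defaults to the compound score's theoretical range `[-1, +1]`,
which is data-independent and stable; `empirical_scaling` instead fits
`oldMin`/`oldMax` to the observed score distribution.  "Discrete interval of
integers" is implemented as rounding half away from zero, which keeps the
conversion odd-symmetric about the midpoint (so `scale(−x) = −scale(x)`).
The user score `s(v)` is the un-rounded arithmetic mean of the scaled tweet
scores.  A tweet is *neutral* when its raw compound lies in `[-0.05, 0.05]`.

Users that appear in the graph only because others mention them have no
tweets; they receive `s(v) = 0` (neutral), an empty topic set, and a
`defaulted` flag in the profile table, so the graph stays intact and the
defaulting is auditable.  Strict mode raises instead.

## Topic model

Tweets are tokenized by a tweet-aware tokenizer (URLs and mention tokens
removed, `#` stripped from hashtags, punctuation-only tokens dropped), then
stop-words are removed and tokens are Porter-stemmed.  The vocabulary keeps
tokens whose document frequency lies in `[2%, 50%]` of documents (one tweet
= one document; the bounds are exclusive on the outside, so exactly-2% and
exactly-50% tokens survive) and truncates to the 100 000 most frequent.

One LDA model (scikit-learn, batch variational inference, 20 iterations,
seeded) is fitted per candidate K in 2..30; candidates exceeding the number
of documents are skipped with a warning.  Model selection maximizes a
C_V-style coherence computed from the corpus itself: word probabilities are
estimated over a boolean sliding window of 110 tokens (one window per tweet
in practice, since tweets are short); each of a topic's top-10 words gets a
context vector of NPMI values against the topic's top words; topic coherence
is the mean cosine similarity between each word's vector and the vector sum
of the whole top-word set (one-set segmentation), and the model score is the
mean over topics.  Coherence ties resolve to the smaller K.

A user's topic set `T(v)` is, by default, the union over their tweets of the
single highest-probability topic per tweet (*dominant* rule).  A *threshold*
rule (all topics with per-tweet probability ≥ p, default 0.25) is available;
the assignment rule is a genuinely open design point and both are exposed.
Tweets with no in-vocabulary token are not analyzable; users with none get
an empty topic set and a warning.

## Edge re-weighting

With `ss(v_i, v_j) = 2α − |s(v_i) − s(v_j)| ∈ [0, 2α]` and
`ts(v_i, v_j) = |T| − |T(v_i) Δ T(v_j)| ∈ [0, |T|]` (Δ the symmetric
difference), the semantic schemes replace the active weight by `w_ss = 1 +
ss`, `w_ts = 1 + ts`, or `w_h = 1 + ss + ts`, leaving the edge set unchanged
and keeping `w_t` as an edge attribute for change analyses.  Weights are
real-valued (the `s(v)` means are fractional) and never re-rounded.  The
algebraic identity `w_h = w_ss + w_ts − 1` holds per edge.  The hybrid sum
is implemented literally; its scale imbalance (`ss` ranges over `[0, 60]`
while `ts` ranges over `[0, |T|]`) is a known property of this formulation,
not corrected here.

## Partitioning

The bisection is a native multilevel scheme:

1. *Coarsening*: repeated heavy-edge matching (seeded random visiting order,
   heaviest unmatched neighbour, ties to the smaller vertex id) until at
   most 50 vertices remain or a level shrinks the graph by less than 5%.
2. *Initial bisection*: greedy region growing — repeatedly add the
   admissible vertex with the strongest connection to the growing side —
   from each of 10 seeded restarts (all starts when the coarsest graph is
   that small), keeping the best admissible state seen along each
   trajectory.
3. *Uncoarsening*: project the partition down one level at a time and refine
   with boundary Fiduccia–Mattheyses passes: vertices move at most once per
   pass, the best prefix of the move trail is kept, and a pass asserts it
   never worsens the cut.  Up to 10 passes per level.

Balance: a side may hold at most `max(ceil(n/2), floor(tol·n/2))` vertices
(tolerance 1.03 by default, roughly the near-balance the method is meant to
produce).  The `max` with `ceil(n/2)` keeps the most balanced split
admissible for odd n, where a literal `tol·n/2` bound close to 1 would be
unattainable.  At coarse levels, where vertices carry merged weights, the
bound is relaxed by the largest vertex weight and re-tightened as weights
shrink during uncoarsening.  Disconnected graphs: when no component exceeds
the admissible side size, whole components are packed greedily onto the two
sides (zero cut); otherwise the largest component is bisected and the
remaining components are assigned, largest first, to the smaller side.  All
tie-breaks are by vertex identifier under the run seed, so a graph plus a
seed determines the bisection exactly.

A brute-force enumerator over admissible bisections (graphs up to 14
vertices) provides ground-truth optimal cuts in tests; on 100 random
connected graphs with up to 10 vertices the multilevel partitioner attains
the optimum in well over 80% of cases and stays within 1.5× throughout.

## Controversy measures

Random walks move to a neighbour with probability proportional to the
*active* edge weight by default, so semantic weights shape the walks; a
uniform mode provides parity with the unweighted literature variant.

**RWC / ARWC.**  Authoritative nodes are, per side, those whose (unweighted)
degree ranks in the top `ceil(15% · side size)`, with every tie at the
cutoff degree included — the set is never empty for a nonempty side.  Walks
are absorbed on first arrival at any authoritative node, with absorption
checked strictly *after* each step: a walk that starts at an authoritative
node is not trivially absorbed at time 0.  This single convention keeps RWC
(random starts, which may be authoritative) and ARWC (authoritative starts
only) on the same footing and is mirrored exactly by the closed-form oracle.
Starts: `ceil(0.60 · min(|X|, |Y|))` nodes sampled per side (equal counts on
both sides), 10 walks per start by default.  The walk length is
`ceil(2 · ASP)`, where ASP is the mean unweighted hop distance over the
largest connected component; a walk not absorbed in time restarts from a
freshly drawn node (side with probability ½, capped at 50 restarts), and an
estimate aborts with advice to raise `l_rw` if more than half the episodes
fail.  The estimate is end-conditioned: `P_AB = (#walks that started in A
and were absorbed in B) / (#walks absorbed in B)`, so `P_XX + P_YX = 1` and
`P_YY + P_XY = 1` by construction, and `RWC = P_XX·P_YY − P_XY·P_YX =
P_XX + P_YY − 1`.  The value is reported unclamped — it can be negative for
anti-polarized partitions — with a binomial standard error.

The exact oracle solves `(I − Q)B = R` for the absorbing chain (same
transition rule, no step cap, up to 2000 vertices) and aggregates absorption
probabilities under a start distribution: uniform per side, authoritative
sets, or an explicit start multiset.  When validating the estimator, the
oracle is evaluated on the estimator's *sampled* starts (exposed in its
diagnostics): the sampling of 60% of each side is part of the estimator's
definition, and comparing against the all-nodes average would conflate walk
noise with start-sampling noise.  Equivalence tests also pass a walk-length
cap well above `2·ASP`, since the oracle does not model the restart
mechanism; the default cap stays `2·ASP`.

**DRWC.**  For each sampled node one walk of exactly `l_rw` steps runs with
no absorption; `n_cc` counts steps whose endpoint lies in the other
community than the step's origin, and `DRWC = mean(1 − n_cc/l_rw) ∈ [0, 1]`.
Disconnected communities give exactly 1; the side-partitioned complete
bipartite graph gives exactly 0.

**Boundary connectivity.**  `u ∈ X` is a boundary vertex iff it has a
neighbour in Y *and* a neighbour in X that itself has no neighbour in Y;
internal vertices are the rest.  `d_i(u)`/`d_b(u)` count edges from `u` to
the internal and boundary sets, which are the unions `I = I_X ∪ I_Y` and
`B = B_X ∪ B_Y` by default (the measure's wording refers to the sets I and
B); the `own_side_only` switch restricts them to the vertex's own side, the
scoping used in the measure's original source.  Both scopings are exposed
because the two formulations genuinely differ.  An empty boundary makes BC
undefined and raises — it is not reported as 0.  For two bridged stars with
k leaves each, `BC = k/(k+1) − ½`, approaching the 0.5 maximum as the stars
grow.

**Quality.**  Weighted Newman–Girvan modularity and coverage
(intra-community edge weight over total edge weight) complete the report;
two equal disconnected modules give modularity exactly 0.5 and coverage 1.

## Synthetic study conditions

The generator plants two communities of `n_users = 50` each.  Per unordered
pair, the mention count is Poisson with mean `p_in = 3.0` within a community
and `p_out = 0.3` across — after the threshold of 3 this yields a dense
intra-community graph (a pair survives with probability ≈ 0.58) with only a
handful of surviving cross edges (rate ratio 10): strongly but not
perfectly separated communities, so that boundary-based measures remain
defined and the controversy measures sit below their degenerate maxima.
Sentiment targets are Normal(μ, σ = 0.15) on the compound scale, clipped to
`[-1, 1]`, with μ_A = +0.6 and μ_B = −0.6 (separation 1.2); each tweet
embeds a phrase from a bank built out of lexicon words and calibrated
against the active scorer at generation time, so the realized compound
scores track the targets whatever scorer is plugged in.  Topic words come
from two disjoint 12-word community vocabularies mixed with a shared
vocabulary at rate 0.3; every tweet carries the crawl hashtag so the
term filter is an identity on synthetic data (and the hashtag itself is
removed from the topic vocabulary by the 50% document-frequency bound).
Verified flags are Bernoulli(0.22) in the science-flavoured community A and
Bernoulli(0.12) in the politics-flavoured community B, loosely mirroring the
asymmetry such studies report.  Each user additionally posts
Poisson(6) mention-free tweets.  Corpus and graph generators consume one
shared seed stream for the pair counts, so the mention graph built from the
corpus reproduces the planted graph exactly.

What the generator does *not* emulate: realistic language (texts are bags of
calibrated phrases and topic words), heavy-tailed degree and activity
distributions, temporal dynamics, retweets/replies/follower structure, or
platform-scale corpora.  Passing tests therefore establish that the pipeline
recovers planted structure of the stated strength under its own modelling
assumptions — not that real conversations of interest have that structure.

## Problem sizes in the test suite

Tests run on deliberately modest sizes: planted-partition recovery uses 200
nodes over 20 seeds; the estimator/oracle suite uses 20 planted graphs of
20–30 nodes at roughly 10 000 walks per estimate; the end-to-end semantic
runs use 100 users (~8 000 tweets) with the LDA sweep restricted to K =
2..5, which is sufficient for the two planted themes plus slack.  These
sizes keep the full suite in the minutes range while leaving every code path
(coarsening included, via dedicated larger fixtures) exercised.

## Known limitations

- The lexicon is compact (~230 entries); coverage of real tweet vocabulary
  is far below a production lexicon, which matters for real data but not for
  the calibrated synthetic corpora.
- `P_AB` estimates condition on the walk being absorbed within the restart
  budget; the restart mechanism slightly reweights the effective start
  distribution when many walks hit the cap.  With the default
  `l_rw = 2·ASP` on well-connected graphs the effect is small, and the
  failure guard aborts rather than report badly biased values.
- The hybrid weighting inherits the scale imbalance discussed above.
- k-way partitioning (k > 2), directed conversation graphs and alternative
  similarity combinations are out of scope.
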