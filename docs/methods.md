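# Methods

`inferatlas` re-implements, as a tested pipeline, a text-mining procedure for
exploring the *causes of inferiority feelings* expressed on Chinese
microblogs.  The original corpus (public Sina Weibo posts) cannot be
redistributed, so the package couples every analysis stage to a synthetic
corpus generator with planted ground truth.  This note describes each model,
its assumptions, the defaults, and what the synthetic experiments do and do
not establish.

## Pipeline overview

1. **Corpus assembly.** Posts carry an account id, a follower-count snapshot,
   a date, raw text, and a segmented token list.  The package operates on
   pre-tokenized input: Chinese word segmentation is an interchangeable
   upstream dependency, not part of the method, and the synthetic generator
   emits token lists directly.
2. **Marketing-account pre-filter.** Accounts with *more than* 5000 followers
   are treated as marketing accounts and their posts dropped.  The inequality
   is strict — a 5000-follower account is kept — following the literal
   phrasing of the rule.  Follower counts are per-post snapshots; no attempt
   is made to reconcile an account whose count crossed the threshold over
   time.
3. **Ontology-attribute selection.** Relevant posts are the union of two
   strategies: (a) posts containing the head keyword 自卑 (*inferiority*),
   and (b) posts matching the boolean conjunction over six attribute groups
   derived from dictionary definitions of the concept,
   `A1 ∩ A2 ∩ A3 ∩ A4 ∩ (A5 ∪ A6)` — *think*, *oneself*, *inferior to*,
   *other people*, and the affect groups *feel low* / *sadness*, each a head
   word plus synonyms.  Matching is exact token equality on the segmented
   list by default; substring matching on raw text is available for
   unsegmented input.  Pronoun members ("he", "she", "them") are matched like
   any other token — no coreference resolution, mirroring plain keyword
   search.
4. **Relevance classification.** A linear-kernel SVM (C = 1.0) separates
   *target* from *off-target* posts.  Posts are vectorized as the arithmetic
   mean of their in-vocabulary token embeddings (the minimal scheme
   consistent with training the embedding first); bag-of-words counts are
   kept as a baseline.  The validation split is balanced per class.  Because
   the vectorizer needs the embedding, the pipeline trains the background
   skip-gram model immediately after selection and classifies afterwards.
5. **Background embedding.** Skip-gram with negative sampling, written
   directly on NumPy: dynamic context windows (uniform in `1..window`),
   unigram^0.75 noise distribution, five negatives per pair, linearly decayed
   learning rate (0.025 → 1e-4), mini-batches with within-batch gradient
   accumulation.  Training is single-threaded and fully seeded, so vectors
   are bit-reproducible.  Reference settings: window 10, dimension 400;
   `min_count` 5 and 5 epochs are package defaults where the procedure left
   them unstated.  Skip-gram pairs are drawn once per training run and
   reshuffled each epoch.
6. **SF-SAI primitive extraction.**  For a theme (field) corpus, candidates
   are tokens passing a POS filter (content words), a stop-word list (empty
   by default for synthetic runs), and membership in the embedding
   vocabulary.  Two scores per candidate:
   * **SF** — relative frequency among candidate tokens, `count(w)/Σcount`;
   * **SAI** — mean cosine similarity to every other candidate in embedding
     space, a coherence measure.
   Both are min–max normalized over the candidate set and combined as a
   product; ties break lexicographically.  This is a reconstruction from the
   published description ("semantic frequency" + "semantic active index
   based on the coherence of the text"); the exact original formulas appear
   only in an appendix not available to us, so the scores, normalization and
   combiner are pluggable for users holding them.  Default `k` = 30
   primitives per theme (published maps display on the order of tens).
7. **Semantic atlas.** Primitive vectors are projected to 2D with t-SNE
   (exact gradient, PCA init, default perplexity 5 for small primitive sets,
   seeded) and min–max normalized per axis to the unit square, making all
   map distances *relative*.  Per map we report min, lower quartile, median,
   mean, max (and upper quartile) of the `n(n−1)/2` pairwise Euclidean
   distances; quartiles use linear interpolation (type 7) — a convention the
   source leaves unstated but that must be fixed for testability.  A Gaussian
   KDE (rule-of-thumb bandwidth, overridable) provides the density shading.
   **Closeness rule:** two primitives are semantically close when their
   distance is strictly below *both* the mean and the lower quartile of the
   map's distances.  The inequalities are strict ("bigger than").  Because
   normalization is per-axis min–max, uniformly rescaling raw coordinates
   leaves every verdict unchanged.
8. **Theme coding.** An eight-code codebook (physical defects IF-PD, love and
   affection IF-LA, family background IF-FB, personality IF-P, personal
   experiences IF-PE, social interaction IF-SI, learning IF-L, abilities
   IF-A).  Posts are sampled 200 per publication year (seeded, without
   replacement); one code per post.  Percentages are half-up rounded to two
   decimals, which reproduces published coding tables exactly (e.g.
   270/1400 → 19.29).  Consistency is verified on a seeded 140-post
   subsample with Cohen's kappa, `κ = (p_o − p_e)/(1 − p_e)`; per-code
   kappas are one-vs-rest (a modeling choice; the alternative — kappa on
   per-theme subsets — is not computable from one-vs-rest marginals).  When
   `p_e = 1` with perfect agreement κ is defined as 1; with imperfect
   agreement it is undefined and raised as an error.

## The synthetic corpus generator

The generator is first-class, tested code; its defaults are the study
conditions every acceptance check runs under.

* **Post types.** Exact planted counts: 35% keyword posts (contain 自卑 /
  `zibei`), 25% attribute posts (one token from each of A1–A4 plus one from
  A5 ∪ A6, never the head keyword), 40% off-target posts built from two
  disjoint noise vocabularies (advertisement-like and aphorism-like, 40
  tokens each) and containing no selection token at all.  By construction
  the union selection has precision = recall = 1 against ground truth, which
  is what makes filter fidelity assertable.
* **Themes.** Each relevant post draws one of the eight codes with weights
  mirroring the empirical distribution of causes (IF-PE 19.28% … IF-FB
  1.79%).  Content tokens come 60% from the theme's ten planted core tokens
  and 40% from a shared 240-token filler pool.
* **Filler topical skew.** Each filler token is assigned a random "home"
  theme and 70% of a post's filler draws come from the home fillers of the
  post's theme.  Without this skew, fillers appear uniformly everywhere,
  their skip-gram vectors collapse onto a single hub near the corpus
  centroid, and the hub out-scores genuinely thematic tokens on the
  coherence index — an artifact of uniform synthetic vocabularies, not of
  the method.  Real filler vocabulary is topically skewed, so the biased
  generator is the more faithful emulation, and it leaves the embedding
  non-degenerate (fillers scatter across theme clusters rather than forming
  separable blobs).
* **Accounts and dates.** `round(marketing_fraction × n_accounts)` accounts
  get follower counts in 5001–50000, the rest 10–5000; post dates are
  uniform over 2011–2017.
* **Raters.** Two simulated coders each report the true theme with
  probability `1 − error_rate` (default 0.1), otherwise a uniformly random
  other code.  At error rate 0.1 with eight codes the expected observed
  agreement is `0.9² + 0.1²/7 ≈ 0.811` and κ lands around 0.79, inside the
  0.65–0.89 range reported for human coders in comparable studies.
* **What it does not model.** Real microblog style, post lengths, user
  networks, segmentation errors, class imbalance drift, or polysemy.
  Passing tests therefore establish that the pipeline's machinery recovers
  structure it is pointed at — not that it would achieve any particular
  accuracy on real Weibo data.  In particular the published 80.38%
  classifier accuracy and the printed per-map distances depend on the
  unavailable 1.2-million-post corpus and are not reproduction targets; the
  synthetic corpus is far more separable (held-out accuracy is typically
  1.0).

## Problem sizes and numerical choices

* Tests and the acceptance script run the generator at 1000–2000 posts with
  embedding dimension 100, window 5, 5 epochs — sizes chosen so planted
  structure is recovered reliably while the whole suite stays fast; the
  full reference settings (dimension 400, window 10, 6000 posts) are the
  pipeline defaults and complete a demonstration run in minutes.
* Primitive-recovery checks use the five major theme codes.  At default
  scale their field corpora are ~80–130 posts, comparable to real coded
  theme samples (110–270 posts); the two rarest codes yield corpora of
  ~20–40 posts, below what frequency/coherence estimation needs, and small
  field corpora are a sample-size limitation of the method itself.
* Degenerate inputs: a zero-norm vector has cosine similarity 0 by
  convention; a map axis with zero extent normalizes to 0.5; min–max
  normalization of a constant score vector returns all ones (so full ties
  fall through to the lexicographic tie-break); t-SNE requires
  `perplexity < n` and at least three points.
* All randomness flows from explicit integer seeds; the pipeline derives
  per-stage seeds from its single top-level seed.

## Known limitations

* The SF-SAI scores are a documented reconstruction, not a verified copy of
  the original appendix formulas.
* SAI is a centrality measure over the candidate set; very small candidate
  sets or hub-shaped embedding geometries can favor non-thematic tokens
  (see the filler-skew discussion above).
* Cosine distances in the 400-dimensional space and Euclidean distances on
  the 2D map order pairs differently in general; all closeness analysis is
  deliberately performed in map space, where the published distance
  statistics live.
* Kappa on a 140-post subsample has wide sampling error (±0.1 is ordinary);
  per-code one-vs-rest kappas for rare codes are undefined when a code never
  appears in the subsample.
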