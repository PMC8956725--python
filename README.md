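# inferatlas

Semantic-atlas mining of the **causes of inferiority feelings** from
microblog posts.

People who feel inferior rarely seek face-to-face help, but they talk about
it on social media.  `inferatlas` implements a complete, tested pipeline for
mining those posts: it selects inferiority-related posts with an
ontology-attribute keyword filter, cleans them with a marketing-account
filter and an SVM relevance classifier, trains a skip-gram embedding of the
background corpus, extracts each theme's *semantic primitives* with an
SF-SAI score, and lays the primitives out on a 2D semantic atlas whose
distance statistics drive a closeness analysis.  Because the original Weibo
corpus cannot be redistributed, the package ships a synthetic corpus
generator with planted ground truth, so every stage is verifiable end to
end.  It is aimed at computational-social-science and digital-epidemiology
researchers who want to reuse or audit the method.

## The method in brief

* **Selection.** A post is inferiority-related if it contains the head
  keyword 自卑 (*inferiority*), or if it matches the attribute conjunction

  ```
  A1 ∩ A2 ∩ A3 ∩ A4 ∩ (A5 ∪ A6)
  ```

  over six keyword groups (*think*, *oneself*, *inferior to*, *other
  people*, *feel low*, *sadness* — each a head word plus synonyms, shipped
  as a CSV table).  Posts from accounts with more than 5000 followers are
  dropped as marketing accounts.
* **Embedding.** Skip-gram with negative sampling (reference settings:
  window 10, dimension 400), single-threaded and seeded, so vectors are
  bit-reproducible.
* **SF-SAI.** For a theme corpus, every candidate token gets a semantic
  frequency `SF(w) = count(w)/Σcount` and a semantic active index
  `SAI(w) = mean cosine similarity to the other candidates`; both are
  min–max normalized and multiplied, and the top-k tokens are the theme's
  semantic primitives.
* **Atlas.** t-SNE projects primitive vectors to the unit square; per map
  the minimum, lower quartile, median, mean and maximum of all pairwise
  relative distances are reported, with a Gaussian-KDE density shading.
  Two primitives are *semantically close* when their distance is strictly
  below both the mean and the lower quartile.
* **Theme coding.** An 8-code codebook (IF-PD, IF-LA, IF-FB, IF-P, IF-PE,
  IF-SI, IF-L, IF-A), 200 posts sampled per year, percentage tables with
  half-up rounding, and Cohen's kappa
  `κ = (p_o − p_e)/(1 − p_e)` on a 140-post consistency subsample.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

```python
import inferatlas as ia

# a synthetic corpus with planted structure (all randomness from one seed)
cfg = ia.SyntheticConfig(n_posts=1000, seed=7)
pool, truth = ia.generate_corpus(cfg)

# selection: marketing filter, then keyword ∪ attribute-conjunction
kept = ia.filter_marketing_accounts(pool)                 # > 5000 followers out
groups = ia.default_groups(ascii_tokens=True)
selected = ia.union_select(kept, groups, head_keyword="zibei")
print(len(pool), len(kept), len(selected))                # 1000 792 467

# background embedding + SF-SAI primitives for one theme
model = ia.train_skipgram(pool, dim=100, window=5, min_count=5, epochs=5, seed=7)
field = ia.PostPool([p for p in pool if p.theme_code == "IF-PE"], "IF-PE corpus")
prims = ia.extract_primitives(field, model, k=10, allowed_pos={"n"})
print([p.token for p in prims][:3])    # ['pe_core09', 'pe_core05', 'pe_core06']

# semantic atlas and the closeness rule
smap = ia.build_map(ia.extract_primitives(field, model, k=30, allowed_pos={"n"}),
                    perplexity=5, seed=42)
s = smap.stats
print(f"mean {s.mean:.4f}  Q1 {s.lower_quartile:.4f}")    # mean 0.6082  Q1 0.1030
verdict = ia.is_close(smap.distances[0, 1], s)            # distance 0.0431
print(verdict.close)                                      # True

# rater-consistency check on the theme codes
raters = ia.simulate_raters(truth, error_rate=0.1, seed=7)
k = ia.cohens_kappa(list(raters.rater1), list(raters.rater2))
print(f"kappa {k.kappa:.3f}")                             # kappa 0.765
```

The selection keeps exactly the planted keyword/attribute posts
(precision = recall = 1 against ground truth), the top primitives are the
theme's planted core tokens, and a rater error rate of 10% over eight codes
yields a kappa near 0.77 — the level considered substantial agreement in
coding studies.

A one-command demonstration of the whole pipeline (selection →
classification → embedding → primitives → atlases → theme coding), writing
all artifacts plus a JSON run report:

```bash
inferatlas run-all --out pipeline_out --seed 0
```

Per-stage subcommands (`simulate`, `filter`, `embed`, `classify`,
`extract`, `atlas`, `code`) operate on the same file formats; see
`inferatlas --help`.

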