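# Methods

This note documents the models and procedures implemented in
`contratopics`, the parameters that matter, the design choices made where
the design was genuinely open, and what the synthetic-data tests do and do
not demonstrate.

## Corpus cleansing

Input tables follow the tab-separated Drugs.com/UCI dialect (header row;
the review field double-quoted with embedded quotes doubled, so embedded
tabs and newlines survive). Rows with unparseable or out-of-range ratings
(the scale is 1–10) or empty text are rejected at parse time and reported
with line numbers.

The cleansing chain is: condition filter → deduplication →
ambiguous-generic removal → method categorization. Choices:

* **Condition matching** is case-insensitive exact match after whitespace
  trimming ("Birth Control" ≡ "birth control").
* **Duplicate key** is (lower-cased whitespace-collapsed text, rating,
  date). Duplicates in this corpus arise from one review being listed
  under both a product's brand and generic name; this key collapses
  exactly those pairs without merging genuinely distinct reviews, which
  would have to coincide in all three fields. Among duplicates the
  brand-name record survives (brand entries are flagged `is_brand` in the
  catalog): brand names are more informative because products sharing an
  active ingredient differ in dose and schedule. Deduplication is
  idempotent.
* **Ambiguous generics** (by default bare "levonorgestrel", which may be a
  hormonal IUD or emergency contraception, and "Provera", which may be the
  contraceptive shot or a non-contraceptive oral progestin) are dropped
  and counted.
* **Categorization** maps each drug name to one of 11 methods: COCP, POP,
  91-day-cycle OCP, implant, hormonal IUD, copper IUD, vaginal ring, shot,
  patch, emergency contraception, spermicide. The last two are dropped
  (negligible review counts), leaving 9 analysis methods. Unmapped names
  are routed to an "unmapped" report and the run continues.
* **Unfavorable flag**: rating ≤ 5. This window is deliberately wider than
  "strictly negative" (≤ 3) so that neutral-to-negative reviews, which
  still describe unpleasant experiences, are included.

The product→method catalog ships as an editable CSV seeded with the most
commonly reviewed brands and generics per method. It does not cover every
product ever listed on the source site, so corpus counts on the real
dataset reproduce only up to the catalog's coverage; the unmapped report
quantifies the gap. Every stage writes removal counts to a JSON run log,
and the invariant `input = output + Σ removals` holds at each stage.

## Text preparation

Fixed order: clean → expand abbreviations → tokenize + lemmatize →
stop-word removal → domain-term removal. Expansion precedes noise-word
removal so "yr" → "year" is then dropped with the calendar words; stop
words are removed after tokenization so expansions producing stop words
("i'm" → "i am") are swept up. Rerunning the chain on its own output is a
no-op from the tokenize stage onward.

* **Cleaning** decodes HTML entities (including double-escaped ones, a
  scraping artifact), maps typographic quotes/dashes to ASCII, strips
  control characters and collapses whitespace.
* **Abbreviations**: a CSV catalog of 134 short forms — contractions plus
  clinical and colloquial short forms — matched case-insensitively as
  whole tokens, longest first. Short forms with several readings carry one
  configured expansion (e.g. "he's" → "he is"), stored in the catalog
  rather than hard-coded.
* **Tokenization** keeps alphabetic tokens of length ≥ 2 (numerals and
  stray single letters otherwise dominate the vocabulary; the shipped word
  lists contain no numerals, consistent with this choice).
* **Lemmatization** is a rule-based English noun lemmatizer: plural
  suffix stripping with an irregular-forms table and a not-a-plural list.
  Inflected verbs ("started", "taking") deliberately pass through
  unchanged, matching a noun-default dictionary lemmatizer on this
  domain's vocabulary. Tokens on the stop list are not lemmatized — they
  are about to be removed, and lemmatizing them could only move them off
  the list (e.g. "does" → "doe").
* **Stop list**: a versioned in-repo snapshot of the standard English stop
  list (plus apostrophe-stripped variants, since tokenization removes
  apostrophes), shipped in the repo because external lists drift between
  library versions. "not" is excluded from the list and always retained:
  negation carries meaning in complaint text ("not worth it").
* **Domain terms**: all product-name tokens from the method catalog plus
  generic method words (iud, pill, implant, …) are removed so extracted
  topics are product- and method-agnostic; the six calendar/noise words
  month, day, year, week, birth, control are removed because they are
  high-frequency but carry no side-effect signal.

## Vectorization

Smoothed TF-IDF: entry(d, t) = tf(d, t) · (ln((1+N)/(1+df(t))) + 1), rows
scaled to unit Euclidean norm (this is scikit-learn's default variant,
stated explicitly so any implementation is bit-comparable; the test suite
checks it against an independent brute-force recomputation). Vocabulary
pruning defaults to `min_df = 5` documents and `max_df = 0.95` — terms in
fewer than 5 or more than 95% of documents are noise or carry no
discriminative weight. Both are configurable; tiny corpora need
`min_df = 1–2`.

## Factorization

`A ≈ W H` with `W (N×k), H (k×V) ≥ 0`, minimizing `‖A − WH‖²_F` by
Lee–Seung multiplicative updates from a seeded uniform-random nonnegative
initialization scaled by `sqrt(mean(A)/k)`. Defaults: `max_iter = 500`,
stop when the relative per-iteration objective decrease falls below
`tol = 1e−5`; 5 seeds with the best final objective kept. The
per-iteration objective is recorded and is provably non-increasing; the
test suite asserts this on every fit (tolerance `1e−9 · initial`, for
floating-point slack from the `1e−12` division guards). A denominator
guard of `1e−12` keeps updates defined at zero.

After fitting, rows of `H` are rescaled to unit L2 norm with compensating
column scaling of `W`; the product `WH` is unchanged (asserted against the
final traced objective). **Dominant topic** = argmax of a document's `W`
row, ties toward the lower index; all-zero rows get an `UNASSIGNED`
sentinel, are counted, and are excluded from topic tables.

Degenerate inputs are fatal with diagnostics: `k > min(N, V)`, an all-zero
matrix, an empty post-pruning vocabulary.

## Topic-count selection

Per `k` on the grid (default 3–13) the report records the best-of-seeds
objective, the top-10 terms per topic, mean UMass coherence

    score(topic) = Σ_{i>j} ln((D(w_i, w_j) + 1) / D(w_j))

over the ranked top terms (D = document frequency; pairs whose
conditioning term is absent are skipped and counted), and the mean cosine
silhouette of the dominant-topic clustering.

Two empirical facts, established on planted-topic corpora, drive the
selection rule:

* Coherence collapses — by several times its usual across-`k` spread —
  when a topic's top terms mix two unrelated themes (typical of too-small
  `k`), but otherwise plateaus and moves little with `k`.
* Silhouette computed on rows of `W` cannot detect a too-small `k`:
  documents of two merged themes collapse onto the same fitted axis and
  look like one tight cluster. Computed instead on the TF-IDF document
  rows, silhouette peaks at the planted `k` from both directions (merged
  clusters are internally heterogeneous in term space; split clusters are
  mutually close). `select_model` therefore scores silhouette in term
  space; `silhouette_on_topics` accepts any per-document representation,
  so the `W`-row variant remains available.

The default criterion: the chosen `k` maximizes coherence, where all `k`
within `tie_tol · |best coherence|` of the best (default `tie_tol = 0.10`)
count as tied and are broken by silhouette, then by the smaller `k`. The
band is relative to the coherence magnitude (not the grid spread) so it
stays meaningful when no `k` on the grid merges themes. Silhouette
subsamples to ≤ 2000 documents with a fixed seed for tractability. The
per-`k` report is always emitted: the automatic choice is a default for
unattended runs, and domain judgment is expected to review it.

"Coherence" is fixed to the UMass formulation here; no claim is made that
selection scores are comparable across differently preprocessed corpora.

## Association statistics

* Rating histograms store exact counts per rating 1–10; mean and
  **population** SD (ddof = 0) are computed from the counts and agree
  exactly with the un-binned ratings. Population SD is used because these
  tables are descriptive summaries of a complete corpus, not sample
  estimates.
* Percentages follow printed-table conventions: rounding is half away
  from zero at the table's precision (e.g. 234/800 → 29.3%), implemented
  via decimal arithmetic because Python's built-in rounding is
  banker's.
* Dominant-topic share tables are per-method distributions over topics
  among unfavorable reviews; each row sums to 1 before rounding. The
  **scaled** variant multiplies a share by the method's unfavorable rate,
  giving the complaint's prevalence among *all* of the method's reviews;
  it is additive over disjoint topic sets before scaling and can never
  exceed the unfavorable rate.
* Per-topic rating summaries use linear-interpolation quartiles.
* No inferential statistics: the data are self-selected online reviews
  violating independence and distributional assumptions, so the package
  deliberately stops at description.

## Synthetic corpora

The generator emulates the statistical structure of the review corpus so
the pipeline is testable without the study data. Defaults define the
standard test scenario and echo the observed corpus structure:

* `n_reviews = 500`, `k_topics = 4`, `separation = 0.9`,
  mean document length 40 tokens (Poisson), roughly matching the ~46
  post-preparation tokens per review in real data.
* `unfavorable_mix = 0.43`: the fraction of reviews drawn from the
  unfavorable generative component, matching the ~43% unfavorable share
  observed in the real corpus. Unfavorable ratings come from per-topic
  left-skewed distributions on 1–5 (a point mass at 1 mixed with a
  uniform) whose means span 2.3–2.9 across topics; favorable ratings from
  a high-mass distribution on 6–10 (mean 8.8). The components are
  disjoint on the rating scale, so the rating ≤ 5 flag recovers component
  membership exactly — a simplification of real data, where favorable
  experiences occasionally receive low scores.
* Topic lexicons are editable word lists themed on the eight complaint
  families (weight, skin, libido, mood, menstrual irregularities,
  cramps/pain, continuous bleeding, mixed dissatisfaction) so synthetic
  topics are human-interpretable in test reports. Unfavorable documents
  draw a `separation` fraction of tokens from their planted topic's
  lexicon, the rest 70/30 from background vocabulary and other topics;
  favorable documents draw from a positive lexicon instead.
* Method labels are drawn with volume weights echoing the real corpus
  (COCPs ~44%, implants ~23%, …) and carry per-method topic-prevalence
  weights echoing the observed pattern (IUD complaints concentrate on
  cramps/pain, implant and shot complaints on continuous bleeding, POP
  and 91-day-pill complaints on menstrual irregularities).
* Surface text is dressed with stop-word fillers, occasional
  contractions (one with the HTML-entity-mangled apostrophe seen in
  scraped data) and plural forms, so cleaning, expansion and
  lemmatization all have work to do. Generation is deterministic given
  the config seed; the TSV output round-trips losslessly through the
  ingest reader.

**What passing tests show — and don't.** Documents are bags of words with
disjoint planted lexicons and no grammar, polysemy, misspelling, or
topic overlap. Perfect recovery on these corpora demonstrates that the
pipeline's stages compose correctly and that the factorization finds
well-separated structure when it exists; it does not predict topic quality
on real reviews, where themes overlap (menstrual irregularities vs
continuous bleeding share vocabulary) and dominant-topic attribution is
genuinely ambiguous for multi-complaint reviews.

Recovery is measured as permutation-matched accuracy: the fitted→planted
topic matching that maximizes agreement is found by solving the assignment
problem on the confusion matrix, so topic relabeling cannot affect the
score.

## Problem sizes in the test suite

Unit tests run on toy fixtures; the end-to-end recovery check uses the
default 500-review scenario, `k`-selection uses a 1200-review five-topic
corpus with a 3–9 grid and 3 seeds per `k`, and law-of-large-numbers
checks on the generator use 10,000 reviews. These sizes give stable
outcomes across seeds while keeping the whole suite under half a minute
on one CPU.

## Known limitations

* The shipped product catalog is a seed, not a census; real-corpus counts
  reproduce only within its coverage (the unmapped report makes the
  shortfall explicit).
* The lemmatizer is rule-based and noun-only; rare irregular plurals
  outside its exception table may pass through unlemmatized, and words
  like "prizes" strip to a non-dictionary stem. This is harmless for
  bag-of-words modeling but the token lists are not a general-purpose
  lemmatization resource.
* Dominant-topic attribution assigns exactly one topic per review; the
  per-review topic weights in `W` are richer and are persisted with the
  model for analyses that need them.
* Selection diagnostics (coherence, silhouette) are heuristics; on real
  corpora the emitted per-`k` report, not the automatic argmax, is the
  intended interface.
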