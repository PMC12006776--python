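# contratopics

Topic mining and rating-association statistics for online reviews of female
contraceptive products.

Drug-review websites pair a free-text comment with a 1–10 satisfaction
rating. Across tens of thousands of birth-control reviews, that pairing
makes it possible to ask not just *which* side effects women describe —
weight gain, skin problems, loss of libido, mood problems, menstrual
irregularities, cramps and pain, continuous bleeding — but how strongly
each complaint is associated with low ratings, and how complaint profiles
differ between contraceptive methods (pills, IUDs, implants, shots, rings,
patches). This package implements that analysis as a tested, reproducible
pipeline for researchers in pharmacovigilance and women's-health text
mining.

## What it does

1. **Corpus cleansing** (`contratopics.ingest`) — reads review tables in
   the tab-separated Drugs.com/UCI dialect, filters to a condition label,
   collapses brand/generic duplicate listings (keeping the brand name),
   drops generics that cannot be tied to one method, maps every product to
   one of 9 contraceptive methods via an editable CSV catalog, and flags
   ratings ≤ 5 as *unfavorable*. Every removal is counted in a run log so
   input and output sizes always reconcile.
2. **Text preparation** (`contratopics.textprep`) — repairs scraped text
   (HTML entities, typographic punctuation), expands >110 abbreviations
   ("can't" → "cannot", "PMS" → "premenstrual syndrome"), tokenizes and
   lemmatizes (noun-default, so "cramps" → "cramp" but "started" stays),
   removes stop words *except "not"*, and strips product/method names and
   calendar noise words so topics come out product-agnostic.
3. **Topic extraction** (`contratopics.topics`) — vectorizes the
   unfavorable reviews with smoothed TF-IDF,
   `tf · (ln((1+N)/(1+df)) + 1)` with L2-normalized rows, and factorizes
   the document–term matrix `A ≈ W H` (`W, H ≥ 0`) by Lee–Seung
   multiplicative updates minimizing `‖A − WH‖²_F`. Each review's
   **dominant topic** is `argmax` of its row of `W`. The topic count `k`
   is scanned over a grid and chosen by UMass coherence with a
   term-space silhouette tie-break; the full per-`k` report is always
   emitted for human judgment.
4. **Association statistics** (`contratopics.stats`) — rating histograms
   with mean/population-SD, per-method unfavorable shares, dominant-topic
   share tables per method, the **scaled topic share** (share among a
   method's unfavorable reviews × the method's unfavorable rate = the
   complaint's corpus-wide prevalence), and per-topic rating summaries.
5. **Synthetic corpora** (`contratopics.synth`) — a generator that plants
   topic lexicons, method-dependent topic prevalence and topic-dependent
   ratings in the same TSV schema, with ground truth, so the whole
   pipeline is testable end to end without the original dataset.

A thin CLI (`contratopics simulate|ingest|prep|fit|select|stats|run`)
exposes each stage; `run` executes everything from one YAML config into a
self-contained run directory.

## Worked example

`examples/04_topic_model.py` generates a 500-review synthetic corpus with
four planted complaint topics, fits the model on its unfavorable subset
and prints:

```
document-term matrix: 223 reviews x 118 terms
NMF converged after 27 iterations; final objective 80.00
topic 0 (30.0% dominant): pimple complexion chin rash greasy jawline forehead breakout
topic 1 (22.4% dominant): gaining belly gain waist slim gained eating scale
topic 2 (24.2% dominant): swing panic anxiety anxious mood crying emotional temper
topic 3 (23.3% dominant): intercourse uninterested attraction intimacy romance sexually partner drive
permutation-matched recovery of planted topics: 1.000
```

Each line is one extracted topic: the share of unfavorable reviews whose
dominant topic it is, followed by its highest-weight terms — here clearly
the planted skin, weight, mood and libido lexicons. The recovery score of
1.0 means every review's fitted dominant topic matches its planted topic
under the best one-to-one relabeling. `examples/05_select_topic_count.py`
shows the `k`-selection report choosing the planted `k = 5` on a
five-topic corpus; the other examples cover simulation, ingest,
text preparation and the full pipeline.

## Layout

```
src/contratopics/        library modules (ingest, textprep, topics, stats,
                         synth, pipeline, cli) and editable data catalogs
examples/                one narrative script per capability
tests/                   pytest suite incl. acceptance tests
scripts/acceptance.py    recomputes the reported statistics as JSON
docs/methods.md          models, parameters, design choices, limitations
```
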