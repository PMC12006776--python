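"""Cleanse a raw review table and compute the rating statistics.

Writes a synthetic corpus to disk first, then runs the full cleansing
chain (condition filter, dedup, ambiguous-generic removal, method
categorization) and summarizes ratings overall and per method.
"""

import tempfile
from pathlib import Path

from contratopics import (GeneratorConfig, histogram_mean_sd, method_summary,
                          rating_histogram, ingest_corpus, simulate_to_dir)
from contratopics.resources import default_method_catalog

with tempfile.TemporaryDirectory() as tmp:
    tsv, _ = simulate_to_dir(GeneratorConfig(n_reviews=400, seed=7), tmp)
    corpus, log = ingest_corpus(tsv, default_method_catalog())

print(f"corpus: {len(corpus)} reviews "
      f"({sum(r.unfavorable for r in corpus)} unfavorable)")
print("stage counts:", {k: v for k, v in sorted(log.counts.items())})

hist = rating_histogram(corpus)
mean, sd = histogram_mean_sd(hist)
print(f"rating mean {mean:.2f}, SD {sd:.2f} (1-10 scale; ratings <= 5 are "
      "flagged unfavorable)")

print(method_summary(corpus).round(3).to_string())
print()
print("Per method: review count, corpus share, rating mean/SD and the "
      "unfavorable share - the rate later used to scale topic shares.")
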