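"""Generate a synthetic review corpus with planted topic structure.

Every review gets a planted complaint topic, a contraceptive method and a
favorable/unfavorable component; the ground-truth table makes downstream
recovery measurable.
"""

from contratopics import GeneratorConfig, generate_corpus

config = GeneratorConfig(n_reviews=300, k_topics=4, separation=0.9, seed=42)
reviews, truth = generate_corpus(config)

print(reviews.head(3).to_string())
print()
print("planted topics:", ", ".join(config.topic_names))
share = (reviews.rating <= 5).mean()
print(f"unfavorable share: {share:.3f} (configured mix: {config.unfavorable_mix})")
print(truth.topic.value_counts().to_string())
print()
print("Each row mimics the Drugs.com TSV schema; the unfavorable share is "
      "the fraction of ratings <= 5 and converges to the configured mix.")
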