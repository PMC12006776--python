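"""Normalize review text into token streams.

Shows the fixed chain - clean, expand abbreviations, tokenize + lemmatize,
remove stop words (keeping "not"), remove product/method names and
calendar noise words - on one mangled review, then ranks the corpus
vocabulary.
"""

from contratopics import (GeneratorConfig, PrepConfig, corpus_word_frequency,
                          generate_corpus, prepare_corpus)
from contratopics.textprep import clean_text, expand_abbreviations, prepare_document

config = PrepConfig.default()

raw = ("I&#039;ve had my Mirena IUD for 3 months and can&#039;t stand the "
       "cramps or the PMS; not worth it!")
print("raw:     ", raw)
print("cleaned: ", clean_text(raw))
print("expanded:", expand_abbreviations(clean_text(raw), config.abbreviations))
print("tokens:  ", " ".join(prepare_document(raw, "demo", config).tokens))
print()
print("Note: the entity-mangled apostrophes were repaired, 'PMS' expanded, "
      "'cramps' lemmatized, 'Mirena'/'IUD'/'months' removed, 'not' kept.")

reviews, _ = generate_corpus(GeneratorConfig(n_reviews=300, seed=3))
streams, _ = prepare_corpus(list(zip(reviews.uniqueID, reviews.review)),
                            config)
freq = corpus_word_frequency(streams)
print()
print("top corpus tokens (count, share of all tokens):")
print(freq.head(10).round(4).to_string(index=False))
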