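"""Semantic search: rank samples by the likelihood of generating a query.

The score of sample d is Score(d) = prod_n sum_z psi_{z,q_n} theta_{d,z} —
the probability that d's topic mixture generates every query word.  Samples
described with related (not necessarily identical) words rank high because
they share topics with the query words.
"""

import numpy as np

from ecotopics import train
from ecotopics.search import preprocess_query, score_samples
from ecotopics.synth import generate_corpus

corpus, truth = generate_corpus(K=5, D=300, V=40, S=25, alpha=0.2, beta=0.1,
                                gamma=0.1, N_d=150, M_d=15, seed=11)
model = train(corpus, K=5, iterations=300, seed=3)

# query with the two words most characteristic of topic 0
top_words = np.argsort(model.psi[0])[::-1][:2]
query_text = " ".join(model.word_vocab[s] for s in top_words)
print(f"query: {query_text!r}")

query = preprocess_query(query_text, model)
result = score_samples(model, query)
print("rank  sample        score     theta on queried topic")
for rank, (sid, score) in enumerate(result.top(5), start=1):
    d = model.sample_ids.index(sid)
    print(f"{rank:4d}  {sid}  {score:.3e}  {model.theta[d, 0]:.3f}")
print("high-scoring samples load on the topic that generates the query words")
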