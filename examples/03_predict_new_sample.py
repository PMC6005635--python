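"""Predict the topic mixture of a new sample from genus counts alone.

A new sample is synthesized as a 70/30 blend of two learned genus
sub-communities; prediction Gibbs-samples its tokens with the trained model
frozen.  Running 100 independent chains gives per-topic standard deviations
— a goodness-of-fit signal: small sd means the model explains the sample
consistently.
"""

import numpy as np

from ecotopics import train
from ecotopics.corpus import RawProfile
from ecotopics.predict import predict_with_stability
from ecotopics.synth import generate_corpus

corpus, _ = generate_corpus(K=5, D=300, V=40, S=25, alpha=0.2, beta=0.1,
                            gamma=0.1, N_d=150, M_d=15, seed=11)
model = train(corpus, K=5, iterations=300, seed=3)

rng = np.random.default_rng(42)
mix_true = np.array([0.7, 0.0, 0.3, 0.0, 0.0])
counts = rng.multinomial(10_000, mix_true @ model.phi)
profile = RawProfile("new_sample", {model.genus_vocab[v]: int(c)
                                    for v, c in enumerate(counts) if c > 0})

result = predict_with_stability(model, profile, chains=100, seed=9)
print("true mixture:     ", mix_true)
print("predicted mixture:", result.proportions.round(3))
print("per-topic sd:     ", result.sd.round(4))
print(f"tokens used: {result.n_tokens_used}, "
      f"out-of-vocabulary mass: {result.oov_mass:.3f}")
print("sd well below 0.05 everywhere indicates a stable, well-fit prediction")
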