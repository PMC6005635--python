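"""Choose the number of topics by held-out perplexity.

Half of each test sample's sequence tokens are folded in to estimate its
topic mixture; the other half is scored.  Lower perplexity means better
prediction of unseen sequences; the curve typically drops steeply up to the
true number of topics and then flattens.
"""

import numpy as np

from ecotopics.corpus import subset_corpus
from ecotopics.evaluate import select_K
from ecotopics.synth import generate_corpus

full, _ = generate_corpus(K=8, D=250, V=30, S=20, alpha=1 / 8, beta=0.1,
                          gamma=0.1, N_d=100, M_d=10, seed=5)
idx = np.random.default_rng(0).permutation(full.D)
train_c, test_c = subset_corpus(full, idx[:200]), subset_corpus(full, idx[200:])

print(f"training on {train_c.D} samples, evaluating on {test_c.D} (true K = 8)")
for report in select_K(train_c, test_c, [2, 4, 8, 16], chains=3,
                       iterations=200, seed=1):
    print(f"K={report.K:3d}: perplexity {report.mean:7.3f} +/- {report.sd:.3f}")
print("expect a large drop up to K=8 and little or no gain beyond it")
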