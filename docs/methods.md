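# Methods

## Model

The package implements a correspondence topic model for paired count data.
Sample *d* observes `N_d` sequence tokens (genus assignments of individual
reads) and `M_d` word tokens (its cleaned description). A topic *z* is a
pair of distributions: `phi_z` over the `V` genera (a sub-community) and
`psi_z` over the `S` vocabulary words. Topic proportions `theta_d` get an
*asymmetric* Dirichlet prior `alpha` (per-topic concentrations), because
environments are very unevenly represented in public archives and an
asymmetric prior absorbs that corpus-level bias; `phi` and `psi` get
symmetric priors `beta` and `gamma`.

The defining feature is the word-topic conditional: a word token's topic
`c_dm` is drawn from the sample's empirical sequence-topic frequencies
`N_zd / N_d`, not from `theta_d`. Descriptions therefore annotate the
community that was actually observed; a topic can only generate words in a
sample where it also owns at least one read (the *support invariant*
`M_zd > 0 ⇒ N_zd > 0`, maintained by every sampler step).

## Inference

With `theta`, `phi`, `psi` integrated out, the joint splits into
`P(Z|alpha) · P(W|Z,beta) · P(C|Z) · P(T|C,gamma)`; the first two and the
last are Dirichlet-multinomial (Polya) terms, `P(C|Z)` is a product of
per-sample multinomials. Collapsed Gibbs sampling resamples every token:

* sequence token: `P(z_dn=k|·) ∝ (N_kd\dn + alpha_k) · (N_kw\dn + beta)/(N_k\dn + beta·V) · prod_z (N_zd\dn + [z=k])^{M_zd}`.
  The last factor — the exact coupling with the sample's word topics — is
  computed in log space. If removing the token would leave its own topic
  with words but no sequences, the conditional is a point mass on that
  topic; this is handled explicitly (at most one topic can be in that
  state), never by smoothing.
* word token: `P(c_dm=k|·) ∝ N_kd · (M_kt\dm + gamma)/(M_k\dm + gamma·S)`.

Within each sample all sequence tokens are resampled before the word
tokens (matching the generative direction and keeping the support
invariant maintainable); after each full sweep, one Minka fixed-point step
updates `alpha` (per component), `beta` and `gamma` (pooled), floored at
1e-8. Initial values are `alpha = 50/K`, `beta = gamma = 0.1` — ordinary
starting points, not claims about the data. Point estimates are the
smoothed count ratios of the final state
(`theta_dk = (N_kd + alpha_k)/(N_d + Σalpha)`, analogous for `phi`, `psi`);
averaging the last R states of a chain is available but not the default,
since labels are stable within one chain and the joint likelihood is
required to have plateaued. All randomness flows from one integer seed,
fanned out per sweep/chain through `numpy.random.SeedSequence`. Hot loops
are numba kernels; the Python single-token operations implement the same
conditionals and the two are cross-checked in the tests, along with an
exhaustive-enumeration oracle for the full posterior on tiny instances.

The empirical-Bayes caveat: the fixed point for `alpha` has its maximizer
at infinity when per-sample topic proportions show no variation beyond
multinomial noise (e.g. a freshly randomized state). This is correct
behaviour of the estimator, not divergence; in practice the sweep's
resampling step introduces the across-sample variation the update needs.

## Evaluation

Held-out perplexity follows document completion: per test sample, a
uniformly random half of the *sequence* tokens (fraction configurable) is
folded in — a single Gibbs chain with `phi` and `alpha` frozen, 200
iterations, 50% burn-in, posterior-mean `theta_hat` — and
`perplexity = exp(-Σ log Σ_z theta_hat_z phi_z,w / n_heldout)` over the
other half. Word tokens play no role in fold-in, and normalization is by
held-out token count. Out-of-vocabulary genera in test samples are dropped
with a warning; vocabularies are aligned by genus name, so test corpora
need not share the training matrix layout.

Topic similarity uses Jensen-Shannon divergence with base-2 logarithms, so
disjoint supports score exactly 1. Environment labelling sums `psi_z` over
a group of marker words and calls the topic associated when the sum
exceeds 5%; the default groups (gut; oral; skin; vagina; ocean;
freshwater; soil; hot spring) ship as an editable TSV.

## Prediction

A new sample is depth-filtered like training data (discard under 1,000
assigned reads, subsample over 10,000), its out-of-vocabulary genus mass
is reported, and its tokens are Gibbs-sampled under
`P(z=k|·) ∝ phi_kw (N_kd\dn + alpha_k)` with the model read-only — the
learned sub-communities act as fixed source communities. The default
estimate is the posterior mean over the second half of 200 iterations.
Stability runs `chains` independent chains (default 100) and reports the
across-chain standard deviation per topic; one recorded draw per chain is
the default, matching a draw-and-average protocol, and multiple evenly
spaced draws per chain are supported.

## Mapping

Parametric t-SNE: input affinities are Gaussian conditionals calibrated
per point by bisection to entropy log2(perplexity) (default 30, clamped to
(n-1)/3 for small batches), symmetrized and normalized; map affinities are
Student-t with one degree of freedom; the loss is KL(P‖Q) per mini-batch
(batch 512 or the full set if smaller, re-drawn each epoch). The network is
K→160→160→640→2 with rectifier hidden units and a linear output, trained
with Adam (step size 1e-3, 200 epochs by default; He initialization). The
trained map is a pure function: embedding is bit-exact repeatable for a
fixed input batch, adding points never moves existing ones, and one-hot
inputs define the topic anchors. Distances on `theta` are Euclidean on the
raw probability vectors. Degenerate inputs whose affinity calibration
cannot reach the target entropy (duplicate-heavy sets) raise an error.

## Search

Queries are cleaned exactly like training descriptions (lowercasing,
edge-punctuation stripping, lemmatization, stop-word and pattern removal);
words outside the model vocabulary are discarded with a log message.
`Score(d) = prod_n Σ_z psi_{z,q_n} theta_{dz}` is accumulated in log space
(multi-word scores are routinely at the 1e-6 scale) with query terms in a
canonical order, so scores are exactly invariant to term order; ties rank
by sample id. Taxon terms are matched case-insensitively against the genus
vocabulary plus an optional lineage table (TSV: genus, rank, ancestor);
scores are multiplied by the taxon's relative abundance per sample, or the
summed abundance of descendant genera for ranks above genus, so samples
lacking the taxon score zero. Synonym resolution is out of scope; the
lineage table is the extension point.

## Text and count preprocessing

Depth filter: strict `< 1000` discard; subsampling to exactly 10,000 is
uniform *without replacement* over the token multiset (multivariate
hypergeometric), preserving a true sub-multiset. Word cleaning drops
tokens with any non-alphabetic character (hyphenated words included;
sentence punctuation is shed from token edges first), tokens whose A/T/C/G
fraction is ≥ 70% (case-insensitive), stop words (scikit-learn's English
list by default) and a user-supplied generic-word list. The lemmatizer is
a small rule-based English one (irregular domain forms plus plural-suffix
rules) and is pluggable — any `str -> str` callable. Vocabulary filters
remove words with corpus total < 20, words in > 30% of samples, and —
when sample→study labels are supplied — words confined to one study
(skipped with a warning otherwise). The filter keeps emptied documents as
empty bags so it is idempotent; assembly then intersects the modalities,
drops empty samples and trims unused vocabulary columns. All vocabularies
are sorted lexicographically with 0-based indices.

## Synthetic data

The generator draws corpora from the model's own process; the standard
recovery regime is K=5, D=300, V=40, S=25, N_d=150, M_d=15 with sparse
emissions (`beta = gamma = 0.1`) and `alpha = 1/K` — minutes-scale to fit
and separated enough to be identifiable. Parameter and token draws use
separate seed streams so tokens can be redrawn under pinned parameters; a
draw that leaves a vocabulary item with no token anywhere is retried with
the next derived stream (redrawing parameters too unless pinned) so the
corpus invariants hold. Synthetic data makes no attempt to imitate real
16S quirks — no overdispersion beyond the model, contamination, chimeras
or compositional artefacts — so passing recovery tests shows the inference
is correct *under the model*, not that the model fits any particular real
habitat. Label switching in recovery scoring is resolved by Hungarian
matching on total-variation distance between emission rows.

## Problem sizes and numerical choices

Test and acceptance runs use desk-scale sizes chosen as the package's
standard study conditions: the recovery regime above (500 sweeps), an
enumerable 8-token corpus for exactness checks (50,000 sweeps against the
exact posterior), a K_true=8 corpus (250 samples) for the perplexity
curve with 3 chains per K, 10,000-token samples for prediction, and
150-point, 3-cluster mixtures for the embedder. Likelihood terms use
log-gamma throughout; conditionals are normalized from a max-shifted log
scale; digamma comes from scipy. Known limitations: single-chain point
estimates (no cross-chain topic alignment), no variational alternative,
exact-match-only taxon recognition, and a deliberately simple lemmatizer —
reproducing any particular published vocabulary is not attempted.
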