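# Methods

This note documents the models, conventions, and design choices behind
`semnet`, and what the simulation-based validation does and does not
establish.

## Network construction

One free-association encounter presents a cue and collects up to three
responses. Every distinct cue–response pair becomes one undirected edge;
its weight is the number of times the pair occurred across positions,
encounters, and (for the aggregate network) participants. Response
position carries no discount: nothing in the elicitation design justifies
weighting a first response more than a third. A response identical to its
cue is discarded. The cue→response direction is not retained; edges are
undirected from the start. Second encounters of repeated cues contribute
by default (`include_repeats=True`) — the design's stated response yield
counts them — and the flag is exposed because either convention is
defensible.

Word canonicalization is deliberately minimal: lower-case, trim, collapse
internal whitespace. No lemmatization, spelling correction, or diacritic
folding, so node identity in the resulting networks remains auditable;
multi-word responses stay single nodes. Files are UTF-8.

Common subnetworks induce each participant's network on the intersection
of all node sets; all participants then have the same |V|, removing
coverage differences before structural comparison.

## Macroscopic statistics

For each network: node count |V|; unweighted mean degree ⟨k⟩ = 2E/|V|;
mean local clustering C where nodes of degree < 2 contribute 0 and stay
in the mean (the common convention; excluding them raises C on sparse
graphs); mean shortest-path length L over unordered node pairs of the
largest connected component, with edges unweighted (disconnected pairs
are thereby excluded by construction rather than treated as infinite).
All macro statistics ignore edge weights. Group summaries are unweighted
arithmetic means across member networks. L is delegated to igraph's C
implementation; tests verify exact agreement with a Floyd–Warshall
oracle on small graphs. Degree-distribution similarity between two
networks is the Pearson correlation of their degree vectors over shared
nodes. Community detection uses the Louvain method on weighted edges
with a fixed seed and sorted node order, so partitions are reproducible.

## Node measures

**Scaled PageRank.** The stationary distribution of a damped random walk
(damping d = 0.85, the classical value) on the symmetrized graph, by
power iteration to an L1 change below 1e-12, then multiplied by |V| so
that values are comparable across networks of different sizes (the scaled
values average exactly 1). The pipeline runs PageRank on the raw
co-occurrence counts — not PPMI-reweighted — because the frequency bias
that PPMI corrects is a problem for similarity, not for centrality, where
frequent hub words *should* rank high. Isolated nodes are handled as
dangling mass.

**Katz walk similarity.** With P the row-normalized adjacency and decay
α ∈ (0,1), the walk profile matrix is S = Σ_{t≥1} αᵗ Pᵗ = (I − αP)⁻¹ − I.
Subtracting the identity removes self-walks so that the cosine between
two rows reflects shared neighborhoods rather than self-similarity; a
connected word still has cosine 1 with itself, and words in different
components have cosine 0. α defaults to 0.75, the value used in the walk-
similarity literature on association norms. By default the adjacency is
first PPMI-reweighted: PPMI(i,j) = max(0, log₂ p(i,j)/(p(i)p(j))) with
p(i,j) = w_ij/W and marginals accumulating each undirected edge into both
endpoints; zero-PPMI pairs are dropped. This suppresses edges explained
by word frequency alone. Networks of up to 2,000 nodes use a dense LU
solve of the resolvent; larger ones accumulate the geometric series until
the current term's largest entry falls below 1e-10. Both routes agree to
better than 1e-8 on overlapping sizes; note that a *fixed* 50-term
truncation at α = 0.75 has an analytic tail bound of α⁵¹/(1−α) ≈ 2e-6
and therefore cannot guarantee 1e-8 — the implementation iterates to
tolerance instead of a fixed term count.

## Behavioral linkage

All effects are raw mean differences (not standardized), each reported
with the sizes of its comparison sets so users can standardize
downstream, and each computable under the participant's own network or
the aggregate network through the same code path.

* *Fluency retrieval*: mean scaled PageRank of retrieved candidate words
  minus non-retrieved candidates. Category candidates come from an
  explicit word list; letter candidates default to all network words
  whose first character matches the task letter (`letter_rule =
  "task_letter"`); the alternative reading — words sharing any retrieved
  word's initial — is available as `"own_initial"`.
* *Lag similarity*: mean walk-similarity cosine over ordered retrieval
  pairs ℓ positions apart (ℓ = 1..3), indexing positions in the original
  sequence; pairs with an out-of-network endpoint are dropped, the
  sequence is never re-spliced.
* *Episodic profiles*: statuses partition the in-network words of one
  trial into retrieved (studied ∧ recalled), missing (studied only), and
  intrusions (recalled only); each status gets a mean scaled PageRank and
  a mean cosine to the retrieved words (excluding self for retrieved
  words). With no retrieved word in the network the similarity profile is
  undefined but the centrality profile is still returned.
* *Paired associates*: mean cue–target cosine of recalled minus
  unrecalled pairs.

Degenerate cases (an empty comparison set, a single-outcome pair list)
raise an explicit undefined-effect error rather than returning a number.

## Reliability

Repeat consistency follows the second-against-first direction: of the
responses given at a cue's repeat encounter, the proportion already given
at its first encounter, pooled over repeated cues with set semantics
(position ignored). The reverse direction is an option because the two
differ when response counts differ. The repeat-association profile
reports the percentage of distinct cue–response pairs occurring more than
once and the maximum count. Cross-network correlations are Pearson
correlations over shared nodes — of centrality vectors, and of the upper
triangle of the shared-node pairwise cosine matrices (with a seeded
common subsample above 100,000 pairs, reporting an approximate SE); a
per-node mean-cosine variant is provided as an alternative reading.

## Synthetic cohorts

The generator's role is adversarial honesty: it encodes known structure
so the pipeline can be shown to recover it.

**Ground truth.** Each age group gets a connected ring-rewired network
over a shared pseudo-word lexicon (6-letter tokens over an 8-letter
alphabet, so letter-cued candidate sets are a useful fraction of the
lexicon). Starting from a ring lattice of degree k, each edge is rewired
with probability 1 − `clustering_control`; the new endpoint is drawn
proportional to a lognormal node salience (σ = 0.9) rather than
uniformly, and edge weights scale with the product of endpoint saliences.
Salience is essential, not cosmetic: a plain constant-degree rewired ring
has almost no centrality variance, so there would be nothing for
centrality-coupled behavior to reveal; salience-biased rewiring gives the
heavy-tailed degree and strength distributions real lexicons show (the
frequency bias that motivates PPMI in the first place). The young/old
contrast is carried by lexicon size and degree — old: 2,000 words at
degree 6 with control 0.4; young: 1,200 words at degree 10 with control
0.85 at desk scale — because rewiring alone cannot raise C and shorten L
at the same time. Categories are contiguous ring blocks (semantically
clustered, as real categories are); the first doubles as the
fluency-task category.

**Associations.** Cues are a uniform sample of the lexicon, except that
fluency-relevant words (category exemplars, letter candidates) are always
included — mirroring how fixed cue lists are designed to cover task
materials, and necessary for the built networks to measure candidate
centrality at partial cue coverage. Each encounter draws three responses
without replacement from the cue's truth neighborhood proportional to
edge weight, with a small uniform-lexicon noise rate making individual
networks diverge. A repeat encounter copies each response slot from the
first encounter with probability q (`repeat_fidelity`) and otherwise
resamples from the neighborhood *excluding* the first-encounter
responses; the exclusion makes q the expected downstream consistency
exactly, so the estimator can be checked against the parameter without a
chance-overlap correction.

**Behavior.** Retrieval is coupled to the *truth* network's measures
(scaled PageRank with count weights; PPMI walk similarity): fluency is a
sequential softmax over candidates with utilities
β_c·PR + β_s·cosine-to-previous; episodic recall is Bernoulli with
logistic(intercept + β_c·PR); paired-associate recall is Bernoulli with
logistic(intercept + β_s·cosine) over pairs spanning the cosine range
(half neighbor pairs, half random). Defaults β_c = 4, β_s = 8 are sized
to the predictors' spread (scaled-PageRank sd ≈ 0.6–1.3, cosine range
≈ 0–0.4); unset intercepts are centred at runtime so baseline retrieval
is about one half. Setting both slopes to zero yields exactly null
effects, which the validation uses for calibration.

**Problem sizes.** The desk-scale default (600 unique + 120 repeated cues
per participant over a 2,000-word lexicon, eight participants) is about
one fifth of a full study and runs in roughly a second per cohort. The
Monte-Carlo validation profile (`small_cohort_config`) shrinks the truth
networks to 350/600 words with 315 + 63 cues (90% cue coverage of the
young lexicon), 14-item fluency sequences over 50-word categories, eight
15-word episodic lists, and 40 word pairs, so that hundred-participant
recovery experiments run in seconds. The repeat-fidelity check runs at
full study scale (3,000 + 600 cues), where the binomial SE of the
consistency estimate is about 0.012.

**What passing validation shows — and what it does not.** Recovery of
the structural ordering and of all four behavioral couplings in ≥95% of
simulated participants shows the pipeline's statistics point the right
way when the generating process matches the model family: group-shared
truth, salience-driven hubs, logistic couplings, clean canonical tokens.
Real data differ in ways the generator does not emulate: responses need
cleaning and lemmatization decisions, cue lists are not uniform samples,
individual truths differ *within* groups, retrieval has dynamics
(clustering runs, fatigue) beyond one-step softmax, and real effect sizes
are far smaller. Passing therefore validates the machinery, not the
empirical claims themselves.

## Numerical conventions and degenerate inputs

Power iteration raises a convergence error carrying the residual rather
than returning a stale vector. Scaled PageRank is renormalized to sum
exactly |V|. Walk-similarity rows of words isolated after PPMI are zero;
their cosines are defined as 0. Pearson correlations of constant vectors
are reported as NaN (undefined), except that identical degree vectors
(including regular graphs against themselves) give 1. Community
detection, subsampling, and every generator accept explicit seeds; the
pipeline derives per-stage substreams from one root seed, and identical
config + seed reproduce byte-identical CSVs. Single-node components have
undefined (NaN) path length; a single isolated node has scaled PageRank 1.

## Known limitations

German-specific normalization (umlaut handling, compound splitting) is
out of scope; canonicalization is language-agnostic. The letter-task
candidate rule is a convention with two readings (see above). Effects are
unstandardized mean differences, appropriate for within-participant sign
comparisons but not directly comparable across networks with different
measure scales. The aggregate-versus-individual comparison is confounded
with weighted-versus-unweighted edges, as any pooled design is; the
package reports both means and their difference without a significance
test, since eight participants do not support one.
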