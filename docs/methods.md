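# Methods

`synlethal` predicts synthetic-lethal (SL) gene pairs — pairs of genes
whose simultaneous loss kills a cell while the loss of either alone does
not — from three protein-level data sources: 3-D structures, amino-acid
sequences, and a protein–protein interaction (PPI) network. This note
documents the model, the numerical choices, the synthetic benchmark data,
and the limitations of both.

## Feature extraction

**Structural branch.** For each protein we read the Cα trace from its PDB
file (first model; the chain with the most CA atoms — AlphaFold-style files
are single-chain). The pairwise Euclidean distance matrix
D_ij = ‖r_i − r_j‖ over Cα coordinates is thresholded into a binary contact
map, A_ij = 1 iff D_ij < `cmap_thresh` and i ≠ j. The threshold defaults to
10 Å Cα–Cα, the common contact-map convention; the comparison is strict and
the diagonal is forced to zero, while sequential neighbors are retained so
the backbone remains connected in the graph. The contact map defines an
unweighted residue graph, which is embedded with node2vec (below); the
residue-node vectors are mean-pooled into one fixed-size vector per
protein. A protein whose contact graph has no edges (e.g. a single residue)
maps to the zero vector. node2vec consumes topology only; a flag optionally
appends the mean one-hot amino-acid composition (20 extra dimensions,
default off).

**PPI branch.** The STRING-style edge list (protein_a, protein_b, score) is
deduplicated keeping the maximum score per undirected pair, self-loops
dropped, and optionally filtered at a minimum confidence score (default 0,
i.e. no filter — exposed as `min_ppi_score`). node2vec on this weighted
graph yields one vector per protein.

**Sequence branch.** A residue embedder maps a sequence to a tensor of
shape (layers+1) × T × d_model; the protein vector is the per-layer mean
over the T residues followed by an element-wise sum across layers. The
embedder is a pluggable contract: a pre-trained protein language model
(ELMo/SeqVec-style, d_model 1024) is one realization; the built-in k-mer
hash embedder — each residue's vector is a seeded hash of the k-mer
centered on it (default k = 3) — is a deterministic, fully offline
realization used in all tests. It preserves the properties the pooling
depends on (locality, determinism, shared components between similar
sequences) but carries no evolutionary information.

**node2vec.** Walks are second-order biased: from the state (prev → curr),
the unnormalized weight of candidate u is w(curr,u)·α with α = 1/p if
u = prev, α = 1 if u is adjacent to prev, and α = 1/q otherwise; the first
step is proportional to edge weights alone. Skip-gram with negative
sampling (noise distribution ∝ unigram^0.75, output vectors zero-initialized,
input vectors uniform in ±0.5/dim) is trained by minibatch SGD with a
linearly decayed learning rate (0.025 → 0.025·10⁻³); within-batch gradient
collisions are accumulated exactly (`np.add.at`), so single-threaded runs
are bit-for-bit reproducible under a fixed seed. The skip-gram input vector
is the node embedding. Defaults: 10 walks per node of length 80, window 10,
5 epochs, 5 negatives, p = q = 1 — all configurable.

## Dataset assembly

Gene features are the concatenation [sequence | PPI | structure] of the
mapped protein's three blocks; genes whose protein lacks any block are
excluded and counted. A many-to-many gene↔protein map is resolved by
keeping the protein with the longest sequence (ties: lexicographically
smallest ID).

Known SL pairs are positives. Known non-SL pairs are used first as
negatives; if they fall short of the configured positive:negative ratio
(1:1 by default, with 1:3 / 1:5 / 1:7 used in the imbalance sweep), the
remainder is drawn uniformly at random from unordered pairs of valid genes,
excluding self-pairs and every known pair in either orientation — sampling
is rejection-based with a full-enumeration fallback, exact in count,
duplicate-free, and seeded. Each pair's feature vector concatenates the two
gene vectors in canonical (lexicographic) gene-ID order, which makes
predictions symmetric in the two genes by construction.

Cross-validation uses 5 folds with a 6.4 : 1.6 : 2 train/validation/test
proportion per fold (the fold's 20% share is the test set; the remaining
80% is split 80/20 into train/validation), stratified by label and
deterministic under a seed. Standardization (per-dimension z-scoring;
zero-variance dimensions pass through unscaled) is fitted on each fold's
training rows only.

## The MLP link predictor

Three ReLU hidden layers of 256, 128 and 64 units, sigmoid output, dropout
0.5 after every hidden activation (inverted dropout), binary cross-entropy
loss plus an L2 penalty λ Σ_k ‖W^(k)‖² on the weight matrices (biases
exempt; λ defaults to 1e-4). Adam starts at learning rate 0.004; the rate
is halved when the validation loss fails to improve by a relative 10⁻³ for
5 consecutive epochs; training stops early after 10 epochs without
improvement and the best-validation weights are restored. Predictions at
exactly 0 or 1 are clamped at 10⁻⁷ inside the loss. The network, backprop
and Adam are implemented directly in numpy; single-threaded training is
bit-exact under a fixed seed.

Defaults chosen where the protocol is otherwise silent: batch size 256,
maximum 200 epochs, F1 decision threshold 0.5.

Evaluation reports AUC (area under ROC), AUPR (average precision, the
step-wise area under the precision–recall curve) and F1 at threshold 0.5,
as mean ± sd over the five folds. The test suite checks these against an
independent sort-based reference implementation.

## Synthetic benchmark bundles

The fixture generator writes all five inputs (PDB files, FASTA, PPI TSV,
SL CSV, gene-map TSV) at toy scale with a planted, tunable SL signal.
Genes carry latent functional modules; SL pairs are within-module pairs and
known non-SL pairs are cross-module. The selected block(s) expose module
membership:

* **struct** — module members share a fold template: a persistent random
  walk with exact 3.8 Å Cα steps, perturbed per member by Gaussian jitter
  of sd 0.15/(1+strength) Å (step lengths renormalized afterwards) and a
  random rigid motion, which the contact map ignores.
* **seq** — module members share a template sequence with point mutations
  at rate min(0.6, 0.15/strength).
* **ppi** — module members are densely interconnected (edge probability
  1 − e^(−strength), scores 900–999) on top of an Erdős–Rényi background
  (default edge probability 0.1, scores 150–999), giving SL partners many
  common neighbors.
* **none / strength 0** — all features are background noise and SL labels
  are uniform random pairs.

Defaults: 40 genes in modules of 8, 140 SL pairs (all within-module pairs,
so that no unlabeled within-module pair can be drawn as a random negative
and masquerade as label noise), 20 known non-SL pairs — scarce relative to
positives, mirroring the real imbalance between curated SL and non-SL
interactions. One chain length per bundle is drawn from 20–80 residues and
shared by all proteins: per-module lengths would leak module identity
through embedding norms and confound the location of the planted signal.

**Degree-balanced known negatives.** In signal-carrying bundles the known
non-SL pairs are built from successive random cross-module perfect
matchings, so every gene appears equally often (±1) among them. A
benchmark that supplies as many known negatives as positives thereby
removes gene-frequency artifacts — a classifier cannot score pairs by how
often their genes appear among negatives — and isolates the feature-driven
signal.

**Label-graph transduction, and why the ablation benchmark is sized the
way it is.** When SL labels form large within-module cliques, an MLP can
partially reconstruct the module partition from the *training label graph
alone*: it memorizes each gene's (otherwise uninformative) feature vector
and learns which memorized vectors co-occur in positive pairs, a form of
transductive link completion. With 40 genes in 5 modules of 8 we measure
test AUC ≈ 0.67–0.73 with pure-noise features. This ceiling-free leak is a
property of pair-level splits, not of any feature block, so the
signal-localization (ablation) benchmark uses 90 genes in modules of 6
with degree-balanced known negatives covering the full negative demand:
there the pure-noise floor is ≈ 0.52–0.55, while the structure-driven
variants reach AUC ≥ 0.95. Removing the structure block then collapses
performance to that floor, and removing sequence or PPI blocks does not.

**Scaled-down study conditions.** Fixture-driven experiments (the test
suite and the acceptance script) run with sequence dimension 64, PPI and
structure dimensions 32, walks 4 × 15 with window 3 and 2 epochs, and MLP
batch size 32. The reduced batch size matters: with a few hundred training
rows, batch 256 yields a single optimizer step per epoch, starving Adam
relative to the step count the protocol assumes at full scale. The
library's defaults (1024/128/128, walks 10 × 80, batch 256) are unchanged.

## What the synthetic benchmarks do and do not show

Passing the planted-signal, null, ablation and ratio-sweep checks shows the
pipeline is implemented coherently end to end: features propagate the
information they are supposed to carry, the sampler and splits are
leak-free in canonical-pair space, the optimizer learns, and the
evaluation is calibrated. It does **not** show that the method attains any
particular accuracy on real SynLethDB/STRING/AlphaFold-scale data: the
fixtures have block-structured ground truth, uniform protein lengths,
unrealistic PPI degree distributions, and a hash embedder in place of a
pre-trained language model.

## Known limitations

* Contact definition is Cα–Cα only; no all-atom contacts, secondary
  structure, or pLDDT-based masking of low-confidence regions.
* The residue embedder contract ships without pre-trained weights; plugging
  in a real language model is the user's responsibility.
* Negative sampling is uniform; degree-matched or hard-negative schemes are
  out of scope, and the transduction effect described above applies to any
  pair-level split on clustered interaction labels, including real SL data.
* Pan-cancer labels only; no cell-line-specific modeling.
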