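# Methods

## Problem and model

The package predicts unobserved lncRNA–disease associations by completing a
sparse binary relational matrix. Three association tables are used: a
miRNA–disease matrix `MD` (nm × nd), a miRNA–lncRNA matrix `ML` (nm × nl)
and the lncRNA–disease matrix `LD` (nl_ld × nd_ld), where the curated
lncRNA–disease evidence typically covers only a subset of the lncRNA and
disease universes; injective index maps connect LD's rows/columns to the
full spaces. Every disease and lncRNA is represented by its miRNA
interaction profile — a binary vector of length nm — so the miRNA space is
the shared feature space of both entity types.

Each entity type has its own small convolutional network: a convolutional
layer whose kernels span the full profile (one scalar output per kernel,
nd kernels on the disease side, nl on the lncRNA side), followed by three
fully connected layers, all ReLU-activated. Layer widths are
(nd, nd, nm, 1) on the disease side and (nl, nl, nm, 1) on the lncRNA
side. The completed score matrix couples the two middle weight matrices of
each side directly:

    LD' = sigmoid( W_l2 · W_l3 · W_d3ᵀ · W_d2ᵀ )        (nl × nd)

i.e. prediction uses the learned weights as entity representations rather
than a forward pass — the fourth layer participates in training only
through its regularisation term.

## Balanced negative sampling

Known associations are a few percent of the matrix, so the supervised term
uses a balanced sample: all 1-cells as positives, and an equal number of
negatives drawn uniformly from cells with *zero propagation support*.
Support is measured by a KATZ-style matrix accumulating all 1-, 2- and
3-step walks through the association matrix and the two similarity
matrices (restricted to the LD sub-space, the only conformable blocks):

    FLD = LD·LDᵀ·LD + LD·S_D·S_D + S_L·S_L·LD + S_L·LD·S_D

"Zero" means exactly 0.0; an epsilon tolerance is configurable and an
opt-in fallback tops up from the lowest-support cells when fewer exact
zeros exist than positives. Cross-validation folds re-sample negatives
from the fold's own training matrix so no support leaks from test
positives.

## Loss function

Training minimises

    loss_total = loss1 + λ1·loss2 + λ2·loss3 + λ3·loss4 + λ4·loss5

with defaults λ1 = 1e-3, λ2 = 0.1, λ3 = 10, λ4 = 1 (a grid-search optimum
over {1e-3, 1e-2, 0.1, 1, 10} per weight).

* **loss1** — squared error of LD' against the sampled positives (target
  1) and negatives (target 0); a raw sum over the p + q sampled cells.
  With all-zero parameters every score is exactly 0.5 and
  loss1 = 0.25·(p + q).
* **loss2** — squared reconstruction error of the layer-3 output (length
  nm) against the entity's own miRNA profile, summed over the diseases and
  lncRNAs incident to the sample; ties the feature extractors to the
  profiles. Layer 3 is the only layer whose width matches the profile.
* **loss3** — `mean((W_l2 − S_L)²) + mean((W_d2 − S_D)²)`: anchors the
  middle weight matrices at the lncRNA functional and disease semantic
  similarity matrices.
* **loss4** — per-entry mean-square penalty on the four matrices entering
  the predictor.
* **loss5** — per-entry mean-square penalty on every weight and bias.

### Why the parameter terms are per-entry means

The two data terms are sums over sampled cells/entities; the three
parameter terms are normalised by their matrix sizes. This is a deliberate
convention, not a simplification. With unnormalised Frobenius penalties and
λ3 = 10, the largest total-loss reduction the supervised term can ever
deliver is its full stake 0.25·(p + q) (tens to a few hundred), while any
weight configuration whose four-factor product carries signal costs a
penalty of order (λ3 + λ4) × the Schatten-1/2 factorisation cost — hundreds
to thousands at every realistic size. The global optimum then pins the
predictor at exactly zero (verified numerically: loss1 stays at
0.25·(p + q) to 12 digits and every score is 0.5 for any initialisation
scale), and the loss_total < 1e-3 stopping rule can never fire because
loss3 → 0 forces λ3·loss4 ≥ 10·‖S_D‖²_F. Mean reduction — the default of
deep-learning frameworks — removes both pathologies while leaving the λ
balance, the non-negativity of every term, the λ-linearity of the total
and the loss1 closed form untouched.

Even under this convention the balance remains size-dependent: below
roughly 35 known associations the penalties still dominate the stake and
the predictor stays at its zero optimum. The default synthetic conditions
(60 positives) sit comfortably on the learning side of the transition;
very small instances are useful for testing mechanics but not recovery.

## Similarities

Disease semantic similarity follows the classical MeSH-DAG contribution
scheme: a disease's own tree-number nodes contribute 1 and each ancestor
contributes `decay` (default 0.5) times the best contribution among its
children inside the disease's DAG; a node reachable through several tree
numbers takes the maximum. Similarity of two diseases is the sum of both
contributions over shared nodes divided by the sum of their total semantic
values. Unannotated diseases get zero off-diagonal similarity and a unit
diagonal.

lncRNA functional similarity is the best-match average over the disease
sets the two lncRNAs are associated with through LD. lncRNAs without
associations (including all lncRNAs outside the LD sub-space) get zero
off-diagonal similarity and a unit diagonal; under loss3 their rows of
W_l2 shrink toward zero, which is documented behaviour.

## Optimisation

Full-batch Adam (β1 = 0.9, β2 = 0.999, eps = 1e-8) on analytic gradients;
the objective is one small matrix expression, so batching would add noise
without saving memory. Learning rate 1e-3, initialisation i.i.d.
N(0, 0.01²) weights with zero biases, all draws seeded. The loop records
the loss each iteration and stops the first time loss_total < tolerance
(default 1e-3) or at max_iterations (default 5000). At realistic sizes the
tolerance floor set by the similarity anchoring makes the cap the binding
rule; on the default synthetic conditions the fit is converged by roughly
1000 iterations. Everything is single-threaded double precision, so a
fixed seed reproduces traces bitwise; a non-finite loss raises a
divergence error naming the iteration and learning rate.

## Evaluation protocols

* **K-fold CV** (5 and 10): positives are sorted, shuffled by seed, split
  into folds differing by at most one in size. Per fold the test positives
  are zeroed in the training matrix, negatives re-sampled, the model
  retrained with a fold-derived seed (base + fold index), and the fold AUC
  computed over test positives (label 1) versus all never-known cells
  (label 0), training positives excluded. Headline number = mean per-fold
  AUC; the per-fold values and population variance are reported alongside.
* **LODOCV**: per disease with at least one known lncRNA, its whole LD
  column is hidden, the model retrained, and all nl lncRNAs ranked for it.
  This probes diseases with no training associations at all.
* **LOOCV**: one association hidden per round; the held-out score and the
  round's never-known scores are pooled across rounds into one AUC.
* **ROC/AUC**: threshold sweep over distinct score values with trapezoid
  integration, which equals tie-corrected Mann–Whitney pair counting
  (ties get half credit). Verified against exhaustive pair counting and
  an independent reference implementation.
* **Candidate ranking**: for one disease, all lncRNAs without a known
  association ranked by descending score, ties broken by name.

## Synthetic data generator

The generator emulates the *shape* of the curated corpora: three binary
association matrices sharing a latent miRNA feature space, similarity
matrices consistent with the planted signal, and an optional MeSH-style
annotation table. Every entity belongs to one of `latent_rank` (default 4)
communities and gets a non-negative latent vector supported on that
community's private pair of coordinates with Gamma(2, 1) magnitudes.
Associations arise by thresholding latent inner products at the quantile
matching the target density (default 5%, the order seen in curated
association databases); similarities are clipped cosines of the latents.

The block-disjoint supports are essential: they make cross-community
similarities *exactly* zero, mirroring diseases in disjoint MeSH branches
that share no ancestors. Without exact zeros the propagation matrix is
entrywise positive and the exact-zero negative-sampling rule has no cells
to draw from. Within a community, similarity still varies continuously, so
the planted signal is not merely a block structure.

Label noise moves a fraction of the 1-entries to uniformly chosen 0-cells,
preserving density; flipping a fraction of *all* cells would multiply the
association count several-fold and empty the zero-support pool. The
default sizes are nm = 60, nd = 50, nl = 80 with a 40 × 30 LD block —
about two-thirds of the real corpus along each axis of the LD sub-space,
chosen so a full cross-validation experiment completes in minutes on one
core. Entities required by the LD pair file are guaranteed at least one
miRNA association so the written pair files remain mutually resolvable.

What the generator does not emulate: the heavy-tailed degree
distributions, inter-community bridges and annotation depth heterogeneity
of real curated databases. Passing the recovery checks demonstrates that
the pipeline recovers planted low-rank community structure from its own
kind of data, not that it reproduces published performance on the real
corpora (whose extracts are not redistributable).

## Numerical choices and edge cases

* ReLU subgradient at 0 is taken as 0; gradient checks use generic points.
* The sigmoid is evaluated in the overflow-free split form; strict (0, 1)
  bounds hold until |logit| ≈ 37, where double precision saturates.
* Score matrices are written with 17 significant digits and re-read with
  round-trip float parsing, so write/read is bit-identical.
* Checkpoints are zip archives with fixed timestamps: identical parameters
  give byte-identical files, making end-to-end runs hash-reproducible.
* Degenerate quantile thresholds (all products equal) raise an error
  advising a larger latent rank; empty annotations yield empty
  contribution maps; duplicate conflicting MeSH lines are rejected.
* `variance` in CV reports is the population variance of per-unit AUCs.

## Known limitations

* The learning/no-learning transition with the published λ weights means
  very small problems silently sit at the zero optimum; inspect the
  training trace (`loss1` stuck at 0.25·(p+q)) to detect this regime.
* The permuted-label control can exhaust the exact-zero pool; the
  evaluation API exposes the lowest-support top-up fallback for that case.
* LOOCV retrains once per known association and is only practical at
  small scale or with a reduced iteration cap.
* Scores are well-ordered but not calibrated probabilities; the heavy
  weight shrinkage keeps logits small except on well-supported cells.
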