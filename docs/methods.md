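# Methods

`sitepart` implements a pipeline for discovering classes of protein
alignment sites that evolve under distinct physiochemical constraints and
for estimating a class-specific empirical amino-acid substitution model
for each class.  This note documents the models, the numerical choices,
and what the synthetic data used by the tests does and does not emulate.

## Site profiles

Each alignment column is summarised by the mean of the Kidera factors of
its residues: nine near-orthogonal scales (bulk P1; hydrophobicity P2–P4;
β-structure preference P5–P6; α-helix preference P7; bend preference
P8–P9) distilled by multivariate reduction from 188 published property
measures.  The scales are centred over the 20 amino acids, so the `n×9`
profile matrix places every site in a common physiochemical space.  Gaps,
unknowns (`X`) and ambiguity codes (`B`, `Z`, `J`) are excluded from both
the numerator and the denominator of the column mean: curated protein
alignments are assumed, and a column with no canonical residue is an
error rather than a silently imputed row.  Stop symbols (`*`) are
rejected outright.

## Site classification

Profiles are clustered by K-means (Lloyd's algorithm with random initial
assignments).  Because K-means is a hill climber, each fit is restarted
many times (default 1000) and the restart minimising the pooled
within-cluster sum of squares `W_k` is kept; this makes the achieved
minimum dispersion, not the particular algorithm, the defining criterion.
The number of classes is chosen with the gap statistic:
`Gap(k) = mean_b log W*_kb − log W_k`, where the `B` (default 100)
reference datasets are drawn uniformly inside the bounding box of the
data expressed in its right-singular-vector basis (the shape-aware
uniform null).  The standard-error term is
`s_k = sd_b(log W*_kb) · sqrt(1 + 1/B)`, and the selected `k` is the
smallest one with `Gap(k) ≥ Gap(k+1) − s_{k+1}` (the one-standard-error
rule).  `k = 1` is always evaluated so "no structure" is expressible;
when no `k` below `k_max` satisfies the rule, `k_max` is returned with a
warning flag.  Reference fits use fewer restarts (default 25) than
observed-data fits — reference data have no structure to miss and their
dispersion dominates neither the gap nor its error term.  Group labels
are always renumbered by decreasing size (1 = largest).

## The substitution model

Amino-acid evolution within a class follows a 20-state reversible
continuous-time Markov model, `Q = R·diag(π)`: `R` is the symmetric
matrix of exchangeabilities (190 off-diagonal pairs, 189 free once one
pair pins the scale) and `π` the equilibrium frequencies, estimated
empirically per data subset (+F) with a pseudocount of 1e−6 per residue
class so classes dominated by a few residues keep strictly positive
frequencies.  `Q` is reported on the mean-rate-one scale
(`−Σ π_i q_ii = 1`) so branch lengths read as expected substitutions per
site.

Likelihoods are computed by Felsenstein pruning on a fixed topology with
site patterns compressed to unique columns.  `P(t) = exp(Qt)` comes from
the symmetric eigendecomposition of `diag(√π)·Q·diag(1/√π)`.  The engine
also supplies analytic first derivatives of the log-likelihood with
respect to every branch length (`dP/dt = QP`) and every exchangeability
pair, the latter through the spectral (Fréchet) derivative of the matrix
exponential; one full gradient costs a small multiple of one likelihood
evaluation, which is what makes maximum-likelihood estimation of 189
parameters tractable at desk scale.

### Optimisation

Two strategies are provided, both run from one or more starting matrices
with the best final likelihood kept:

* **joint** — all free log-exchangeabilities and all log branch lengths
  in a single bounded L-BFGS-B search.  The (W,V) reference pair is held
  at its starting value here to remove the exactly flat direction
  (rescaling `R` against branch lengths).
* **cyclic** — alternating phases: branch lengths at fixed
  exchangeabilities, then exchangeabilities at fixed branch lengths,
  until the improvement per cycle falls below 0.01 log-units (default
  cap 10 cycles).  Within an exchangeability phase the fixed branch
  lengths already identify the overall rate scale, so all 190 pairs are
  left free there; fixing the reference pair instead couples the two
  phases along a near-flat ridge and the alternation creeps by ~0.01
  log-units per cycle indefinitely.  On test problems the two strategies
  agree to better than 0.1 log-units.

Free exchangeabilities are optimised on a log scale with bounds
`[1e−6, 1e3]`; branch lengths with bounds `[1e−8, 50]` (the lower bound
keeps `P(t)` well conditioned).  Fitted matrices are rescaled to mean
rate one afterwards, with branch lengths rescaled inversely so the
likelihood is unchanged.  Pairs involving residues never observed in the
data subset are reported but flagged as weakly identified.

The public `optimize_branch_lengths` follows the classical per-branch
Brent scheme (messages recomputed per branch, so the likelihood is
monotone across updates, iterated until the per-sweep gain drops below
1e−6).  The fitting routines internally use the joint quasi-Newton
search on log branch lengths with the analytic gradient — the same
optimum, considerably faster.

### Per-class branch scaling

As a cheaper alternative to free per-class branch lengths, a single
multiplier `s` per site class can be fitted by one-dimensional bounded
search on `[1e−3, 100]`, stretching a reference tree's branch lengths
uniformly.  Boundary solutions raise a warning.

## Noise analysis

To ask whether class-specific matrices differ from the joint matrix by
more than chance, `S` (default 50) random site partitions with the
observed class sizes are drawn, a matrix is fitted to every random
subset, and each matrix's distance to the reference matrix is measured
as the Euclidean distance over the 190 pairs after both matrices are
rescaled to mean rate one under their own subset frequencies (raw
exchangeabilities are defined only up to scale, so distances without a
scale convention are meaningless).  Per class, a one-sided test asks
whether the mean random distance falls below the observed one.  The
standard error uses the prediction form `sd·sqrt(1 + 1/S)`: under the
null hypothesis the observed partition is itself one random draw, and
the plain one-sample form (which treats it as a constant) rejects with
probability ≈0.3 per class on truly homogeneous data.  With the
prediction form the test is exactly calibrated under exchangeability,
and at real-data effect sizes (observed distances tens of standard
deviations beyond the random mean) the two forms are indistinguishable.
P-values are Bonferroni-corrected over the classes.  Failed replicate
fits are skipped with a warning rather than aborting the campaign, with
the realised `S` reported.

## Cross-validation

Each class is split 50/50 into training and validation halves (the odd
site goes to training).  A matrix is fitted to every training half, and
every validation half is scored under every training matrix and under
the supplied complete-data matrix.  Validation scoring uses the
validation subset's empirical frequencies and re-optimises branch
lengths under each candidate matrix, so only the exchangeabilities are
under test; reusing training branch lengths is available behind a flag.
Ten replicates are summarised as the mean and standard deviation of
`logL(V_i|R_Ti) − logL(V_i|alternative)`.  The class memberships are
fixed before training (they come from clustering the complete data), so
this is deliberately not a standard cross-validation: it validates the
published-matrix use case, where a class map is supplied together with
the matrices.

## Synthetic data

`make_fixture` builds group-structured alignments: per class, sites are
simulated i.i.d. down a shared random tree under a class-specific
`(R, π)` and the concatenated columns are shuffled with the true map
retained.  The default three-class recipe mimics the composition of
mitochondrial site classes — one class dominated by bulky hydrophobics
(L, I, V, F, M), one by alanine/threonine, one by the small bend-formers
(G, P, S, N).

Desk-scale defaults were chosen so that the planted structure is
actually recoverable by the methods being tested, and sit deliberately
in particular corners of parameter space:

* 24 taxa with mean branch length 2.0 substitutions/site.  Site profiles
  are means over the column's residues; with shallow trees every column
  stays near its root residue and each class becomes a lumpy mixture of
  per-residue clusters that the gap statistic resolves as extra classes.
  Deep divergence (as in real mitogenomic datasets) mixes each column
  toward its class's frequency profile.
* Class sizes 140/130/120.  With one dominant class (e.g. 200/120/80 at
  a few hundred sites) the gap curve keeps rising past the true `k`
  because splitting the large, elongated class reduces `log W` faster
  than the uniform reference; the published datasets, two orders of
  magnitude larger, do not sit in this regime.
* Class rate matrices are log-normal with sd 0.8 around a common scale —
  distinct but fast-mixing; extreme dispersion produces slow-mixing
  residues and lumpy columns again.

The noise-analysis and cross-validation test fixtures instead use broad
Dirichlet frequency profiles covering all 20 residues: with 8–12 taxa
and a few hundred sites, concentrated profiles leave most of the 190
pairs without data, and matrix distances are then dominated by optimiser
noise rather than by the planted class differences.  Class distinctness
in those fixtures is carried by the exchangeability matrices, which is
the quantity those analyses actually test.

What the fixtures do **not** emulate: among-site rate variation,
alignment error and gap structure, compositional drift across lineages,
overlapping reading frames, or the phylogenetic scale of real
mitogenomic data (hundreds of taxa, thousands of sites).  Passing the
test suite therefore demonstrates correctness of the machinery and
recoverability of planted structure under favourable, realistic-depth
conditions — not that real data will yield any particular `k` or matrix.

Test and acceptance problem sizes (e.g. 20 taxa × 3000 sites for
parameter recovery; 8 taxa × 400 sites with `S = 10` for the noise
analysis; 900 sites over three classes with 10 replicates for
cross-validation; `B = 30` reference draws and 200 restarts for
clustering runs) are the package's desk-scale choices; the defaults
baked into the library (`B = 100`, 1000 restarts, `S = 50`) follow the
real-data protocol.

## Known limitations

* No among-site rate variation (gamma categories) and no mixture
  likelihoods; classes are hard partitions, as in the underlying method.
* Topology is never searched; all estimation conditions on a user-
  supplied tree.
* The exchangeability-distance is an unweighted Euclidean over pairs;
  rarely-observed pairs contribute noise to it, which is why both the
  noise analysis and any matrix comparison rescale to mean rate one and
  should be read alongside the weak-pair flags.
* Published starting matrices (mtMam, mtREV24, JTT, WAG) are not
  bundled; any PAML-style `.dat` file can be supplied as a starting
  point, and the flat matrix plus a seeded random matrix are the
  defaults.  A physiochemical distance matrix used as a start is
  accepted like any other symmetric non-negative matrix.
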