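# Methods

`mitosignal` dissects the phylogenetic signal of mitogenomic alignments:
it quantifies where an alignment's information about a deep split lives,
how much of it is non-phylogenetic (compositional convergence, saturation,
rate heterogeneity), and whether standard signal-reduction strategies
(gene exclusion, codon-position filtering, translation, fast-site removal)
change the answer.  This note documents the models, statistics,
conventions and design choices, in the order a run encounters them.

## Alignments, coordinates, exclusion rule

Alignments are rectangular matrices over `{A,C,G,T}` + IUPAC ambiguity +
gap, or the 20 amino acids + `X`/`*` + gap.  All user-facing coordinates
— annotation positions, partition columns — are 1-based inclusive
(GenBank convention).  One exclusion rule is set centrally and inherited
everywhere: gaps and ambiguity codes are never counted, in composition,
disparity, saturation or pairwise statistics.  Translation uses the
invertebrate mitochondrial code (NCBI table 5) by default; codons touched
by a gap or ambiguity become `X`, internal stops translate to `*` with a
warning rather than an error (truncated stop codons are routine in
mitogenomes).

## Annotation arithmetic

Feature length is `end − start + 1`; the spacer between adjacent features
is `next.start − prev.end − 1`, negative for overlaps.  Genome length is
the maximum annotated end; strand tallies count genes only (the control
region is not a gene).  Features wrapping the origin of a circular
molecule are rejected rather than guessed; a `circular` flag reports the
terminal junction separately.  The bundled transcription of the published
*L. grossipedia* annotation keeps the printed size/IGN values in
`*_published` columns; a handful of printed cells (two sizes, four
spacers) are internally inconsistent with their own coordinates, and the
tests distinguish printed-column arithmetic from coordinate-derived
arithmetic accordingly.

## Composition statistics

AT-skew `(A−T)/(A+T)` and GC-skew `(G−C)/(G+C)` are computed from counts
or percentages interchangeably (scale invariance is property-tested, and
reverse-complementing a sequence negates both skews).  GARP% is the
frequency of Gly+Ala+Arg+Pro, the amino acids encoded by GC-rich codons.
Tables round percentages to 1 dp and skews to 2 dp; computation keeps
full precision.  Per-gene summaries report max/mean/min and sd across
taxa; both sample (`ddof=1`, default) and population sd are available
because published summaries rarely say which they used.

## Disparity-index homogeneity test

For two aligned sequences compared over their mutually unambiguous sites,
the disparity statistic is `D = ½ Σ_i (n_i(x) − n_i(y))²` over the
residue-count vectors.  Significance comes from an exact Monte-Carlo
null: at each of the `Nd` differing sites the two observed residues are
swapped between the sequences with probability ½, independently.  Under
the null hypothesis that both sequences evolved from their common
ancestor under one reversible, stationary process, the two orientations
of every differing site are exchangeable, so the observed statistic is
one draw from this null regardless of any per-site normalisation (the
normalised `D/L` variant is exposed but cannot change the decision).
The p-value uses plus-one smoothing, `p = (1+k)/(1+n)`; with the default
1000 replicates its resolution is ~1/1001.  For `Nd ≤ 16` the null can be
enumerated exactly (`2^Nd` swap patterns); the Monte-Carlo tail is tested
against this oracle, and the rejection rate under homogeneous simulation
is calibrated against the nominal level.  Pairwise summaries report, per
gene, the count and percentage of significant pairs over all C(n,2)
comparisons at α = 0.01.

## Posterior-predictive compositional test

The global statistic is `max_t d_t`, where `d_t = Σ_i |f_i(t) −
f_i(pooled)|` is taxon *t*'s compositional deviation from the pooled
residue frequencies.  A homogeneous substitution model fitted to the data
(tree, branch lengths, gamma shape) generates `n_sim` replicate
alignments of the same size; the test reports `Z = (obs − mean)/sd` and
`p = P(sim ≥ obs)`, plus NDT, the number of taxa whose observed `d_t`
exceeds the 95th percentile of their own simulated deviations.  This is a
parametric bootstrap around a point estimate rather than an integral over
a posterior: the statistic and the Z/p/NDT summaries keep their usual
posterior-predictive semantics, at desk scale.  Self-consistency is
verified by simulation (p uniform on data generated under the fitted
model family) and power by injection (Z grows monotonically with the
size of an induced AT shift; the shifted taxon enters NDT).

## Substitution saturation

`Iss = mean_site H_obs / H_fss`, where `H_obs` is the per-column plug-in
entropy (log base 2, gaps excluded) and `H_fss` is the *expected* plug-in
entropy of a column of the same number of taxa drawn i.i.d. from the
alignment's global base frequencies, estimated by seeded simulation —
the plug-in entropy of a finite sample is biased below the population
entropy, so the reference must be computed at matched depth.  A fully
random alignment therefore has `Iss ≈ 1`, a constant one `Iss = 0`.  The
critical value `Iss.c` is the least-specified part of the published
method; here it is a documented, seeded simulation: balanced quartets
(internal branch one fifth of the terminals) are simulated over a depth
grid under a frequency-matched model, each depth yields a mean `Iss` and
a true-split recovery rate by parsimony split counting, and `Iss.c` is
the `Iss` at which recovery interpolates through 0.7 (midway between
certainty and the ⅓ chance level).  The verdict — saturated unless `Iss`
is significantly below `Iss.c` by a one-sided test on the mean per-site
entropy — is advisory; `Iss` itself is the exactly testable quantity.

## Nonsynonymous rate (Ka)

Nei–Gojobori-style counting under the chosen genetic code: per codon
position, the synonymous fraction is taken over the non-stop
single-nucleotide alternatives; multi-step codon differences average over
all equal-weight mutational pathways that avoid stop codons (codon pairs
with no stop-free pathway are skipped, as are codons containing gaps or
ambiguity and stop codons themselves).  The proportion `pN = Nd/N` is
Jukes–Cantor corrected, `Ka = −¾ ln(1 − 4pN/3)`; `pN ≥ ¾` leaves the
correction undefined and is reported as such.  "Against the outgroup"
means the mean over the designated outgroup taxa.  Note that convergent
composition between a lineage and the outgroup *reduces* apparent
divergence; rate comparisons should use Ka on data without such
convergence or interpret it jointly with the compositional diagnostics.

## Likelihood engine

Felsenstein pruning over alignment site patterns (unique columns with
weights), with per-node, per-category rescaling against underflow.
Models: JC69, HKY, GTR for nucleotides and Poisson for amino acids, each
optionally with discrete-gamma rates (K equal-probability categories,
conditional-mean rates; the weighted mean rate is exactly 1 for any
shape).  Reversible rate matrices are scaled to one expected substitution
per site and exponentiated via symmetric eigendecomposition.  Likelihood
is invariant to root placement for these models (property-tested), so
trees are handled as unrooted where topology matters.

Fitting is coordinate ascent: bounded Brent on each branch length
(bounds 1e-8 … 10), bounded search on log gamma-shape (0.05 … 50), and
optionally L-BFGS-B on log GTR exchangeabilities; stationary frequencies
are fixed at empirical counts with a 0.5 pseudocount.  A sweep improving
the log-likelihood by less than 1e-6 stops iteration; hitting the sweep
cap flags non-convergence.  Equality between the pruning likelihood and
an exhaustive sum over internal-node states is tested to 1e-10 relative
tolerance, and two-taxon JC69 against its closed form.

Simulation draws a gamma category per site, a root state from the
stationary frequencies, and evolves states root-to-tips.  Two forms of
lineage heterogeneity are supported: per-branch rate multipliers, and
per-branch stationary-frequency overrides — the flagged branch evolves
under the same exchangeabilities but different equilibrium frequencies,
a simple, reproducible form of nonstationary composition drift
(continuous drift along a branch is deliberately out of scope).

Topology search (`ml_tree_small`) is exhaustive to 8 taxa — a coarse
branch-length screen of all topologies, then full optimisation of the
five leaders — and NNI hill-climbing from a neighbor-joining start with
seeded random restarts for 9–12 taxa.  This is a desk-scale stand-in for
production tree search, used on synthetic experiments only.

## Gamma-category assignment and fast-site stripping

Per site, the posterior over rate categories is proportional to category
weight times the site likelihood at that category's rate (empirical
Bayes under the fitted model and tree; the tree is an explicit input).
Assignment is the posterior argmax with exact ties resolved toward the
slower category, so stripping is conservative.  Stripping removes all
sites assigned to the fastest category and reports the removed fraction.
Two cautions learned from the synthetic experiments and documented as
behaviour, not bugs: (i) the assignment is only as good as the tree and
model it conditions on — with very few taxa, convergent sites can be
misclassified as mid-rate because the distorted tree explains them
cheaply; rate assignment should use the full taxon sample even when the
downstream question concerns a quartet; (ii) stripping trades signal for
bias reduction — on clean data it only discards information, and it
helps exactly when homoplasy is concentrated in the fastest category.

## Four-cluster likelihood mapping

Taxa are partitioned into four disjoint clusters; each quartet with one
taxon per cluster is scored under the three quartet topologies
(`12|34`, `13|24`, `14|23`) by ML — model parameters are fitted once on
the full alignment, branch lengths re-optimised per quartet — and the
log-likelihoods are mapped to barycentric weights by a stabilised
softmax.  The simplex is divided into seven regions by a rule frozen in
one function so percentages are bit-for-bit reproducible:

* `corner_i` iff `w_i > 2/3` (fully resolved for topology *i*);
* `center` iff `max(w) < 1/2` and all pairwise `|w_i − w_j| < 1/3`
  (unresolved, star-like signal);
* otherwise the edge between the two largest weights (partly resolved).

The published tool does not print its boundary convention; this partition
is the package's own documented stand-in, unit-tested at boundary points.
Quartet enumeration takes all cluster products up to a cap (default
1000), above which a seeded uniform subsample without replacement is
drawn.  Summaries report the seven region percentages, the quartet count
and the percentage supporting a designated preferred topology (as its
corner share and as the argmax share).

## Synthetic scenario

The generator produces the conditions the pipeline is meant to detect: a
fixed 10-taxon tree — a single-taxon lineage `L1` sister to a two-genus
clade `(S,C)`, `N` as their sister, an `A` clade, and an outgroup `O1` —
with six genes of 300–600 codons (HKY, κ = 4, per-gene background AT
between 56% and 64%, mean 60%), gamma shape 0.5 with four categories.
In the heterogeneous configuration `L1` runs 1.5× faster and drifts to a
*tip target* of 80% AT; frequency overrides are specified as target tip
composition, and the process frequencies are solved numerically from the
branch length and gamma rates (unattainable targets clamp at 99.5% AT).

Two design choices deserve emphasis.  First, the outgroup `O1` drifts
convergently to the same AT target: compositional attraction is an
interaction between *two* compositionally similar, phylogenetically
distant lineages, and a lone shifted lineage simply has no partner to be
attracted to — in trials with only `L1` shifted, homogeneous-model ML
recovered the true quartet in 8/8 replicates and there was no artifact
to mitigate.  Second, branch lengths were chosen so that the three
qualitative regimes the pipeline is designed around actually hold
simultaneously: homogeneous data recover the true quartet, heterogeneous
data are misled toward the `(L1,O1)` grouping, and removing the fastest
gamma category restores recovery.  The mechanism constrains this window:
a convergent match needs substitutions on *both* biased branches (rate
enters quadratically) while the true split needs one change on the
internal edge (rate enters linearly), so homoplasy always concentrates
in fast sites relative to true signal, but stripping can only win if the
internal edge is long enough for slow-to-mid sites to record it.  Hence
moderate biased terminals (0.3 and 0.4 expected substitutions/site) and
an internal edge of 0.4 rather than the near-star geometry one might
first sketch.  These are parameters of a detectability experiment, not
claims about any real taxon; all are exposed on the config.

What the generator does *not* emulate: codon structure and selection
(sites are i.i.d. nucleotides, so translated synthetic genes contain
internal stops), gene rearrangements, within-gene rate structure, base
compositional drift that is gradual rather than branch-switched, and
realistic taxon sampling.  Passing tests on this generator demonstrate
that the statistics detect the injected effects at these effect sizes —
not that any particular real dataset is free of, or doomed by, such
effects.

## Pipeline, seeding, problem sizes

Dataset recipes apply, in fixed order: gene subset → codon-position
filter → optional translation → optional fast-site stripping.  Named
recipes cover the standard mitogenomic constructions (all genes at
positions 1+2; all-gene amino acids; six genes at positions 1+2; seven
proteins; seven proteins with fast sites removed).  The two gene-level
reduction strategies are: rank genes by `|gene AT% − overall AT%|` of a
focal taxon and drop the top *k* (the published ranking rule is not
printed; this one is documented); and drop genes whose per-gene
compositional test gives p below a threshold (default 0.05).

Every random stage of a report run consumes an independent sub-seed
spawned from the master seed and recorded in the log; report bundles
contain no timestamps, so reruns are byte-identical.  Test-suite
experiments are scaled to desk size as the package's own study design:
calibration uses 500 pairs of 1000-site sequences, the
posterior-predictive checks use 40–60 replicate fits with 60–99
simulations each, and the artifact/rescue experiment uses 30 seeds of the
default scenario with quartet-level re-estimation (rate assignment on
all 10 taxa).  Verdict-style conclusions (sign tests, rejection-rate
intervals) are asserted at the 5% level against their exact binomial
nulls.

## Known limitations

* The amino-acid model is Poisson(+Γ); no empirical exchangeability
  matrix ships with the package, so amino-acid likelihoods are cruder
  than nucleotide ones.  Site-heterogeneous mixture models (CAT-like)
  are out of scope; the compositional test deliberately checks a
  *homogeneous* model, so its rejections bundle all departures from that
  model.
* `Iss.c` depends on a stylised quartet geometry and a fixed recovery
  threshold; verdicts are advisory and not comparable with other
  implementations' critical-value tables.
* The Monte-Carlo disparity null conditions on the observed residue
  pairs at differing sites; alternative nulls (e.g. parametric) would
  differ for strongly unequal base compositions.
* Tree search is exact only to 8 taxa and heuristic to 12; it is a
  vehicle for synthetic experiments, not a general tree-inference tool.
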