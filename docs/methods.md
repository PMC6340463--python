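# Methods

`ilstools` implements the bespoke statistical machinery of a
comparative-phylogenomic study of a rapid radiation (modelled on the
*Thunnus* tunas): coalescent-null tests of gene-tree discordance and
mitochondrial introgression, a phylogenetic scan for parallel selection
on standing variation (PhyloGWAS), evolutionary-distinctness
conservation scoring, and the deterministic data-preparation filters
that feed them. A synthetic-data generator stands in for raw
transcriptome genotypes so that every stage is testable end to end.

## Coalescent-unit conventions

Species-tree branch lengths arrive in coalescent units, but different
tools place different multiples of the effective population size behind
one unit. The package models a convention as "generations per unit =
k x Ne" and converts by the ratio of multipliers:

| name | k | origin |
|------|---|--------|
| SNAQ | 1 | network-inference output (generations/Ne) |
| COAL | 2 | the scale on which CF_minor = (1/3)e^(-t) holds |
| MS   | 4 | Hudson's `ms` (generations/4Ne) |

SNAQ -> MS therefore divides lengths by 4. Organelle genomes have
Ne/4, so their lengths are multiplied by 4 before the convention
change; for SNAQ -> MS the two factors cancel exactly and mitochondrial
lengths pass through unchanged. The k=1 reading of SNAQ units follows
the source analyses; some literatures define coalescent units as
generations/2Ne, so the multipliers are configurable fields rather than
hard-coded constants.

## Multispecies-coalescent simulation

Gene genealogies are drawn with a censored Kingman coalescent run
branch-by-branch over the species tree (postorder): within a branch of
length L (ms units), k lineages coalesce pairwise at total rate
k(k-1); survivors pass to the parent branch; the root branch has
infinite duration, as does any branch explicitly set to `inf`
("forced monophyly"). On this scale the expected within-population
pairwise coalescence time is 0.5 and the triplet discordance
probability for an internal branch of t COAL units is (2/3)e^(-t);
both are verified against closed forms and against msprime as an
independent oracle.

Non-ultrametric coalescent-unit trees are accepted: each branch
contributes exactly its stated length of coalescent opportunity, and a
lineage accrues gene-tree branch length equal to the opportunity time
it has itself experienced. For ultrametric inputs this is the standard
MSC; for non-ultrametric inputs it preserves the property that
topology probabilities depend only on the stated internal lengths,
which is what the concordance-factor formulas assume.

Single-change site patterns emulate `ms -s 1`: one mutation is placed
on the realized genealogy with probability proportional to branch
length, and the induced binary derived/ancestral split of the sampled
chromosomes is returned.

Randomness: every public sampling entry point takes one integer seed;
bulk operations run one deterministic `random.Random` stream, and
replicate/gene substreams are derived through numpy `SeedSequence`
spawning, so outputs are platform-stable and reproducible.

## Discordance tests

**Clade-frequency test.** "Clustering" of a species pair is
operationalised as the pair's chromosomes forming an exclusive clade in
the rooted gene tree, with one chromosome per species — matching the
observation of a species-pair sister relationship in a mitochondrial
tree. The defaults are 100 replicates of 100,000 simulated gene trees;
the mean per-replicate clustering frequency is read directly as the P
value for "this pairing arose by ILS alone". The organelle flag
applies the quarter-Ne scaling and haploid sampling.

**Quartet concordance factors.** Observed CFs reduce each gene tree to
quartet topologies, averaging first over combinations of one tip per
species within a gene and then with equal weight over informative
genes (unresolved combinations from polytomies are excluded; a gene
with no resolved combination is uninformative). Expected CFs come from
the species tree: the induced internal branch of the quartet (summed
over all species-tree edges whose clade contains exactly two of the
four species) gives CF_major = 1-(2/3)e^(-t) on the COAL scale. The
goodness-of-fit statistic is a Pearson chi-square on counts n x CF,
pooled over quartets with 2 df each. Two declared caveats travel with
the result: quartets sharing gene trees are not independent, so the
global P value is approximate, and expected proportions are floored at
a configurable epsilon (default 1e-8) so the no-ILS limit does not
divide by zero.

## Parallel-selection scan (PhyloGWAS)

Species-level codon alignments are scanned codon by codon. A codon
column is *testable* when it has at most two distinct amino-acid
states among non-missing species (more than two suggests repeated
substitution rather than sorting of a single ancestral variant) and at
most two missing taxa; any codon containing a gap, N, or IUPAC
ambiguity code counts as missing for that species. A testable site is
a *shared substitution* when all focal species carry one amino acid,
every non-missing non-focal species carries a different one, and all
required species have data. `N_var` counts all testable sites with two
amino-acid states — including ones that are not species-diagnostic —
mirroring how the variable-site denominator in the source analyses was
counted; sites filtered by the >2-state rule are excluded from
`N_var`, the stricter of the two defensible readings.

The null is Monte-Carlo: single-change genes simulated under the MSC
over the species tree with two chromosomes per species (diploid
sampling, one individual per species; the outgroup is sampled if it is
in the tree). A simulated gene matches when its mutation splits the
focal group cleanly from everything else, which implicitly requires
within-species fixation of both chromosomes. Matching is unpolarized
by default ("either"): observed amino-acid fixed differences carry no
ancestral/derived orientation. Missing data are handled by exact
configuration weighting: for every missing-taxa subset observed among
tested codons, the simulated patterns are re-matched with those taxa
ignored, and the per-configuration match rates are averaged with the
observed configuration frequencies. Configurations in which a
*required* species is missing can never yield a counted site, so they
contribute probability zero (a strict mode raises instead); keeping
those sites in `N_var` with rate zero preserves the null mean.

A crucial calibration detail: the per-trial probability is
*conditional on the simulated site being testable*. The observed count
is binomial over `N_var` tested variable amino-acid sites, but a
random single mutation usually is not such a site — it may fall on a
within-species branch (the consensus turns it into missing data, not
variation) or produce no species-level contrast. The estimator
therefore collapses each simulated pattern to species consensus (a
split species is missing) and reports, per missingness configuration,
Pr[clean focal/non-focal split | every non-ignored species fixed and
both states present]. The conditioning raises the per-site probability
several-fold over the raw per-simulated-gene rate, and without it the
excess test rejects a true null most of the time; with it, the
end-to-end type-I error sits at the nominal level. The raw,
unconditional rate (the description one would read off the source
procedure) remains available via `conditional=False`. Both versions
are validated against brute-force oracles that place mutations
exhaustively on stored genealogies. Observed counts for the
calibration test are site-level: sites are the binomial sampling unit,
whereas gene-level counts (the headline unit of the source analyses,
also reported) are deflated by the clustering of qualifying sites
within a gene that shares one genealogy.

The excess P value is either the fraction of simulated datasets of
`N_var` single-change genes with at least the observed count
(dataset-grouping, the source procedure) or the equivalent binomial
tail Pr[X >= observed], X ~ Binomial(N_var, p-hat); the two agree
within Monte-Carlo error and both are labelled in the output. The
default null size is 10^6 simulated genes (the source analyses used
10^8; at 10^6 the Monte-Carlo SE of p-hat is reported alongside it and
is negligible relative to the effects of interest at desk scale).

## Data-preparation filters

Occupancy filtering removes alignment columns with <10% occupancy
(ambiguity codes and N count as occupied, gaps do not), then sequences
with >50% gaps, then discards alignments with <4 surviving species —
in that declared order. Because a removed sequence can in principle
strand a column just below the occupancy threshold, the single-pass
order, not a fixpoint iteration, is the contract; on realistic data
the operation is idempotent and the tests assert as much. Gene trees
whose present outgroup individuals are not an exclusive clade are
discarded (zero or one outgroup tips pass vacuously). Per transcript
cluster, the tree with the most nodes of SH-like support strictly
greater than 10 is kept, ties broken by lexicographic gene id; trees
with no such node are dropped. Supermatrix concatenation fills absent
genes with N and emits 1-based inclusive partition ranges. 4-fold
degenerate extraction keeps a third codon position only if every
non-missing species' codon prefix lies in a 4-fold family of the
translation table (missing species are ignored; a stricter
contamination-free convention than checking one reference species).

## Evolutionary distinctness and EDGE

ED uses fair-proportion apportionment — each branch's length (My)
divided equally among its descendant tips — which conserves total tree
length exactly and reproduces the internal consistency of the
published scores; equal-splits is available behind a flag (it divides
the carried value by the out-degree at every split and does not
conserve total length). EDGE = ln(1+ED) + GE ln 2 with GE in {0..4}
from the IUCN category; data-deficient species get ED but an undefined
(not zero) EDGE.

## Synthetic data

The generator's defaults are the study conditions: a nine-taxon
tuna-like radiation (outgroup plus eight ingroup species; the
three-species bluefin-like focal group is paraphyletic because a
warm-water-like clade nests between its members), internal branches of
0.5–1 SNAQ units, putting major quartet CFs around 0.5–0.65 — the
heavy-ILS regime the analyses assume. Two chromosomes per species are
simulated and collapsed to a fixed-nucleotide species consensus
(within-species polymorphism becomes missing data, as in genotype
calls), so the data-generating process matches the diploid null
exactly. Background evolution places Poisson single-nucleotide
mutations (rate 0.01 per site per ms unit) on gene-tree branches over
a random stop-free ancestral CDS of 80 codons per gene; codons that
acquire stops are re-drawn locally, or reverted if a stop persists.
Missingness masks whole codons per taxon at rate 0.02. The default
gene count (400) was set once so that the ILS-null expectation of
shared substitutions is about 5 — a desk-scale rendering of the source
regime, where observed counts sit against a non-trivial null mean —
which keeps the discrete null distribution resolvable around the 5%
critical region.

What the generator does *not* emulate: assembly and mapping artifacts,
expression-dependent coverage, indels/frame errors, codon-model
selection dynamics (background mutations are nucleotide-uniform), gene
flow or hybridization (the null is a tree), and recombination within
genes. Passing tests therefore demonstrate correctness of the
statistical machinery under its stated model, not robustness to those
real-data complications.

## Numerical choices and edge cases

- Branch lengths absent in newick load as 0 with a warning (so
  topology-only gene trees can be CF-counted); `inf` is a legal length
  meaning forced monophyly.
- Support values are internal-node labels; nodes without supports are
  collapsed only on request.
- Root-to-tip variance is the population (ddof=0) variance.
- Chi-squared continuity floor 1e-8 on expected CFs.
- Tie-breaks everywhere are lexicographic; all stochastic stages take
  explicit seeds and fixed seeds give byte-identical outputs.
- Acceptance-scale problem sizes: 10^5 gene trees per closed-form
  comparison, 100 x 10,000 trees for the star-tree clade-frequency
  check, 2 x 10^5 null patterns shared across 200 null datasets for the
  type-I check — sizes chosen to put Monte-Carlo error well inside the
  tolerances being asserted.

## Known limitations

- The clade-frequency "clustering" definition (exclusive clade among
  species-level lineages) is one of several defensible readings of a
  sister relationship in a tree of individuals; alternates can be
  composed from `is_exclusive_clade`.
- The chi-squared CF comparison follows the description of the test as
  a Pearson comparison of observed and expected CFs; it is not the
  full published TICR outlier procedure.
- Quartet non-independence makes the pooled CF test approximate; the
  report carries this caveat.
- The dataset-grouping P value resolves no finer than 1/n_datasets;
  the binomial tail is exact given p-hat but inherits its Monte-Carlo
  error.
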