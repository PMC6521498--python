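# Methods

## The problem

A germplasm collection of a clonally propagated crop holds accessions
from several diverged sub-specific races plus hybrid cultivars.  The
package implements a two-stage characterization: (1) discover
polymorphic loci cheaply by sequencing one pooled DNA sample per race
and reading allele frequencies off read proportions; (2) genotype a
small assay panel on all accessions and infer the collection's genetic
structure — who is pure, who is admixed, which accessions form a
trustworthy reference core for each race, and who is related to whom.

## Pool calling

A pool's status at a locus is called from read depth `d` and alt-read
proportion `x`.  Depth bounds (defaults 6 and 200) bracket the usable
part of the coverage distribution: below, allele frequencies are
unreadable; above, collapsed repeats and mapping artifacts inflate
false positives.  Within bounds the call is `AB` when
`het_lower ≤ x ≤ het_upper` (defaults 0.2/0.8) with at least
`min_alt_reads` (default 2) supporting reads, `BB` above the band, `AA`
below.  The band and read minimum follow common pooled variant-caller
behavior; downstream accounting only uses the AB / non-AB split, so the
exact band matters less than its symmetry.

Loci are then classified by cross-pool profile: the category is the
number of `AB` pools; loci with no `AB` pool but opposite homozygous
calls still segregate in the collection ("None" category).  `NA` pools
do not contribute to the category (an `NA`-vs-`AB` ambiguity the input
format cannot resolve; the summary records the convention).  Loci with
no evidence of two alleles are excluded and counted.  Category and
profile frequencies are tested against a uniform null with Pearson's
goodness-of-fit χ² (df = cells − 1).

Validation cross-tabulates predicted pool calls against "actual" calls
derived from the genotyped panel: a pool is actually polymorphic when
at least one genotyped member is heterozygous (a `require_two_genotypes`
flag switches to the two-distinct-genotypes rule); predicted `NA`
counts as not-predicted-polymorphic.  Sensitivity is the true-positive
rate over actually polymorphic loci; AB precision is the share of
predicted-`AB` loci that are actually polymorphic; the allele-frequency
correlation is Pearson's r over (locus, pool) cells defined on both
sides.

## Marker QC

PIC = 1 − Σ pᵢ² ranks marker informativeness.  LD between two biallelic
loci is r² = D²/(p₁p₂q₁q₂), D = p₁₁p₂₂ − p₁₂p₂₁, on haplotype
proportions.  (The same expression without squaring D is sometimes
printed as "r²" although it is algebraically r; this package computes
the squared version so the 0.7 pruning threshold lives on the r² scale,
with `threshold_on_r` to switch.)  Panel genotypes are unphased, so
haplotype proportions come from an EM step: all genotype pairs except
double heterozygotes resolve their two gametes by counting; the double
heterozygote splits between coupling and repulsion phase with weights
re-estimated each iteration.  A Burrows composite estimate (squared
genotype correlation) is available as `ld_method="composite"`.

The filter chain applies, in order: loci with > 10% no-calls, samples
with > 30% no-calls (order swappable via `samples_first`; the source
recipe states both in one sentence), loci with PIC < 0.1, then LD
pruning of pairs with r² > 0.7 keeping the higher-PIC member (tie: the
later locus is dropped).  All thresholds are strict inequalities — a
locus with exactly 10% no-calls survives.  The report accounts for
every locus and sample exactly once.

## Distances, trees, bootstrap

For alt dosages gᵢ, gⱼ ∈ {0,1,2} the shared-allele count at a locus is
2 − |gᵢ − gⱼ|, so D = 1 − PSA = Σ|gᵢ − gⱼ| / 2L over the pair's
co-called loci (pairwise-complete; per-pair L recorded).  Ward
clustering uses the standard Ward.D2 criterion (`squared=False` gives
the unsquared variant).  Bootstrap support resamples L loci with
replacement, rebuilds distances and the tree, and counts replicates
containing each original bipartition as a leaf-set split (topological
containment only).  Replicates are computed in a canonical accession
order so supports are invariant to input row order despite the frequent
distance ties of discrete genotype data.  Supports are reported out of
`n_boot` (1000 by convention) and flagged for display above 650.

## Admixture model

The standard unlinked-locus admixture model: accession i has ancestry
qᵢ ~ Dirichlet(α) over K populations; population k has alt-allele
frequency p_kl ~ Beta(λ, λ) at locus l; each of the two allele copies of
a genotype draws a source population from qᵢ, then its allele from that
population's frequency.  A Gibbs sampler updates allele-copy origins z,
then P | z, then Q | z; α is inferred by a Metropolis random walk with a
uniform prior on (0, 10] (fix it with `infer_alpha=False`).  Inferring α
matters: with α pinned at 1.0 the posterior mean Q of a truly pure
accession is shrunk to ≈ 0.90; with α inferred (it settles near
0.05–0.2 on pure-race data) recovery reaches ≈ 0.99.  The reported Q is
the posterior mean of post-burn-in, thinned sweeps; the log-likelihood
trace uses the binomial mixture likelihood of genotypes given (Q, P).

Runs are label-aligned by exhaustive column permutation against the
first run (K! ≤ 8 enforced; `greedy` beyond) and averaged — sufficient
at the K ≈ 3 scale this package targets; full pairwise alignment schemes
matter only for larger K.  ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K)) over
run-mean log-likelihoods selects K; a K with zero spread across runs has
ΔK undefined and is flagged.  Supervised classification pins each core
accession's ancestry to its population indicator (no migration-rate
machinery — the cores only serve to anchor population allele
frequencies) and samples the rest.

Reference-scale MCMC settings are 5000 burn-in / 50,000 sweeps / 20
runs; the defaults here (500 / 2000 / 5) are desk-scale.  Sampler
quality is asserted by truth recovery on simulations, not by iteration
count.

## F_ST, core sets, classification

Per locus, H_T = 2p̄(1 − p̄) on the pooled (call-count-weighted) allele
frequency and H_S = Σₖ (nₖ/n)·2pₖ(1 − pₖ); F_ST = (H_T − H_S)/H_T, with
monomorphic loci excluded and the panel summarized by the median.  Note
this diversity-partition quantity is *not* an unbiased estimate of a
drift parameter when K is small: under Balding–Nichols divergence F its
expectation is ≈ F(1 − 1/K)/(1 − F/K) (≈ 0.22 for F = 0.3, K = 3).  The
synthetic module therefore ships `divergence_fst`, a Weir–Cockerham-
style ratio-of-sums moment estimator that is nearly unbiased for F and
is the right tool for recovery checks; the diversity partition is the
right tool for comparing classification methods on equal footing.

Core sets intersect three classifications: botanical label, dendrogram
cluster (k = 3 cut; the tree cut level is the one genuinely open choice
and is documented as such), and admixture component (clusters and
components are mapped to races by majority botanical label; the
admixture label additionally requires Q > 0.85).  Accessions where all
three agree are the core of their race.  Supervised ancestries then
classify everyone: components ≥ 0.15 (the complement of the 0.85 purity
threshold; configurable) are "present" — one present component is a
pure-race accession, two a bi-racial hybrid, three a complex hybrid.

## PCA and kinship

PCA is fitted only on the cores: dosages standardized by core allele
frequencies, (g − 2p)/√(2p(1 − p)), missing cells imputed to the mean,
columns centered, SVD.  Loci monomorphic within cores are dropped.  All
accessions are projected with the *core* frequencies and centering onto
the core loadings, so projection is linear, core accessions reproduce
their fitted coordinates exactly, and admixed accessions land between
race clusters rather than distorting the axes.

Kinship is the KING-robust between-family estimator
φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i) + N_Aa(j)) over each pair's co-called
loci.  Duplicated genotypes give φ = 0.5, parent–offspring pairs center
on 0.25, and unrelated accessions from diverged populations go negative
(a feature of the estimator, not a bug).  The relatedness graph
connects pairs with φ ≥ 0.25 by default; the report also annotates the
conventional degree bins (≥ 0.354 duplicate, 0.177–0.354 first degree,
0.0884–0.177 second degree) because a 0.25 cutoff sits inside the
first-degree bin even when described as second-degree relatedness.

## Synthetic germplasm: what it does and does not emulate

The generator states its world once: ancestral allele frequencies
uniform on (0.05, 0.95) (panel-style markers, not random genome
positions); race frequencies Balding–Nichols Beta with drift F
(default 0.3); genotypes by two independent allele draws with per-copy
ancestry (unlinked loci — adequate because the panel is LD-pruned
downstream); pool depth Poisson with mean 33 (optional Gamma
overdispersion via `depth_dispersion`, the squared CV of the per-locus
mean); reads drawn binomially from the pool's true allele frequency
(equal DNA per member); panels sampled uniformly at random, optionally
restricted to discovered loci to mirror how real assay panels are
designed.  The default composition mirrors the motivating collection:
pools of 17 + 10 + 23 race-classified accessions and 50 non-pooled
cultivars/hybrids.

It does **not** emulate: linkage (no map, no within-genome LD beyond
shared ancestry), sequencing or genotyping error, allele-specific
amplification in pools, pedigree structure among cultivars, or a
realistic (discovery-ascertained) allele-frequency spectrum.  The last
limitation is consequential: real discovered loci are heavily enriched
for intermediate frequencies in *all* pools, whereas Balding–Nichols at
F = 0.3 produces a U-shaped race spectrum with many barely polymorphic
loci.  Pool-call sensitivity against genotyped truth is therefore
structurally lower in this synthetic world (≈ 0.6–0.7, with an
infinite-depth ceiling ≈ 0.7) than the 0.77–0.94 observed on real
pooled data.  A green recovery test here certifies the estimators, not
that the generator reproduces real ascertainment.

## Numerical choices

* Genotype missingness sentinel is −1 internally, `NA` in text formats;
  never conflated with homozygous-reference.
* EM for haplotype frequencies starts from the neutral 50/50 phase
  split, tolerance 1e-10, ≤ 200 iterations; deterministic given data.
* Ward tie-breaks follow the linkage implementation's deterministic
  order; bootstrap replicates canonicalize accession order first.
* The sampler clips Q entries at 1e-12 before the α update's log.
* All stochastic code takes explicit seeds; the pipeline derives stage
  seeds from one master seed by fixed offsets.

## Known limitations

* Admixture run averaging aligns to the first run, not a global
  consensus; fine at K ≤ 3, unsafe for large K with multimodal runs.
* The EM LD estimator assumes random mating when splitting double
  heterozygotes; highly selfed material would bias r² slightly.
* Supervised mode has no migration/mis-assignment prior, so a mislabeled
  core accession contaminates its population's allele frequencies.
* The pool-count input format cannot distinguish a pool with no data
  from one filtered by depth bounds; both are `NA` calls.
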