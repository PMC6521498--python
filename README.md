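# germpool

Characterization of a crop germplasm collection from pooled-DNA
sequencing, built around the workflow used for clonally maintained tree
crops such as avocado (*Persea americana*), whose collections mix three
diverged botanical races (Guatemalan, Mexican, West Indian) with hybrid
cultivars of unknown pedigree.

Rather than genotyping every accession up front, the workflow sequences
one pooled DNA sample per race, estimates each pool's allele frequency
from read proportions, and screens for polymorphic loci.  A genotyping
subpanel then validates the pool predictions and feeds the population
genetics: genetic distances and trees, model-based ancestry, core-set
selection, PCA and kinship.

## What the package computes

* **Pool discovery** — per-pool calls at each locus from read depth `d`
  and alternative-allele proportion `x`: `NA` outside the depth bounds
  (default 6 ≤ d ≤ 200), `AB` (polymorphic) for 0.2 ≤ x ≤ 0.8 with ≥ 2
  alt reads, else `AA`/`BB`; cross-pool polymorphism profiles (e.g.
  `pG-pM-npWI`), χ² tests of profile frequencies, and validation of pool
  predictions against individual genotypes (sensitivity, AB precision,
  allele-frequency correlation).
* **Marker QC** — PIC = 1 − Σᵢ pᵢ²; two-locus LD r² = D²/(p₁p₂q₁q₂)
  with haplotype frequencies EM-estimated from unphased genotypes; the
  filter chain: loci > 10% no-calls, samples > 30% no-calls, PIC < 0.1,
  and one member of each pair with r² > 0.7.
* **Relationships** — distance D = 1 − PSA with
  PSA = Σᵢ PSᵢ / 2L (shared alleles counted with multiplicity), Ward
  dendrograms, and locus-bootstrap bipartition supports (out of 1000 by
  convention; supports > 650 flagged for display).
* **Ancestry** — a Gibbs sampler for the admixture model (population
  allele frequencies `P`, per-accession ancestries `Q` with an inferred
  Dirichlet concentration α), Evanno ΔK = |L(K+1) − 2L(K) + L(K−1)|/sd(L(K))
  model choice, label alignment and averaging of independent runs, and a
  supervised mode that pins reference (core) accessions to their
  population.
* **Classification** — F_ST = (H_T − H_S)/H_T per locus with
  sample-size-weighted H_S; consensus core sets where botanical label,
  dendrogram cluster, and admixture assignment (Q > 0.85) agree; and
  pure / bi-racial / tri-racial categories from supervised ancestries.
* **Kinship & PCA** — PCA fitted on cores with frequency-standardized
  genotypes `(g − 2p)/√(2p(1−p))` and projection of all accessions onto
  the core axes; KING-robust kinship
  φ = (N_Aa,Aa − 2·N_AA,aa)/(N_Aa(i) + N_Aa(j)); relatedness graph of
  pairs with φ ≥ 0.25.
* **Synthetic germplasm** — a generator with known truth (Balding–Nichols
  race divergence, per-allele ancestry draws for hybrids, Poisson ~33X
  pooled read sampling, 192-assay panels) so every stage is testable.

## Worked example

```bash
germpool run-all --seed 1 --out-dir out/
```

simulates a 100-accession collection (17 Guatemalan + 10 Mexican + 23
West Indian pooled accessions plus 50 non-pooled cultivars/hybrids,
1,000 loci at drift F = 0.3, 33X pools), then runs every stage.  From
`out/report.json` of that run:

* 804 of 1,000 loci segregate in the pools: 120 polymorphic in all
  three pools, 295 in two, 356 in one, 33 in none (both alleles present
  only across pools); the three-pool-category χ² against uniformity is
  116.8 (df = 2, p < 0.001).
* Pool-call validation on a 192-locus panel drawn from the discovered
  loci: sensitivity 0.63 / 0.65 / 0.68 (G/M/WI), AB precision 1.00, and
  r = 0.98 between pool allele proportions and genotype-derived
  frequencies.
* The marker filter keeps 191 of 192 panel loci; Evanno ΔK peaks at
  K = 3 (ΔK = 878 vs 172 at K = 2); all 50 pooled accessions form
  consensus cores (17/10/23), median core F_ST 0.20.
* Supervised classification recovers 62 pure-race accessions and the
  simulated 12 + 9 + 8 bi-racial and 9 complex hybrids; the first two
  PCs carry 24% and 16% of core variance; no kinship edge reaches
  φ ≥ 0.25 (the simulated accessions are unrelated).

Each stage is also available as its own subcommand (`simulate`,
`discover`, `validate`, `filter`, `tree`, `admix`, `kinship`) operating
on the TSV/CSV interchange formats documented in `germpool.io`.

## Acceptance script

```bash
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

re-runs the full pipeline from scratch on a seeded synthetic collection
(all randomness derives from `--seed`) and writes its result JSON;
intermediate tables land under `scratch/`.

See `docs/methods.md` for the models, assumptions, parameter defaults,
and known limitations.
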