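"""Marker panel quality control: missingness, PIC, and LD pruning.

The filter chain reproduces a standard panel-cleaning recipe for a
biallelic genotyping panel:

1. drop loci with > 10% no-calls;
2. drop samples with > 30% no-calls;
3. drop low-information loci with PIC < 0.1;
4. prune linked locus pairs with r² > 0.7, keeping the higher-PIC member.

PIC (polymorphism information content) is ``1 - Σ p_i²`` over allele
proportions.  LD is quantified as ``r² = D² / (p₁ p₂ q₁ q₂)`` with
``D = p₁₁ p₂₂ − p₁₂ p₂₁`` on haplotype proportions; since panel genotypes
are unphased, haplotype proportions are estimated by EM over the
double-heterozygote ambiguity (a composite-LD alternative is exposed).
Note the quantity ``D / sqrt(p₁ p₂ q₁ q₂)`` sometimes printed as "r²" is
algebraically the correlation r; the 0.7 threshold here applies on the
squared (r²) scale, with a flag to threshold |r| instead.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from germpool.io import MISSING, GenotypeMatrix


def compute_pic(freqs: np.ndarray) -> float | np.ndarray:
    """PIC = 1 - Σ p_i² for one locus (1-D) or many (2-D, loci x alleles)."""
    p = np.asarray(freqs, dtype=float)
    sums = p.sum(axis=-1)
    if np.abs(sums - 1.0).max() > 1e-9:
        raise ValueError("allele proportions must sum to 1")
    pic = 1.0 - (p**2).sum(axis=-1)
    return float(pic) if pic.ndim == 0 else pic


def pic_from_genotypes(genos: GenotypeMatrix) -> np.ndarray:
    """Per-locus PIC from alt-allele frequencies (NaN where no calls)."""
    p = genos.alt_allele_frequency()
    return 1.0 - (p**2 + (1.0 - p) ** 2)


@dataclass
class HaplotypePairFrequencies:
    """Two-locus haplotype proportions with their allele margins."""

    p11: float
    p12: float
    p21: float
    p22: float

    def __post_init__(self) -> None:
        hap = np.array([self.p11, self.p12, self.p21, self.p22])
        if (hap < -1e-9).any() or abs(hap.sum() - 1.0) > 1e-6:
            raise ValueError("haplotype proportions must be non-negative and sum to 1")

    @property
    def p1(self) -> float:
        return self.p11 + self.p12

    @property
    def p2(self) -> float:
        return self.p21 + self.p22

    @property
    def q1(self) -> float:
        return self.p11 + self.p21

    @property
    def q2(self) -> float:
        return self.p12 + self.p22


def compute_ld(hap: HaplotypePairFrequencies) -> float:
    """Squared LD correlation r² = D²/(p₁p₂q₁q₂); NaN if a locus is fixed."""
    D = hap.p11 * hap.p22 - hap.p12 * hap.p21
    denom = hap.p1 * hap.p2 * hap.q1 * hap.q2
    if denom <= 0:
        return float("nan")
    return float(D * D / denom)


def estimate_haplotype_frequencies(
    g1: np.ndarray,
    g2: np.ndarray,
    max_iter: int = 200,
    tol: float = 1e-10,
) -> HaplotypePairFrequencies:
    """EM estimate of two-locus haplotype proportions from unphased calls.

    Genotypes are alt dosages {0,1,2} with :data:`MISSING` sentinels; only
    accessions called at both loci contribute.  All genotype combinations
    except the double heterozygote resolve haplotypes by counting; the
    double heterozygote splits its two haplotypes between coupling
    (ref-ref / alt-alt) and repulsion (ref-alt / alt-ref) phase with
    probabilities re-estimated each EM step.  Deterministic given data.
    """
    g1 = np.asarray(g1)
    g2 = np.asarray(g2)
    both = (g1 != MISSING) & (g2 != MISSING)
    a, b = g1[both].astype(int), g2[both].astype(int)
    if a.size < 2:
        raise ValueError("need >= 2 accessions called at both loci")

    # haplotype order: (ref,ref)=11, (ref,alt)=12, (alt,ref)=21, (alt,alt)=22
    counts = np.zeros(4)
    n_dhet = 0
    alleles = {0: (0, 0), 1: (0, 1), 2: (1, 1)}
    for x, y in zip(a, b):
        if x == 1 and y == 1:
            n_dhet += 1  # phase ambiguous: coupling vs repulsion
            continue
        # at most one locus heterozygous -> the two gametes are determined
        ga, gb = alleles[x], alleles[y]
        for ha, hb in ((ga[0], gb[0]), (ga[1], gb[1])):
            counts[2 * ha + hb] += 1

    total = 2.0 * a.size
    hap = (counts + 0.5 * n_dhet * np.array([1, 1, 1, 1])) / total  # neutral start
    for _ in range(max_iter):
        p11, p12, p21, p22 = hap
        coupling = p11 * p22
        repulsion = p12 * p21
        w = coupling / (coupling + repulsion) if (coupling + repulsion) > 0 else 0.5
        new = counts + n_dhet * np.array([w, 1 - w, 1 - w, w])
        new = new / total
        if np.abs(new - hap).max() < tol:
            hap = new
            break
        hap = new
    return HaplotypePairFrequencies(*[float(h) for h in hap])


def composite_ld(g1: np.ndarray, g2: np.ndarray) -> float:
    """Burrows composite r² directly from unphased dosages (no EM)."""
    g1 = np.asarray(g1, dtype=float)
    g2 = np.asarray(g2, dtype=float)
    both = (g1 != MISSING) & (g2 != MISSING)
    x, y = g1[both], g2[both]
    if x.size < 2 or np.std(x) == 0 or np.std(y) == 0:
        return float("nan")
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r)


def ld_r2_matrix(genos: GenotypeMatrix, method: str = "em") -> np.ndarray:
    """Pairwise r² over all locus pairs (NaN where undefined)."""
    L = genos.n_loci
    out = np.full((L, L), np.nan)
    np.fill_diagonal(out, 1.0)
    for i in range(L):
        gi = genos.geno[:, i]
        for j in range(i + 1, L):
            gj = genos.geno[:, j]
            if method == "em":
                try:
                    out[i, j] = compute_ld(estimate_haplotype_frequencies(gi, gj))
                except ValueError:
                    out[i, j] = np.nan
            else:
                out[i, j] = composite_ld(gi, gj)
            out[j, i] = out[i, j]
    return out


@dataclass
class FilterReport:
    """Accounting of every locus and sample through the filter chain."""

    input_loci: int
    input_samples: int
    removed_missingness_loci: list[str] = field(default_factory=list)
    removed_missingness_samples: list[str] = field(default_factory=list)
    removed_pic_loci: list[str] = field(default_factory=list)
    removed_ld_loci: list[str] = field(default_factory=list)
    surviving_loci: list[str] = field(default_factory=list)
    surviving_samples: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "input": {"loci": self.input_loci, "samples": self.input_samples},
            "removed": {
                "missingness_loci": self.removed_missingness_loci,
                "missingness_samples": self.removed_missingness_samples,
                "pic_loci": self.removed_pic_loci,
                "ld_loci": self.removed_ld_loci,
            },
            "surviving": {
                "loci": len(self.surviving_loci),
                "samples": len(self.surviving_samples),
            },
        }


def filter_markers(
    genos: GenotypeMatrix,
    locus_na_max: float = 0.10,
    sample_na_max: float = 0.30,
    pic_min: float = 0.1,
    ld_r2_max: float = 0.7,
    ld_method: str = "em",
    samples_first: bool = False,
    threshold_on_r: bool = False,
) -> tuple[GenotypeMatrix, FilterReport]:
    """Apply the missingness / PIC / LD filter chain in order.

    Thresholds are strict inequalities (a locus at exactly 10% no-calls
    survives).  For a linked pair exceeding the LD threshold the
    lower-PIC member is dropped (tie: the later locus), maximizing panel
    informativeness.  ``samples_first`` swaps steps 1 and 2.
    """
    if genos.geno.size == 0:
        raise ValueError("empty genotype matrix")
    report = FilterReport(input_loci=genos.n_loci, input_samples=genos.n_accessions)
    current = genos

    def drop_loci(gm: GenotypeMatrix) -> GenotypeMatrix:
        na_frac = (~gm.called_mask()).mean(axis=0)
        keep = na_frac <= locus_na_max
        report.removed_missingness_loci.extend(
            gm.loci[i].name for i in np.flatnonzero(~keep)
        )
        return gm.subset_loci(np.flatnonzero(keep))

    def drop_samples(gm: GenotypeMatrix) -> GenotypeMatrix:
        na_frac = (~gm.called_mask()).mean(axis=1)
        keep = na_frac <= sample_na_max
        report.removed_missingness_samples.extend(
            gm.accessions[i] for i in np.flatnonzero(~keep)
        )
        return gm.subset_accessions(np.flatnonzero(keep))

    current = drop_samples(current) if samples_first else drop_loci(current)
    current = drop_loci(current) if samples_first else drop_samples(current)

    pic = pic_from_genotypes(current)
    keep = np.nan_to_num(pic, nan=-1.0) >= pic_min
    report.removed_pic_loci.extend(current.loci[i].name for i in np.flatnonzero(~keep))
    current = current.subset_loci(np.flatnonzero(keep))

    if current.n_loci > 0:
        r2 = ld_r2_matrix(current, method=ld_method)
        stat = np.sqrt(np.abs(r2)) if threshold_on_r else r2
        pic_now = pic_from_genotypes(current)
        dropped = np.zeros(current.n_loci, dtype=bool)
        for i in range(current.n_loci):
            for j in range(i + 1, current.n_loci):
                if dropped[i] or dropped[j]:
                    continue
                if np.isnan(stat[i, j]) or stat[i, j] <= ld_r2_max:
                    continue
                pi, pj = pic_now[i], pic_now[j]
                victim = j if (pj < pi or np.isclose(pi, pj)) else i
                dropped[victim] = True
        report.removed_ld_loci.extend(current.loci[i].name for i in np.flatnonzero(dropped))
        current = current.subset_loci(np.flatnonzero(~dropped))

    if current.n_loci == 0 or current.n_accessions == 0:
        raise ValueError("no markers survive filtering")
    report.surviving_loci = current.locus_names()
    report.surviving_samples = list(current.accessions)
    return current, report
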