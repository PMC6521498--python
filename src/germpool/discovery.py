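"""Pool polymorphism calling, profile classification, and validation.

A sequenced DNA pool is called at each locus from its read depth and
alternative-allele read proportion: loci outside the depth screening
bounds are NA; within bounds, an intermediate alt proportion marks the
pool as polymorphic (AB), extreme proportions as fixed (AA/BB).  Loci are
then classified by their cross-pool polymorphism profile (how many and
which pools are AB), profile frequencies are tested against a uniform
null, and pool predictions are validated against individual genotyping of
the pools' member accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from germpool.io import (
    MISSING,
    AccessionMetadata,
    CALL_TO_CODE,
    CODE_TO_CALL,
    GenotypeMatrix,
    PoolCallTable,
    PoolCountTable,
)

AA, AB, BB, NA = CALL_TO_CODE["AA"], CALL_TO_CODE["AB"], CALL_TO_CODE["BB"], CALL_TO_CODE["NA"]


@dataclass
class PoolCallConfig:
    """Thresholds for calling a pool's status at a locus.

    The depth bounds (6–200 reads) bracket the peak of the coverage
    distribution; very high coverage inflates false positives.  The
    heterozygous band [het_lower, het_upper] on the alt read proportion
    and the minimum alt-read count are VarScan-like defaults — downstream
    accounting depends only on the AB / non-AB split.
    """

    min_depth: int = 6
    max_depth: int = 200
    het_lower: float = 0.2
    het_upper: float = 0.8
    min_alt_reads: int = 2

    def __post_init__(self) -> None:
        if not (0.0 < self.het_lower < self.het_upper < 1.0):
            raise ValueError("need 0 < het_lower < het_upper < 1")
        if self.min_depth > self.max_depth:
            raise ValueError("min_depth must be <= max_depth")


def call_pool_status(depth: int, alt_prop: float, cfg: PoolCallConfig | None = None) -> str:
    """Call one pool at one locus: AA / AB / BB / NA.

    NA outside the depth bounds; AB when the alt proportion falls in the
    heterozygous band with enough supporting alt reads; otherwise the
    fixed homozygous call on the nearer side.
    """
    cfg = cfg or PoolCallConfig()
    if depth < cfg.min_depth or depth > cfg.max_depth:
        return "NA"
    alt_reads = alt_prop * depth
    if cfg.het_lower <= alt_prop <= cfg.het_upper and alt_reads >= cfg.min_alt_reads - 1e-9:
        return "AB"
    if alt_prop > cfg.het_upper:
        return "BB"
    return "AA"


def call_pool_table(counts: PoolCountTable, cfg: PoolCallConfig | None = None) -> PoolCallTable:
    """Vectorized :func:`call_pool_status` over a full count table."""
    cfg = cfg or PoolCallConfig()
    depth = counts.depth
    prop = counts.alt_prop
    call = np.full(depth.shape, NA, dtype=np.int8)
    in_bounds = (depth >= cfg.min_depth) & (depth <= cfg.max_depth) & ~np.isnan(prop)
    p = np.nan_to_num(prop)
    alt_reads = p * depth
    het = in_bounds & (p >= cfg.het_lower) & (p <= cfg.het_upper) & (alt_reads >= cfg.min_alt_reads - 1e-9)
    bb = in_bounds & (p > cfg.het_upper) & ~het
    aa = in_bounds & ~het & ~bb
    call[het], call[bb], call[aa] = AB, BB, AA
    return PoolCallTable(loci=list(counts.loci), pool_names=list(counts.pool_names), call=call)


@dataclass
class ProfileSummary:
    """Tally of loci by cross-pool polymorphism profile.

    ``category_counts`` keys loci by the number of AB pools (3, 2, 1, 0);
    category 0 ("None") holds loci with no polymorphic pool but opposite
    homozygous calls across pools, so both alleles are still present in
    the collection.  ``profile_counts`` breaks each category into named
    profiles such as ``pG-pM-npWI`` (polymorphic in the Guatemalan and
    Mexican pools, not in the West Indian).  Loci with no evidence of both
    alleles (or NA everywhere) are excluded and counted separately.
    """

    category_counts: dict[int, int]
    profile_counts: dict[str, int]
    total: int
    n_excluded: int = 0
    na_pool_note: str = (
        "category counts AB pools only; NA pools do not contribute to the category"
    )

    @property
    def percentages(self) -> dict[int, float]:
        """Category percentages of the segregating-locus total."""
        if self.total == 0:
            return {k: float("nan") for k in self.category_counts}
        return {k: 100.0 * v / self.total for k, v in self.category_counts.items()}

    @classmethod
    def from_counts(cls, category_counts: dict[int, int]) -> "ProfileSummary":
        """Build a summary from externally tallied category counts."""
        total = sum(category_counts.values())
        return cls(category_counts=dict(category_counts), profile_counts={}, total=total)

    def to_dict(self) -> dict:
        return {
            "category_counts": {str(k): v for k, v in self.category_counts.items()},
            "percentages": {str(k): round(v, 4) for k, v in self.percentages.items()},
            "profile_counts": dict(self.profile_counts),
            "total": self.total,
            "n_excluded": self.n_excluded,
            "note": self.na_pool_note,
        }


def _profile_label(pool_names: list[str], is_poly: np.ndarray) -> str:
    def short(name: str) -> str:
        caps = "".join(ch for ch in name if ch.isupper())
        return caps if caps else name[:2].title()

    return "-".join(
        ("p" if poly else "np") + short(name) for name, poly in zip(pool_names, is_poly)
    )


def classify_profiles(calls: PoolCallTable) -> ProfileSummary:
    """Assign each segregating locus to a polymorphism profile.

    A locus segregates in the collection when at least one pool is AB, or
    two pools carry opposite homozygous calls.  Each such locus lands in
    exactly one category (its count of AB pools); all-NA or
    single-allele loci are excluded.
    """
    if calls.call.size == 0:
        raise ValueError("empty call table")
    call = calls.call
    is_ab = call == AB
    has_aa = (call == AA).any(axis=1)
    has_bb = (call == BB).any(axis=1)
    n_ab = is_ab.sum(axis=1)
    segregating = (n_ab > 0) | (has_aa & has_bb)

    category_counts = {k: int(((n_ab == k) & segregating).sum()) for k in (3, 2, 1, 0)}
    profile_counts: dict[str, int] = {}
    seg_idx = np.flatnonzero(segregating)
    for i in seg_idx:
        label = _profile_label(calls.pool_names, is_ab[i])
        profile_counts[label] = profile_counts.get(label, 0) + 1
    return ProfileSummary(
        category_counts=category_counts,
        profile_counts=profile_counts,
        total=int(segregating.sum()),
        n_excluded=int((~segregating).sum()),
    )


def profile_chi_square(counts: list[int] | np.ndarray) -> tuple[float, int, float]:
    """Pearson goodness-of-fit of profile counts against a uniform null.

    Returns ``(statistic, df, p)`` with df = cells - 1.
    """
    counts = np.asarray(counts, dtype=float)
    if counts.size < 2:
        raise ValueError("need at least 2 cells")
    expected = np.full(counts.size, counts.sum() / counts.size)
    if (expected == 0).any():
        raise ValueError("zero expected count")
    stat, p = stats.chisquare(counts, expected)
    return float(stat), counts.size - 1, float(p)


CALL_ORDER = ["AA", "AB", "BB", "NA"]


@dataclass
class ValidationReport:
    """Pool-call validation against individual genotyping of pool members.

    ``contingency[pool]`` is a 4x4 DataFrame, rows = actual call derived
    from member genotypes, columns = predicted pool call, both over
    {AA, AB, BB, NA}.  Sensitivity is the true-positive rate of
    polymorphism prediction; precision_ab is the fraction of predicted-AB
    loci that are actually polymorphic (the AB-column true positive
    percentage).
    """

    contingency: dict[str, pd.DataFrame]
    sensitivity: dict[str, float]
    precision_ab: dict[str, float]
    allele_freq_correlation: float

    def to_dict(self) -> dict:
        return {
            "contingency": {
                pool: {r: df.loc[r].to_dict() for r in df.index}
                for pool, df in self.contingency.items()
            },
            "sensitivity": self.sensitivity,
            "precision_ab": self.precision_ab,
            "allele_freq_correlation": self.allele_freq_correlation,
        }


def validation_metrics(contingency: pd.DataFrame) -> tuple[float, float]:
    """Sensitivity and AB-precision from one actual-vs-predicted cross-tab.

    Sensitivity = predicted-AB ∩ actual-AB over all actual-AB loci
    (predicted NA counts as not-predicted-polymorphic).  Precision =
    predicted-AB ∩ actual-AB over all predicted-AB loci.
    """
    tp = float(contingency.loc["AB", "AB"])
    actual_ab = float(contingency.loc["AB"].sum())
    predicted_ab = float(contingency["AB"].sum())
    sensitivity = tp / actual_ab if actual_ab > 0 else float("nan")
    precision = tp / predicted_ab if predicted_ab > 0 else float("nan")
    return sensitivity, precision


def _actual_pool_call(sub: np.ndarray, require_two_genotypes: bool = False) -> int:
    """Actual polymorphism status of a pool from its members' genotypes."""
    called = sub[sub != MISSING]
    if called.size == 0:
        return NA
    if require_two_genotypes:
        poly = np.unique(called).size > 1
    else:
        poly = (called == 1).any()
    if poly:
        return AB
    # nominally fixed pool; majority allele decides the (rare) case of
    # opposite homozygotes with no heterozygote
    return AA if called.mean() < 1.0 else BB


def validate_against_genotypes(
    calls: PoolCallTable,
    counts: PoolCountTable | None,
    genos: GenotypeMatrix,
    metadata: AccessionMetadata,
    require_two_genotypes: bool = False,
) -> ValidationReport:
    """Cross-tabulate predicted pool calls against genotyped reality.

    The actual call of a pool at a locus is AB if any genotyped member is
    heterozygous (or, with ``require_two_genotypes``, if two distinct
    genotypes occur), else the fixed homozygous call, else NA when all
    members are missing.  The allele-frequency correlation is the Pearson
    r between pool alt read proportions and genotype-derived alt-allele
    frequencies over all (locus, pool) cells where both are defined.
    """
    panel_names = {l.name: j for j, l in enumerate(genos.loci)}
    call_idx = [i for i, l in enumerate(calls.loci) if l.name in panel_names]
    if not call_idx:
        raise ValueError("no overlapping loci between pool calls and genotypes")
    geno_idx = [panel_names[calls.loci[i].name] for i in call_idx]

    acc_index = {a: i for i, a in enumerate(genos.accessions)}
    contingency: dict[str, pd.DataFrame] = {}
    sensitivity: dict[str, float] = {}
    precision: dict[str, float] = {}
    xs: list[float] = []
    ys: list[float] = []
    for j, pool in enumerate(calls.pool_names):
        members = [acc_index[m] for m in metadata.pool_members(pool) if m in acc_index]
        table = pd.DataFrame(0, index=CALL_ORDER, columns=CALL_ORDER)
        for ci, gi in zip(call_idx, geno_idx):
            predicted = CODE_TO_CALL[int(calls.call[ci, j])]
            sub = genos.geno[members, gi]
            actual = CODE_TO_CALL[_actual_pool_call(sub, require_two_genotypes)]
            table.loc[actual, predicted] += 1
            if counts is not None:
                prop = counts.alt_prop[ci, j]
                called = sub[sub != MISSING]
                if not np.isnan(prop) and called.size > 0:
                    xs.append(float(prop))
                    ys.append(float(called.sum() / (2.0 * called.size)))
        contingency[pool] = table
        sens, prec = validation_metrics(table)
        sensitivity[pool] = sens
        precision[pool] = prec

    if len(xs) >= 2 and np.std(xs) > 0 and np.std(ys) > 0:
        r = float(stats.pearsonr(xs, ys).statistic)
    else:
        r = float("nan")
    return ValidationReport(
        contingency=contingency,
        sensitivity=sensitivity,
        precision_ab=precision,
        allele_freq_correlation=r,
    )
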