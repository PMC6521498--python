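"""Synthetic germplasm collections with known truth.

The generator emulates the statistical structure the analysis pipeline
assumes: a collection of accessions drawn from a small number of diverged
races plus race hybrids, pooled sequencing of each race at moderate
expected depth, and an assay subpanel of the discovered loci.

Model
-----
* Ancestral allele frequencies per locus: uniform on (0.05, 0.95) (keeps
  loci segregating; extreme-rare variants are not informative for a
  genotyping panel).
* Race allele frequencies: Balding–Nichols Beta around the ancestral
  frequency, ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, with ``F`` the per-race
  drift parameter (the expected Wright F_ST of the races).
* Genotypes: two independent allele draws per accession per locus; for an
  admixed accession each allele copy first draws its source race from the
  accession's ancestry vector (unlinked loci).
* Pools: the DNA of a race's accessions mixed in equal amounts; read depth
  per locus is Poisson with mean ``mean_depth`` (optionally Gamma
  overdispersed) and each read's allele is Bernoulli with the pool's true
  allele frequency (the mean genotype dosage over members / 2).
* Panel: a uniform random locus subset without replacement, mimicking
  random selection of assays for validation genotyping.

Defaults mirror the motivating study: 3 races, ~33X expected pool depth,
a 192-assay panel, 100 accessions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from germpool.io import (
    AccessionMetadata,
    GenotypeMatrix,
    Locus,
    PoolCountTable,
    RACES,
)


class ConfigError(ValueError):
    """An invalid simulation configuration."""


#: Default non-pooled material: 50 accessions of mixed/unverified ancestry
#: standing in for a collection's unidentified accessions and cultivars
#: (bi-racial crosses, complex hybrids, and some pure-bred cultivars).
DEFAULT_HYBRIDS: tuple[tuple[tuple[float, ...], int], ...] = (
    ((0.5, 0.5, 0.0), 12),
    ((0.5, 0.0, 0.5), 10),
    ((0.0, 0.5, 0.5), 8),
    ((1 / 3, 1 / 3, 1 / 3), 8),
    ((1.0, 0.0, 0.0), 4),
    ((0.0, 1.0, 0.0), 4),
    ((0.0, 0.0, 1.0), 4),
)


@dataclass
class SimulationConfig:
    """Parameters of the synthetic collection.

    hybrid_specs lists ``(ancestry_proportions, count)`` pairs; each
    proportion vector has one entry per race and sums to 1.
    """

    n_loci: int = 2000
    n_races: int = 3
    fst_divergence: float = 0.3
    race_sizes: Sequence[int] = (17, 10, 23)
    hybrid_specs: Sequence[tuple[Sequence[float], int]] = DEFAULT_HYBRIDS
    mean_depth: float = 33.0
    depth_dispersion: float = 0.0
    panel_size: int = 192
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.fst_divergence < 1.0):
            raise ConfigError(f"fst_divergence must be in (0, 1), got {self.fst_divergence}")
        if self.n_loci < 1 or self.n_races < 1:
            raise ConfigError("n_loci and n_races must be >= 1")
        if len(self.race_sizes) != self.n_races:
            raise ConfigError("race_sizes length must equal n_races")
        if any(s < 1 for s in self.race_sizes):
            raise ConfigError("all race sizes must be >= 1")
        for q, count in self.hybrid_specs:
            if len(q) != self.n_races:
                raise ConfigError("hybrid ancestry vector length must equal n_races")
            if abs(sum(q) - 1.0) > 1e-9:
                raise ConfigError("hybrid ancestry proportions must sum to 1")
            if count < 1:
                raise ConfigError("hybrid counts must be >= 1")
        if self.mean_depth <= 0:
            raise ConfigError("mean_depth must be positive")
        if self.depth_dispersion < 0:
            raise ConfigError("depth_dispersion must be >= 0")

    @property
    def race_names(self) -> list[str]:
        if self.n_races == 3:
            return list(RACES)
        return [f"Race{i + 1}" for i in range(self.n_races)]


@dataclass
class SyntheticTruth:
    """Ground truth retained for recovery tests."""

    ancestral_freq: np.ndarray  # (n_loci,)
    race_freq: np.ndarray  # (n_races, n_loci)
    race_names: list[str]
    true_q: pd.DataFrame | None = None  # accession x race ancestry
    pool_freq: pd.DataFrame | None = None  # pool x locus true allele freq

    def __post_init__(self) -> None:
        if ((self.ancestral_freq < 0) | (self.ancestral_freq > 1)).any():
            raise ValueError("ancestral frequencies outside [0, 1]")
        if ((self.race_freq < 0) | (self.race_freq > 1)).any():
            raise ValueError("race frequencies outside [0, 1]")
        if self.true_q is not None:
            sums = self.true_q.to_numpy().sum(axis=1)
            if np.abs(sums - 1.0).max() > 1e-9:
                raise ValueError("true_q rows must sum to 1")


def _default_loci(n_loci: int, rng: np.random.Generator) -> list[Locus]:
    # alternate ref/alt pairs to exercise the allele bookkeeping
    pairs = [("A", "C"), ("G", "T"), ("C", "T"), ("A", "G")]
    return [
        Locus(f"contig{1 + i // 50}", 1 + 20 * (i % 50), *pairs[i % 4]) for i in range(n_loci)
    ]


def simulate_race_frequencies(config: SimulationConfig) -> SyntheticTruth:
    """Draw ancestral and per-race allele frequencies.

    The Balding–Nichols Beta has mean equal to the ancestral frequency and
    variance ``F p (1 - p)``, so ``fst_divergence`` is the expected
    differentiation of the races.
    """
    rng = np.random.default_rng(config.seed)
    p = rng.uniform(0.05, 0.95, size=config.n_loci)
    F = config.fst_divergence
    shape = (1.0 - F) / F
    a = np.clip(p * shape, 1e-12, None)
    b = np.clip((1.0 - p) * shape, 1e-12, None)
    race_freq = np.stack([rng.beta(a, b) for _ in range(config.n_races)])
    return SyntheticTruth(ancestral_freq=p, race_freq=race_freq, race_names=config.race_names)


def simulate_genotypes(
    truth: SyntheticTruth, config: SimulationConfig
) -> tuple[GenotypeMatrix, AccessionMetadata, SyntheticTruth]:
    """Draw accession genotypes (pure races then hybrids) and metadata.

    Each allele copy independently draws a source race from the
    accession's ancestry vector, then an allele from that race's
    frequency.  Pure-race accessions are assigned to their race's pool;
    hybrids carry the ``cultivar`` botanical label and no pool.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    races = truth.race_names
    n_loci = truth.race_freq.shape[1]

    q_rows: list[np.ndarray] = []
    names: list[str] = []
    race_labels: list[str] = []
    pool_labels: list[object] = []
    for r, size in enumerate(config.race_sizes):
        for i in range(size):
            q = np.zeros(config.n_races)
            q[r] = 1.0
            q_rows.append(q)
            names.append(f"{races[r]}_{i + 1:03d}")
            race_labels.append(races[r])
            pool_labels.append(races[r])
    for h, (q_spec, count) in enumerate(config.hybrid_specs):
        for i in range(count):
            q_rows.append(np.asarray(q_spec, dtype=float))
            names.append(f"Hybrid{h + 1}_{i + 1:03d}")
            race_labels.append("cultivar")
            pool_labels.append(None)

    Q = np.stack(q_rows)  # (n_acc, n_races)
    n_acc = Q.shape[0]
    geno = np.zeros((n_acc, n_loci), dtype=np.int8)
    for copy in range(2):
        # source race per accession x locus, then allele from that race
        src = np.array(
            [rng.choice(config.n_races, size=n_loci, p=Q[i]) for i in range(n_acc)]
        )
        freqs = truth.race_freq[src, np.arange(n_loci)[None, :]]
        geno += (rng.random((n_acc, n_loci)) < freqs).astype(np.int8)

    loci = _default_loci(n_loci, rng)
    genos = GenotypeMatrix(accessions=names, loci=loci, geno=geno)
    meta = AccessionMetadata(
        table=pd.DataFrame(
            {"botanical_race": race_labels, "pool": pool_labels}, index=pd.Index(names, name="accession_id")
        )
    )
    truth.true_q = pd.DataFrame(Q, index=names, columns=races)
    return genos, meta, truth


def simulate_pools(
    genos: GenotypeMatrix,
    metadata: AccessionMetadata,
    config: SimulationConfig,
    truth: SyntheticTruth | None = None,
) -> PoolCountTable:
    """Sequence each race pool: Poisson depth, binomial allele sampling.

    The pool's true allele frequency at a locus is the mean alt dosage of
    its member accessions divided by 2 (equal DNA amounts per member).
    With ``depth_dispersion > 0`` the per-locus Poisson mean is Gamma
    distributed with that squared coefficient of variation
    (a negative-binomial depth model).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2]))
    pools = [p for p in metadata.pools()]
    if not pools:
        raise ConfigError("no pool memberships assigned")
    n_loci = genos.n_loci
    depth = np.zeros((n_loci, len(pools)), dtype=np.int64)
    alt_prop = np.full((n_loci, len(pools)), np.nan)
    pool_freqs = {}
    acc_index = {a: i for i, a in enumerate(genos.accessions)}
    for j, pool in enumerate(pools):
        members = metadata.pool_members(pool)
        if not members:
            raise ConfigError(f"pool {pool!r} is empty")
        rows = [acc_index[m] for m in members]
        freq = genos.geno[rows, :].astype(float).mean(axis=0) / 2.0
        pool_freqs[pool] = freq
        mean = config.mean_depth
        if config.depth_dispersion > 0:
            k = 1.0 / config.depth_dispersion
            lam = rng.gamma(shape=k, scale=mean / k, size=n_loci)
        else:
            lam = np.full(n_loci, mean)
        d = rng.poisson(lam)
        alt_reads = rng.binomial(d, freq)
        depth[:, j] = d
        with np.errstate(invalid="ignore"):
            alt_prop[:, j] = np.where(d > 0, alt_reads / np.maximum(d, 1), np.nan)
    if truth is not None:
        truth.pool_freq = pd.DataFrame(
            np.stack([pool_freqs[p] for p in pools]),
            index=pools,
            columns=[l.name for l in genos.loci],
        )
    return PoolCountTable(loci=list(genos.loci), pool_names=pools, depth=depth, alt_prop=alt_prop)


def sample_panel(
    genos: GenotypeMatrix,
    panel_size: int,
    seed: int,
    candidate_idx: Sequence[int] | None = None,
) -> GenotypeMatrix:
    """Uniform random locus subset without replacement (the assay panel).

    ``candidate_idx`` restricts sampling to given locus indices (e.g. loci
    that were discovered as polymorphic in the pools).
    """
    pool = np.arange(genos.n_loci) if candidate_idx is None else np.asarray(list(candidate_idx))
    if panel_size > pool.size:
        raise ValueError(f"panel_size {panel_size} exceeds {pool.size} candidate loci")
    rng = np.random.default_rng(seed)
    idx = np.sort(rng.choice(pool, size=panel_size, replace=False))
    return genos.subset_loci(idx)


def simulate_collection(
    config: SimulationConfig,
) -> tuple[PoolCountTable, GenotypeMatrix, AccessionMetadata, SyntheticTruth]:
    """One-call convenience: frequencies -> genotypes -> pools."""
    truth = simulate_race_frequencies(config)
    genos, meta, truth = simulate_genotypes(truth, config)
    pools = simulate_pools(genos, meta, config, truth)
    return pools, genos, meta, truth


def divergence_fst(race_freq: np.ndarray) -> float:
    """Moment estimate of the drift parameter F from race allele frequencies.

    For K populations with frequencies ``p_k`` at each locus, the K-1
    denominator sample variance ``s^2`` has expectation ``F p (1-p)`` under
    the Balding–Nichols model, and ``mean(p_k)(1-mean(p_k)) + s^2/K`` has
    expectation ``p (1-p)``; the ratio of their sums over loci is therefore
    a nearly unbiased estimator of F (a Weir–Cockerham-style ratio of
    averages).  Used to verify that simulated races carry the requested
    divergence; the diversity-partition F_ST of the analysis modules is a
    different (downward-biased for K small) quantity.
    """
    p = np.asarray(race_freq, dtype=float)
    if p.ndim != 2 or p.shape[0] < 2:
        raise ValueError("race_freq must be (n_races >= 2, n_loci)")
    K = p.shape[0]
    pbar = p.mean(axis=0)
    s2 = p.var(axis=0, ddof=1)
    num = s2.sum()
    den = (pbar * (1.0 - pbar) + s2 / K).sum()
    return float(num / den)
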