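"""Core-anchored PCA with projection, KING-robust kinship, relatedness graph.

PCA is fitted on the core (pure-race reference) accessions only: each
locus is standardized as ``(g − 2p) / sqrt(2 p (1 − p))`` with ``p`` the
core alt-allele frequency, and the SVD of the centered standardized
matrix yields sample coordinates and per-locus loadings.  All other
accessions are then *projected* onto the fixed core axes using the core
frequencies, so admixed material falls between the race clusters instead
of distorting them.

Pairwise kinship uses the KING-robust between-family moment estimator,

    φ = (N_Aa,Aa − 2 N_AA,aa) / (N_Aa(i) + N_Aa(j)),

with counts over the pair's co-called loci: shared heterozygotes,
opposite homozygotes, and each member's heterozygous-site count.  It is
robust to population structure; unrelated pairs from diverged
populations go negative, duplicated genotypes give φ = 0.5, and
parent–offspring pairs center on 0.25.  Accession pairs at or above a
kinship threshold (default 0.25) are connected in the relatedness graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from germpool.io import MISSING, GenotypeMatrix

#: Conventional kinship degree bins (lower φ bound per relationship degree).
DEGREE_BINS = {"duplicate": 0.354, "first": 0.177, "second": 0.0884}


def degree_of(phi: float) -> str:
    for name, lo in DEGREE_BINS.items():
        if phi >= lo:
            return name
    return "unrelated"


@dataclass
class PcaModel:
    """Core frequencies, loadings, eigenvalues, and core coordinates.

    ``col_mean`` holds the column means of the standardized core matrix
    (the centering applied before the SVD); projection subtracts the same
    vector so cores reproduce their fitted coordinates exactly.
    """

    locus_names: list[str]
    core_freq: np.ndarray
    col_mean: np.ndarray
    eigenvalues: np.ndarray  # non-increasing
    loadings: np.ndarray  # (n_loci, n_pc), orthonormal columns
    core_coordinates: pd.DataFrame  # core accession x PC
    dropped_loci: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-8):
            raise ValueError("eigenvalues must be non-increasing")
        gram = self.loadings.T @ self.loadings
        if not np.allclose(gram, np.eye(gram.shape[0]), atol=1e-8):
            raise ValueError("loadings not orthonormal")

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.eigenvalues / self.eigenvalues.sum()


def _standardize(geno: np.ndarray, freq: np.ndarray) -> np.ndarray:
    """Center/scale dosages by given frequencies; missing cells imputed to
    the frequency mean (zero after standardization)."""
    denom = np.sqrt(2.0 * freq * (1.0 - freq))
    return (np.where(geno == MISSING, 2.0 * freq, geno) - 2.0 * freq) / denom


def pca_fit(core_genos: GenotypeMatrix, n_pc: int | None = None) -> PcaModel:
    """Fit PCA on the core accessions (frequency-standardized covariance).

    Loci monomorphic within the cores carry no variance signal and are
    dropped (recorded on the model).
    """
    if core_genos.n_accessions < 3:
        raise ValueError("need >= 3 core accessions")
    freq = core_genos.alt_allele_frequency()
    keep = np.isfinite(freq) & (freq > 0) & (freq < 1)
    dropped = [core_genos.loci[i].name for i in np.flatnonzero(~keep)]
    genos = core_genos.subset_loci(np.flatnonzero(keep))
    freq = freq[keep]
    X = _standardize(genos.geno, freq)
    col_mean = X.mean(axis=0)
    U, s, Vt = np.linalg.svd(X - col_mean, full_matrices=False)
    n = X.shape[0]
    eigenvalues = (s**2) / (n - 1)
    k = min(n_pc or len(s), len(s))
    coords = U[:, :k] * s[:k]
    return PcaModel(
        locus_names=genos.locus_names(),
        core_freq=freq,
        col_mean=col_mean,
        eigenvalues=eigenvalues[:k],
        loadings=Vt[:k].T,
        core_coordinates=pd.DataFrame(
            coords, index=genos.accessions, columns=[f"PC{i + 1}" for i in range(k)]
        ),
        dropped_loci=dropped,
    )


def pca_project(model: PcaModel, genos: GenotypeMatrix) -> pd.DataFrame:
    """Project accessions onto the fitted core axes.

    Standardization and centering use the CORE statistics, so projection
    is linear in the genotype row and core accessions land on their
    fitted coordinates.
    """
    name_to_col = {n: j for j, n in enumerate(genos.locus_names())}
    shared_model_idx = [i for i, n in enumerate(model.locus_names) if n in name_to_col]
    if not shared_model_idx:
        raise ValueError("no locus overlap with the PCA model")
    geno = genos.geno[:, [name_to_col[model.locus_names[i]] for i in shared_model_idx]]
    all_missing = (geno == MISSING).all(axis=1)
    if all_missing.any():
        bad = [genos.accessions[i] for i in np.flatnonzero(all_missing)]
        raise ValueError(f"accessions with no called model loci: {bad}")
    freq = model.core_freq[shared_model_idx]
    X = _standardize(geno, freq) - model.col_mean[shared_model_idx]
    coords = X @ model.loadings[shared_model_idx]
    return pd.DataFrame(coords, index=genos.accessions, columns=model.core_coordinates.columns)


@dataclass
class KinshipMatrix:
    """Pairwise φ with the counts it was computed from."""

    accessions: list[str]
    phi: np.ndarray  # (n, n), NaN where undefined, 0.5 on the diagonal
    n_het_shared: np.ndarray  # N_Aa,Aa per pair
    n_opposite_hom: np.ndarray  # N_AA,aa per pair
    n_het_i: np.ndarray  # per-pair heterozygous-site count of the row member

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.phi, index=self.accessions, columns=self.accessions)

    def pair(self, a: str, b: str) -> float:
        i, j = self.accessions.index(a), self.accessions.index(b)
        return float(self.phi[i, j])


def king_kinship(genos: GenotypeMatrix) -> KinshipMatrix:
    """KING-robust between-family kinship for every accession pair."""
    if genos.n_accessions < 2:
        raise ValueError("need >= 2 accessions")
    g = genos.geno
    called = (g != MISSING).astype(np.float64)
    het = (g == 1).astype(np.float64)
    hom_ref = (g == 0).astype(np.float64)
    hom_alt = (g == 2).astype(np.float64)

    n_het_shared = het @ het.T
    n_opp = hom_ref @ hom_alt.T + hom_alt @ hom_ref.T
    # heterozygous sites of i restricted to loci co-called with j (and vice versa)
    n_het_i = het @ called.T
    n_het_j = n_het_i.T

    denom = n_het_i + n_het_j
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = np.where(denom > 0, (n_het_shared - 2.0 * n_opp) / denom, np.nan)
    np.fill_diagonal(phi, 0.5)
    return KinshipMatrix(
        accessions=list(genos.accessions),
        phi=phi,
        n_het_shared=n_het_shared,
        n_opposite_hom=n_opp,
        n_het_i=n_het_i,
    )


@dataclass
class RelatednessGraph:
    graph: nx.Graph
    threshold: float

    @property
    def edges(self) -> list[tuple[str, str, float]]:
        return [(a, b, d["phi"]) for a, b, d in self.graph.edges(data=True)]

    def components(self) -> list[set[str]]:
        return [set(c) for c in nx.connected_components(self.graph) if len(c) > 1]

    def to_dict(self) -> dict:
        return {
            "threshold": self.threshold,
            "edges": [
                {"a": a, "b": b, "phi": round(p, 6), "degree": degree_of(p)}
                for a, b, p in self.edges
            ],
            "components": [sorted(c) for c in self.components()],
        }


def relatedness_graph(kin: KinshipMatrix, threshold: float = 0.25) -> RelatednessGraph:
    """Undirected graph connecting pairs with φ >= threshold."""
    G = nx.Graph()
    G.add_nodes_from(kin.accessions)
    n = len(kin.accessions)
    for i in range(n):
        for j in range(i + 1, n):
            p = kin.phi[i, j]
            if np.isfinite(p) and p >= threshold:
                G.add_edge(kin.accessions[i], kin.accessions[j], phi=float(p))
    return RelatednessGraph(graph=G, threshold=threshold)
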