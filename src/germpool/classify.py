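"""F_ST, consensus core-set selection, and race/hybrid assignment.

Three independent classifications of each accession — its botanical
(morphological) race label, its cluster in the shared-allele dendrogram,
and its majority ancestry in the unsupervised admixture model (Q above a
purity threshold) — are intersected: accessions on which all three agree
form the *core set* of their race.  Core sets are the least admixed
representatives and are scored by the differentiation they induce:
``F_ST = (H_T − H_S) / H_T`` per locus, with ``H_T`` the expected
heterozygosity of the pooled collection and ``H_S`` the sample-size
weighted mean subpopulation expected heterozygosity, summarized by the
median across the marker panel.  Finally every accession is classified
against the cores with the supervised admixture model: ancestry
components above a presence threshold decide pure race vs bi-racial vs
tri-racial hybrid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from germpool.io import MISSING, AccessionMetadata, GenotypeMatrix, RACES
from germpool.admixture import QMatrix


@dataclass
class FstResult:
    """Per-locus diversity partition and its median over the panel."""

    per_locus: pd.DataFrame  # index locus name; columns h_t, h_s, fst
    median: float
    n_excluded: int  # monomorphic-everywhere loci

    def to_dict(self) -> dict:
        return {"median_fst": self.median, "n_loci": int(self.per_locus.shape[0]),
                "n_excluded": self.n_excluded}


def compute_fst(genos: GenotypeMatrix, subpop_labels: dict[str, str]) -> FstResult:
    """Diversity-partition F_ST per locus from genotypes and subpop labels.

    ``H_T = 2 p̄ (1 − p̄)`` on the pooled allele frequency (weighted by
    called sample sizes), ``H_S = Σ_k (n_k / n) 2 p_k (1 − p_k)``.  Loci
    monomorphic in the pooled sample (H_T = 0) are excluded and counted.
    """
    labels = {a: subpop_labels[a] for a in genos.accessions if a in subpop_labels}
    pops = sorted(set(labels.values()))
    if len(pops) < 2:
        raise ValueError("need >= 2 non-empty subpopulations")
    rows_by_pop = {
        p: [i for i, a in enumerate(genos.accessions) if labels.get(a) == p] for p in pops
    }
    g = genos.geno
    called = g != MISSING

    n_k = np.zeros((len(pops), genos.n_loci))
    p_k = np.zeros((len(pops), genos.n_loci))
    for j, p in enumerate(pops):
        sub = g[rows_by_pop[p]]
        subcalled = called[rows_by_pop[p]]
        counts = subcalled.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            p_k[j] = np.where(counts > 0, np.where(subcalled, sub, 0).sum(axis=0) / (2.0 * counts), np.nan)
        n_k[j] = counts
    n_tot = n_k.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p_bar = np.nansum(n_k * p_k, axis=0) / n_tot
        h_t = 2.0 * p_bar * (1.0 - p_bar)
        h_s = np.nansum((n_k / n_tot) * 2.0 * p_k * (1.0 - p_k), axis=0)
        fst = (h_t - h_s) / h_t

    ok = np.isfinite(fst) & (h_t > 0)
    per_locus = pd.DataFrame(
        {"h_t": h_t[ok], "h_s": h_s[ok], "fst": fst[ok]},
        index=[genos.loci[i].name for i in np.flatnonzero(ok)],
    )
    return FstResult(
        per_locus=per_locus,
        median=float(np.median(per_locus["fst"])) if len(per_locus) else float("nan"),
        n_excluded=int((~ok).sum()),
    )


@dataclass
class CoreSetAssignment:
    """Per-accession labels from the three methods and their consensus."""

    table: pd.DataFrame  # columns botanical, dendrogram, admixture, core, core_race
    method_counts: pd.DataFrame  # rows = method combos; columns = per-race counts

    def core_members(self) -> dict[str, list[str]]:
        core = self.table[self.table["core"]]
        return {
            race: list(core.index[core["core_race"] == race])
            for race in sorted(set(core["core_race"].dropna()))
        }


def _majority_map(cluster_of: dict[str, int], botanical: dict[str, str], races: list[str]) -> dict[int, str | None]:
    """Map cluster ids to races by majority botanical label (None if no majority)."""
    out: dict[int, str | None] = {}
    for c in sorted(set(cluster_of.values())):
        members = [a for a, cc in cluster_of.items() if cc == c]
        counts = pd.Series([botanical[a] for a in members if botanical.get(a) in races])
        if counts.empty:
            out[c] = None
            continue
        tally = counts.value_counts()
        top = tally.index[0]
        out[c] = str(top) if (len(tally) == 1 or tally.iloc[0] > tally.iloc[1]) else None
    return out


def select_core_sets(
    metadata: AccessionMetadata,
    dendrogram_clusters: dict[str, int],
    q_matrix: QMatrix,
    genos: GenotypeMatrix | None = None,
    q_threshold: float = 0.85,
    races: list[str] | None = None,
) -> CoreSetAssignment:
    """Consensus of botanical, dendrogram, and admixture classifications.

    Dendrogram clusters and admixture components are each mapped to races
    by the majority botanical label of their members; an accession's
    admixture label requires its mapped component to exceed
    ``q_threshold``.  The core flag is true iff all three labels are
    defined and equal.  With ``genos`` given, the per-method (and
    combination) race counts and median F_ST are tabulated.
    """
    races = races or [r for r in RACES]
    accs = [a for a in q_matrix.q.index]
    botanical = {a: metadata.race_of(a) for a in metadata.accessions}

    cluster_race = _majority_map(dendrogram_clusters, botanical, races)
    dendro = {a: cluster_race.get(dendrogram_clusters.get(a)) for a in accs}

    # map admixture components to races by majority botanical label of
    # accessions whose max component is that column
    comp_of = {a: int(np.argmax(q_matrix.q.loc[a].to_numpy())) for a in accs}
    comp_race = _majority_map(comp_of, botanical, races)
    admix = {}
    for a in accs:
        comp = comp_of[a]
        qmax = float(q_matrix.q.loc[a].iloc[comp])
        admix[a] = comp_race.get(comp) if qmax > q_threshold else None

    rows = []
    for a in accs:
        b = botanical.get(a) if botanical.get(a) in races else None
        d, m = dendro.get(a), admix.get(a)
        core = b is not None and b == d and b == m
        rows.append({"botanical": b, "dendrogram": d, "admixture": m,
                     "core": core, "core_race": b if core else None})
    table = pd.DataFrame(rows, index=accs)

    combos = {
        "A_botanical": ["botanical"],
        "B_dendrogram": ["dendrogram"],
        "C_admixture": ["admixture"],
        "A&B": ["botanical", "dendrogram"],
        "A&C": ["botanical", "admixture"],
        "B&C": ["dendrogram", "admixture"],
        "A&B&C": ["botanical", "dendrogram", "admixture"],
    }
    count_rows = {}
    for name, cols in combos.items():
        agree = table[cols[0]].notna()
        for c in cols[1:]:
            agree &= table[c].notna() & (table[c] == table[cols[0]])
        labels = table.loc[agree, cols[0]]
        row = {race: int((labels == race).sum()) for race in races}
        if genos is not None:
            lab_map = {a: labels[a] for a in labels.index}
            if len(set(lab_map.values())) >= 2:
                row["median_fst"] = compute_fst(genos, lab_map).median
            else:
                row["median_fst"] = float("nan")
        count_rows[name] = row
    return CoreSetAssignment(table=table, method_counts=pd.DataFrame.from_dict(count_rows, orient="index"))


@dataclass
class RaceAssignment:
    """Pure-race / hybrid categories from supervised ancestry."""

    table: pd.DataFrame  # per-accession Q plus 'category' and 'components'

    def to_dict(self) -> dict:
        return self.table.to_dict(orient="index")


def classify_accessions(supervised_q: QMatrix, minor_component_min: float = 0.15) -> RaceAssignment:
    """Threshold supervised ancestries into pure / bi- / tri-racial classes.

    A component is *present* when >= ``minor_component_min`` (chosen as
    the complement of the 0.85 core-purity threshold).  One present
    component → pure race; two → bi-racial hybrid of that pair; three →
    tri-racial (complex) hybrid.
    """
    arr = supervised_q.q.to_numpy()
    if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
        raise ValueError("Q rows must sum to 1")
    pops = list(supervised_q.q.columns)
    rows = []
    for a, q in zip(supervised_q.q.index, arr):
        present = [pops[j] for j in range(len(pops)) if q[j] >= minor_component_min]
        if not present:  # all tiny (K > 3 edge); call the max component
            present = [pops[int(np.argmax(q))]]
        if len(present) == 1:
            category = f"pure:{present[0]}"
        elif len(present) == 2:
            category = f"hybrid:{present[0]}x{present[1]}"
        else:
            category = "hybrid:complex"
        row = {p: float(qq) for p, qq in zip(pops, q)}
        row["components"] = "+".join(present)
        row["category"] = category
        rows.append(row)
    return RaceAssignment(table=pd.DataFrame(rows, index=supervised_q.q.index))
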