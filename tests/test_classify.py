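import numpy as np
import pandas as pd
import pytest

from germpool.admixture import McmcConfig, QMatrix, run_admixture
from germpool.classify import classify_accessions, compute_fst, select_core_sets
from germpool.io import AccessionMetadata, RACES
from germpool.simulate import SimulationConfig, divergence_fst, simulate_race_frequencies
from germpool.tree import cut_k_clusters, psa_distance, ward_tree

from conftest import make_genotypes


def _labels(genos, groups):
    """groups: list of (prefix_count, label) consumed in order."""
    out = {}
    i = 0
    for count, label in groups:
        for _ in range(count):
            out[genos.accessions[i]] = label
            i += 1
    return out


class TestFst:
    def test_opposite_fixation_is_one(self):
        gm = make_genotypes([[0], [0], [2], [2]])
        res = compute_fst(gm, _labels(gm, [(2, "p1"), (2, "p2")]))
        assert res.per_locus["fst"].iloc[0] == pytest.approx(1.0)
        assert res.per_locus["h_t"].iloc[0] == pytest.approx(0.5)
        assert res.per_locus["h_s"].iloc[0] == pytest.approx(0.0)

    def test_identical_frequencies_give_zero(self):
        gm = make_genotypes([[1], [1], [1], [1]])
        res = compute_fst(gm, _labels(gm, [(2, "p1"), (2, "p2")]))
        assert res.per_locus["fst"].iloc[0] == pytest.approx(0.0)

    def test_direct_arithmetic_case(self):
        # equal-size subpops with p = 0.2 and 0.8:
        # H_S = 0.32, H_T = 0.5, F_ST = 0.36
        gm = make_genotypes([[1], [0], [0], [0], [1], [1], [2], [2], [2], [1]])
        res = compute_fst(gm, _labels(gm, [(5, "p1"), (5, "p2")]))
        assert res.per_locus["h_s"].iloc[0] == pytest.approx(0.32)
        assert res.per_locus["h_t"].iloc[0] == pytest.approx(0.5)
        assert res.per_locus["fst"].iloc[0] == pytest.approx(0.36)

    def test_monomorphic_locus_excluded(self):
        gm = make_genotypes([[0, 1], [0, 0], [0, 1], [0, 2]])
        res = compute_fst(gm, _labels(gm, [(2, "p1"), (2, "p2")]))
        assert res.n_excluded == 1
        assert len(res.per_locus) == 1

    def test_allele_relabel_and_subpop_copy_invariance(self):
        rng = np.random.default_rng(2)
        g = rng.integers(0, 3, size=(12, 30))
        gm = make_genotypes(g.tolist())
        labels = _labels(gm, [(6, "p1"), (6, "p2")])
        base = compute_fst(gm, labels).per_locus["fst"]
        flipped = compute_fst(make_genotypes((2 - g).tolist()), labels).per_locus["fst"]
        np.testing.assert_allclose(base, flipped, atol=1e-12)
        # duplicating every subpopulation's members preserves frequencies
        # and weights, hence per-locus F_ST
        g2 = np.vstack([g, g])
        gm2 = make_genotypes(g2.tolist())
        labels2 = dict(labels)
        labels2.update({gm2.accessions[12 + i]: labels[gm2.accessions[i]] for i in range(12)})
        dup = compute_fst(gm2, labels2).per_locus["fst"]
        np.testing.assert_allclose(base, dup, atol=1e-12)

    def test_needs_two_subpopulations(self):
        gm = make_genotypes([[0], [1]])
        with pytest.raises(ValueError):
            compute_fst(gm, _labels(gm, [(2, "p1")]))

    def test_median_fst_monotone_in_divergence(self):
        """The diversity-partition F_ST tracks the simulated drift level."""
        medians = []
        for F in (0.05, 0.15, 0.3):
            cfg = SimulationConfig(n_loci=800, fst_divergence=F,
                                   race_sizes=(15, 15, 15), hybrid_specs=(), seed=9)
            from germpool.simulate import simulate_genotypes

            truth = simulate_race_frequencies(cfg)
            genos, meta, _ = simulate_genotypes(truth, cfg)
            labels = {a: meta.race_of(a) for a in genos.accessions}
            medians.append(compute_fst(genos, labels).median)
        assert medians[0] < medians[1] < medians[2]


def _metadata_from(labels: dict[str, str], pools: dict[str, str] | None = None):
    pools = pools or {}
    return AccessionMetadata(
        table=pd.DataFrame(
            {
                "botanical_race": [labels[a] for a in labels],
                "pool": [pools.get(a) for a in labels],
            },
            index=pd.Index(list(labels), name="accession_id"),
        )
    )


@pytest.fixture(scope="module")
def labeled_world(pure_race_world):
    genos = pure_race_world["genos"]
    meta = pure_race_world["meta"]
    clusters = cut_k_clusters(ward_tree(psa_distance(genos)), 3)
    q = run_admixture(genos, 3, McmcConfig(burn_in=200, reps=900, n_runs=3, seed=3), seed=60)
    return {"genos": genos, "meta": meta, "clusters": clusters, "q": q}


class TestCoreSets:
    def test_full_agreement_makes_everyone_core(self, labeled_world):
        assign = select_core_sets(
            labeled_world["meta"], labeled_world["clusters"], labeled_world["q"],
            genos=labeled_world["genos"],
        )
        cores = assign.core_members()
        assert sum(len(v) for v in cores.values()) == assign.table["core"].sum()
        counts = assign.method_counts
        # consensus equals each single method when everything agrees
        for race in RACES:
            assert counts.loc["A&B&C", race] == counts.loc["A_botanical", race]

    def test_botanical_mislabel_breaks_consensus(self, labeled_world):
        meta = labeled_world["meta"]
        tampered = meta.table.copy()
        victim = tampered.index[0]
        true_race = tampered.loc[victim, "botanical_race"]
        tampered.loc[victim, "botanical_race"] = (
            "Mexican" if true_race != "Mexican" else "WestIndian"
        )
        assign = select_core_sets(
            AccessionMetadata(table=tampered), labeled_world["clusters"], labeled_world["q"]
        )
        assert not assign.table.loc[victim, "core"]

    def test_consensus_cores_at_least_as_divergent_as_botanical(self, mixed_collection):
        """Contaminating botanical groups with admixed accessions lowers
        their F_ST relative to the consensus core sets."""
        genos, meta = mixed_collection["genos"], mixed_collection["meta"]
        # mislabel some hybrids as pure-race material (field mislabeling)
        table = meta.table.copy()
        hybrids = [a for a in table.index if a.startswith(("Hybrid1", "Hybrid2", "Hybrid3"))][:15]
        for i, a in enumerate(hybrids):
            table.loc[a, "botanical_race"] = list(RACES)[i % 3]
        noisy_meta = AccessionMetadata(table=table)
        clusters = cut_k_clusters(ward_tree(psa_distance(genos)), 3)
        q = run_admixture(genos, 3, McmcConfig(burn_in=200, reps=900, n_runs=3, seed=3), seed=61)
        assign = select_core_sets(noisy_meta, clusters, q, genos=genos)
        counts = assign.method_counts
        assert counts.loc["A&B&C", "median_fst"] >= counts.loc["A_botanical", "median_fst"]


class TestRaceAssignment:
    def _q(self, rows):
        return QMatrix(
            q=pd.DataFrame(rows, columns=list(RACES),
                           index=[f"a{i}" for i in range(len(rows))]),
        )

    def test_nearly_pure_accession(self):
        res = classify_accessions(self._q([[0.99, 0.005, 0.005]]))
        assert res.table["category"].iloc[0] == "pure:Guatemalan"

    def test_fifty_fifty_hybrid(self):
        res = classify_accessions(self._q([[0.5, 0.5, 0.0]]))
        assert res.table["category"].iloc[0] == "hybrid:GuatemalanxMexican"

    def test_tri_racial_hybrid(self):
        res = classify_accessions(self._q([[1 / 3, 1 / 3, 1 / 3]]))
        assert res.table["category"].iloc[0] == "hybrid:complex"

    def test_rows_must_sum_to_one(self):
        q = self._q([[0.5, 0.5, 0.0]])
        q.q.iloc[0, 0] = 0.7  # corrupt after construction
        with pytest.raises(ValueError):
            classify_accessions(q)

    def test_threshold_is_configurable(self):
        res = classify_accessions(self._q([[0.8, 0.2, 0.0]]), minor_component_min=0.25)
        assert res.table["category"].iloc[0] == "pure:Guatemalan"
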