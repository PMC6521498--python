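from itertools import permutations

import numpy as np
import pandas as pd
import pytest

from germpool.admixture import (
    EvannoTable,
    McmcConfig,
    QMatrix,
    admixture_sweep,
    align_and_average_runs,
    evanno_delta_k,
    run_admixture,
    supervised_assignment,
)
from germpool.io import RACES
from germpool.simulate import SimulationConfig, SyntheticTruth, simulate_genotypes

FAST = McmcConfig(burn_in=200, reps=900, n_runs=3, seed=11)


def _align_to_truth(q: np.ndarray, truth: np.ndarray) -> np.ndarray:
    K = q.shape[1]
    best = min(permutations(range(K)), key=lambda p: ((q[:, list(p)] - truth) ** 2).sum())
    return q[:, list(best)]


class TestSampler:
    def test_k1_is_degenerate(self, pure_race_world):
        q = run_admixture(pure_race_world["genos"], K=1)
        assert (q.q.to_numpy() == 1.0).all()

    def test_pure_race_recovery(self, pure_race_world):
        """Three diverged races, K=3: aligned posterior-mean ancestries are
        nearly pure for every accession."""
        q = run_admixture(pure_race_world["genos"], 3, FAST, seed=50)
        aligned = _align_to_truth(q.q.to_numpy(), pure_race_world["truth"].true_q.to_numpy())
        assert aligned.max(axis=1).mean() >= 0.9

    def test_model_simulated_data_correlates_with_truth(self):
        # data simulated from the admixture model itself at K=2
        cfg = SimulationConfig(
            n_loci=200, n_races=2, fst_divergence=0.4, race_sizes=(15, 15),
            hybrid_specs=(((0.5, 0.5), 10), ((0.8, 0.2), 10)), seed=21,
        )
        from germpool.simulate import simulate_race_frequencies

        truth = simulate_race_frequencies(cfg)
        genos, meta, truth = simulate_genotypes(truth, cfg)
        q = run_admixture(genos, 2, FAST, seed=51)
        aligned = _align_to_truth(q.q.to_numpy(), truth.true_q.to_numpy())
        r = np.corrcoef(aligned[:, 0], truth.true_q.to_numpy()[:, 0])[0, 1]
        assert r >= 0.95

    def test_log_likelihood_trace_finite_and_improving(self, pure_race_world):
        q = run_admixture(pure_race_world["genos"], 3, FAST, seed=52)
        ll = q.log_likelihood
        assert np.isfinite(ll).all()
        # post-burn-in likelihood beats a random-ancestry baseline
        half = len(ll) // 2
        assert ll[half:].mean() >= ll[:half].mean() - 50


class TestEvanno:
    def test_recovers_k3_on_three_races(self, pure_race_world):
        genos = pure_race_world["genos"].subset_loci(range(150))
        cfg = McmcConfig(burn_in=150, reps=600, n_runs=2, seed=13)
        _, _, table = admixture_sweep(genos, cfg, [1, 2, 3, 4, 5])
        assert table.best_k == 3

    def test_zero_sd_flagged_undefined(self):
        runs = {
            k: [
                QMatrix(q=pd.DataFrame({"p1": [1.0, 1.0]}, index=["a", "b"]),
                        mean_log_likelihood=ll)
                for ll in lls
            ]
            for k, lls in {1: (-10.0, -10.0), 2: (-8.0, -8.0), 3: (-7.5, -7.0)}.items()
        }
        table = evanno_delta_k(runs)
        assert np.isnan(table.table.loc[2, "delta_k"])

    def test_delta_k_non_negative(self):
        rng = np.random.default_rng(1)
        runs = {
            k: [
                QMatrix(q=pd.DataFrame({"p1": [1.0]}, index=["a"]),
                        mean_log_likelihood=float(-100 * k + rng.normal(0, 3)))
                for _ in range(4)
            ]
            for k in (1, 2, 3, 4)
        }
        table = evanno_delta_k(runs)
        dk = table.table["delta_k"].dropna()
        assert (dk >= 0).all()

    def test_requires_consecutive_ks(self):
        runs = {1: [], 3: [], 5: []}
        with pytest.raises(ValueError):
            evanno_delta_k(runs)


def _toy_q(arr, cols=("pop1", "pop2", "pop3")):
    return QMatrix(
        q=pd.DataFrame(np.asarray(arr, dtype=float), columns=list(cols),
                       index=[f"a{i}" for i in range(len(arr))]),
        mean_log_likelihood=-1.0,
    )


class TestAlignment:
    def test_column_swap_is_undone(self):
        q1 = _toy_q([[0.9, 0.05, 0.05], [0.1, 0.8, 0.1], [0.2, 0.2, 0.6]])
        swapped = q1.q[["pop2", "pop3", "pop1"]].to_numpy()
        q2 = _toy_q(swapped)
        avg = align_and_average_runs([q1, q2])
        np.testing.assert_allclose(avg.q.to_numpy(), q1.q.to_numpy(), atol=1e-12)

    def test_noise_averages_out(self):
        rng = np.random.default_rng(3)
        base = rng.dirichlet(np.ones(3), size=30)
        runs = []
        for _ in range(20):
            noisy = np.clip(base + rng.normal(0, 0.02, base.shape), 1e-6, None)
            noisy /= noisy.sum(axis=1, keepdims=True)
            perm = rng.permutation(3)
            runs.append(_toy_q(noisy[:, perm]))
        ref = _toy_q(base)
        avg = align_and_average_runs([ref] + runs)
        assert np.abs(avg.q.to_numpy() - base).max() < 0.02

    def test_rows_sum_to_one_and_order_invariant(self):
        rng = np.random.default_rng(4)
        runs = [_toy_q(rng.dirichlet(np.ones(3), size=5)) for _ in range(4)]
        avg1 = align_and_average_runs(runs)
        avg2 = align_and_average_runs([runs[0]] + runs[1:][::-1])
        np.testing.assert_allclose(avg1.q.to_numpy().sum(axis=1), 1.0)
        np.testing.assert_allclose(avg1.q.to_numpy(), avg2.q.to_numpy(), atol=1e-12)

    def test_k_over_8_requires_greedy(self):
        rng = np.random.default_rng(5)
        runs = [
            QMatrix(q=pd.DataFrame(rng.dirichlet(np.ones(9), size=4),
                                   columns=[f"p{i}" for i in range(9)],
                                   index=list("abcd")), mean_log_likelihood=-1.0)
            for _ in range(2)
        ]
        with pytest.raises(ValueError, match="greedy"):
            align_and_average_runs(runs)
        avg = align_and_average_runs(runs, greedy=True)
        assert avg.K == 9


@pytest.fixture(scope="module")
def supervised_world():
    cfg = SimulationConfig(
        n_loci=400, race_sizes=(12, 12, 12),
        hybrid_specs=(
            ((0.5, 0.5, 0.0), 8),
            ((1 / 3, 1 / 3, 1 / 3), 6),
            ((1.0, 0.0, 0.0), 4),  # pure but outside the reference cores
        ),
        seed=31,
    )
    from germpool.simulate import simulate_collection

    pools, genos, meta, truth = simulate_collection(cfg)
    cores = {a: meta.race_of(a) for a in meta.accessions if meta.race_of(a) in RACES}
    q = supervised_assignment(genos, cores, McmcConfig(burn_in=250, reps=1200, n_runs=3, seed=41))
    return {"genos": genos, "meta": meta, "truth": truth, "cores": cores, "q": q}


class TestSupervised:
    def test_core_member_is_fixed_to_own_population(self, supervised_world):
        cores, q = supervised_world["cores"], supervised_world["q"]
        acc, race = next(iter(cores.items()))
        assert q.q.loc[acc, race] == pytest.approx(1.0)

    def test_pure_noncore_assigned_to_own_race(self, supervised_world):
        q = supervised_world["q"]
        pure = [a for a in q.q.index if a.startswith("Hybrid3_")]  # the 100% race-1 spec
        assert len(pure) == 4
        assert (q.q.loc[pure, "Guatemalan"] >= 0.85).all()

    def test_tri_hybrid_has_all_components(self, supervised_world):
        q = supervised_world["q"]
        tri = [a for a in q.q.index if a.startswith("Hybrid2_")]
        assert (q.q.loc[tri].to_numpy() >= 0.15).all()

    def test_fifty_fifty_hybrids_balanced(self, supervised_world):
        q = supervised_world["q"]
        hyb = [a for a in q.q.index if a.startswith("Hybrid1_")]
        est = q.q.loc[hyb, ["Guatemalan", "Mexican"]].to_numpy().mean(axis=0)
        assert np.abs(est - 0.5).max() < 0.15

    def test_empty_core_rejected(self, supervised_world):
        genos = supervised_world["genos"]
        with pytest.raises(ValueError):
            supervised_assignment(genos, {genos.accessions[0]: "X"})
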