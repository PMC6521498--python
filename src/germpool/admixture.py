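"""Model-based ancestry estimation: a Gibbs sampler for the admixture model.

The model is the standard Bayesian admixture model for unlinked biallelic
loci: each accession *i* has an ancestry vector ``q_i`` over K
populations (Dirichlet(alpha) prior), each population *k* has an
alt-allele frequency ``p_kl`` at each locus (Beta(lambda, lambda) prior),
and each of the two allele copies of genotype ``g_il`` independently
draws a source population ``z`` from ``q_i`` and then its allele from
``p_{z,l}``.  The collapsed quantities are sampled in turn:

* ``z | q, p``  — categorical per allele copy;
* ``p | z``     — Beta with allele-assignment counts;
* ``q | z``     — Dirichlet with copy-assignment counts.

The reported Q matrix is the posterior mean over post-burn-in sweeps.
Multiple independent runs are label-aligned (exhaustive column
permutation against a reference run) and averaged, and the number of
populations is chosen by the Evanno second-order rate of change of the
log-likelihood across K.

Supervised classification against reference (core) populations fixes the
core accessions' ancestries to their population indicator, so population
allele frequencies are learned mainly from the cores while the remaining
accessions' ancestries are sampled freely.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import permutations

import numpy as np
import pandas as pd
from scipy.special import gammaln

from germpool.io import MISSING, GenotypeMatrix


@dataclass
class McmcConfig:
    """Sampler settings.

    Literature-scale settings are 5000 burn-in / 50,000 sweeps / 20 runs
    over K = 1..10; the reduced defaults here (500 / 2000 / 5) recover
    simulated ancestries to the tolerances the test-suite asserts at a
    fraction of the cost.  ``alpha`` is the symmetric Dirichlet admixture
    hyperparameter; by default it is inferred by a Metropolis random walk
    (uniform prior on (0, alpha_max]) as the reference implementation
    does, starting from ``alpha``.  ``freq_lambda`` is the Beta
    allele-frequency prior.
    """

    burn_in: int = 500
    reps: int = 2000
    n_runs: int = 5
    k_range: tuple[int, int] = (1, 10)
    alpha: float = 1.0
    infer_alpha: bool = True
    alpha_max: float = 10.0
    alpha_prop_sd: float = 0.05
    freq_lambda: float = 1.0
    seed: int = 0
    thin: int = 5

    def __post_init__(self) -> None:
        if self.burn_in >= self.reps:
            raise ValueError("burn_in must be < reps")
        if self.n_runs < 1:
            raise ValueError("n_runs must be >= 1")
        if self.alpha <= 0 or self.freq_lambda <= 0:
            raise ValueError("alpha and freq_lambda must be positive")


@dataclass
class QMatrix:
    """Accession x population ancestry proportions plus sampler trace."""

    q: pd.DataFrame  # accessions x K, rows sum to 1
    log_likelihood: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_log_likelihood: float = float("nan")

    def __post_init__(self) -> None:
        arr = self.q.to_numpy()
        if ((arr < -1e-9) | (arr > 1 + 1e-9)).any():
            raise ValueError("ancestry proportions outside [0, 1]")
        if np.abs(arr.sum(axis=1) - 1.0).max() > 1e-6:
            raise ValueError("ancestry rows must sum to 1")

    @property
    def K(self) -> int:
        return self.q.shape[1]


def _allele_copies(genos: GenotypeMatrix) -> tuple[np.ndarray, np.ndarray]:
    """Split genotypes into two 0/1 allele-copy matrices plus a called mask."""
    g = genos.geno
    called = g != MISSING
    x1 = (g >= 1) & called  # one alt copy when het or hom-alt
    x2 = (g == 2) & called
    return np.stack([x1, x2]).astype(np.int8), called


def _log_likelihood(g: np.ndarray, called: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    """Binomial mixture log-likelihood of the genotypes given Q and P."""
    u = np.clip(Q @ P, 1e-12, 1 - 1e-12)  # (n, L) per-copy alt prob
    gg = np.where(called, g, 0).astype(float)
    ll = gg * np.log(u) + (2.0 - gg) * np.log1p(-u)
    ll = ll + np.where(called & (g == 1), np.log(2.0), 0.0)
    return float(ll[called].sum())


def _gibbs(
    alleles: np.ndarray,
    called: np.ndarray,
    g: np.ndarray,
    K: int,
    cfg: McmcConfig,
    rng: np.random.Generator,
    fixed_q: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Core sampler.  ``fixed_q`` rows with a finite entry pin an accession's
    ancestry (supervised mode); NaN rows are sampled."""
    n, L = called.shape
    Q = rng.dirichlet(np.full(K, 1.0), size=n)
    pinned = np.zeros(n, dtype=bool)
    if fixed_q is not None:
        pinned = ~np.isnan(fixed_q[:, 0])
        Q[pinned] = fixed_q[pinned]
    free = ~pinned
    P = rng.beta(cfg.freq_lambda, cfg.freq_lambda, size=(K, L))
    alpha = cfg.alpha

    keep_sweeps = 0
    q_sum = np.zeros((n, K))
    ll_trace = []
    for sweep in range(cfg.reps):
        # --- z | Q, P : one categorical draw per allele copy
        copy_counts = np.zeros((n, K))  # copies per accession per pop
        alt_counts = np.zeros((K, L))  # alt alleles assigned to pop k at locus l
        tot_counts = np.zeros((K, L))
        for c in range(2):
            x = alleles[c]  # (n, L) 0/1
            # emission prob of this copy under each pop
            em = np.where(x[:, :, None] == 1, P.T[None, :, :], (1.0 - P).T[None, :, :])
            probs = Q[:, None, :] * em  # (n, L, K)
            cum = probs.cumsum(axis=2)
            u = rng.random((n, L))[:, :, None] * cum[:, :, -1:]
            z = (u > cum).sum(axis=2)  # (n, L) in 0..K-1
            zm = np.where(called, z, -1)
            for k in range(K):
                sel = zm == k
                copy_counts[:, k] += sel.sum(axis=1)
                alt_counts[k] += (sel & (x == 1)).sum(axis=0)
                tot_counts[k] += sel.sum(axis=0)
        # --- P | z
        P = rng.beta(cfg.freq_lambda + alt_counts, cfg.freq_lambda + (tot_counts - alt_counts))
        # --- Q | z (Dirichlet via normalized Gammas)
        gamma = rng.gamma(alpha + copy_counts)
        Q = gamma / np.maximum(gamma.sum(axis=1, keepdims=True), 1e-300)
        Q = np.clip(Q, 1e-12, None)
        Q = Q / Q.sum(axis=1, keepdims=True)
        if fixed_q is not None:
            Q[pinned] = fixed_q[pinned]
        # --- alpha | Q : Metropolis random walk on the Dirichlet
        # concentration, over the freely sampled ancestry rows only
        if cfg.infer_alpha and free.any():
            prop = alpha + rng.normal(0.0, cfg.alpha_prop_sd)
            if 0.0 < prop <= cfg.alpha_max:
                sum_log_q = np.log(Q[free]).sum()
                n_free = int(free.sum())

                def dir_ll(a: float) -> float:
                    return n_free * (gammaln(K * a) - K * gammaln(a)) + (a - 1.0) * sum_log_q

                if np.log(rng.random()) < dir_ll(prop) - dir_ll(alpha):
                    alpha = prop
        if sweep >= cfg.burn_in and (sweep - cfg.burn_in) % cfg.thin == 0:
            q_sum += Q
            keep_sweeps += 1
            ll_trace.append(_log_likelihood(g, called, Q, P))
        if not np.isfinite(P).all() or not np.isfinite(Q).all():
            raise FloatingPointError("non-finite sampler state")
    return q_sum / keep_sweeps, np.asarray(ll_trace)


def run_admixture(
    genos: GenotypeMatrix,
    K: int,
    cfg: McmcConfig | None = None,
    seed: int | None = None,
    fixed_q: np.ndarray | None = None,
) -> QMatrix:
    """One Gibbs run; returns the posterior-mean Q and log-likelihood trace."""
    cfg = cfg or McmcConfig()
    if K < 1:
        raise ValueError("K must be >= 1")
    cols = [f"pop{k + 1}" for k in range(K)]
    if K == 1:
        q = pd.DataFrame(1.0, index=genos.accessions, columns=cols)
        alleles, called = _allele_copies(genos)
        ll = _log_likelihood(genos.geno, called, np.ones((genos.n_accessions, 1)),
                             np.full((1, genos.n_loci), np.clip(genos.alt_allele_frequency(), 1e-12, 1 - 1e-12)))
        return QMatrix(q=q, log_likelihood=np.array([ll]), mean_log_likelihood=ll)
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    alleles, called = _allele_copies(genos)
    q_mean, ll = _gibbs(alleles, called, genos.geno, K, cfg, rng, fixed_q=fixed_q)
    q_mean = q_mean / q_mean.sum(axis=1, keepdims=True)
    return QMatrix(
        q=pd.DataFrame(q_mean, index=genos.accessions, columns=cols),
        log_likelihood=ll,
        mean_log_likelihood=float(ll.mean()),
    )


@dataclass
class EvannoTable:
    """Mean/sd of the log-likelihood per K and the ΔK statistic."""

    table: pd.DataFrame  # index K; columns mean_ll, sd_ll, delta_k
    best_k: int | None

    def to_dict(self) -> dict:
        return {
            "per_k": self.table.replace({np.nan: None}).to_dict(orient="index"),
            "best_k": self.best_k,
        }


def evanno_delta_k(runs_by_k: dict[int, list[QMatrix]]) -> EvannoTable:
    """ΔK = |L(K+1) - 2 L(K) + L(K-1)| / sd(L(K)) over run-mean likelihoods.

    Needs at least three consecutive K values with >= 2 runs each; a K
    with zero spread across runs has ΔK undefined (flagged NaN).
    """
    ks = sorted(runs_by_k)
    if len(ks) < 3 or ks != list(range(ks[0], ks[-1] + 1)):
        raise ValueError("need >= 3 consecutive K values")
    rows = {}
    for k in ks:
        lls = np.array([r.mean_log_likelihood for r in runs_by_k[k]])
        if lls.size < 2:
            raise ValueError(f"need >= 2 runs at K={k}")
        rows[k] = {"mean_ll": lls.mean(), "sd_ll": lls.std(ddof=1)}
    for k in ks:
        if k == ks[0] or k == ks[-1]:
            rows[k]["delta_k"] = np.nan
            continue
        sd = rows[k]["sd_ll"]
        if sd == 0:
            rows[k]["delta_k"] = np.nan
            continue
        rows[k]["delta_k"] = (
            abs(rows[k + 1]["mean_ll"] - 2.0 * rows[k]["mean_ll"] + rows[k - 1]["mean_ll"]) / sd
        )
    table = pd.DataFrame.from_dict(rows, orient="index")
    dk = table["delta_k"]
    best_k = int(dk.idxmax()) if dk.notna().any() else None
    return EvannoTable(table=table, best_k=best_k)


def align_and_average_runs(q_list: list[QMatrix], greedy: bool = False) -> QMatrix:
    """Label-align runs to the first and average (the CLUMPP step).

    Ancestry labels are arbitrary per run, so each run's columns are
    permuted to minimize the Frobenius distance to the first run
    (exhaustive over K! permutations for K <= 8; ``greedy`` required
    beyond).  Averaged rows are renormalized.
    """
    if not q_list:
        raise ValueError("no runs to average")
    K = q_list[0].K
    ref = q_list[0].q.to_numpy()
    index, cols = q_list[0].q.index, q_list[0].q.columns
    if K > 8 and not greedy:
        raise ValueError("K > 8: exhaustive permutation refused, pass greedy=True")
    total = np.zeros_like(ref)
    for run in q_list:
        if run.K != K or list(run.q.index) != list(index):
            raise ValueError("runs must share accessions and K")
        arr = run.q.to_numpy()
        if greedy and K > 8:
            perm = _greedy_perm(ref, arr)
        else:
            perm = min(
                permutations(range(K)),
                key=lambda p: float(((arr[:, list(p)] - ref) ** 2).sum()),
            )
        total += arr[:, list(perm)]
    avg = total / len(q_list)
    avg = avg / avg.sum(axis=1, keepdims=True)
    lls = np.array([r.mean_log_likelihood for r in q_list])
    return QMatrix(q=pd.DataFrame(avg, index=index, columns=cols),
                   mean_log_likelihood=float(np.nanmean(lls)))


def _greedy_perm(ref: np.ndarray, arr: np.ndarray) -> tuple[int, ...]:
    K = ref.shape[1]
    remaining = set(range(K))
    perm = []
    for k in range(K):
        best = min(remaining, key=lambda j: float(((arr[:, j] - ref[:, k]) ** 2).sum()))
        perm.append(best)
        remaining.remove(best)
    return tuple(perm)


def admixture_sweep(
    genos: GenotypeMatrix,
    cfg: McmcConfig | None = None,
    k_values: list[int] | None = None,
) -> tuple[dict[int, list[QMatrix]], dict[int, QMatrix], EvannoTable | None]:
    """Run n_runs independent chains per K; average per K; Evanno if possible."""
    cfg = cfg or McmcConfig()
    ks = k_values or list(range(cfg.k_range[0], cfg.k_range[1] + 1))
    seeds = np.random.SeedSequence(cfg.seed).spawn(len(ks) * cfg.n_runs)
    runs_by_k: dict[int, list[QMatrix]] = {}
    averaged: dict[int, QMatrix] = {}
    s = 0
    for k in ks:
        runs = []
        for _ in range(cfg.n_runs):
            runs.append(run_admixture(genos, k, cfg, seed=seeds[s].generate_state(1)[0] % (2**31)))
            s += 1
        runs_by_k[k] = runs
        averaged[k] = align_and_average_runs(runs)
    evanno = None
    if len(ks) >= 3 and cfg.n_runs >= 2 and ks == list(range(ks[0], ks[-1] + 1)):
        evanno = evanno_delta_k(runs_by_k)
    return runs_by_k, averaged, evanno


def supervised_assignment(
    genos: GenotypeMatrix,
    core_labels: dict[str, str],
    cfg: McmcConfig | None = None,
) -> QMatrix:
    """Classify accessions against fixed reference (core) populations.

    ``core_labels`` maps core accession IDs to population names; each
    core's ancestry is pinned to its population indicator so the
    population allele frequencies are anchored by the cores.  The
    remaining accessions' ancestries are sampled; ``n_runs`` independent
    chains are aligned (alignment is the identity here, since labels are
    anchored) and averaged.
    """
    pops = sorted(set(core_labels.values()))
    K = len(pops)
    if K < 1:
        raise ValueError("no core populations given")
    for p in pops:
        if sum(1 for v in core_labels.values() if v == p) < 2:
            raise ValueError(f"core population {p!r} needs >= 2 members")
    missing = [a for a in core_labels if a not in genos.accessions]
    if missing:
        raise ValueError(f"core accessions not in genotype matrix: {missing}")
    cfg = cfg or McmcConfig()
    fixed = np.full((genos.n_accessions, K), np.nan)
    pop_idx = {p: j for j, p in enumerate(pops)}
    for i, acc in enumerate(genos.accessions):
        if acc in core_labels:
            fixed[i] = 0.0
            fixed[i, pop_idx[core_labels[acc]]] = 1.0
    seeds = np.random.SeedSequence(cfg.seed).spawn(cfg.n_runs)
    runs = [
        run_admixture(genos, K, cfg, seed=sq.generate_state(1)[0] % (2**31), fixed_q=fixed)
        for sq in seeds
    ]
    avg = align_and_average_runs(runs)  # identity alignment; averaging only
    avg.q.columns = pops
    return avg
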