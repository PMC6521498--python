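import numpy as np
import pandas as pd
import pytest

from germpool.io import AccessionMetadata, GenotypeMatrix, Locus
from germpool.simulate import SimulationConfig, simulate_collection


def make_genotypes(rows: list[list[int]], accessions: list[str] | None = None) -> GenotypeMatrix:
    """Small genotype matrix from dosage rows (-1 = missing)."""
    rows = np.asarray(rows, dtype=np.int8)
    n_acc, n_loci = rows.shape
    accessions = accessions or [f"acc{i + 1}" for i in range(n_acc)]
    loci = [Locus(f"c{j + 1}", 10 * (j + 1), "A", "C") for j in range(n_loci)]
    return GenotypeMatrix(accessions=accessions, loci=loci, geno=rows)


@pytest.fixture(scope="session")
def pure_race_world():
    """Three pure diverged races, no hybrids: 60 accessions x 200 loci."""
    cfg = SimulationConfig(
        n_loci=200, race_sizes=(20, 20, 20), hybrid_specs=(), seed=5
    )
    pools, genos, meta, truth = simulate_collection(cfg)
    return {"config": cfg, "pools": pools, "genos": genos, "meta": meta, "truth": truth}


@pytest.fixture(scope="session")
def mixed_collection():
    """Race pools plus hybrid cultivars (the full collection shape), 300 loci."""
    cfg = SimulationConfig(n_loci=300, seed=11)
    pools, genos, meta, truth = simulate_collection(cfg)
    return {"config": cfg, "pools": pools, "genos": genos, "meta": meta, "truth": truth}
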