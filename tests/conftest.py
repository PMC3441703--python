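import numpy as np
import pandas as pd
import pytest

import nagblup as ng


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def hwe_matrix(rng, n, m, p_low=0.1, p_high=0.9):
    """Unrelated HWE individuals at uniform allele frequencies."""
    p = rng.uniform(p_low, p_high, m)
    dos = rng.binomial(2, p, size=(n, m)).astype(np.int8)
    return ng.GenotypeMatrix(
        [f"i{k}" for k in range(n)],
        [f"s{j}" for j in range(m)],
        dos,
        np.zeros((n, m), dtype=bool),
    ), p


@pytest.fixture
def hwe_genotypes(rng):
    g, _ = hwe_matrix(rng, 50, 40)
    return g


@pytest.fixture(scope="session")
def small_pipeline():
    """One small simulated dataset with fitted models, shared across tests.

    mvn-mode phenotypes over 200 reference + 80 test individuals, all four
    models fitted on the reference records.
    """
    cfg = ng.SimulationConfig(n_ref=200, n_test=80, m=400, n_founders=120,
                              litter_size=4, seed=777)
    g, meta = ng.simulate_genotypes(cfg)
    truth = ng.simulate_phenotypes(g, meta, cfg)
    mats = ng.build_relationship_matrices(g)
    pheno = truth.table[["individual_id", "phenotype", "litter", "is_reference"]].rename(
        columns={"phenotype": "dgc"}
    )
    fits = ng.fit_model_family(pheno, mats["additive"], mats["epistatic"], mats["dominance"])
    preds = ng.predict_model_family(
        fits, mats["additive"], mats["epistatic"], mats["dominance"], pheno
    )
    return {
        "cfg": cfg,
        "genotypes": g,
        "meta": meta,
        "truth": truth,
        "matrices": mats,
        "pheno": pheno,
        "fits": fits,
        "predictions": preds,
    }
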