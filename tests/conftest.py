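import numpy as np
import pandas as pd
import pytest

import leafqtl as lq


@pytest.fixture(scope="session")
def small_cross():
    """2 linkage groups x 20 markers at 5 cM, 179 progeny."""
    spec = lq.CrossSpec(
        n_progeny=179, linkage_groups=2, markers_per_group=20, marker_spacing=5.0, seed=11
    )
    return lq.simulate_cross(spec)


@pytest.fixture(scope="session")
def planted_scan(small_cross):
    """Phenotype with one planted testcross QTL of theoretical PVE 20%."""
    lmap, geno = small_cross
    marker = "m01_0010"
    if geno.marker_info.loc[marker, "seg_type"] != "testcross2":
        marker = next(
            m for m in geno.marker_ids
            if geno.marker_info.loc[m, "seg_type"] == "testcross2"
        )
    qtls = lq.QTLSpec(effects=[lq.QTLEffect("LA", marker, (0.0, 2.0))], residual_sd=2.0)
    pheno, truth = lq.simulate_phenotypes(geno, qtls, seed=21)
    return lmap, geno, pheno, truth, marker


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def pheno_three_modules(rng):
    """Correlated synthetic traits covering all three modules."""
    n = 120
    base = rng.normal(size=n)
    values = pd.DataFrame(
        {
            "LA": 100 + 30 * base + rng.normal(0, 10, n),
            "LP": 50 + 8 * base + rng.normal(0, 4, n),
            "Cir": 0.7 - 0.05 * base + rng.normal(0, 0.05, n),
            "LLo": np.clip(np.round(3 + base + rng.normal(0, 1, n)), 0, 8),
            "R": rng.normal(57, 10, n),
            "G": rng.normal(74, 15, n),
        },
        index=[f"F1_{i:03d}" for i in range(n)],
    )
    return lq.PhenotypeTable(values)
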