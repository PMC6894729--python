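import numpy as np
import pandas as pd
import pytest

from osteoqtl.containers import ExpressionMatrix, GeneSetCollection, GenotypeMatrix
from osteoqtl.simulate import SimulationConfig, simulate_genotypes


@pytest.fixture
def tiny_genotypes() -> GenotypeMatrix:
    """4 strains x 6 markers on two chromosomes, no missing calls."""
    markers = pd.DataFrame(
        {
            "chrom": ["1", "1", "1", "2", "2", "2"],
            "locus": ["m1", "m2", "m3", "m4", "m5", "m6"],
            "cM": [0.0, 5.0, 10.0, 0.0, 10.0, 20.0],
            "Mb": [0.0, 10.0, 20.0, 0.0, 20.0, 40.0],
        }
    )
    calls = np.array(
        [
            list("BBBBBB"),
            list("BBDDDB"),
            list("DDBBDD"),
            list("DDDDBD"),
        ]
    )
    return GenotypeMatrix(["s1", "s2", "s3", "s4"], markers, calls)


@pytest.fixture
def family_genotypes() -> GenotypeMatrix:
    """A 30-strain RI family on a small 3-chromosome map."""
    from osteoqtl.simulate import default_marker_map

    cfg = SimulationConfig(
        seed=11, n_strains=30, marker_map=default_marker_map(3, 20, 5.0), unknown_rate=0.0
    )
    return simulate_genotypes(cfg)


@pytest.fixture
def gene_sets() -> GeneSetCollection:
    return GeneSetCollection(
        {
            "GO:A": frozenset({"G1", "G2", "G3"}),
            "GO:B": frozenset({"G4", "G5"}),
        },
        {"GO:A": "set A", "GO:B": "set B"},
    )


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """8 probes x 6 strains with a planted coexpression pair (P1, P2)."""
    rng = np.random.default_rng(5)
    strains = [f"s{i}" for i in range(1, 7)]
    base = rng.normal(8, 1, 6)
    values = {
        "P1": base,
        "P2": base + 0.01 * rng.normal(size=6),  # near-duplicate of P1
    }
    for i in range(3, 9):
        values[f"P{i}"] = rng.normal(8, 1, 6)
    df = pd.DataFrame(values, index=strains).T
    pmap = pd.Series(
        {"P1": "G1", "P2": "G2", "P3": "G3", "P4": "G4", "P5": "G5",
         "P6": "G6", "P7": "G7", "P8": "G8"}
    )
    return ExpressionMatrix(df, pmap)


@pytest.fixture
def phenotype_table() -> pd.DataFrame:
    """Individual records for 3 strains x 2 sexes with a clean age trend."""
    rng = np.random.default_rng(2)
    rows = []
    k = 0
    for strain, shift in [("A", 0.0), ("B", 1.0), ("C", 2.0)]:
        for sex, sex_eff in [("F", 0.0), ("M", 0.5)]:
            for _ in range(4):
                k += 1
                age = rng.uniform(50, 375)
                value = 10 + shift + sex_eff + 2.0 * np.log10(age) + rng.normal(0, 0.1)
                rows.append((f"i{k}", strain, sex, age, 25.0, value))
    return pd.DataFrame(
        rows, columns=["animal", "strain", "sex", "age_days", "weight_g", "trait"]
    )
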