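import numpy as np
import pandas as pd
import pytest

import ewce


@pytest.fixture(scope="session")
def tiny_dataset():
    """Hand-built 4-gene x 8-cell dataset: 3 subtypes in 2 cell types.

    Subtype cell counts: A=3, B=3, C=2.  Values are small integers so every
    downstream mean is exact.
    """
    genes = ["g1", "g2", "g3", "g4"]
    cells = [f"c{i}" for i in range(1, 9)]
    counts = pd.DataFrame(
        [
            [2, 4, 0, 0, 0, 0, 0, 0],   # g1: marker of A (means 2, 0, 0)... cells c1,c2 in A
            [1, 1, 1, 3, 3, 3, 5, 5],   # g2: everywhere
            [0, 0, 0, 8, 8, 8, 0, 0],   # g3: marker of B
            [0, 0, 3, 0, 0, 0, 0, 1],   # g4: low expression
        ],
        index=genes,
        columns=cells,
        dtype=float,
    )
    subtype = pd.Series(
        ["A", "A", "A", "B", "B", "B", "C", "C"], index=cells
    )
    return ewce.SingleCellDataset(
        expression=counts,
        subtype_of_cell=subtype,
        celltype_of_subtype={"A": "N", "B": "N", "C": "G"},
    )


@pytest.fixture(scope="session")
def sim_reference():
    """Planted-marker synthetic reference plus its specificity matrices."""
    cfg = ewce.SimulationConfig(seed=11)
    ds, truth = ewce.simulate_sct(cfg)
    sub, cell = ewce.specificity_from_dataset(ds)
    background = ewce.build_background(sub, [])
    return {
        "config": cfg,
        "dataset": ds,
        "truth": truth,
        "subtype_spec": sub,
        "celltype_spec": cell,
        "background": background,
    }


@pytest.fixture(scope="session")
def dyadic_spec():
    """6 genes x 3 groups with exactly representable (dyadic) specificities.

    Row sums are exactly 1 in binary floating point, so summed specificities
    of gene pairs are exact and enumeration oracles are tie-safe.
    """
    values = pd.DataFrame(
        [
            [0.50, 0.25, 0.25],
            [0.75, 0.125, 0.125],
            [0.25, 0.50, 0.25],
            [0.125, 0.75, 0.125],
            [0.25, 0.25, 0.50],
            [0.125, 0.125, 0.75],
        ],
        index=[f"g{i}" for i in range(1, 7)],
        columns=["A", "B", "C"],
    )
    return ewce.SpecificityMatrix(values=values, level="subtype")


def enumeration_pvalues(spec, background_genes, target, continuity=False):
    """Independent oracle: exact p per group by enumerating all n-subsets."""
    from itertools import combinations

    n = len(target)
    t_gamma = spec.values.loc[list(target)].sum(axis=0)
    subsets = list(combinations(background_genes, n))
    counts = pd.Series(0, index=spec.values.columns)
    for subset in subsets:
        g = spec.values.loc[list(subset)].sum(axis=0)
        counts += (g >= t_gamma).astype(int)
    if continuity:
        return (counts + 1) / (len(subsets) + 1)
    return counts / len(subsets)
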