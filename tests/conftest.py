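import numpy as np
import pandas as pd
import pytest

from cerna.expression import ExpressionMatrix
from cerna.interactions import TargetMap


def write_tsv(path, rows, header=("mirna", "target")):
    with open(path, "w") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return path


@pytest.fixture
def tiny_maps():
    """Hand-built target maps with a known overlap structure."""
    lnc = TargetMap(
        "lncRNA",
        {
            "LNCA": frozenset({"m1", "m2", "m3", "m4", "m5"}),
            "LNCB": frozenset({"m6", "m7"}),
        },
    )
    mrna = TargetMap(
        "mRNA",
        {
            "GENE1": frozenset({"m1", "m2", "m3", "m4", "m8"}),
            "GENE2": frozenset({"m9"}),
        },
    )
    return lnc, mrna


@pytest.fixture
def small_matrix():
    """4 genes x 8 samples, two groups, one correlated lnc-mRNA pair."""
    rng = np.random.default_rng(7)
    n = 8
    z = rng.standard_normal(n)
    rows = np.vstack(
        [
            np.exp(z),
            np.exp(z + 0.05 * rng.standard_normal(n)),
            np.exp(rng.standard_normal(n)),
            np.exp(rng.standard_normal(n)),
        ]
    )
    values = pd.DataFrame(
        rows,
        index=["LNC1", "MRNA1", "LNC2", "MRNA2"],
        columns=[f"s{i}" for i in range(n)],
    )
    labels = {f"s{i}": ("g1" if i < 4 else "g2") for i in range(n)}
    classes = {"LNC1": "lncRNA", "LNC2": "lncRNA", "MRNA1": "mRNA", "MRNA2": "mRNA"}
    return ExpressionMatrix(values=values, gene_class=classes), labels
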