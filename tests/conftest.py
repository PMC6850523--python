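import numpy as np
import pandas as pd
import pytest

from lenbias import CountMatrix, GeneAnnotation, generate_dataset, preset_small_study


def make_counts(values, gene_ids=None, sample_ids=None, conditions=None, replicates=None):
    """Small CountMatrix builder for fixtures."""
    values = np.asarray(values)
    n, s = values.shape
    gene_ids = gene_ids or [f"g{i+1}" for i in range(n)]
    sample_ids = sample_ids or [f"s{j+1}" for j in range(s)]
    conditions = conditions or ["A"] * s
    if replicates is None:
        seen = {}
        replicates = []
        for c in conditions:
            seen[c] = seen.get(c, 0) + 1
            replicates.append(seen[c])
    return CountMatrix(
        pd.DataFrame(values, index=gene_ids, columns=sample_ids),
        pd.Series(conditions, index=sample_ids),
        pd.Series(replicates, index=sample_ids),
    )


def make_annotation(lengths, gc=None, gene_ids=None):
    gene_ids = gene_ids or [f"g{i+1}" for i in range(len(lengths))]
    table = pd.DataFrame({"length_bp": lengths}, index=gene_ids)
    if gc is not None:
        table["gc_fraction"] = gc
    return GeneAnnotation(table)


@pytest.fixture(scope="session")
def preset_dataset():
    """One realization of the documented preset, shared across tests."""
    return generate_dataset(preset_small_study(seed=7))
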