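import numpy as np
import pandas as pd
import pytest

from nifsip.sip import FractionTable


def make_fraction_table(
    counts: np.ndarray,
    densities,
    condition: str,
    taxa=None,
    unfractionated=None,
) -> FractionTable:
    """Assemble a FractionTable from bare arrays (test convenience)."""
    counts = np.asarray(counts)
    taxa = taxa or [f"t{i + 1}" for i in range(counts.shape[0])]
    cols = [f"{condition[0].upper()}_F{j + 1:02d}" for j in range(counts.shape[1])]
    return FractionTable(
        counts=pd.DataFrame(counts, index=taxa, columns=cols),
        densities=pd.Series(list(densities), index=cols),
        condition=condition,
        unfractionated=None
        if unfractionated is None
        else pd.Series(list(unfractionated), index=taxa),
    )


@pytest.fixture
def two_leaf_tree():
    from nifsip.placement import ReferenceTree

    # A sits on a 0.10 branch, B on 0.20, joined at the root
    return ReferenceTree.from_newick("(A:0.10,B:0.20);")
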