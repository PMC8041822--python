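import numpy as np
import pandas as pd
import pytest

from coevo.alignment import LabeledAlignment


def make_alignment(rows, labels=None, subtypes=None, species=None,
                   families=None, ids=None):
    """Small LabeledAlignment from a list of sequence strings."""
    n = len(rows)
    ids = ids or [f"s{i}" for i in range(n)]
    labels = labels or [f"p{j}" for j in range(len(rows[0]))]
    meta = pd.DataFrame({
        "subtype": subtypes or ["st"] * n,
        "species": species or ["sp"] * n,
        "protein_family": families or ["fam"] * n,
    }, index=pd.Index(ids, name="seq_id"))
    matrix = np.array([list(r) for r in rows], dtype="<U1")
    return LabeledAlignment(ids, matrix, labels, meta)


@pytest.fixture
def toy_alignment():
    return make_alignment(["ARNDC", "ARNDC", "GRNEC", "ARKDC"])


@pytest.fixture(scope="session")
def small_family():
    """Reduced synthetic receptor/G-alpha family pair for integration tests."""
    from coevo.simulate import SyntheticSpec, generate_families
    spec = SyntheticSpec(n_subtypes_r=8, seqs_per_subtype=25, n_pos_r=60,
                         n_pos_g=40, n_conserved_r=6, n_coevolved_r=12,
                         n_selectivity_r=3, n_conserved_g=6, n_coevolved_g=8,
                         n_selectivity_g=3,
                         coupling_map={f"R{k + 1:02d}":
                                       ("Gi/o", "Gq/11", "Gs", "G12/13")[k % 4:k % 4 + 1]
                                       for k in range(8)},
                         seed=11)
    return generate_families(spec)
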