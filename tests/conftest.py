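import numpy as np
import pandas as pd
import pytest

from igdom.alignment import Alignment, LabeledAlignment


def make_labeled(ids_rows, isotype=None, animal_class=None, domain_kind=None):
    """Build a LabeledAlignment from {id: row} plus optional per-id label dicts."""
    ids = list(ids_rows)
    rows = [ids_rows[i] for i in ids]
    labels = pd.DataFrame(
        {
            "isotype": [(isotype or {}).get(i, "IgG") for i in ids],
            "animal_class": [(animal_class or {}).get(i, "Mammalia") for i in ids],
            "domain_kind": [(domain_kind or {}).get(i, "CH3") for i in ids],
        },
        index=pd.Index(ids, name="id"),
    )
    return LabeledAlignment(Alignment(ids=ids, rows=rows), labels)


@pytest.fixture
def rng():
    return np.random.default_rng(20230801)


def random_alignment(rng, n, L, alphabet="ACDEFGHIKLMNPQRSTVWY", gap_rate=0.0):
    symbols = np.array(list(alphabet))
    arr = rng.choice(symbols, size=(n, L))
    if gap_rate:
        arr[rng.random((n, L)) < gap_rate] = "-"
    return Alignment(ids=[f"s{i}" for i in range(n)], rows=["".join(r) for r in arr])
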