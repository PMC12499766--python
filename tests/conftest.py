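import numpy as np
import pytest

from grape.data_io import InteractionRecord
from grape.embeddings import EmbedderSpec, embed_sequences

AA = "ACDEFGHIKLMNPQRSTVWY"


def random_records(rng, n_tcr=12, n_epitope=4, n_rows=30, p_pos=0.6):
    """Random labeled pair table over small synthetic sequence pools."""
    tcrs = ["C" + "".join(rng.choice(list(AA), size=8)) + "F"
            for _ in range(n_tcr)]
    epis = ["".join(rng.choice(list(AA), size=9)) for _ in range(n_epitope)]
    seen, records = set(), []
    while len(records) < n_rows and len(seen) < n_tcr * n_epitope:
        t = tcrs[int(rng.integers(n_tcr))]
        e = epis[int(rng.integers(n_epitope))]
        if (t, e) in seen:
            continue
        seen.add((t, e))
        records.append(InteractionRecord(t, e, int(rng.random() < p_pos)))
    return records


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def small_records(rng):
    return random_records(rng)


@pytest.fixture
def small_spec():
    # narrow embedding keeps the desk-scale encoder tests fast
    return EmbedderSpec(width=48, k=2)


@pytest.fixture
def small_embeddings(small_records, small_spec):
    seqs = [r.tcr for r in small_records] + [r.epitope for r in small_records]
    return embed_sequences(seqs, small_spec)
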