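import numpy as np
import pytest

from deepcoral.datamodel import AlignedSequence, Alignment, BASINS


def make_alignment(seqs, marker="test", **meta_per_row):
    """Build an Alignment from raw strings; meta_per_row maps field -> list."""
    rows = []
    for i, s in enumerate(seqs):
        kwargs = {k: v[i] for k, v in meta_per_row.items()}
        rows.append(AlignedSequence(seq_id=f"s{i + 1}", symbols=s, **kwargs))
    return Alignment(rows=tuple(rows), marker_name=marker)


def random_alignment(rng, n_rows=6, n_cols=20, alphabet="ACGT-RN", dup_prob=0.3):
    """Random alignment with deliberate duplicate rows and messy symbols."""
    seqs = []
    for _ in range(n_rows):
        if seqs and rng.random() < dup_prob:
            seqs.append(seqs[rng.integers(len(seqs))])
        else:
            seqs.append("".join(rng.choice(list(alphabet), size=n_cols)))
    return make_alignment(seqs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def aln_builder():
    return make_alignment
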