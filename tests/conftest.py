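import numpy as np
import pytest
from hypothesis import settings

from clonocna.models import Clonotype, Rearrangement, SampleRepertoire

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


def make_repertoire(freqs, sample_id="s1", group=None, genes=None, cdr3s=None, total_reads=100000):
    """Build a SampleRepertoire with the given frequency vector."""
    n = len(freqs)
    genes = genes or [f"TRBV{i+1}" for i in range(n)]
    cdr3s = cdr3s or [f"CASS{_alpha(i)}F" for i in range(n)]
    order = sorted(range(n), key=lambda i: -freqs[i])
    clonotypes = []
    for rank, i in enumerate(order, start=1):
        clonotypes.append(
            Clonotype(
                sample_id=sample_id,
                v_gene=genes[i],
                cdr3_aa=cdr3s[i],
                read_count=max(1, round(freqs[i] * total_reads)),
                frequency=freqs[i],
                rank=rank,
            )
        )
    return SampleRepertoire(
        sample_id=sample_id,
        clonotypes=clonotypes,
        group_label=group,
        n_reads_kept=sum(c.read_count for c in clonotypes),
    )


def _alpha(i: int) -> str:
    letters = "ACDEFGHIKLMNPQRSTVWY"
    s = ""
    i += 1
    while i:
        s = letters[i % 20] + s
        i //= 20
    return s


def make_read(sample_id="s1", v_call="TRBV12-3*01", cdr3="CASSLKF",
              productive=True, v_identity=98.0, count=1, seq_id="r1"):
    return Rearrangement(
        sample_id=sample_id, sequence_id=seq_id, v_call=v_call,
        d_call="TRBD1*01", j_call="TRBJ2-1*01", cdr3_aa=cdr3,
        productive=productive, v_identity=v_identity, duplicate_count=count,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def twelve_count_repertoire():
    """The 12-clonotype fixture with read counts [30,20,10,8,7,6,5,4,3,3,2,2]."""
    counts = [30, 20, 10, 8, 7, 6, 5, 4, 3, 3, 2, 2]
    total = sum(counts)
    return make_repertoire([c / total for c in counts], total_reads=total)
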