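import pytest

from cladeprimer.seq_io import Alignment, SequenceRecord
from cladeprimer.synthetic import GeneratorConfig, simulate_pool


@pytest.fixture(scope="session")
def small_pool():
    """Four clades at realistic divergences, with outgroup; used by several
    tree/collection tests."""
    cfg = GeneratorConfig(
        clade_sizes={"CladeA": 16, "CladeB": 10, "CladeC": 10, "CladeD": 10},
        alignment_length=600,
        rng_seed=3,
    )
    return simulate_pool(cfg)


@pytest.fixture(scope="session")
def classifier_pool():
    """Five clades for classifier training/holdout."""
    cfg = GeneratorConfig(
        clade_sizes={
            "CladeA": 30, "CladeB": 25, "CladeC": 25, "CladeD": 20, "CladeE": 20
        },
        alignment_length=900,
        include_outgroup=False,
        rng_seed=11,
    )
    return simulate_pool(cfg)


def make_alignment(seqs: dict[str, str], labels: dict[str, str] | None = None):
    labels = labels or {}
    return Alignment(
        tuple(
            SequenceRecord(id=k, residues=v, taxon_label=labels.get(k))
            for k, v in seqs.items()
        )
    )
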