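import pytest

from txselect.scoring import (
    FeatureKey,
    HintCollection,
    Hyperparameters,
    PredictedTranscript,
)


@pytest.fixture
def params() -> Hyperparameters:
    return Hyperparameters()


def make_tx(
    tx_id="t1",
    gene_id="g1",
    seqname="chr1",
    strand="+",
    cds=((100, 200), (300, 400)),
    **kw,
):
    return PredictedTranscript(
        tx_id=tx_id, gene_id=gene_id, seqname=seqname, strand=strand, cds=tuple(cds), **kw
    )


def make_hints(*entries, seqname="chr1", strand="+"):
    """entries: (kind, start, end, src, mult) tuples."""
    hints = HintCollection()
    for kind, start, end, src, mult in entries:
        hints.add(FeatureKey(seqname, start, end, kind, strand), src, mult)
    return hints


@pytest.fixture
def mk_tx():
    return make_tx


@pytest.fixture
def mk_hints():
    return make_hints
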