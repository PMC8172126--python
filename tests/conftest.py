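import numpy as np
import pandas as pd
import pytest

from lncnet.models import GenomicInterval, TranscriptModel, genes_from_transcripts


def make_transcript(tid, exons, strand="+", chrom="chr1", gene=None, biotype="coding"):
    return TranscriptModel(
        tid,
        gene or tid,
        [GenomicInterval(chrom, s, e, strand) for s, e in exons],
        biotype=biotype,
    )


@pytest.fixture
def coding_gene():
    """One coding gene: 3 exons of 400 bp separated by 3 kb introns, '+'.

    Span 10000-17200; exons 10000-10400, 13400-13800, 16800-17200.
    """
    t = make_transcript(
        "mrnaA", [(10000, 10400), (13400, 13800), (16800, 17200)], "+", gene="geneA"
    )
    return genes_from_transcripts([t])[0]


@pytest.fixture
def design_3v3():
    return pd.DataFrame(
        {
            "sample_id": ["IV_1", "IV_2", "IV_3", "V_1", "V_2", "V_3"],
            "stage": ["IV"] * 3 + ["V"] * 3,
            "replicate": [1, 2, 3, 1, 2, 3],
        }
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
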