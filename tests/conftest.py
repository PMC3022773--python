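from __future__ import annotations

import pytest

from vlincseq.models import TranscriptModel
from vlincseq.studies import (
    run_domain_recovery_replicates,
    run_mixture_recovery,
    run_negative_control,
)


@pytest.fixture()
def toy_transcripts():
    """Two genes on chr1: one 3-exon gene and one single-exon gene."""
    return [
        TranscriptModel(
            transcript_id="geneA",
            chrom="chr1",
            strand="+",
            start=1_000,
            end=10_000,
            exon_starts=(1_000, 4_000, 9_000),
            exon_ends=(2_000, 5_000, 10_000),
        ),
        TranscriptModel(
            transcript_id="geneB",
            chrom="chr1",
            strand="-",
            start=20_000,
            end=21_000,
            exon_starts=(20_000,),
            exon_ends=(21_000,),
        ),
    ]


# Session-scoped: these simulations back several tests each; running them
# once keeps the suite fast without changing the study conditions.

@pytest.fixture(scope="session")
def domain_recovery_replicates():
    return run_domain_recovery_replicates(seed=7, n_replicates=5)


@pytest.fixture(scope="session")
def negative_control_domains():
    return run_negative_control(seed=7)


@pytest.fixture(scope="session")
def mixture_recovery_result():
    return run_mixture_recovery(seed=11)
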