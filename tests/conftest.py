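from __future__ import annotations

import numpy as np
import pytest

from nmdpipe.synthetic import SyntheticSpec, gen_genome_and_transcripts
from nmdpipe.transcript_models import Genome, MrnaMap, TranscriptModel


@pytest.fixture(scope="session")
def demo_annotation():
    """Mid-sized synthetic genome shared by read-only tests."""
    return gen_genome_and_transcripts(SyntheticSpec(seed=11, n_transcripts=150))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_single_exon_map(tid: str, length: int, junctions: tuple[int, ...] = ()):
    """MrnaMap for a transcript laid out contiguously from genomic position 0."""
    return MrnaMap(
        transcript_id=tid,
        mrna_length=length,
        junctions=junctions,
        genomic_positions=np.arange(length, dtype=np.int64),
    )


def make_transcript(exons, strand="+", tid="t1", biotype="protein_coding"):
    return TranscriptModel(
        transcript_id=tid,
        gene_id="g1",
        chrom="chrI",
        strand=strand,
        exons=tuple(exons),
        biotype=biotype,
    )


def random_genome(rng: np.random.Generator, length: int = 2000) -> Genome:
    bases = np.array(list("ACGT"))
    return Genome({"chrI": "".join(bases[rng.integers(0, 4, size=length)])})
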