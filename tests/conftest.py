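import numpy as np
import pytest
from hypothesis import settings

from pafinder.io_formats import SequencingRead

settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")


def make_read(bases: str, q: int = 37, read_id: str = "r") -> SequencingRead:
    return SequencingRead(read_id, bases, np.full(len(bases), q, dtype=np.int16))


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def toy_gtf(tmp_path):
    """Two genes on one chromosome, opposite strands, UTRs implicit.

    gene1 (+): exons [100,200) and [300,500), CDS [150,200)+[300,400)
               -> 5'UTR [100,150), 3'UTR [400,500), intron [200,300), TTS 499.
    gene2 (-): exon [600,800), CDS [650,750)
               -> 3'UTR [600,650), 5'UTR [750,800), TTS 600.
    (all 0-based half-open; the GTF below is 1-based inclusive)
    """
    lines = []

    def row(chrom, feat, start0, end0, strand, gid, tid=None):
        attrs = f'gene_id "{gid}";'
        if tid:
            attrs += f' transcript_id "{tid}";'
        lines.append("\t".join(
            [chrom, "test", feat, str(start0 + 1), str(end0), ".", strand, ".", attrs]))

    row("chr1", "gene", 100, 500, "+", "gene1")
    row("chr1", "transcript", 100, 500, "+", "gene1", "gene1.t1")
    row("chr1", "exon", 100, 200, "+", "gene1", "gene1.t1")
    row("chr1", "exon", 300, 500, "+", "gene1", "gene1.t1")
    row("chr1", "CDS", 150, 200, "+", "gene1", "gene1.t1")
    row("chr1", "CDS", 300, 400, "+", "gene1", "gene1.t1")
    row("chr1", "gene", 600, 800, "-", "gene2")
    row("chr1", "transcript", 600, 800, "-", "gene2", "gene2.t1")
    row("chr1", "exon", 600, 800, "-", "gene2", "gene2.t1")
    row("chr1", "CDS", 650, 750, "-", "gene2", "gene2.t1")
    path = tmp_path / "toy.gtf"
    path.write_text("\n".join(lines) + "\n")
    return path
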