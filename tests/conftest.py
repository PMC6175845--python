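import pytest

from protohap.genome_model import GenomeSequence, TranscriptModel
from protohap.synthetic_data import SimulationConfig, build_toy_reference


def write(path, text):
    path.write_text(text)
    return str(path)


@pytest.fixture(scope="session")
def toy():
    """Toy reference: 2-exon + strand, 3-exon - strand, single-exon transcripts."""
    return build_toy_reference(SimulationConfig(seed=11))


@pytest.fixture(scope="session")
def toy_paths(toy, tmp_path_factory):
    d = tmp_path_factory.mktemp("toyref")
    return {
        "fasta": write(d / "ref.fa", toy.fasta_text),
        "gff": write(d / "models.gff3", toy.gff_text),
    }


@pytest.fixture(scope="session")
def toy_genome(toy):
    return toy.genome


@pytest.fixture()
def simple_plus_transcript():
    """chr1 = ATG AAA CCC TAA fully coding on the + strand."""
    return (
        TranscriptModel(
            transcript_id="T1",
            gene_id="G1",
            chrom="chr1",
            strand=1,
            exons=((1, 12),),
            cds_intervals=((1, 12),),
            display_name="T1-001",
        ),
        GenomeSequence({"chr1": "ATGAAACCCTAA"}),
    )
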