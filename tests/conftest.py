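import numpy as np
import pytest

from lncannotate.fixtures import ToySizes, make_toy_world
from lncannotate.pipeline import run_all


@pytest.fixture(scope="session")
def toy_world_dir(tmp_path_factory):
    """The default toy world, written to disk once per session."""
    out = tmp_path_factory.mktemp("toy_world")
    world = make_toy_world(seed=1, out_dir=out)
    return world, out


def world_config(world_dir):
    return {
        "transcripts_fasta": str(world_dir / "transcripts.fasta"),
        "alignments_gff3": str(world_dir / "alignments.gff3"),
        "annotation_gff3": str(world_dir / "annotation.gff3"),
        "te_gff3": str(world_dir / "te.gff3"),
        "predictions_tsv": str(world_dir / "predictions.tsv"),
        "library_fasta": str(world_dir / "lncrna_library.fasta"),
        "species_map_tsv": str(world_dir / "library_species.tsv"),
        "expression_tsv": str(world_dir / "expression.tsv"),
        "library_meta_tsv": str(world_dir / "libraries.tsv"),
        "chrom_lengths_tsv": str(world_dir / "chrom_lengths.tsv"),
    }


@pytest.fixture(scope="session")
def pipeline_out(toy_world_dir, tmp_path_factory):
    """Full pipeline run over the toy world."""
    world, world_dir = toy_world_dir
    out = tmp_path_factory.mktemp("pipeline_out")
    run_all(world_config(world_dir), out)
    return world, world_dir, out


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
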