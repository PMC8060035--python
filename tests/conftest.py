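import numpy as np
import pytest

from termtk.io_formats import CoverageTrack, GenomeSeq
from termtk.synthetic_data import (
    SimulationConfig,
    generate_genome_with_truth,
    simulate_rnet,
    simulate_tracks,
)
from termtk.termination_metrics import STRAINS


@pytest.fixture(scope="session")
def clean_config():
    return SimulationConfig(
        genome_length=30_000, n_terminators=10, depth=200.0, noise="none", seed=7
    )


@pytest.fixture(scope="session")
def clean_world(clean_config):
    """A small noiseless simulated dataset shared across test modules."""
    genome, truth = generate_genome_with_truth(clean_config)
    tracks = {s: simulate_tracks(genome, truth, s, clean_config) for s in STRAINS}
    rnet = {
        s: simulate_rnet(genome, truth, s, clean_config) for s in ("WT", "dnusG")
    }
    return {
        "config": clean_config,
        "genome": genome,
        "truth": truth,
        "tracks": tracks,
        "rnet": rnet,
    }


def make_track(values, strand="+", kind="rnaseq", genome_id="g"):
    return CoverageTrack(
        genome_id=genome_id, strand=strand, kind=kind, values=np.asarray(values, float)
    )


def make_genome(seq, gid="g"):
    return GenomeSeq(id=gid, sequence=seq)
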