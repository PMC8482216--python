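from __future__ import annotations

import pytest
from hypothesis import settings

from snoscout.pipeline import PipelineConfig
from snoscout.synthetic_data import (
    SimulationConfig,
    SyntheticDataset,
    generate_genome,
    simulate_dataset,
)

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=60)
settings.load_profile("ci")


def small_sim_config(seed: int = 11) -> SimulationConfig:
    """A scaled-down dataset for fast unit tests: 9 planted snoRNAs over a
    60 kb genome (the full-size study conditions live in the defaults and are
    exercised by the acceptance tests)."""
    return SimulationConfig(
        seed=seed,
        genome_length=60_000,
        n_genes=4,
        exons_per_gene=3,
        n_cd=3,
        n_haca=3,
        n_sca=3,
        n_decoys=3,
        n_intergenic=2,
        n_tu_hosted=2,
        background_reads=50,
        n_samples=8,
    )


@pytest.fixture(scope="session")
def small_dataset() -> SyntheticDataset:
    return generate_genome(small_sim_config())


@pytest.fixture(scope="session")
def small_paths(tmp_path_factory) -> dict:
    outdir = tmp_path_factory.mktemp("smalldata")
    return simulate_dataset(small_sim_config(), outdir)


@pytest.fixture()
def small_pipeline_config(small_paths) -> PipelineConfig:
    return PipelineConfig(
        genome=str(small_paths["genome"]),
        annotation=str(small_paths["annotation"]),
        alignments=str(small_paths["medium_alignments"]),
        total_alignments=str(small_paths["total_alignments"]),
        candidate_counts=str(small_paths["candidate_counts"]),
        host_counts=str(small_paths["host_counts"]),
        reference=str(small_paths["reference"]),
        seed=11,
    )
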