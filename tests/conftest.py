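import os

import pytest

from srnapipe.pipeline import RunConfig, run_all
from srnapipe.simulate import SimConfig, TruthManifest, write_dataset


def _run(tmp_path, sim_config: SimConfig):
    paths = write_dataset(str(tmp_path), sim_config)
    cfg = RunConfig(
        genome_fasta=paths["genome"],
        genes_gff=paths["genes"],
        repeats=paths["repeats"],
        ncrna_bed=paths["ncrna"],
        ncrna_ref=paths["ncrna_ref"],
        known_mirnas=paths["known_mirnas"],
        go_map=paths["go_map"],
        reads_454=paths["reads_454"],
        reads_solid={"EF": paths["reads_EF"], "EC": paths["reads_EC"]},
        truth=paths["truth"],
        out_dir=os.path.join(str(tmp_path), "out"),
    )
    results = run_all(cfg)
    results["paths"] = paths
    results["truth_manifest"] = TruthManifest.read(paths["truth"])
    results["sim_config"] = sim_config
    return results


@pytest.fixture(scope="session")
def clean_run(tmp_path_factory):
    """Default synthetic experiment (seed 17, zero color error) run
    end-to-end through every stage."""
    return _run(tmp_path_factory.mktemp("clean"), SimConfig())


@pytest.fixture(scope="session")
def noisy_run(tmp_path_factory):
    """Same design with a 2% per-color error rate."""
    return _run(
        tmp_path_factory.mktemp("noisy"), SimConfig(color_error_rate=0.02)
    )


@pytest.fixture(scope="session")
def sim_genome():
    """Genome bundle + truth manifest only (no reads, no pipeline)."""
    from srnapipe.simulate import generate_genome

    return generate_genome(SimConfig())
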