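import pytest

from mirforge.annotate import GenomeIndex, annotation_count_matrix, classify_tags
from mirforge.diffexpr import CountMatrix
from mirforge.preprocess import RETAINED, PreprocessConfig, preprocess_samples
from mirforge.synthetic_data import SimulationConfig, simulate_library


@pytest.fixture(scope="session")
def small_sim(tmp_path_factory):
    """A reduced-depth synthetic study shared across tests (8k reads/library
    keeps the whole suite fast; the study design is otherwise the default)."""
    config = SimulationConfig(seed=1, reads_per_library=8000)
    return simulate_library(config, tmp_path_factory.mktemp("sim"))


@pytest.fixture(scope="session")
def small_run(small_sim):
    """Preprocess + annotate + count-matrix results for the shared study."""
    config = PreprocessConfig(
        adapter=small_sim.manifest["config"]["adapter"],
        contaminant_sets={k: str(v) for k, v in small_sim.contaminants.items()},
    )
    tags, ledger = preprocess_samples(small_sim.fastq, config)
    retained = [t for t in tags if t.disposition == RETAINED]
    annotations = classify_tags(
        retained,
        small_sim.precursors,
        small_sim.xeno_precursors,
        GenomeIndex(small_sim.genome),
    )
    counts = annotation_count_matrix(annotations, retained)
    matrix = CountMatrix(counts, small_sim.sample_groups)
    return {
        "sim": small_sim,
        "tags": tags,
        "retained": retained,
        "ledger": ledger,
        "annotations": annotations,
        "counts": counts,
        "matrix": matrix,
    }
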