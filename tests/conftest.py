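import numpy as np
import pytest

from noveltx.coding import train_coding_model, train_cpc_proxy
from noveltx.model import AnnotationIndex, GenomicInterval, TranscriptModel
from noveltx.pipeline import PipelineInputs, PipelineOptions, run_classify
from noveltx.simulate import SimulationConfig, generate_all, simulate, training_corpus

#: Fixture seed used throughout the suite (chosen once, up front).
SEED = 11


@pytest.fixture(scope="session")
def noiseless_config():
    return SimulationConfig.noiseless(seed=SEED)


@pytest.fixture(scope="session")
def sim(noiseless_config):
    """In-memory noiseless simulation shared across tests."""
    return simulate(noiseless_config)


@pytest.fixture(scope="session")
def sim_paths(noiseless_config, tmp_path_factory):
    outdir = tmp_path_factory.mktemp("sim")
    return generate_all(noiseless_config, outdir)


@pytest.fixture(scope="session")
def pipeline_result(sim_paths, tmp_path_factory):
    inputs = PipelineInputs(
        assembly_gtf=sim_paths["assembly"],
        reference_gtf=sim_paths["reference"],
        predicted_gtf=sim_paths["predicted"],
        genome_fasta=sim_paths["genome"],
        expression_tsv=sim_paths["expression"],
        inter_hits_tsv=sim_paths["inter_hits"],
        intra_hits_tsv=sim_paths["intra_hits"],
        contexts_tsv=sim_paths["contexts"],
    )
    outdir = tmp_path_factory.mktemp("run")
    manifest, classified, summaries = run_classify(
        inputs, PipelineOptions(seed=SEED), outdir=outdir
    )
    return manifest, classified, summaries, outdir


@pytest.fixture(scope="session")
def corpora():
    return training_corpus(SEED, n_per_class=60)


@pytest.fixture(scope="session")
def cpat_scorer(corpora):
    coding, noncoding = corpora
    return train_coding_model(coding, noncoding, seed=SEED)


@pytest.fixture(scope="session")
def cpc_scorer(corpora):
    coding, noncoding = corpora
    return train_cpc_proxy(coding, noncoding, seed=SEED)


@pytest.fixture()
def rng():
    return np.random.default_rng(SEED)


@pytest.fixture(scope="session")
def toy_reference():
    """Two genes on chr1 (one plus, one minus) and one on chr2."""
    def tx(tid, locus, chrom, strand, blocks):
        return TranscriptModel(
            tid, locus,
            tuple(GenomicInterval(chrom, s, e, strand) for s, e in blocks),
            "reference",
        )

    transcripts = [
        tx("R1.1", "L1", "chr1", "+", [(1000, 1200), (1800, 2000), (2600, 2900)]),
        tx("R2.1", "L2", "chr1", "-", [(7000, 7300), (8000, 8400)]),
        tx("R3.1", "L3", "chr2", "+", [(500, 900)]),
    ]
    return AnnotationIndex(transcripts)
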