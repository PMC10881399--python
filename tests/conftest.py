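import numpy as np
import pytest

from funcmotif import load_jaspar, packaged_motifs_path
from funcmotif.pipeline import PipelineConfig, run_end_to_end


@pytest.fixture(scope="session")
def pwms():
    return load_jaspar(str(packaged_motifs_path()))


@pytest.fixture(scope="session")
def default_run(tmp_path_factory):
    """One full end-to-end run of the default synthetic configuration.

    Shared across tests that examine different facets of the same run
    (classifier quality, calibration, recovery, persisted outputs).
    """
    out = tmp_path_factory.mktemp("pipeline_run")
    config = PipelineConfig().with_seed(1)
    report = run_end_to_end(config, str(out))
    return {"config": config, "report": report, "out": out}


def tiny_pipeline_config(seed: int = 3) -> PipelineConfig:
    """A minutes-free pipeline config for determinism/plumbing tests."""
    import dataclasses

    from funcmotif.classifier import ClassifierConfig
    from funcmotif.synthetic import SyntheticGenomeConfig, SyntheticPeakSetConfig

    lengths = {**{f"chr{i}": 30_000 for i in range(1, 10)},
               "chrX": 10_000, "chrY": 5_000}
    config = PipelineConfig(
        genome=SyntheticGenomeConfig(chromosome_lengths=lengths),
        peaks=SyntheticPeakSetConfig(n_active_peaks=60, n_inactive_peaks=60),
        classifier=ClassifierConfig(epochs=3, patience=3),
        n_background_windows=5000,
    )
    return config.with_seed(seed)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_windows(rng, n, length=300):
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    return [
        bases[rng.integers(0, 4, length)].tobytes().decode() for _ in range(n)
    ]
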