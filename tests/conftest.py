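import numpy as np
import pandas as pd
import pytest

from teleoarray.dataset import ExpressionDataset
from teleoarray.simulate import SimulationConfig, simulate_transcriptome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(
        seed=11, n_transcripts=60, n_antisense_pairs=6, n_de_genes=8
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return simulate_transcriptome(small_config)


def make_dataset(
    intensities: np.ndarray,
    flags: np.ndarray | None = None,
    probe_ids=None,
    conditions=("normal", "normal", "deformed", "deformed"),
    stage: int = 58,
    spike_ids=(),
) -> ExpressionDataset:
    """Hand-rolled dataset helper for unit tests."""
    intensities = np.asarray(intensities, dtype=float)
    n_probes, n_samples = intensities.shape
    if probe_ids is None:
        probe_ids = [f"T{i:03d}_1" for i in range(n_probes)]
    sample_ids = [f"{stage}d_S{j}" for j in range(n_samples)]
    samples = pd.DataFrame(
        {
            "stage": stage,
            "condition": list(conditions),
            "replicate": list(range(1, n_samples + 1)),
        },
        index=pd.Index(sample_ids, name="sample_id"),
    )
    if flags is None:
        flags = np.ones_like(intensities, dtype=int)
    return ExpressionDataset(
        intensities=pd.DataFrame(intensities, index=probe_ids, columns=sample_ids),
        flags=pd.DataFrame(np.asarray(flags, dtype=int), index=probe_ids, columns=sample_ids),
        samples=samples,
        spike_ids=spike_ids,
    )
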