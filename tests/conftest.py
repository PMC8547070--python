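import pytest

from fruitsplice.builder import build_high_quality_transcriptome
from fruitsplice.synthetic import STAGES, SimulationConfig, simulate_dataset


def replicate_columns(species: str) -> dict[str, list[str]]:
    return {st: [f"{species}_{st}_rep{r + 1}" for r in range(2)] for st in STAGES}


def build_species(bundle, species: str):
    data = bundle.species[species]
    return build_high_quality_transcriptome(
        data.assembled,
        data.reference,
        data.junctions,
        data.expression,
        replicate_columns(species),
    )


@pytest.fixture(scope="session")
def noiseless_bundle():
    """Default study design, zero replicate noise: PSI is exactly recoverable."""
    cfg = SimulationConfig(seed=1, psi_noise_sd=0.0)
    return simulate_dataset(cfg)


@pytest.fixture(scope="session")
def built_transcriptomes(noiseless_bundle):
    bundle, _ = noiseless_bundle
    return {sp: build_species(bundle, sp) for sp in bundle.species}
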