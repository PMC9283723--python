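import numpy as np
import pytest

from cypselect.config import PipelineConfig, SOMSpec, SyntheticSpec, TitrationSpec
from cypselect.synthetic import PlateSpec


@pytest.fixture(scope="session")
def titration() -> np.ndarray:
    """Default 11-point titration, 3.5 nM - 58 µM."""
    return TitrationSpec().concentrations()


@pytest.fixture
def clean_plate_spec() -> PlateSpec:
    """384-well noise-free plate spec for exact-arithmetic tests."""
    return PlateSpec(
        n_rows=16,
        n_cols=24,
        concentration_series=np.geomspace(0.0035, 58.0, 11),
        n_dmso_cols=1,
        n_pos_cols=1,
        noise_cv=0.0,
    )


@pytest.fixture
def small_config() -> PipelineConfig:
    """Desk-scale pipeline config used by the end-to-end tests."""
    return PipelineConfig(
        synthetic=SyntheticSpec(
            n_compounds=40,
            n_clusters=4,
            n_fingerprint_bits=128,
            wells_per_plate_rows=16,
            wells_per_plate_cols=24,
        ),
        som=SOMSpec(rows=2, cols=2, epochs=3),
        seed=11,
    )
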