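import numpy as np
import pytest

from poreqc import PoreGeometry, RunConfig, SimSpec, default_mock_species


@pytest.fixture
def run_config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def mock_spec_factory():
    """Factory for the standard 120/100/100 pM three-species mock."""

    def make(
        duration_s: float = 1800.0,
        seed: int = 0,
        d_tip_nm: float | None = None,
        target_pM: float = 120.0,
        **overrides,
    ) -> SimSpec:
        pore = (
            PoreGeometry(d_tip_nm, 20.0, half_cone_angle_deg=5.0)
            if d_tip_nm is not None
            else None
        )
        return SimSpec(
            species=default_mock_species(target_pM=target_pM),
            duration_s=duration_s,
            pore=pore,
            seed=seed,
            **overrides,
        )

    return make


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
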