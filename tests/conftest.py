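import numpy as np
import pytest

from quenchbind.synthetic import SimulationConfig, simulate_titration

#: per-temperature summary values of the lactoferrin-chlorogenic acid
#: titration (K_A on the 1e4 L/mol scale that reproduces the dG column)
PUBLISHED_THERMO = {
    "temperatures": (290.0, 300.0, 310.0),
    "ksv": (7.11e4, 7.21e4, 7.44e4),
    "kq": (7.11e12, 7.21e12, 7.44e12),
    "ka": (5.29e4, 5.19e4, 5.10e4),
    "n": (1.19, 1.20, 1.22),
    "delta_h_kj": -1.35,
    "delta_s": 85.79,
    "delta_g_kj": (-26.23, -27.09, -27.94),
}


@pytest.fixture(scope="session")
def published_thermo():
    return PUBLISHED_THERMO


@pytest.fixture(scope="session")
def noiseless_sim():
    """Zero-noise, no-IFE synthetic dataset (the inverse-crime oracle)."""
    return simulate_titration(SimulationConfig(noise_sd=0.0, seed=0))


@pytest.fixture(scope="session")
def noiseless_ife_sim():
    """Zero-noise dataset with inner-filter attenuation from ligand absorptivities."""
    return simulate_titration(
        SimulationConfig(noise_sd=0.0, eps_ex=2000.0, eps_em=500.0, seed=0)
    )


@pytest.fixture
def titration_csv(tmp_path, noiseless_sim):
    from quenchbind.data_model_io import titration_to_frame

    path = tmp_path / "titration.csv"
    titration_to_frame(noiseless_sim.series).to_csv(path, index=False)
    return path
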