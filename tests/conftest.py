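import numpy as np
import pytest

import ribosec as rs


@pytest.fixture(scope="session")
def panel() -> rs.PanelResult:
    """Two-condition archetype panel shared across tests (fixed seed)."""
    return rs.make_archetype_panel(seed=0)


@pytest.fixture(scope="session")
def panel_df(panel):
    """Site assignments for every panel sample, default 12-nt offsets."""
    return panel.assignment_table()


def run_simulation(genes, seed=1, **global_params):
    """Simulate a transcriptome + one footprint library from one rng."""
    params = rs.SimParams(genes=tuple(genes), seed=seed, **global_params)
    rng = np.random.default_rng(seed)
    annotations, sequences = rs.simulate_transcriptome(params, rng)
    result = rs.simulate_footprints(annotations, params, rng,
                                    sequences=sequences)
    return annotations, result


@pytest.fixture(scope="session")
def calibration_sim():
    """Deep library for offset calibration: 20 genes, 10% 5'-end jitter."""
    genes = [rs.GeneParams(f"G{i}", 150,
                           70 if i % 2 else None,
                           base_density=60.0, readthrough=0.8)
             for i in range(20)]
    return run_simulation(genes, seed=1, jitter=0.10)
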