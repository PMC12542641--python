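import numpy as np
import pytest

from tierminer import synthetic_data as syn


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def panel():
    return syn.make_reference_panel(np.random.default_rng(7))


@pytest.fixture(scope="session")
def small_sim():
    """One deterministic simulation shared by read-only tests."""
    plants = [
        syn.PlantSpec(reference_id="REF_I_CDDP1", target_identity=95, add_terminal_itr=True),
        syn.PlantSpec(reference_id="REF_II_CDDP1", target_identity=97, paired_overlap_len=127),
        syn.PlantSpec(reference_id="REF_V_CDDP1", target_identity=70),
        syn.PlantSpec(reference_id="REF_IV_CDDP1", target_identity=40),
        syn.PlantSpec(
            reference_id="REF_V_COMP2", target_identity=95,
            ablate_first_motif=True, ablate_second_motif=True,
        ),
    ]
    cfg = syn.SimulationConfig(seed=11, n_samples=2, n_contigs_per_sample=2, planted_operons=plants)
    return syn.simulate_metagenome(cfg)
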