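import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import varmodnet as vm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def toy_cohort() -> vm.Cohort:
    """8 patients (4 cases) x 4 variants with mixed co-occurrence patterns."""
    carriers = np.array(
        [
            # v1 v2 v3 v4
            [1, 1, 0, 0],  # case
            [1, 1, 0, 1],  # case
            [0, 1, 1, 0],  # case
            [1, 0, 0, 0],  # case
            [1, 0, 1, 0],  # control
            [0, 0, 1, 1],  # control
            [0, 1, 1, 0],  # control
            [1, 0, 0, 1],  # control
        ],
        dtype=np.uint8,
    )
    phenotype = np.array([1, 1, 1, 1, 0, 0, 0, 0], dtype=np.uint8)
    return vm.Cohort(
        patients=[f"P{i+1}" for i in range(8)],
        variants=["v1", "v2", "v3", "v4"],
        carriers=carriers,
        phenotype=phenotype,
    )


@pytest.fixture
def strong_module_config() -> vm.SimulationConfig:
    """Strong planted module: 8 of 12 variants, 2,000 patients, 10% cases."""
    gene = "GENE1"
    module = vm.default_variant_names(gene, 12)[:8]
    spec = vm.PlantedModuleSpec(
        gene, module, p_active_case=0.6, p_active_control=0.05,
        q_carrier_active=0.9, q_background=0.02,
    )
    return vm.SimulationConfig(
        n_patients=2000, case_fraction=0.1, genes=[(gene, 12)], planted=[spec], seed=0
    )


def cluster_labels(candidates, order):
    """Integer labels over `order` induced by a candidate partition."""
    lab = np.zeros(len(order), dtype=int)
    for ci, cand in enumerate(candidates):
        for i, v in enumerate(order):
            if v in cand.variants:
                lab[i] = ci
    return lab
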