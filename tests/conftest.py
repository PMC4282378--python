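import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite", derandomize=True, deadline=None, max_examples=50,
    suppress_health_check=[HealthCheck.too_slow])
settings.load_profile("suite")

import snpsieve as sv  # noqa: E402


@pytest.fixture(scope="session")
def mixed_panel() -> sv.HaplotypePanel:
    """A mixed-LD synthetic panel at reference-panel depth."""
    return sv.generate_panel(
        sv.RegionProfile(n_snps=120, mean_block_kb=22.0, seed=11), 566)


@pytest.fixture(scope="session")
def cc_dataset(mixed_panel) -> sv.CaseControlData:
    """One balanced case-control replicate with a clear causal effect."""
    spec = sv.CausalSpec(target_maf=0.2, per_allele_or=1.5)
    return sv.simulate_case_control(mixed_panel, spec, 1000, seed=5)


@pytest.fixture(scope="session")
def scan_table(cc_dataset) -> sv.AssocTable:
    return sv.scan_region(cc_dataset)


@pytest.fixture(scope="session")
def ld_profile(cc_dataset, scan_table) -> sv.LdProfile:
    return sv.build_ld_profile(cc_dataset, scan_table, n_perm=99, seed=123)
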