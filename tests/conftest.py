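import logging

import numpy as np
import pytest

from epiarm.genome_model import assign_arms
from epiarm.scan import ScanData
from epiarm.simdata import SimConfig, SimOutput, simulate

# monomorphic-marker warnings are expected on small simulated panels
logging.getLogger("epiarm.kinship").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def tiny_sim() -> SimOutput:
    """Small 6-arm population with one injected interaction (1AS x 1BS)."""
    cfg = SimConfig(
        n_lines=120,
        markers_per_arm=30,
        n_environments=2,
        seed=7,
        interactions=(("1AS", "1BS", 0.3, "independent"),),
    )
    return simulate(cfg)


@pytest.fixture(scope="session")
def tiny_scan_data(tiny_sim) -> ScanData:
    return ScanData.from_tables(
        tiny_sim.geno, tiny_sim.marker_map, tiny_sim.centromeres, tiny_sim.pheno
    )


def share_kernels(template: ScanData, pheno) -> ScanData:
    """New ScanData over fresh phenotypes reusing the template's kernel caches."""
    d = ScanData(geno=template.geno, assignment=template.assignment, pheno=pheno)
    d._arm_kernels = template._arm_kernels
    d._backgrounds = template._backgrounds
    d._arm_parts = template._arm_parts
    return d
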