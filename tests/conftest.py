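import numpy as np
import pandas as pd
import pytest

from smrkit.ld_reference import compute_ld
from smrkit.simulate import SimScenario, simulate_locus
from smrkit.sumstats_io import harmonize


def locus_and_ld(scenario: SimScenario, seed=None):
    """Simulate one probe and return (HarmonizedLocus, LdMatrix)."""
    eq, gw, ref = simulate_locus(scenario, seed=seed)
    locus = harmonize(gw, eq, scenario.probe_id)
    ld = compute_ld(ref, locus.snps["snp_id"].tolist(),
                    dict(zip(locus.snps["snp_id"], locus.snps["a1"])))
    return locus, ld


#: small cohorts that still give a strong instrument; used where a test
#: needs one representative locus rather than a calibration study
FAST = dict(n_eqtl=2000, n_gwas=3000, n_ref=300, n_snps=20)


@pytest.fixture(scope="session")
def pleiotropy_locus():
    return locus_and_ld(SimScenario(model="pleiotropy", seed=42, **FAST))


@pytest.fixture(scope="session")
def causality_locus():
    return locus_and_ld(SimScenario(model="causality", seed=43, **FAST))


@pytest.fixture(scope="session")
def screen_fixture(tmp_path_factory):
    """A 20-probe multi-model fixture on disk: 5 strong instruments
    (2 causal, 2 pleiotropic, 1 linkage), 15 probes with eQTLs far too
    weak to qualify."""
    from smrkit.simulate import make_fixture

    cohorts = dict(n_eqtl=2000, n_gwas=4000, n_ref=300, n_snps=20)
    strong = [
        SimScenario(model="causality", probe_id="probeC1", gene="CAUS1",
                    b_xy_true=0.3, **cohorts),
        SimScenario(model="causality", probe_id="probeC2", gene="CAUS2",
                    b_xy_true=0.3, **cohorts),
        SimScenario(model="pleiotropy", probe_id="probeP1", gene="PLEI1",
                    b_zy_true=0.15, **cohorts),
        SimScenario(model="pleiotropy", probe_id="probeP2", gene="PLEI2",
                    b_zy_true=0.15, **cohorts),
        SimScenario(model="linkage", probe_id="probeL1", gene="LINK1",
                    b_zy_true=0.15, **cohorts),
    ]
    weak = [
        SimScenario(model="causality", probe_id=f"probeN{i}", gene=f"NULL{i}",
                    b_zx_true=0.02, b_xy_true=0.0, **cohorts)
        for i in range(15)
    ]
    out = tmp_path_factory.mktemp("screen_fixture")
    paths = make_fixture(strong + weak, out, seed=2024)
    return paths
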