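import numpy as np
import pytest

import geovar as gv


@pytest.fixture(scope="session")
def sim_spec() -> gv.SimSpec:
    return gv.SimSpec(n_variants=2000, seed=11)


@pytest.fixture(scope="session")
def sim_table(sim_spec):
    """Archetype-mixture table with per-variant ground-truth codes."""
    return gv.simulate_table(sim_spec)


@pytest.fixture(scope="session")
def sim_vcf_dir(sim_spec, tmp_path_factory):
    out = tmp_path_factory.mktemp("simvcf")
    vcf, panel, truth = gv.simulate_vcf(sim_spec, out)
    return {"vcf": vcf, "panel": panel, "truth": truth, "dir": out}


@pytest.fixture(scope="session")
def sim_freq_table(sim_vcf_dir):
    grouping = gv.read_panel(sim_vcf_dir["panel"])
    return gv.vcf_to_freq_table(sim_vcf_dir["vcf"], grouping)


def brute_force_code(freqs, threshold=0.05):
    """Scalar reference encoder used as the oracle for the vectorised path."""
    out = []
    for f in freqs:
        if f == 0:
            out.append("u")
        elif f <= threshold:
            out.append("R")
        else:
            out.append("C")
    return "".join(out)
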