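import numpy as np
import pandas as pd
import pytest

from shortadapt.genio import GenotypePanel


def make_panel(dosages, populations=None, positions=None, chrom="chr1"):
    """Small hand-built panel; dosages is a samples x sites array (-1 missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_samples, n_sites = dosages.shape
    ids = [f"s{i}" for i in range(n_samples)]
    if populations is None:
        populations = ["captive"] * (n_samples // 2) + ["wild"] * (n_samples - n_samples // 2)
    if positions is None:
        positions = [100 * (j + 1) for j in range(n_sites)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypePanel(
        sample_ids=ids,
        population=dict(zip(ids, populations)),
        sites=sites,
        genotypes=dosages,
    )


@pytest.fixture(scope="session")
def bn_panel():
    """Balding-Nichols panel at the default study conditions (seed 1)."""
    from shortadapt.simdata import SimulationConfig, simulate_two_pop_genotypes

    panel, _ = simulate_two_pop_genotypes(SimulationConfig(seed=1))
    return panel
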