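import numpy as np
import pytest

from extremoseq.burden import GenotypeMatrix
from extremoseq.cohort import CohortDesign
from extremoseq.synthio import SimulationConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast synthetic cohort: 20 genes x 2 sites, one strongly planted gene."""
    return SimulationConfig(
        n_extreme=40,
        n_control=40,
        n_genes=20,
        sites_per_gene=2,
        planted_genes=[["GENE001", 0.5, 0.05, 0.1]],
        missing_rate=0.0,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


def make_matrix(extreme_calls, control_calls, n_sites=1, quals=None):
    """Build a GenotypeMatrix + CohortDesign from per-sample call lists.

    ``extreme_calls`` / ``control_calls`` are lists of per-site call tuples
    (or single ints when n_sites == 1).
    """
    rows = []
    samples = []
    for tag, calls in (("E", extreme_calls), ("C", control_calls)):
        for i, c in enumerate(calls):
            samples.append(f"{tag}{i:03d}")
            rows.append((c,) if np.isscalar(c) else tuple(c))
    sites = [("1", 100 + j, "A", "T") for j in range(n_sites)]
    matrix = GenotypeMatrix(
        samples=samples,
        sites=sites,
        calls=np.array(rows, dtype=np.int8).reshape(len(samples), n_sites),
        quals=quals,
    )
    design = CohortDesign(
        tg_threshold=0.45,
        extreme_ids=[s for s in samples if s.startswith("E")],
        control_ids=[s for s in samples if s.startswith("C")],
    )
    return matrix, design
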