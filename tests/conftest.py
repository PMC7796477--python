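import numpy as np
import pandas as pd
import pytest

from methsig.containers import MethylationMatrix, ProbeAnnotation
from methsig.simulate import SimConfig, generate_cohort, generate_worked_fixture


@pytest.fixture(scope="session")
def default_cohort():
    """One default-scenario cohort bundle (seed 7)."""
    return generate_cohort(SimConfig(seed=7))


@pytest.fixture(scope="session")
def worked_fixture():
    """Tiny deterministic 12-sample cohort with a planted 3-gene signature."""
    return generate_worked_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture()
def small_annotation():
    """Hand-built annotation: 6 probes over 3 genes plus a body-only probe."""
    frame = pd.DataFrame(
        {
            "chrom": ["1", "1", "2", "2", "3", "3"],
            "pos": [100, 200, 100, 150, 100, 400],
            "arm": ["p", "p", "q", "q", "p", "p"],
            "genes": [("GA",), ("GA",), ("GB",), ("GB", "GC"), ("GC",), ("GC",)],
            "region_classes": [
                ("TSS200",), ("Body",), ("TSS1500",), ("5'UTR", "TSS200"),
                ("1stExon",), ("Body",),
            ],
            "relation_to_island": ["Island"] * 6,
        },
        index=pd.Index([f"cg{i}" for i in range(1, 7)], name="probe_id"),
    )
    return ProbeAnnotation(frame)


def make_matrix(beta_values, probes=None, samples=None) -> MethylationMatrix:
    beta = np.asarray(beta_values, dtype=float)
    probes = probes or [f"cg{i}" for i in range(1, beta.shape[0] + 1)]
    samples = samples or [f"S{j}" for j in range(1, beta.shape[1] + 1)]
    return MethylationMatrix.from_beta(
        pd.DataFrame(beta, index=pd.Index(probes, name="probe_id"),
                     columns=samples)
    )
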