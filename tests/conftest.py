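import numpy as np
import pandas as pd
import pytest

from replicade import StudyConfig, generate_study
from replicade.synthgen import null_config


def balanced_sheet(n_per_cell: int = 4, n_batches: int = 2,
                   region: str = "HIP") -> pd.DataFrame:
    """A balanced 2-line x 2-cohort sheet with batches nested in cohort."""
    rows = []
    i = 0
    for cohort in (1, 2):
        for line in ("FRL", "FSL"):
            for j in range(n_per_cell):
                i += 1
                rows.append({
                    "sample": f"s{i:02d}", "animal": f"a{i:02d}",
                    "line": line, "cohort": cohort,
                    "batch": f"c{cohort}_b{j % n_batches + 1}",
                    "region": region,
                })
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def small_study():
    """Seeded study at reduced probeset count, default effect structure."""
    return generate_study(StudyConfig(n_probesets=800, seed=11))


@pytest.fixture(scope="session")
def null_study():
    """Seeded study with no true line effects anywhere."""
    return generate_study(null_config(n_probesets=2000, seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(123)
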