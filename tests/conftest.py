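import numpy as np
import pandas as pd
import pytest

import qtlome as q
from qtlome.types import MarkerMap


@pytest.fixture(scope="session")
def mta_table():
    return q.datasets.load_mta_table()


@pytest.fixture(scope="session")
def mtaqtl_table():
    return q.datasets.load_mtaqtl_table()


@pytest.fixture(scope="session")
def mqtl_table():
    return q.datasets.load_mqtl_table()


@pytest.fixture(scope="session")
def qc_fixture():
    """Engineered 1149-marker matrix with 46/5/24 planted QC failures."""
    return q.gen_qc_fixture(1149, 46, 5, 24, seed=11)


@pytest.fixture(scope="session")
def small_population():
    """165 accessions x 400 markers in 5 subpopulations, light missingness."""
    cfg = q.SimulationConfig(n_accessions=165, n_markers=400, seed=7, missing_rate=0.02)
    mm = q.gen_marker_map(14, 30, 200, seed=7)
    G, sp = q.gen_structured_genotypes(mm, cfg)
    return mm, G, sp, cfg


@pytest.fixture
def toy_map():
    return MarkerMap(
        pd.DataFrame(
            {
                "marker": ["m1", "m2", "m3", "m4"],
                "chromosome": ["1A", "1A", "2B", "2B"],
                "position_cM": [10.0, 30.0, 5.0, 50.0],
            }
        )
    )


@pytest.fixture(scope="session")
def consensus_1chrom():
    return q.gen_marker_map(1, 50, 200, seed=1)
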