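import numpy as np
import pandas as pd
import pytest

from pigdiv import GenotypeMatrix, PanelConfig, simulate_panel


def make_gm(dosage, accession_ids=None, marker_ids=None, passport=None):
    """Build a GenotypeMatrix from a plain dosage array, one chromosome."""
    dosage = np.asarray(dosage, dtype=np.int8)
    n, m = dosage.shape
    accession_ids = accession_ids or [f"acc{i:03d}" for i in range(n)]
    marker_ids = marker_ids or [f"m{j:03d}" for j in range(m)]
    marker_map = pd.DataFrame(
        {"chromosome": "chr01", "position": np.arange(1, m + 1) * 1000,
         "ref_allele": "A", "alt_allele": "G"},
        index=pd.Index(marker_ids, name="marker_id"),
    )
    return GenotypeMatrix(accession_ids, marker_ids, dosage, marker_map, passport)


@pytest.fixture
def gm_factory():
    return make_gm


@pytest.fixture(scope="session")
def two_group_panel():
    """Small structured panel: two diverged inbred groups, no missingness."""
    cfg = PanelConfig(
        n_markers=400, n_chromosomes=4,
        group_spec=(("indica", 40, 0.5), ("japonica", 40, 0.5)),
        selfing_generations=4, n_duplicates=0, missing_rate=0.0, rng_seed=11,
    )
    gm, truth = simulate_panel(cfg)
    return gm, truth


@pytest.fixture(scope="session")
def panmictic_panel():
    """Single unstructured Hardy–Weinberg group."""
    cfg = PanelConfig(
        n_markers=500, n_chromosomes=5, group_spec=(("pop", 100, 0.0),),
        selfing_generations=0, missing_rate=0.0, rng_seed=5,
    )
    gm, truth = simulate_panel(cfg)
    return gm, truth
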