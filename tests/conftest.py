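import numpy as np
import pytest

from popkit import synthetic


@pytest.fixture(scope="session")
def reference_panel():
    """One shared synthetic continental reference panel (fixed seed).

    Five continental clusters in 26 sub-populations plus three target
    groups nested in the East-Asian-analogue cluster; 56 loci passing the
    ancestry-informative selection rule; 20 individuals per population.
    """
    return synthetic.make_reference_panel(preset="paper_like", seed=1)


@pytest.fixture(scope="session")
def panel_table(reference_panel):
    return reference_panel[0]


@pytest.fixture(scope="session")
def panel_freqs(reference_panel):
    return reference_panel[1]


@pytest.fixture()
def small_table():
    """Tiny hand-checkable table: 4 samples, 2 populations, 3 loci."""
    import pandas as pd

    from popkit.io import GenotypeTable, LocusInfo, MISSING

    geno = np.array(
        [
            [[1, 0], [0, 0], [1, 1]],
            [[1, 1], [MISSING, MISSING], [0, 0]],
            [[0, 0], [1, 0], [1, 0]],
            [[1, 0], [1, 1], [MISSING, MISSING]],
        ],
        dtype=np.int8,
    )
    return GenotypeTable(
        sample_ids=["S1", "S2", "S3", "S4"],
        population=["P1", "P1", "P2", "P2"],
        superpopulation=["X", "X", "Y", "Y"],
        loci=[LocusInfo("rs1", "1", 100), LocusInfo("rs2", "2", 200),
              LocusInfo("rs3", "3", 300)],
        genotypes=geno,
    )
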