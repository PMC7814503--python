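import numpy as np
import pytest

import envmeta as em

ENVS = em.synthetic_data.DEFAULT_ENVIRONMENTS


@pytest.fixture(scope="session")
def small_panel():
    """A 200-accession, 300-SNP structured panel with one strong shared QTL
    and a planted epistatic DTF pair; no missing calls for exactness tests."""
    cfg = em.SimConfig(
        n_accessions=200,
        n_snps=300,
        seed=11,
        missing_rate=0.0,
        ws_qtls=[em.QtlSpec(50, 8.0, tuple(ENVS))],
        epistasis=em.EpistasisSpec(locus1=120, locus2=220),
    )
    return em.simulate_panel(cfg)


@pytest.fixture(scope="session")
def tiny_genotypes():
    """Hand-built 4-SNP x 3-accession matrix with one missing call and one
    unplaced SNP."""
    snps = [
        em.SnpRecord("s1", "1H", 100, ("A", "C")),
        em.SnpRecord("s2", "1H", 2000, ("G", "T")),
        em.SnpRecord("s3", "2H", 500, ("A", "G")),
        em.SnpRecord("s4", "2H", None, ("C", "T")),
    ]
    calls = np.array(
        [
            [0, 1, 2],
            [2, em.MISSING, 0],
            [1, 1, 0],
            [0, 2, 2],
        ],
        dtype=np.int16,
    )
    return em.GenotypeMatrix(accessions=["a1", "a2", "a3"], snps=snps, calls=calls)
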