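import numpy as np
import pandas as pd
import pytest

from translatome.synthetic import SimulationConfig, generate_transcriptome


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    return SimulationConfig(seed=11, n_genes=20, cds_codons_range=(30, 80),
                            reads_per_sample=5000)


@pytest.fixture(scope="session")
def small_transcriptome(small_config):
    return generate_transcriptome(small_config)


@pytest.fixture()
def toy_model() -> pd.DataFrame:
    """One 90-nt transcript: 30 nt 5'UTR, 10-codon CDS, 30 nt 3'UTR."""
    return pd.DataFrame([
        {"transcript_id": "T1", "length": 90, "cds_start": 30, "cds_end": 60},
    ])


@pytest.fixture()
def toy_sequence() -> dict[str, str]:
    # CDS codons: ATG GAA GCT GCC CTG AAA GGA TTC GAT TAA
    cds = "ATGGAAGCTGCCCTGAAAGGATTCGATTAA"
    rng = np.random.default_rng(5)
    nt = np.array(list("ACGT"))
    utr5 = "".join(nt[rng.integers(0, 4, 30)])
    utr3 = "".join(nt[rng.integers(0, 4, 30)])
    return {"T1": utr5 + cds + utr3}
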