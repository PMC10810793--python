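import numpy as np
import pandas as pd
import pytest

from mglkit.datatypes import ExpressionMatrix


@pytest.fixture
def toy_tpm():
    """Small TPM matrix exercising the gene-prefix and median filters."""
    values = pd.DataFrame(
        {
            "S1": [5.0, 3.0, 0.5, 1.0, 12.0, 0.0],
            "S2": [6.0, 2.0, 0.9, 1.0, 9.0, 0.0],
            "S3": [4.0, 2.5, 2.0, 0.0, 10.0, 0.0],
        },
        index=["RPL7", "MT-ND1", "P2RY12", "TREM2", "ABCA1", "SALL1"],
    )
    return ExpressionMatrix(values, space="TPM")


@pytest.fixture
def toy_meta():
    return pd.DataFrame(
        {
            "sample_id": ["S1", "S2", "S3"],
            "source": ["exvivo", "exvivo", "imgl"],
            "batch": ["b1", "b1", "b1"],
            "total_reads": [20_000_000, 15_000_000, 30_000_000],
            "alignment_rate": [0.9, 0.8, 0.85],
            "duplicate_fraction": [0.2, 0.3, 0.1],
            "paired_end": [True, True, False],
        }
    )
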