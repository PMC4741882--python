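import numpy as np
import pandas as pd
import pytest

from hervh_crc import qpcr_quant, synthetic_cohort
from hervh_crc.synthetic_cohort import CohortConfig, generate_cohort

CEILINGS = {"rostock": 33.0, "reims": 32.0}
HOUSEKEEPING = ["G6PD", "GAPDH", "HPRT"]
TARGETS = ["X00041_h_gag", "2000045_h", "500502_h", "1400035_h",
           "1300360_h_gag"]


@pytest.fixture(scope="session")
def cohort():
    """Default two-center paired cohort at the canonical seed."""
    ct, annotations, truth = generate_cohort(CohortConfig(seed=0))
    return ct, annotations, truth


@pytest.fixture(scope="session")
def expression(cohort):
    ct, annotations, _ = cohort
    return qpcr_quant.quantify(ct, annotations, CEILINGS, HOUSEKEEPING)


def small_annotations(samples, tissue_classes, cohort="reims"):
    """Minimal annotation frame for hand-built tables."""
    return pd.DataFrame(
        {"patient": [s.rsplit("_", 1)[0] for s in samples],
         "tissue_class": tissue_classes,
         "organ": "colon", "cohort": cohort,
         "msi_status": "unknown", "n_status": "unknown"},
        index=pd.Index(samples, name="sample"))
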