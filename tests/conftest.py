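import numpy as np
import pandas as pd
import pytest

from albh3 import ProteomicsSimConfig, SimConfig
from albh3.simulate import PatientLatent


@pytest.fixture
def latent():
    return PatientLatent(
        patient_id="P1",
        priming_theta=0.8,
        dep_bcl2=0.7,
        dep_bclxl=0.1,
        dep_mcl1=0.6,
    )


@pytest.fixture
def small_config():
    """Plate-sized settings for fast unit tests."""
    return SimConfig(
        seed=11,
        n_patients=6,
        events_per_well=800,
        n_naive=3,
        proteomics=ProteomicsSimConfig(n_proteins=80),
    )


def make_event_table(
    cd38, cd138, kappa=None, lam=None, cytc=None, **meta
) -> pd.DataFrame:
    """Hand-built tidy event table with sensible metadata defaults."""
    n = len(cd38)
    kappa = kappa if kappa is not None else [20.0] * n
    lam = lam if lam is not None else [300.0] * n
    cytc = cytc if cytc is not None else [400.0] * n
    base = {
        "sample_id": meta.get("sample_id", "S1"),
        "well_id": meta.get("well_id", "W1"),
        "condition": meta.get("condition", "BIM"),
        "dose": meta.get("dose", 1.0),
        "control_type": meta.get("control_type", "none"),
    }
    return pd.DataFrame(
        {
            **{k: [v] * n for k, v in base.items()},
            "CD38": np.asarray(cd38, float),
            "CD138": np.asarray(cd138, float),
            "kappa": np.asarray(kappa, float),
            "lambda": np.asarray(lam, float),
            "cytc": np.asarray(cytc, float),
        }
    )
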