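import logging

import numpy as np
import pandas as pd
import pytest

from dyadnet.core_data import SampleMetadata, TaxaTable

logging.getLogger("dyadnet").setLevel(logging.ERROR)


@pytest.fixture
def small_table() -> TaxaTable:
    return TaxaTable(
        kingdom="bacteria",
        taxa_ids=["t1", "t2", "t3"],
        sample_ids=["s1", "s2"],
        counts=np.array([[0, 5], [2, 0], [1, 1]], dtype=float),
    )


def make_metadata(sample_ids, dyad_ids, sample_types, **extra) -> SampleMetadata:
    n = len(sample_ids)
    frame = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "subject_id": [f"subj_{d}_{t}" for d, t in zip(dyad_ids, sample_types)],
            "dyad_id": dyad_ids,
            "sample_type": sample_types,
            "birth_mode": extra.pop("birth_mode", ["vaginal"] * n),
            "prenatal_abx": extra.pop("prenatal_abx", [False] * n),
            "perinatal_abx": extra.pop("perinatal_abx", [False] * n),
            "maternal_postpartum_abx": extra.pop("maternal_postpartum_abx",
                                                 [False] * n),
            "infant_postnatal_abx": extra.pop("infant_postnatal_abx", [False] * n),
            **extra,
        }
    )
    return SampleMetadata(frame)


@pytest.fixture
def tiny_meta(small_table) -> SampleMetadata:
    return make_metadata(["s1", "s2"], ["D1", "D2"], ["milk", "milk"])
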